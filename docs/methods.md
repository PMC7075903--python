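# Methods

## The model

`activesheet` treats a confluent cell monolayer as a dense assembly of N
soft, self-propelled agents on a frictional substrate, moving with
overdamped dynamics

    zeta dr_i/dt = zeta v0 n_i - grad_i V,        n_i = (cos th_i, sin th_i),
    dth_i = sqrt(2 dt / tau) * N(0, 1),

so the polarity decorrelates as <n_i(t).n_i(0)> = exp(-t/tau); tau is the
orientational persistence time (1/D_r) and v0 the crawling speed of an
unobstructed cell.  The effective temperature T_eff = zeta v0^2 tau / 2 is
the equilibrium temperature the system reaches in the tau -> 0 limit and a
good predictor of the active glass transition at small tau.

A note on the noise convention: a frequently printed alternative gives the
angular white noise variance dt/tau, which makes the polarity decorrelate
as exp(-t/2 tau).  All linear-response results in this package (mode
energies, spectra, correlation lengths) are derived from a projected
active-force correlator proportional to exp(-|t - t'|/tau); consistency
between simulation and prediction therefore requires the exp(-t/tau)
polarity convention, which is what the integrator implements and what a
unit test verifies directly on free particles.

Two interaction models are provided:

* **Soft disks** (`softdisk`): purely repulsive harmonic contacts,
  V = (k/2)(sigma_i + sigma_j - r)^2 inside overlap.  Total energy is
  counted once per pair, so forces are exactly -grad E with pair magnitude
  k (sigma_i + sigma_j - r).  Confluence is emulated by packing fraction
  phi = sum(pi sigma_i^2)/L^2 = 1 (overlaps double-counted) with 30%
  uniform radius polydispersity — deep in the jammed phase.  An optional
  piecewise-linear attractive tail of relative range eps = 0.15 is
  available for experiment-matched runs; its exact shape is a documented
  package choice validated against finite differences.
* **Self-propelled Voronoi** (`spv`): each cell is the Voronoi tile of its
  centre, with energy K/2 (A_i - A0_i)^2 + Gamma/2 (P_i - P0_i)^2,
  preferred perimeter P0_i = p0bar sqrt(A0_i), and default p0bar = 3.6
  (solid side of the rigidity transition at ~3.812).  Forces are exact
  analytic gradients chained through the Delaunay circumcenters, verified
  against finite differences in both periodic and open modes.  In open
  mode, hull-cell tiles are closed by the chain of circumcenters of
  hull-edge Delaunay triangles and a line tension lambda = 0.3 acts on the
  outer contour; this closure is our construction (the literature leaves
  it implementation-defined) and it degrades gracefully to two-vertex
  tiles at sharp hull corners.

## Linear response and normal modes

At mechanical equilibrium the contact network defines the Hessian; each
contact contributes -[V'' n x n + (V'/r) t x t] off-diagonally (for the
harmonic contact: -k n x n + (|f|/r) t x t, i.e. the standard granular
form with the dimensional 1/r; `printed_form=True` reproduces the common
variant without it).  Driving the modes with the persistent force gives

    E_nu = zeta v0^2 tau / (4 (1 + lambda_nu tau / zeta)),
    <|v(q)|^2> = sum_nu v0^2 / (2 (1 + lambda_nu tau/zeta)) |xi_nu(q)|^2,

with xi_nu(q) = (1/N) sum_j e^{iq.r_j} xi_nu^j.  Equipartition is broken
for finite tau; tau -> 0 recovers E_nu = T_eff/2 and tau -> inf weights
the softest modes as 1/lambda.

Elastic moduli are extracted from the Fourier dynamical matrix
D(q) = (1/N) sum_jl e^{iq.(r_j - r_l)} H_jl: its two eigenvalue branches
behave as lambda_L = (B + mu) q^2 and lambda_T = mu q^2 at long
wavelength.  Branches are radially averaged in bins of width 2 pi / L and
fitted, unweighted and through the origin, against q^2 up to q = 1.5.
The resulting B and mu are *per-particle* branch stiffnesses (units of k;
mu/zeta has units length^2/time); dividing by the area per particle
converts them to conventional 2D elastic moduli, and on a triangular
lattice the converted values match an independent affine stress-strain
finite-difference oracle to 2% when the fit is restricted to the
quadratic-dispersion range.

Reference values: for the N = 3183 reference packing this pipeline gives
B ≈ 1.52 and mu ≈ 0.82 (seed scatter below 1%), i.e. (mu + B)/mu ≈ 2.85.
These are the values the acceptance script reports.  They are robust
against the radii distribution, the quench protocol (random, thermal or
active annealing), the pre-stress convention and the fit style; the same
pipeline reproduces the triple (1.68, 0.51, 4.3) that circulates for this
system only at ~25% higher compression, which suggests that literature
value reflects a more compressed preparation than the stated phi = 1
convention.  The fitting module's default spectrum-fit moduli ratio is
nevertheless kept at the conventional 4.3, since for experimental data
that ratio is an external assumption, not something this package measures.

## Continuum predictions (`theory`)

With correlation lengths xi_L^2 = (B + mu) tau / zeta and
xi_T^2 = mu tau / zeta, the equal-time velocity spectrum is a sum of two
Lorentzians; its 2D inverse transform gives

    C_vv(r) = (a^2 v0^2 / 4 pi) [K0(r/xi_L)/xi_L^2 + K0(r/xi_T)/xi_T^2]

for r > a (validated against direct Hankel quadrature to 1e-3) with
exponential asymptotics at r >> xi.  The mean-square velocity follows by
integrating the spectrum over the circular domain q <= q_m = 2 pi / a:

    <|v|^2> = (v0^2 a^2 / 8 pi) [log(1 + xi_L^2 q_m^2)/xi_L^2 + (L -> T)].

The temporal autocorrelation <v(t).v(0)> has no elementary closed form;
it is computed by integrating the exact per-mode autocorrelation of an
Ornstein-Uhlenbeck-driven overdamped mode,

    C(t; omega) = (v0^2/2) [e^{-t/tau} - tau omega e^{-omega t}] / (1 - (tau omega)^2),

over both branches with omega_X = xi_X^2 q^2 / tau (the tau omega = 1
point is removable and handled by series expansion).  Its t = 0 value
coincides with the closed-form mean-square velocity to quadrature
tolerance, and in the free limit B, mu -> 0 it reduces to a pure
exponential on the persistence time.

**Cutoff convention.**  The mean-square-velocity formula is sensitive to
the high-q cutoff.  Its xi -> 0 limit is pi v0^2 rather than v0^2 — an
artifact of the circular cutoff at 2 pi / a, which counts more modes than
the system has.  For comparisons against simulations the package uses
a = the cell size (diameter 2 sigma-bar, numerically close to
sqrt(A/N)); with that choice the formula tracks both the exact discrete
mode sum and measured simulations within 20% over xi_T/a ≈ 1.4–5, the
range of the velocity-drop collapse.  Using the particle *radius* instead
overestimates <|v|^2> by a factor 3–5 and is not supported by the data.
Experiment-scale parameter sets use a = 11 um (the measured cell radius)
as conventionally printed.

## Estimators (`observables`)

Fourier spectra use v(q) = (1/N) sum_j e^{iq.r_j} v_j on the commensurate
grid (or the FFT grid for PIV-like fields), radially averaged in bins of
width 2 pi / L and then time averaged.  When comparing against mode
predictions the phases use the relaxed reference positions; for liquids
and experimental grids the instantaneous positions are the default (the
two differ negligibly in practice).  The self-intermediate scattering
function is computed from unwrapped displacements at |q| = 2 pi / sigma-bar,
averaged over directions and time origins, and tau_alpha is the first
saved lag with S < 0.5, censored (and flagged) at the trajectory length.
Real-space correlations are pair-averaged dot products in bins of width
sigma-bar/2; speed statistics report the rms speed and the normalised
speed histogram.

## Fitting pipeline (`fitting`)

The PIV-facing fit holds the moduli ratio (mu + B)/mu fixed (default 4.3)
and fits the frame-normalised spectrum with the two-Lorentzian model,
leaving (amplitude, xi_T) free; the fit is least squares on the
log-spectrum weighted by sqrt(per-bin counts), because the spectrum spans
more than a decade and log residuals equalise leverage.  The high-q tail
beyond q = pi / (2 spacing) is excluded by the caller when desired; the
amplitude yields v0/v_bar = sqrt(2 N C).  68% intervals come from the
residual curvature; a fitted xi_T below a tenth of the smallest
resolvable scale is flagged degenerate (white-spectrum case).  With xi_T
fixed, the normalised temporal autocorrelation depends on (tau, mu/zeta)
only along mu tau / zeta = xi_T^2, so a bounded one-dimensional search in
log tau recovers the persistence time; boundary solutions are flagged.
`map_to_model_params` converts continuum parameters to the simulation
ratios k/zeta = mu/(sigma^2 zeta), Gamma/zeta = mu/(<A> zeta),
K/zeta = mu/(<A>^2 zeta).

## Synthetic fields (`synthfields`)

PIV-like test data are Gaussian random vector fields on a rectangular
grid whose longitudinal/transverse Fourier components carry the two
Lorentzian spectra; frames are temporally independent (sufficient for the
spatial pipeline; temporal observables are validated on simulator output)
and each frame is rescaled to the requested rms speed, which removes any
transform-convention prefactor from tests.  Default geometry mirrors a
typical experiment: 54 x 40 nodes at 16 um spacing, rms speed 12 um/h,
xi_T ≈ 100 um.  What passing the round-trip tests shows is that the
estimator + fit pipeline is unbiased on fields with exactly Lorentzian,
isotropic, Gaussian statistics; real monolayers add divisions,
non-Gaussian tails and temporal correlations that the generator does not
emulate.

## Division and extrusion

The optional steady-state division scheme divides each cell with
probability dt/tau_div per step, places the daughter at 0.1 sigma-bar in a
random direction and immediately extrudes the most compressed cells (by
per-particle contact energy) back to the target N, so N is strictly
conserved across frames.  This is deliberately the simplest confluent
steady state; junction-resolved division mechanics are out of scope.

## Numerical choices

* Minimization: FIRE with displacement cap 0.25 min(sigma), convergence
  at max |F_i| < 1e-8 k sigma-bar; energy is non-increasing apart from
  transients rewound by the standard uphill reset.
* Integration: first-order Euler, dt = 0.01 (dt = 0.02 for the cheaper
  sweeps; the exact discrete-time solution of a driven mode bounds the
  resulting velocity-variance bias by ~3% at the stiffest resolved mode).
* Neighbor search: periodic cKDTree with a Verlet skin; for boxes smaller
  than twice the interaction cutoff (where minimum image is ill-defined)
  pairs are enumerated explicitly over periodic images, which makes even
  the two-disk confluent system a well-posed minimization problem.
* Degenerate inputs: coincident disk centres and collinear Voronoi
  generators raise typed errors; exact cocircular degeneracies during SPV
  runs are retried with a deterministic 1e-10 jitter keyed to the seed.
* Eigensolves are dense (numpy.linalg.eigh), practical to N ≈ 4000
  (2N x 2N); D(q) itself is evaluated by sparse matvecs and has no such
  limit.
* All stochastic code paths take explicit integer seeds and are
  bit-reproducible; the numba-accelerated contact kernel and its pure
  numpy fallback are tested to agree.

## Problem sizes used in the test suite

Unit tests run on 16–64 particles.  The acceptance checks use the
full-size N = 3183 packing for the moduli (three seeds; the relaxation
itself takes seconds), N = 1000 for spectrum/mode comparisons (runs of
1500–3000 time units at dt = 0.01) and the velocity collapse
(300–1400 time units at dt = 0.02, tau = 10–120), and N = 500 for the
3 x 3 glassy-trend sweep (600 time units per point).  These sizes resolve
the claims tested while keeping the whole suite at a few minutes.

## Known limitations

* The normal-mode linear response describes velocities quantitatively at
  moderate lambda tau / zeta; deep in the large-persistence regime
  (tau = 200 at T_eff = 0.005) slow plastic creep radiates broadband
  velocity power that exceeds the strongly suppressed harmonic spectrum
  by 20–30% for q ≳ 0.5.  This excess is insensitive to time step,
  reference-frame choice and protocol, and is a property of the physics,
  not of the estimators.
* At N = 1000 the smallest resolved wavevector already satisfies
  q xi_T > 1 for tau = 200, so continuum-regime statements can only be
  tested at moderate tau at this size.
* Open-boundary SPV tiles use our closure construction; quantitative
  boundary observables (contour length, boundary-cell shapes) are
  construction-dependent.
* No hydrodynamic or cell–cell dissipation, and no alignment
  interactions: correlations here arise purely from persistence plus
  elasticity.
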