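"""Polydisperse soft harmonic disks with overdamped active Brownian dynamics.

The monolayer is modelled as N soft disks in a periodic box. Disks i and j
interact only when they overlap, through the harmonic contact potential

    V(r) = (k/2) (sigma_i + sigma_j - r)^2,   r <= sigma_i + sigma_j,

optionally extended by a short piecewise-linear attractive tail (range
``(1 + eps)(sigma_i + sigma_j)``) for experiment-matched runs.  Total
potential energy is counted once per pair, so forces are exactly the
negative gradient of the reported energy, with pair force magnitude
k (sigma_i + sigma_j - r).

Each disk self-propels at speed v0 along a polarity n_i = (cos th_i, sin th_i)
whose angle diffuses freely; the persistence time tau is the decay time of
<n(t).n(0)> = exp(-t/tau), i.e. angular increments have variance 2 dt / tau.
Positions follow first-order overdamped dynamics

    zeta dr_i/dt = zeta v0 n_i + F_i.

Natural units throughout: k = 1, zeta = 1 and mean radius 1 set the energy,
time and length scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateContactError, NonConvergenceError, UnstableStepWarning

try:  # pragma: no cover - exercised implicitly wherever numba is installed
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SoftDiskConfig",
    "ActiveDriveState",
    "Trajectory",
    "generate_packing",
    "energy_and_forces",
    "relax_to_minimum",
    "step_active",
    "run_trajectory",
    "divide_and_extrude",
]


# --------------------------------------------------------------------------
# domain types


@dataclass
class SoftDiskConfig:
    """Mechanical state of the soft-disk model.

    Parameters
    ----------
    positions : (N, 2) array
        Particle centers, wrapped into the box on construction.
    radii : (N,) array
        Per-particle radii sigma_i > 0.
    box : float or (2,) array
        Periodic box edge length(s); a scalar means a square box.
    stiffness : float
        Contact stiffness k (energy / length^2).
    friction : float
        Substrate friction zeta (force * time / length).
    attraction_eps : float
        Relative range of the optional attractive tail (0 disables it).
    """

    positions: np.ndarray
    radii: np.ndarray
    box: np.ndarray
    stiffness: float = 1.0
    friction: float = 1.0
    attraction_eps: float = 0.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float)).copy()
        self.radii = np.asarray(self.radii, dtype=float).copy()
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 0:
            box = np.array([float(box), float(box)])
        self.box = box
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.n < 2:
            raise ValueError("need at least 2 particles")
        if self.radii.shape != (self.n,):
            raise ValueError("radii must have shape (N,)")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.stiffness <= 0 or self.friction <= 0:
            raise ValueError("stiffness and friction must be positive")
        if not 0 <= self.attraction_eps < 1:
            raise ValueError("attraction_eps must be in [0, 1)")
        self.positions = wrap(self.positions, self.box)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def box_length(self) -> float:
        """Edge length of a square box (raises for rectangular boxes)."""
        if not np.isclose(self.box[0], self.box[1]):
            raise ValueError("box is rectangular; use .box")
        return float(self.box[0])

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))

    @property
    def packing_fraction(self) -> float:
        """phi = sum(pi sigma_i^2) / (Lx Ly); overlaps double-counted."""
        return float(np.sum(np.pi * self.radii**2) / np.prod(self.box))

    @property
    def interaction_cutoff(self) -> float:
        return float((1.0 + self.attraction_eps) * 2.0 * np.max(self.radii))

    def copy(self) -> "SoftDiskConfig":
        return replace(self, positions=self.positions.copy(), radii=self.radii.copy())


@dataclass
class ActiveDriveState:
    """Self-propulsion state: polarity angles, speed v0 and persistence tau.

    tau is the orientational persistence time: <n(t).n(0)> = exp(-t/tau).
    """

    angles: np.ndarray
    speed: float
    persistence: float

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float).copy()
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.speed < 0:
            raise ValueError("speed v0 must be >= 0")
        if self.persistence <= 0:
            raise ValueError("persistence tau must be > 0")

    @property
    def directions(self) -> np.ndarray:
        """Unit polarity vectors n_i, shape (N, 2)."""
        return np.column_stack([np.cos(self.angles), np.sin(self.angles)])

    def copy(self) -> "ActiveDriveState":
        return replace(self, angles=self.angles.copy())


@dataclass
class Trajectory:
    """Time series of simulation snapshots.

    positions are stored unwrapped (continuous across the periodic
    boundary) so that displacement-based observables are well defined;
    ``wrapped_positions`` folds them back into the box.
    """

    times: np.ndarray
    positions: np.ndarray  # (n_frames, N, 2), unwrapped
    velocities: np.ndarray  # (n_frames, N, 2)
    angles: np.ndarray  # (n_frames, N)
    box: np.ndarray
    radii: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.positions.shape[0] != len(self.times):
            raise ValueError("one frame per time stamp required")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    def wrapped_positions(self, frame: int) -> np.ndarray:
        return wrap(self.positions[frame], self.box)

    def after(self, t_min: float) -> "Trajectory":
        """Drop the initial transient: keep frames with t >= t_min."""
        keep = self.times >= t_min
        return Trajectory(
            self.times[keep],
            self.positions[keep],
            self.velocities[keep],
            self.angles[keep],
            self.box,
            self.radii,
            dict(self.metadata),
        )


# --------------------------------------------------------------------------
# geometry helpers


def wrap(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold positions into [0, box) componentwise."""
    out = np.mod(positions, box)
    # guard against out == box from floating-point roundoff
    return np.where(out >= box, 0.0, out)


def minimum_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    return dr - box * np.round(dr / box)


def neighbor_pairs(positions: np.ndarray, box: np.ndarray, cutoff: float):
    """Interacting pair candidates within `cutoff` in a periodic box.

    Returns ``(i, j, shifts)``: for the common case (cutoff < L/2) shifts
    is None and separations follow the minimum-image convention.  For
    boxes smaller than twice the cutoff, where minimum image is
    ill-defined, pairs are enumerated explicitly over periodic images and
    ``shifts`` holds the image displacement added to r_j (this includes a
    particle interacting with several images of the same neighbour, and
    with its own images when L < cutoff).
    """
    n = positions.shape[0]
    if cutoff < 0.5 * np.min(box):
        tree = cKDTree(wrap(positions, box), boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), None
        return pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64), None
    # tiny box: explicit image sums; each unordered interaction counted once
    n_img = int(np.ceil(cutoff / np.min(box)))
    iu, ju = np.triu_indices(n, k=1)  # o = 0: distinct pairs only
    io = np.repeat(np.arange(n), n)  # o > 0: all ordered pairs incl. self-image
    jo = np.tile(np.arange(n), n)
    out_i, out_j, out_s = [], [], []
    for ox in range(-n_img, n_img + 1):
        for oy in range(-n_img, n_img + 1):
            if (ox, oy) == (0, 0):
                ii, jj = iu, ju
            elif (ox, oy) > (0, 0):  # lexicographic half-space
                ii, jj = io, jo
            else:
                continue
            shift = np.array([ox * box[0], oy * box[1]])
            dr = positions[jj] + shift - positions[ii]
            keep = np.einsum("ij,ij->i", dr, dr) < cutoff**2
            out_i.append(ii[keep])
            out_j.append(jj[keep])
            out_s.append(np.broadcast_to(shift, (int(keep.sum()), 2)).copy())
    ii = np.concatenate(out_i).astype(np.int64)
    jj = np.concatenate(out_j).astype(np.int64)
    shifts = np.concatenate(out_s).astype(float)
    return ii, jj, shifts


class _PairList:
    """Verlet pair list with a skin; rebuilt when particles drift too far."""

    def __init__(self, config: SoftDiskConfig, skin: float = 0.4):
        self.skin = skin
        self.cutoff = config.interaction_cutoff
        self.box = config.box
        self.rebuild(config.positions)

    def rebuild(self, positions: np.ndarray):
        self.ref_positions = positions.copy()
        self.i, self.j, self.shifts = neighbor_pairs(
            positions, self.box, self.cutoff + self.skin
        )

    def update(self, positions: np.ndarray):
        disp = minimum_image(positions - self.ref_positions, self.box)
        if np.max(np.abs(disp)) > 0.5 * self.skin:
            self.rebuild(positions)


# --------------------------------------------------------------------------
# energy and forces

# Piecewise contact law (delta = sigsum - r, f = -dV/dr):
#   r <= sigsum                 : V = k delta^2 / 2 + c0,    f =  k delta
#   sigsum < r <= (1+e/2)sigsum : V = k (r-sigsum)^2/2 + c0, f = -k (r-sigsum)
#   (1+e/2)s < r < (1+e)sigsum  : V = -k (rf - r)^2 / 2,     f = -k (rf - r)
# with rf = (1+e) sigsum and c0 = -k (e sigsum / 2)^2 making V continuous.


def _pair_energy_force(r, sigsum, k, eps):
    """Vectorised pair energy and scalar force f = -dV/dr (f > 0 repulsive)."""
    energy = np.zeros_like(r)
    force = np.zeros_like(r)
    if eps == 0.0:
        overlap = r < sigsum
        delta = sigsum[overlap] - r[overlap]
        energy[overlap] = 0.5 * k * delta**2
        force[overlap] = k * delta
        return energy, force
    rf = (1.0 + eps) * sigsum
    rm = (1.0 + 0.5 * eps) * sigsum
    c0 = -k * (0.5 * eps * sigsum) ** 2
    core = r <= sigsum
    mid = (r > sigsum) & (r <= rm)
    tail = (r > rm) & (r < rf)
    energy[core] = 0.5 * k * (sigsum[core] - r[core]) ** 2 + c0[core]
    force[core] = k * (sigsum[core] - r[core])
    energy[mid] = 0.5 * k * (r[mid] - sigsum[mid]) ** 2 + c0[mid]
    force[mid] = -k * (r[mid] - sigsum[mid])
    energy[tail] = -0.5 * k * (rf[tail] - r[tail]) ** 2
    force[tail] = -k * (rf[tail] - r[tail])
    return energy, force


def _pair_stiffness(r, sigsum, k, eps):
    """Second derivative V''(r) on the same piecewise law."""
    vpp = np.zeros_like(r)
    if eps == 0.0:
        vpp[r < sigsum] = k
        return vpp
    rf = (1.0 + eps) * sigsum
    rm = (1.0 + 0.5 * eps) * sigsum
    vpp[r <= rm] = k
    vpp[(r > rm) & (r < rf)] = -k
    return vpp


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _forces_kernel(
        pos, sigsum_flat, ii, jj, k, eps, bx, by, sx, sy, min_image
    ):  # pragma: no cover
        n = pos.shape[0]
        fx = np.zeros(n)
        fy = np.zeros(n)
        energy = 0.0
        mindist = 1e300
        for p in range(ii.shape[0]):
            i = ii[p]
            j = jj[p]
            dx = pos[j, 0] + sx[p] - pos[i, 0]
            dy = pos[j, 1] + sy[p] - pos[i, 1]
            if min_image:
                dx -= bx * np.round(dx / bx)
                dy -= by * np.round(dy / by)
            r = np.sqrt(dx * dx + dy * dy)
            ss = sigsum_flat[p]
            rcut = (1.0 + eps) * ss
            if r >= rcut:
                continue
            if r < mindist:
                mindist = r
            if eps == 0.0:
                delta = ss - r
                energy += 0.5 * k * delta * delta
                f = k * delta
            else:
                rm = (1.0 + 0.5 * eps) * ss
                c0 = -k * (0.5 * eps * ss) ** 2
                if r <= ss:
                    delta = ss - r
                    energy += 0.5 * k * delta * delta + c0
                    f = k * delta
                elif r <= rm:
                    energy += 0.5 * k * (r - ss) ** 2 + c0
                    f = -k * (r - ss)
                else:
                    energy += -0.5 * k * (rcut - r) ** 2
                    f = -k * (rcut - r)
            if r < 1e-12:
                # signalled by caller through mindist
                continue
            ux = dx / r
            uy = dy / r
            fx[i] -= f * ux
            fy[i] -= f * uy
            fx[j] += f * ux
            fy[j] += f * uy
        return energy, fx, fy, mindist


def _energy_forces_pairs(config, ii, jj, shifts=None):
    """Energy and forces restricted to a candidate pair list."""
    pos, box = config.positions, config.box
    k, eps = config.stiffness, config.attraction_eps
    sigsum = config.radii[ii] + config.radii[jj]
    if _HAVE_NUMBA and ii.shape[0] > 0:
        if shifts is None:
            sx = sy = np.zeros(ii.shape[0])
            min_image_flag = True
        else:
            sx, sy = shifts[:, 0], shifts[:, 1]
            min_image_flag = False
        energy, fx, fy, mindist = _forces_kernel(
            pos, sigsum, ii, jj, k, eps, box[0], box[1], sx, sy, min_image_flag
        )
        if mindist < 1e-12:
            raise DegenerateContactError("coincident particle centers")
        return energy, np.column_stack([fx, fy])
    forces = np.zeros_like(pos)
    if ii.shape[0] == 0:
        return 0.0, forces
    if shifts is None:
        dr = minimum_image(pos[jj] - pos[ii], box)
    else:
        dr = pos[jj] + shifts - pos[ii]
    r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
    in_range = r < (1.0 + eps) * sigsum
    if np.any(r[in_range] < 1e-12):
        raise DegenerateContactError("coincident particle centers")
    ii, jj, dr, r, sigsum = (
        ii[in_range],
        jj[in_range],
        dr[in_range],
        r[in_range],
        sigsum[in_range],
    )
    energy, f = _pair_energy_force(r, sigsum, k, eps)
    fvec = (f / r)[:, None] * dr
    np.add.at(forces, ii, -fvec)
    np.add.at(forces, jj, fvec)
    return float(np.sum(energy)), forces


def energy_and_forces(config: SoftDiskConfig, pair_list: _PairList | None = None):
    """Total potential energy and per-particle forces.

    Energy is counted once per pair, so ``forces = -grad(energy)`` exactly
    and the pair force magnitude is k (sigma_i + sigma_j - r) at overlap.
    Newton's third law holds pairwise and the total internal force vanishes.
    """
    if pair_list is None:
        ii, jj, shifts = neighbor_pairs(
            config.positions, config.box, config.interaction_cutoff
        )
    else:
        ii, jj, shifts = pair_list.i, pair_list.j, pair_list.shifts
    return _energy_forces_pairs(config, ii, jj, shifts)


def contact_list(config: SoftDiskConfig):
    """Interacting pairs with geometry, for Hessian assembly and diagnostics.

    Returns (i, j, r, sigsum, unit vectors n_ij) for pairs inside the
    interaction range.  Self-image pairs (possible in very small boxes)
    are dropped: their separation does not vary with the particle
    coordinates, so they contribute neither forces nor curvature.
    """
    ii, jj, shifts = neighbor_pairs(
        config.positions, config.box, config.interaction_cutoff
    )
    if shifts is None:
        dr = minimum_image(config.positions[jj] - config.positions[ii], config.box)
    else:
        dr = config.positions[jj] + shifts - config.positions[ii]
    distinct = ii != jj
    ii, jj, dr = ii[distinct], jj[distinct], dr[distinct]
    r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
    sigsum = config.radii[ii] + config.radii[jj]
    keep = r < (1.0 + config.attraction_eps) * sigsum
    if np.any(r[keep] < 1e-12):
        raise DegenerateContactError("coincident particle centers")
    ii, jj, dr, r, sigsum = ii[keep], jj[keep], dr[keep], r[keep], sigsum[keep]
    nhat = dr / r[:, None]
    return ii, jj, r, sigsum, nhat


def per_particle_energy(config: SoftDiskConfig) -> np.ndarray:
    """Half of each pair energy assigned to both members (compression proxy)."""
    ii, jj, r, sigsum, _ = contact_list(config)
    energy, _f = _pair_energy_force(
        r, sigsum, config.stiffness, config.attraction_eps
    )
    out = np.zeros(config.n)
    np.add.at(out, ii, 0.5 * energy)
    np.add.at(out, jj, 0.5 * energy)
    return out


# --------------------------------------------------------------------------
# packing generation and minimization


def generate_packing(
    n_particles: int,
    packing_fraction: float = 1.0,
    polydispersity: float = 0.3,
    seed: int = 0,
    stiffness: float = 1.0,
    friction: float = 1.0,
    mean_radius: float = 1.0,
    relax: bool = True,
    tolerance: float = 1e-8,
) -> SoftDiskConfig:
    """Random polydisperse packing at the requested packing fraction.

    Radii are uniform on ``mean_radius * [1 - w, 1 + w]`` with
    ``w = polydispersity``; the square box edge solves
    ``sum(pi sigma_i^2) / L^2 = packing_fraction`` (overlaps double-counted).
    Positions start uniformly at random and, if ``relax`` is set, are
    steepest-descended into a mechanically stable minimum.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    if packing_fraction <= 0:
        raise ValueError("packing_fraction must be positive")
    if not 0 <= polydispersity < 1:
        raise ValueError("polydispersity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    radii = mean_radius * rng.uniform(
        1.0 - polydispersity, 1.0 + polydispersity, size=n_particles
    )
    length = np.sqrt(np.sum(np.pi * radii**2) / packing_fraction)
    positions = rng.uniform(0.0, length, size=(n_particles, 2))
    config = SoftDiskConfig(
        positions, radii, length, stiffness=stiffness, friction=friction
    )
    if relax:
        config = relax_to_minimum(config, tolerance=tolerance)
    return config


def max_residual_force(config: SoftDiskConfig) -> float:
    _, forces = energy_and_forces(config)
    return float(np.max(np.linalg.norm(forces, axis=1)))


def relax_to_minimum(
    config: SoftDiskConfig,
    tolerance: float = 1e-8,
    max_iter: int = 500_000,
    dt_start: float = 0.02,
    dt_max: float = 0.15,
) -> SoftDiskConfig:
    """FIRE descent to a mechanical equilibrium (max |F_i| < tolerance).

    Inertial overdamped descent with adaptive time step; energy is
    non-increasing apart from transients that are rewound by the standard
    uphill reset.  Raises NonConvergenceError (carrying the final residual)
    if the iteration cap is reached.
    """
    n_min, f_inc, f_dec, alpha0, f_alpha = 5, 1.1, 0.5, 0.1, 0.99
    config = config.copy()
    pos = config.positions
    vel = np.zeros_like(pos)
    pairs = _PairList(config)
    dt, alpha, since_neg = dt_start, alpha0, 0
    for _ in range(max_iter):
        config.positions = pos
        pairs.update(pos)
        _, forces = _energy_forces_pairs(config, pairs.i, pairs.j, pairs.shifts)
        fmax = np.max(np.linalg.norm(forces, axis=1)) if config.n else 0.0
        if fmax < tolerance:
            config.positions = wrap(pos, config.box)
            return config
        power = float(np.sum(vel * forces))
        if power > 0:
            vnorm = np.linalg.norm(vel)
            fnorm = np.linalg.norm(forces)
            if fnorm > 0:
                vel = (1.0 - alpha) * vel + alpha * (vnorm / fnorm) * forces
            since_neg += 1
            if since_neg > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            vel[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            since_neg = 0
        vel = vel + dt * forces
        step = dt * vel
        # cap single-step displacement at a fraction of the smallest radius
        smax = np.max(np.abs(step))
        cap = 0.25 * np.min(config.radii)
        if smax > cap:
            step *= cap / smax
        pos = pos + step
    config.positions = wrap(pos, config.box)
    raise NonConvergenceError(
        f"FIRE did not reach tolerance {tolerance:g} in {max_iter} iterations "
        f"(residual {fmax:g})",
        residual=fmax,
    )


# --------------------------------------------------------------------------
# active dynamics


def _advance(config, drive, dt, n_steps, rng, pairs, pos_unwrapped):
    """In-place first-order integration over n_steps; returns last velocities.

    Positions in ``config`` stay wrapped (for neighbor search);
    ``pos_unwrapped`` accumulates the unwrapped counterpart.
    """
    zeta = config.friction
    v0 = drive.speed
    sqrt_var = np.sqrt(2.0 * dt / drive.persistence)
    velocities = None
    for _ in range(n_steps):
        pairs.update(config.positions)
        _, forces = _energy_forces_pairs(config, pairs.i, pairs.j, pairs.shifts)
        nhat = drive.directions
        velocities = v0 * nhat + forces / zeta
        disp = dt * velocities
        pos_unwrapped += disp
        config.positions = wrap(config.positions + disp, config.box)
        drive.angles = drive.angles + sqrt_var * rng.standard_normal(config.n)
    return velocities


def step_active(
    config: SoftDiskConfig,
    drive: ActiveDriveState,
    dt: float,
    rng: np.random.Generator,
):
    """Single first-order step of the overdamped active dynamics.

    r <- r + dt (v0 n + F/zeta); theta <- theta + N(0, 2 dt / tau).
    Returns (new config, new drive, velocities), velocities being the
    pre-wrap displacement divided by dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    config = config.copy()
    drive = drive.copy()
    _, forces = energy_and_forces(config)
    if dt * np.max(np.linalg.norm(forces, axis=1)) / config.friction > np.min(
        config.radii
    ):
        warnings.warn(
            "time step moves a particle by more than one radius",
            UnstableStepWarning,
            stacklevel=2,
        )
    velocities = drive.speed * drive.directions + forces / config.friction
    config.positions = wrap(config.positions + dt * velocities, config.box)
    drive.angles = drive.angles + np.sqrt(
        2.0 * dt / drive.persistence
    ) * rng.standard_normal(config.n)
    return config, drive, velocities


def run_trajectory(
    config: SoftDiskConfig,
    drive: ActiveDriveState,
    dt: float,
    n_steps: int,
    save_every: int,
    seed: int = 0,
    include_initial: bool = False,
    division: "DivisionParams | None" = None,
) -> Trajectory:
    """Integrate the active dynamics, saving a frame every ``save_every`` steps.

    Deterministic for a fixed seed.  With ``division`` set, cells divide
    stochastically and the most compressed cells are extruded to hold N at
    its target, so all saved frames share the same N.
    """
    if n_steps < save_every:
        raise ValueError("n_steps must be >= save_every")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    config = config.copy()
    drive = drive.copy()
    if division is not None:
        config, drive = _division_steady_state(config, drive, division)
    pairs = _PairList(config)
    pos_unwrapped = config.positions.copy()
    times, frames_p, frames_v, frames_a = [], [], [], []

    def snapshot(t, velocities):
        times.append(t)
        frames_p.append(pos_unwrapped.copy())
        frames_v.append(velocities.copy())
        frames_a.append(drive.angles.copy())

    if include_initial:
        _, forces = energy_and_forces(config)
        snapshot(0.0, drive.speed * drive.directions + forces / config.friction)
    step_count = 0
    while step_count < n_steps:
        block = min(save_every, n_steps - step_count)
        if division is None:
            velocities = _advance(config, drive, dt, block, rng, pairs, pos_unwrapped)
        else:
            velocities = None
            for _ in range(block):
                velocities = _advance(config, drive, dt, 1, rng, pairs, pos_unwrapped)
                changed, config, drive, pos_unwrapped = _divide_extrude_step(
                    config, drive, dt, division, rng, pos_unwrapped
                )
                if changed:
                    pairs = _PairList(config)
        step_count += block
        snapshot(step_count * dt, velocities)
    return Trajectory(
        np.array(times),
        np.array(frames_p),
        np.array(frames_v),
        np.array(frames_a),
        config.box,
        config.radii.copy(),
        metadata={
            "dt": dt,
            "n_steps": n_steps,
            "save_every": save_every,
            "seed": seed,
            "v0": drive.speed,
            "tau": drive.persistence,
            "k": config.stiffness,
            "zeta": config.friction,
            "model": "softdisk",
        },
    )


# --------------------------------------------------------------------------
# division / extrusion (simplified steady-state scheme)


@dataclass
class DivisionParams:
    """Steady-state division/extrusion: rate 1/cycle_time per cell,
    daughters at a small offset, immediate extrusion of the most compressed
    cells back to ``target_n``."""

    cycle_time: float
    target_n: int
    offset: float = 0.1

    def __post_init__(self):
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be positive")
        if self.target_n < 2:
            raise ValueError("target_n must be >= 2")


def _division_steady_state(config, drive, division):
    if config.n != division.target_n:
        raise ValueError("division runs must start at target_n cells")
    return config, drive


def _divide_extrude_step(config, drive, dt, division, rng, pos_unwrapped):
    """One step of division + extrusion; N is conserved at target_n."""
    p_div = dt / division.cycle_time
    dividing = np.nonzero(rng.random(config.n) < p_div)[0]
    if dividing.size == 0:
        return False, config, drive, pos_unwrapped
    angles_off = rng.uniform(0.0, 2.0 * np.pi, size=dividing.size)
    offset = division.offset * config.mean_radius
    new_pos = config.positions[dividing] + offset * np.column_stack(
        [np.cos(angles_off), np.sin(angles_off)]
    )
    positions = np.vstack([config.positions, new_pos])
    radii = np.concatenate([config.radii, config.radii[dividing]])
    pos_unwrapped = np.vstack([pos_unwrapped, pos_unwrapped[dividing] + (new_pos - config.positions[dividing])])
    angles = np.concatenate(
        [drive.angles, rng.uniform(0.0, 2.0 * np.pi, size=dividing.size)]
    )
    config = SoftDiskConfig(
        positions,
        radii,
        config.box,
        stiffness=config.stiffness,
        friction=config.friction,
        attraction_eps=config.attraction_eps,
    )
    # extrude the most compressed cells to restore target N
    excess = config.n - division.target_n
    if excess > 0:
        compression = per_particle_energy(config)
        remove = np.argsort(compression)[-excess:]
        keep = np.setdiff1d(np.arange(config.n), remove)
        config = SoftDiskConfig(
            config.positions[keep],
            config.radii[keep],
            config.box,
            stiffness=config.stiffness,
            friction=config.friction,
            attraction_eps=config.attraction_eps,
        )
        pos_unwrapped = pos_unwrapped[keep]
        angles = angles[keep]
    drive = ActiveDriveState(angles, drive.speed, drive.persistence)
    return True, config, drive, pos_unwrapped


def divide_and_extrude(
    config: SoftDiskConfig,
    drive: ActiveDriveState,
    dt: float,
    cycle_time: float,
    target_n: int,
    rng: np.random.Generator,
):
    """Apply one division/extrusion step (probability dt/cycle_time per cell).

    Returns (config, drive); N is held at ``target_n``.
    """
    division = DivisionParams(cycle_time=cycle_time, target_n=target_n)
    if config.n != target_n:
        raise ValueError("config must hold target_n cells")
    pos_unwrapped = config.positions.copy()
    _, config, drive, _ = _divide_extrude_step(
        config, drive, dt, division, rng, pos_unwrapped
    )
    return config, drive
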