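"""Continuum-elastic predictions for velocity correlations in active sheets.

A confluent layer of persistently motile agents on a frictional substrate
behaves, below its structural relaxation time, as an elastic sheet driven
by Ornstein-Uhlenbeck forcing.  Longitudinal and transverse Fourier modes
relax at rates (B + mu) q^2 / zeta and mu q^2 / zeta, giving Lorentzian
equal-time velocity spectra with correlation lengths

    xi_L = sqrt((B + mu) tau / zeta),   xi_T = sqrt(mu tau / zeta),

both growing as sqrt(tau).  B and mu are the per-particle branch stiffnesses
of the dynamical matrix (units of k; [mu/zeta] = length^2 / time), `a` is
the microscopic cutoff length (particle radius / cell size) with maximum
wavenumber q_m = 2 pi / a.

All closed forms here follow the discrete (1/N) Fourier convention used by
the measurement pipeline up to the overall factor N stated per function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import k0

__all__ = [
    "TheoryParams",
    "correlation_lengths",
    "vq_theory",
    "vq_normalized",
    "mean_square_velocity",
    "cvv_theory",
    "vacf_theory",
]


@dataclass
class TheoryParams:
    """Inputs to all closed-form predictions.

    Parameters
    ----------
    v0 : float
        Active speed (length/time).
    tau : float
        Orientational persistence time.
    zeta : float
        Substrate friction.
    bulk, shear : float
        Per-particle elastic branch stiffnesses B and mu.
    a : float
        Microscopic length (particle radius / cell size); q_m = 2 pi / a.
    """

    v0: float
    tau: float
    zeta: float = 1.0
    bulk: float = 1.52
    shear: float = 0.82
    a: float = 1.0

    def __post_init__(self):
        for name in ("v0", "tau", "zeta", "shear", "a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bulk + self.shear <= 0:
            raise ValueError("B + mu must be positive")

    @property
    def xi_l(self) -> float:
        return float(np.sqrt((self.bulk + self.shear) * self.tau / self.zeta))

    @property
    def xi_t(self) -> float:
        return float(np.sqrt(self.shear * self.tau / self.zeta))

    @property
    def t_eff(self) -> float:
        """Effective temperature zeta v0^2 tau / 2 (tau -> 0 equilibrium)."""
        return 0.5 * self.zeta * self.v0**2 * self.tau

    @property
    def q_m(self) -> float:
        return 2.0 * np.pi / self.a

    @property
    def moduli_ratio(self) -> float:
        return (self.bulk + self.shear) / self.shear


def correlation_lengths(bulk, shear, tau, zeta=1.0):
    """(xi_L, xi_T) = (sqrt((B+mu) tau/zeta), sqrt(mu tau/zeta))."""
    if bulk + shear <= 0 or shear <= 0 or tau <= 0 or zeta <= 0:
        raise ValueError("moduli, tau and zeta must be positive")
    return (
        float(np.sqrt((bulk + shear) * tau / zeta)),
        float(np.sqrt(shear * tau / zeta)),
    )


def _lorentzians(q, xi_l, xi_t):
    q = np.asarray(q, dtype=float)
    return 1.0 / (1.0 + (xi_l * q) ** 2) + 1.0 / (1.0 + (xi_t * q) ** 2)


def vq_theory(params: TheoryParams, q, n_particles: int = 1):
    """Equal-time Fourier velocity correlation.

    <|v(q)|^2> = (N v0^2 / 2) [1/(1 + xi_L^2 q^2) + 1/(1 + xi_T^2 q^2)]
    in the sum convention v(q) = sum_j e^{iq.r} v_j; divide by N^2 (i.e.
    pass ``n_particles = 1/N``) for the (1/N)-transform convention of the
    measurement pipeline.
    """
    if np.any(np.asarray(q) < 0):
        raise ValueError("q must be >= 0")
    return 0.5 * n_particles * params.v0**2 * _lorentzians(q, params.xi_l, params.xi_t)


def vq_normalized(params: TheoryParams, q, mean_speed: float, n_particles: int = 1):
    """Spectrum of the velocity normalised by its rms value (PIV fit model).

    <|v(q)|^2>_norm = (N/2) (v0 / v_bar)^2 [Lorentzian_L + Lorentzian_T];
    the q -> 0 intercept is N (v0 / v_bar)^2.
    """
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    return (
        0.5
        * n_particles
        * (params.v0 / mean_speed) ** 2
        * _lorentzians(q, params.xi_l, params.xi_t)
    )


def mean_square_velocity(params: TheoryParams) -> float:
    """Mean-square particle velocity with circular cutoff q <= q_m.

    <|v|^2> = (v0^2 a^2 / 8 pi) [log(1 + xi_L^2 q_m^2)/xi_L^2
                                 + log(1 + xi_T^2 q_m^2)/xi_T^2].
    The xi -> 0 limit of the formula is pi v0^2 (a cutoff-convention
    artifact of the circular q_m cutoff, not a physical statement).
    """
    xl2, xt2 = params.xi_l**2, params.xi_t**2
    qm2 = params.q_m**2
    return float(
        params.v0**2
        * params.a**2
        / (8.0 * np.pi)
        * (np.log1p(xl2 * qm2) / xl2 + np.log1p(xt2 * qm2) / xt2)
    )


def cvv_theory(params: TheoryParams, r, asymptotic: bool = False):
    """Real-space equal-time velocity correlation C_vv(r), valid for r > a.

    C_vv(r) = (a^2 v0^2 / 4 pi) [K0(r/xi_L)/xi_L^2 + K0(r/xi_T)/xi_T^2]
    with K0 the modified Bessel function of the second kind; with
    ``asymptotic`` the large-r exponential form
    (a^2 v0^2 / 4 pi) sqrt(pi/2r) [e^{-r/xi_L}/xi_L^{3/2} + e^{-r/xi_T}/xi_T^{3/2}]
    is returned instead.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    pref = params.a**2 * params.v0**2 / (4.0 * np.pi)
    xl, xt = params.xi_l, params.xi_t
    if asymptotic:
        return pref * np.sqrt(np.pi / (2.0 * r)) * (
            np.exp(-r / xl) / xl**1.5 + np.exp(-r / xt) / xt**1.5
        )
    return pref * (k0(r / xl) / xl**2 + k0(r / xt) / xt**2)


def _mode_vacf(s, x):
    """Normalised velocity autocorrelation of one OU-driven overdamped mode.

    For mode rate omega = lambda/zeta and noise memory tau, with s = t/tau
    and x = tau omega:

        C(s, x) / (v0^2/2) = (e^{-s} - x e^{-x s}) / (1 - x^2),

    whose t=0 value is 1/(1+x).  The x -> 1 point is removable.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    shape = np.broadcast(np.asarray(s), x).shape
    out = np.empty(shape if shape else (1,))
    s_b = np.broadcast_to(np.asarray(s, dtype=float), out.shape)
    x_b = np.broadcast_to(x, out.shape)
    near = np.abs(1.0 - x_b) < 1e-6
    safe_x = np.where(near, 2.0, x_b)
    out[:] = (np.exp(-s_b) - safe_x * np.exp(-safe_x * s_b)) / (1.0 - safe_x**2)
    if np.any(near):
        # series around x = 1: C -> e^{-s} (1 - s) / 2 + O(1-x)
        sn = s_b[near]
        out[near] = 0.5 * np.exp(-sn) * (1.0 - sn)
    return out


def vacf_theory(params: TheoryParams, t, quad_limit: int = 200):
    """Temporal velocity autocorrelation <v(t).v(0)> from the mode integral.

    Each elastic branch X in {L, T} contributes an OU-driven overdamped
    mode of rate omega_X(q) = xi_X^2 q^2 / tau at every wavevector;
    integrating the per-mode autocorrelation over the circular q-domain
    (0, q_m] with the same measure as `mean_square_velocity` gives

        C(t) = (a^2 v0^2 / 4 pi) int_0^{q_m} q dq
               sum_X C_mode(t/tau, tau omega_X(q)) ,

    so that C(0) coincides with the closed-form mean-square velocity.
    The inverse-S shape interpolates between the short-time plateau and
    exponential loss of memory on the persistence time.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    xl2, xt2 = params.xi_l**2, params.xi_t**2
    pref = params.a**2 * params.v0**2 / (4.0 * np.pi)
    # error scale: the t = 0 integral (the mean-square velocity)
    scale = mean_square_velocity(params) / pref
    out = np.empty(t.shape)
    for m, tm in enumerate(t):
        s = tm / params.tau

        def integrand(q):
            # x = tau * omega_X = xi_X^2 q^2 is dimensionless
            q2 = q * q
            return (q * (_mode_vacf(s, xl2 * q2) + _mode_vacf(s, xt2 * q2))).item()

        # split at the removable x = 1 points for quadrature robustness
        pts = [p for p in (1.0 / params.xi_l, 1.0 / params.xi_t) if p < params.q_m]
        val, err = quad(
            integrand,
            0.0,
            params.q_m,
            points=pts or None,
            limit=quad_limit,
            epsabs=max(1e-12, 1e-9 * scale),
            epsrel=1e-8,
        )
        if not np.isfinite(val) or err > max(1e-3 * abs(val), 1e-5 * scale):
            raise RuntimeError(
                f"vacf quadrature did not converge at t={tm} (value {val}, err {err})"
            )
        out[m] = pref * val
    return out if out.size > 1 else float(out[0])
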