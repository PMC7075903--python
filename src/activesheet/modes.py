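"""Normal-mode linear response of jammed soft-disk packings.

At a mechanical equilibrium the contact network defines a Hessian
K_ij = d^2 V / dr_i dr_j, organised in 2x2 blocks.  Each contact
contributes the off-diagonal block

    -[ V''(r) n x n + (V'(r)/r) t x t ],

with n the contact normal and t the in-plane tangent, and minus that block
accumulates on the diagonal, so block rows sum to zero (translation
invariance).  For the purely repulsive harmonic contact V'' = k and
V'(r)/r = -|f|/r, recovering the granular-Hessian form -k n x n + (|f|/r) t x t.

Eigenvectors of the Hessian are the normal modes; driving them with the
persistent active noise gives the mode energies

    E_nu = zeta v0^2 tau / (4 (1 + lambda_nu tau / zeta))

and the mode-resolved Fourier velocity correlation

    <|v(q)|^2> = sum_nu v0^2 / (2 (1 + lambda_nu tau/zeta)) |xi_nu(q)|^2,

with xi_nu(q) = (1/N) sum_j exp(i q.r_j) xi_nu^j.  The long-wavelength
branches of the Fourier dynamical matrix D(q) give the bulk and shear
moduli via lambda_L ~ (B+mu) q^2 and lambda_T ~ mu q^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .observables import QCorrelation, commensurate_qgrid, radial_average
from .softdisk import SoftDiskConfig, _pair_energy_force, _pair_stiffness, contact_list

__all__ = [
    "HessianMatrix",
    "ModeSet",
    "ModuliEstimate",
    "assemble_hessian",
    "eigenmodes",
    "mode_energies",
    "mode_velocity_correlation",
    "dynamical_matrix",
    "estimate_moduli",
]


@dataclass
class HessianMatrix:
    """Sparse 2N x 2N Hessian with the configuration it was evaluated at."""

    matrix: sp.csr_matrix
    positions: np.ndarray
    box: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass
class ModeSet:
    """Eigenvalues (ascending) and orthonormal eigenvectors of a Hessian."""

    eigenvalues: np.ndarray  # (2N,)
    eigenvectors: np.ndarray  # (2N, 2N), column nu is mode nu
    positions: np.ndarray
    box: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def mode_displacements(self, nu: int) -> np.ndarray:
        """Mode nu as per-particle 2-vectors, shape (N, 2)."""
        return self.eigenvectors[:, nu].reshape(self.n, 2)


@dataclass
class ModuliEstimate:
    """Bulk and shear moduli from the D(q) branch slopes."""

    bulk: float
    shear: float
    q_max_fit: float
    q_bins: np.ndarray = field(repr=False)
    lambda_l: np.ndarray = field(repr=False)
    lambda_t: np.ndarray = field(repr=False)
    residual_l: float = 0.0
    residual_t: float = 0.0

    @property
    def moduli_ratio(self) -> float:
        """(mu + B) / mu, the squared ratio of correlation lengths."""
        return (self.shear + self.bulk) / self.shear


def assemble_hessian(
    config: SoftDiskConfig,
    printed_form: bool = False,
    equilibrium_tol: float = 1e-6,
) -> HessianMatrix:
    """Assemble the contact Hessian at (approximate) mechanical equilibrium.

    ``printed_form`` drops the 1/r in the tangential (pre-stress) block,
    i.e. uses |f| t x t instead of (|f|/r) t x t; the default is the exact
    second derivative of the energy, validated by finite differences.
    Warns when the configuration carries a residual force above
    ``equilibrium_tol`` (pre-stress then shifts the spectrum).
    """
    from .softdisk import energy_and_forces

    _, forces = energy_and_forces(config)
    resid = float(np.max(np.linalg.norm(forces, axis=1)))
    if resid > equilibrium_tol:
        warnings.warn(
            f"Hessian evaluated away from equilibrium (max |F| = {resid:.2e})",
            stacklevel=2,
        )
    ii, jj, r, sigsum, nhat = contact_list(config)
    k, eps = config.stiffness, config.attraction_eps
    _, fmag = _pair_energy_force(r, sigsum, k, eps)  # f = -V'(r)
    vpp = _pair_stiffness(r, sigsum, k, eps)
    that = np.column_stack([-nhat[:, 1], nhat[:, 0]])
    # off-diagonal block: -(V'' n x n + (V'/r) t x t); V' = -fmag
    tang = -fmag if printed_form else -fmag / r
    blocks = -(
        vpp[:, None, None] * np.einsum("pa,pb->pab", nhat, nhat)
        + tang[:, None, None] * np.einsum("pa,pb->pab", that, that)
    )
    n = config.n
    rows, cols, vals = [], [], []
    for a in range(2):
        for b in range(2):
            v = blocks[:, a, b]
            rows.extend([2 * ii + a, 2 * jj + a, 2 * ii + a, 2 * jj + a])
            cols.extend([2 * jj + b, 2 * ii + b, 2 * ii + b, 2 * jj + b])
            vals.extend([v, v, -v, -v])
    matrix = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * n, 2 * n),
    ).tocsr()
    return HessianMatrix(matrix, config.positions.copy(), config.box.copy())


def eigenmodes(hessian: HessianMatrix) -> ModeSet:
    """Full dense spectrum of the Hessian (ascending, orthonormal)."""
    evals, evecs = np.linalg.eigh(hessian.toarray())
    return ModeSet(evals, evecs, hessian.positions, hessian.box)


def mode_energies(
    modes: ModeSet, v0: float, tau: float, zeta: float = 1.0
) -> np.ndarray:
    """Mean energy per mode, E_nu = zeta v0^2 tau / (4 (1 + lambda tau/zeta)).

    tau -> 0 recovers equipartition at T_eff/2 with T_eff = zeta v0^2 tau/2;
    tau -> inf gives zeta^2 v0^2 / (4 lambda), dominated by the soft modes.
    """
    lam = np.clip(modes.eigenvalues, 0.0, None)
    return zeta * v0**2 * tau / (4.0 * (1.0 + lam * tau / zeta))


def mode_fourier_weights(modes: ModeSet, q_vectors: np.ndarray) -> np.ndarray:
    """|xi_nu(q)|^2 for every mode and wavevector, shape (n_q, 2N).

    xi_nu(q) = (1/N) sum_j exp(i q.r_j) xi_nu^j (a 2-component complex
    vector per mode).
    """
    n = modes.n
    phases = np.exp(1j * q_vectors @ modes.positions.T)  # (n_q, N)
    evecs = modes.eigenvectors.reshape(n, 2, 2 * n)
    tx = phases @ evecs[:, 0, :]
    ty = phases @ evecs[:, 1, :]
    return (np.abs(tx) ** 2 + np.abs(ty) ** 2) / n**2


def mode_velocity_correlation(
    modes: ModeSet,
    v0: float,
    tau: float,
    zeta: float = 1.0,
    q_max: float = 2.5,
    q_vectors: np.ndarray | None = None,
) -> QCorrelation:
    """Mode-sum prediction of the Fourier velocity correlation.

    Uses the (1/N)-normalised transform convention of the measurement
    pipeline; values are radially averaged on bins of width 2 pi / L.
    """
    if q_vectors is None:
        q_vectors = commensurate_qgrid(modes.box, q_max)
    weights2 = v0**2 / (2.0 * (1.0 + np.clip(modes.eigenvalues, 0, None) * tau / zeta))
    values = mode_fourier_weights(modes, q_vectors) @ weights2
    qmag = np.linalg.norm(q_vectors, axis=1)
    return radial_average(qmag, values, bin_width=2.0 * np.pi / np.max(modes.box))


def dynamical_matrix(hessian: HessianMatrix, q_vectors: np.ndarray) -> np.ndarray:
    """Fourier dynamical matrix D(q) = (1/N) sum_jl e^{iq.rj} H_jl e^{-iq.rl}.

    Returns an (n_q, 2, 2) array of Hermitian matrices.
    """
    n = hessian.n
    h = hessian.matrix
    out = np.empty((q_vectors.shape[0], 2, 2), dtype=complex)
    chunk = 256
    for start in range(0, q_vectors.shape[0], chunk):
        qs = q_vectors[start : start + chunk]
        phases = np.exp(-1j * hessian.positions @ qs.T)  # (N, m)
        m = qs.shape[0]
        w = np.zeros((2 * n, 2 * m), dtype=complex)
        w[0::2, 0::2][:, np.arange(m)] = phases
        w[1::2, 1::2][:, np.arange(m)] = phases
        hw = h @ w  # (2N, 2m)
        conj = np.conj(phases)  # e^{+iq.rj}
        for a in range(2):
            for b in range(2):
                out[start : start + m, a, b] = (
                    np.sum(conj * hw[a::2, b::2], axis=0) / n
                )
    return out


def estimate_moduli(
    config: SoftDiskConfig,
    hessian: HessianMatrix | None = None,
    q_max_fit: float = 1.5,
) -> ModuliEstimate:
    """Bulk and shear moduli from the long-wavelength D(q) branches.

    D(q) is built on the commensurate q-grid with |q| <= q_max_fit and
    diagonalised; the eigenvector with the larger projection on q-hat is
    the longitudinal branch.  Branch eigenvalues are radially averaged
    (bins of width 2 pi / L) and fitted, unweighted and through the origin,
    as lambda = slope * q^2 for q <= q_max_fit, giving slope_L = B + mu and
    slope_T = mu.
    """
    if hessian is None:
        hessian = assemble_hessian(config)
    q_vectors = commensurate_qgrid(config.box, q_max_fit)
    if q_vectors.shape[0] < 8:
        raise ValueError(
            "too few commensurate wavevectors below q_max_fit; box too small"
        )
    dmats = dynamical_matrix(hessian, q_vectors)
    qmag = np.linalg.norm(q_vectors, axis=1)
    qhat = q_vectors / qmag[:, None]
    evals, evecs = np.linalg.eigh(dmats)  # ascending, (n_q, 2), (n_q, 2, 2)
    # projection of each eigenvector on q-hat
    proj = np.abs(np.einsum("qa,qab->qb", qhat.astype(complex), evecs))
    long_is_second = proj[:, 1] >= proj[:, 0]
    lam_l = np.where(long_is_second, evals[:, 1], evals[:, 0])
    lam_t = np.where(long_is_second, evals[:, 0], evals[:, 1])
    bin_width = 2.0 * np.pi / np.max(config.box)
    corr_l = radial_average(qmag, lam_l, bin_width=bin_width)
    corr_t = radial_average(qmag, lam_t, bin_width=bin_width)

    def slope_through_origin(q, lam):
        x = q**2
        s = float(np.sum(lam * x) / np.sum(x * x))
        resid = float(np.sqrt(np.mean((lam - s * x) ** 2)))
        return s, resid

    slope_l, res_l = slope_through_origin(corr_l.q, corr_l.values)
    slope_t, res_t = slope_through_origin(corr_t.q, corr_t.values)
    mu = slope_t
    bulk = slope_l - mu
    return ModuliEstimate(
        bulk=bulk,
        shear=mu,
        q_max_fit=q_max_fit,
        q_bins=corr_l.q,
        lambda_l=corr_l.values,
        lambda_t=corr_t.values,
        residual_l=res_l,
        residual_t=res_t,
    )
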