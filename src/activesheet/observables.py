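"""Correlation estimators for trajectories and gridded velocity fields.

All Fourier-space measurements use the (1/N)-normalised transform

    v(q) = (1/N) sum_j exp(i q . r_j) v_j,

radially averaged over wavevector direction in bins of width 2 pi / L and
then time averaged.  For comparisons against normal-mode predictions the
phases should use the equilibrium reference positions (pass
``reference_positions``); for liquids and experimental grids the
instantaneous positions are the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncommensurateWavevectorWarning
from .softdisk import Trajectory, minimum_image
from .synthfields import GridVelocityField

__all__ = [
    "QCorrelation",
    "RCorrelation",
    "VACF",
    "ScatteringResult",
    "commensurate_qgrid",
    "radial_average",
    "measure_vq",
    "measure_cvv",
    "measure_sisf",
    "measure_vacf",
    "speed_stats",
    "structure_factor",
]


@dataclass
class QCorrelation:
    """Radially averaged Fourier-space correlation."""

    q: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    normalization: str = "none"


@dataclass
class RCorrelation:
    """Radially averaged real-space velocity correlation C_vv(r)."""

    r: np.ndarray
    values: np.ndarray
    counts: np.ndarray


@dataclass
class VACF:
    """Temporal velocity autocorrelation <v(t).v(0)>."""

    lags: np.ndarray
    values: np.ndarray
    normalized: bool = False


@dataclass
class ScatteringResult:
    """Self-intermediate scattering function at fixed |q| and tau_alpha."""

    lags: np.ndarray
    values: np.ndarray
    q: float
    tau_alpha: float
    censored: bool


# --------------------------------------------------------------------------
# q-space machinery


def commensurate_qgrid(box, q_max: float, half_plane: bool = True) -> np.ndarray:
    """Wavevectors 2 pi (nx/Lx, ny/Ly) with 0 < |q| <= q_max.

    With ``half_plane`` only one of each (q, -q) pair is returned (their
    correlation values are identical for real fields).
    """
    box = np.asarray(box, dtype=float)
    nmax = np.ceil(q_max * box / (2.0 * np.pi)).astype(int)
    nx, ny = np.meshgrid(
        np.arange(-nmax[0], nmax[0] + 1), np.arange(-nmax[1], nmax[1] + 1), indexing="ij"
    )
    qx = 2.0 * np.pi * nx / box[0]
    qy = 2.0 * np.pi * ny / box[1]
    qmag = np.hypot(qx, qy)
    keep = (qmag > 0) & (qmag <= q_max)
    if half_plane:
        keep &= (qy > 0) | ((qy == 0) & (qx > 0))
    return np.column_stack([qx[keep], qy[keep]])


def radial_average(x: np.ndarray, values: np.ndarray, bin_width: float) -> QCorrelation:
    """Bin scalar samples by |x| in fixed-width bins; empty bins are dropped.

    Reported abscissa is the mean |x| inside each bin.
    """
    idx = np.floor(x / bin_width).astype(int)
    nbins = int(np.max(idx)) + 1 if idx.size else 0
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=values, minlength=nbins)
    xsums = np.bincount(idx, weights=x, minlength=nbins)
    nonempty = counts > 0
    return QCorrelation(
        q=xsums[nonempty] / counts[nonempty],
        values=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
    )


def _check_commensurate(q_vectors, box):
    n = np.asarray(q_vectors) * np.asarray(box) / (2.0 * np.pi)
    if not np.allclose(n, np.round(n), atol=1e-8):
        import warnings

        warnings.warn(
            "wavevectors are not commensurate with the periodic box",
            IncommensurateWavevectorWarning,
            stacklevel=3,
        )


def _as_field_list(frames):
    if isinstance(frames, GridVelocityField):
        return [frames]
    if isinstance(frames, (list, tuple)) and frames and isinstance(
        frames[0], GridVelocityField
    ):
        return list(frames)
    return None


def measure_vq(
    frames,
    q_max: float = 2.5,
    q_vectors: np.ndarray | None = None,
    reference_positions: np.ndarray | None = None,
    normalize: str = "none",
    bin_width: float | None = None,
) -> QCorrelation:
    """Radially and time averaged Fourier velocity correlation <|v(q)|^2>.

    Parameters
    ----------
    frames : Trajectory or sequence of GridVelocityField
        Velocity data.  Grid fields use the grid nodes as positions and the
        FFT wavevectors of the grid as the q-set.
    normalize : {"none", "frame_rms"}
        ``frame_rms`` divides each frame's velocities by that frame's
        root-mean-square speed before transforming (the convention used
        when fitting PIV data).
    reference_positions : array, optional
        Fixed phase positions (e.g. the relaxed packing) instead of the
        per-frame instantaneous positions; required when comparing against
        normal-mode predictions.
    """
    if normalize not in ("none", "frame_rms"):
        raise ValueError("normalize must be 'none' or 'frame_rms'")
    fields = _as_field_list(frames)
    if fields is not None:
        return _measure_vq_grid(fields, normalize, bin_width)
    traj: Trajectory = frames
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    if q_vectors is None:
        q_vectors = commensurate_qgrid(traj.box, q_max)
    else:
        _check_commensurate(q_vectors, traj.box)
    qmag = np.linalg.norm(q_vectors, axis=1)
    accum = np.zeros(q_vectors.shape[0])
    n = traj.n
    for f in range(traj.n_frames):
        pos = (
            reference_positions
            if reference_positions is not None
            else traj.wrapped_positions(f)
        )
        vel = traj.velocities[f]
        if normalize == "frame_rms":
            vel = vel / np.sqrt(np.mean(np.sum(vel**2, axis=1)))
        phases = np.exp(1j * q_vectors @ pos.T)
        vq = phases @ vel / n  # (n_q, 2) complex
        accum += np.sum(np.abs(vq) ** 2, axis=1)
    accum /= traj.n_frames
    if bin_width is None:
        bin_width = 2.0 * np.pi / np.max(traj.box)
    out = radial_average(qmag, accum, bin_width)
    out.normalization = normalize
    return out


def _measure_vq_grid(fields, normalize, bin_width):
    first = fields[0]
    nx, ny = first.shape
    n = first.n
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=first.spacing)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=first.spacing)
    qmag = np.hypot(*np.meshgrid(qx, qy, indexing="ij")).ravel()
    accum = np.zeros(nx * ny)
    for fld in fields:
        if fld.shape != first.shape or fld.spacing != first.spacing:
            raise ValueError("all frames must share the same grid geometry")
        vel = fld.velocities
        if normalize == "frame_rms":
            vel = vel / np.sqrt(np.mean(np.sum(vel**2, axis=-1)))
        vqx = np.fft.fft2(vel[:, :, 0]) / n
        vqy = np.fft.fft2(vel[:, :, 1]) / n
        accum += (np.abs(vqx) ** 2 + np.abs(vqy) ** 2).ravel()
    accum /= len(fields)
    keep = qmag > 0  # drop the mean-drift q = 0 point
    if bin_width is None:
        bin_width = 2.0 * np.pi / np.max(first.extent)
    out = radial_average(qmag[keep], accum[keep], bin_width)
    out.normalization = normalize
    return out


# --------------------------------------------------------------------------
# real space


def measure_cvv(
    frames,
    bin_width: float | None = None,
    r_max: float | None = None,
    frame_stride: int = 1,
) -> RCorrelation:
    """Pair-averaged velocity dot product binned by separation.

    Periodic minimum-image distances for trajectories; plain Euclidean
    distances for grid fields.
    """
    fields = _as_field_list(frames)
    if fields is not None:
        pos = fields[0].positions()
        box = None
        vel_iter = [f.flat_velocities() for f in fields[::frame_stride]]
        pos_iter = [pos] * len(vel_iter)
        default_bin = fields[0].spacing
        default_rmax = 0.5 * float(np.max(fields[0].extent))
    else:
        traj: Trajectory = frames
        box = traj.box
        sel = range(0, traj.n_frames, frame_stride)
        vel_iter = [traj.velocities[f] for f in sel]
        pos_iter = [traj.wrapped_positions(f) for f in sel]
        default_bin = 0.5 * float(np.mean(traj.radii))
        default_rmax = 0.5 * float(np.min(traj.box))
    if not vel_iter:
        raise ValueError("no frames")
    bin_width = default_bin if bin_width is None else bin_width
    r_max = default_rmax if r_max is None else r_max
    nbins = int(np.ceil(r_max / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    rsums = np.zeros(nbins)
    for pos, vel in zip(pos_iter, vel_iter):
        ii, jj = np.triu_indices(pos.shape[0], k=1)
        dr = pos[jj] - pos[ii]
        if box is not None:
            dr = minimum_image(dr, box)
        r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
        keep = r < r_max
        idx = np.floor(r[keep] / bin_width).astype(int)
        dots = np.einsum("ij,ij->i", vel[ii[keep]], vel[jj[keep]])
        sums += np.bincount(idx, weights=dots, minlength=nbins)
        rsums += np.bincount(idx, weights=r[keep], minlength=nbins)
        counts += np.bincount(idx, minlength=nbins)
    nonempty = counts > 0
    return RCorrelation(
        r=rsums[nonempty] / counts[nonempty],
        values=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
    )


# --------------------------------------------------------------------------
# temporal observables


def _origin_indices(n_frames, lag, max_origins):
    origins = np.arange(n_frames - lag)
    if origins.size > max_origins:
        origins = origins[:: int(np.ceil(origins.size / max_origins))]
    return origins


def measure_sisf(
    trajectory: Trajectory,
    q_magnitude: float | None = None,
    n_directions: int = 12,
    max_origins: int = 64,
    max_lags: int = 150,
) -> ScatteringResult:
    """Self-intermediate scattering function S(q, t) and alpha-relaxation time.

    Uses unwrapped displacements, averaging over particles, time origins
    and ``n_directions`` directions at fixed |q| (default 2 pi / mean
    radius).  tau_alpha is the first saved lag with S < 0.5; if S never
    drops below 0.5 the result is censored at the trajectory length.
    """
    if q_magnitude is None:
        q_magnitude = 2.0 * np.pi / float(np.mean(trajectory.radii))
    nf = trajectory.n_frames
    if nf < 2:
        raise ValueError("need at least two frames")
    angles = np.linspace(0.0, np.pi, n_directions, endpoint=False)
    qdirs = q_magnitude * np.column_stack([np.cos(angles), np.sin(angles)])
    lag_idx = np.arange(1, nf)
    if lag_idx.size > max_lags:
        lag_idx = np.unique(
            np.round(np.geomspace(1, nf - 1, max_lags)).astype(int)
        )
    lags = trajectory.times[lag_idx] - trajectory.times[0]
    values = np.empty(lag_idx.size)
    pos = trajectory.positions
    for m, lag in enumerate(lag_idx):
        origins = _origin_indices(nf, lag, max_origins)
        disp = pos[origins + lag] - pos[origins]  # (n0, N, 2)
        phase = disp @ qdirs.T  # (n0, N, ndir)
        values[m] = float(np.mean(np.cos(phase)))
    below = values < 0.5
    if np.any(below):
        tau_alpha = float(lags[np.argmax(below)])
        censored = False
    else:
        tau_alpha = float(trajectory.times[-1] - trajectory.times[0])
        censored = True
    return ScatteringResult(
        lags=lags,
        values=values,
        q=float(q_magnitude),
        tau_alpha=tau_alpha,
        censored=censored,
    )


def measure_vacf(
    trajectory: Trajectory,
    max_origins: int = 128,
    max_lags: int = 200,
    normalized: bool = False,
) -> VACF:
    """Velocity autocorrelation <v(t).v(0)> over particles and time origins."""
    nf = trajectory.n_frames
    if nf < 2:
        raise ValueError("need at least two frames")
    lag_idx = np.arange(0, nf)
    if lag_idx.size > max_lags:
        lag_idx = np.unique(
            np.concatenate(
                [[0], np.round(np.geomspace(1, nf - 1, max_lags - 1)).astype(int)]
            )
        )
    vel = trajectory.velocities
    values = np.empty(lag_idx.size)
    for m, lag in enumerate(lag_idx):
        origins = _origin_indices(nf, lag, max_origins)
        values[m] = float(
            np.mean(np.einsum("fij,fij->fi", vel[origins], vel[origins + lag]))
        )
    if normalized:
        values = values / values[0]
    return VACF(
        lags=trajectory.times[lag_idx] - trajectory.times[0],
        values=values,
        normalized=normalized,
    )


def speed_stats(frames, bin_edges: np.ndarray | None = None):
    """Root-mean-square speed, mean-square velocity and normalised speed pdf.

    Returns (v_bar, msv, (bin_centers, density)) where the histogram is of
    |v| / v_bar with unit-area normalisation.
    """
    fields = _as_field_list(frames)
    if fields is not None:
        vel = np.concatenate([f.flat_velocities() for f in fields])
    else:
        vel = np.asarray(frames.velocities).reshape(-1, 2)
    if vel.size == 0:
        raise ValueError("no velocities")
    speeds = np.linalg.norm(vel, axis=1)
    msv = float(np.mean(speeds**2))
    v_bar = float(np.sqrt(msv))
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 4.0, 41)
    density, edges = np.histogram(speeds / v_bar, bins=bin_edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return v_bar, msv, (centers, density)


def structure_factor(
    trajectory: Trajectory, q_max: float = 3.0, bin_width: float | None = None
) -> QCorrelation:
    """Static structure factor S(q) = <|sum_j e^{iq.r_j}|^2> / N."""
    q_vectors = commensurate_qgrid(trajectory.box, q_max)
    qmag = np.linalg.norm(q_vectors, axis=1)
    accum = np.zeros(q_vectors.shape[0])
    for f in range(trajectory.n_frames):
        pos = trajectory.wrapped_positions(f)
        rho = np.exp(1j * q_vectors @ pos.T).sum(axis=1)
        accum += np.abs(rho) ** 2 / trajectory.n
    accum /= trajectory.n_frames
    if bin_width is None:
        bin_width = 2.0 * np.pi / np.max(trajectory.box)
    return radial_average(qmag, accum, bin_width)
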