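"""Synthetic PIV-style velocity fields and small deterministic fixtures.

`generate_field` draws statistically isotropic Gaussian random vector
fields on a rectangular grid whose longitudinal and transverse Fourier
components carry Lorentzian spectra 1/(1 + xi_L^2 q^2) and
1/(1 + xi_T^2 q^2) — the continuum-elastic prediction for the velocity
correlations of an actively driven sheet.  Frames are temporally
independent, which is sufficient for testing the spatial-spectrum
pipeline; temporal observables are tested on simulator output instead.
Defaults mirror a typical experimental PIV geometry: a 54 x 40 grid at
16 um spacing with mean speed ~12 um/h and transverse correlation length
~100 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .softdisk import SoftDiskConfig, generate_packing

__all__ = ["GridVelocityField", "generate_field", "make_fixture_packing"]


@dataclass
class GridVelocityField:
    """Velocity vectors on a regular rectangular grid.

    velocities[ix, iy] is the 2-vector at position
    origin + spacing * (ix, iy).
    """

    velocities: np.ndarray  # (nx, ny, 2)
    spacing: float
    origin: np.ndarray = None
    time: float = 0.0

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 3 or self.velocities.shape[2] != 2:
            raise ValueError("velocities must have shape (nx, ny, 2)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")
        self.origin = (
            np.zeros(2) if self.origin is None else np.asarray(self.origin, float)
        )

    @property
    def shape(self):
        return self.velocities.shape[:2]

    @property
    def n(self) -> int:
        return self.velocities.shape[0] * self.velocities.shape[1]

    @property
    def extent(self) -> np.ndarray:
        """Periodic box lengths (nx * spacing, ny * spacing)."""
        return self.spacing * np.array(self.shape, dtype=float)

    def positions(self) -> np.ndarray:
        nx, ny = self.shape
        gx, gy = np.meshgrid(
            self.origin[0] + self.spacing * np.arange(nx),
            self.origin[1] + self.spacing * np.arange(ny),
            indexing="ij",
        )
        return np.column_stack([gx.ravel(), gy.ravel()])

    def flat_velocities(self) -> np.ndarray:
        return self.velocities.reshape(-1, 2)


def generate_field(
    nx: int = 54,
    ny: int = 40,
    spacing: float = 16.0,
    xi_l: float = 207.0,
    xi_t: float = 100.0,
    v_rms: float = 12.0,
    n_frames: int = 200,
    seed: int = 0,
) -> list[GridVelocityField]:
    """Independent Gaussian velocity-field frames with Lorentzian spectra.

    White Gaussian vector noise is filtered in Fourier space: the component
    along q-hat gets amplitude sqrt(1/(1 + xi_l^2 q^2)), the perpendicular
    component sqrt(1/(1 + xi_t^2 q^2)).  Each frame is rescaled to the
    requested root-mean-square speed (spatial average), removing any
    transform-convention prefactor.
    """
    if nx < 8 or ny < 8:
        raise ValueError("grid must be at least 8 x 8")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if xi_l < 0 or xi_t < 0 or v_rms <= 0:
        raise ValueError("lengths must be >= 0 and v_rms > 0")
    rng = np.random.default_rng(seed)
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    qxg, qyg = np.meshgrid(qx, qy, indexing="ij")
    q2 = qxg**2 + qyg**2
    qmag = np.sqrt(q2)
    with np.errstate(invalid="ignore", divide="ignore"):
        qhx = np.where(qmag > 0, qxg / qmag, 0.0)
        qhy = np.where(qmag > 0, qyg / qmag, 0.0)
    amp_l = 1.0 / np.sqrt(1.0 + xi_l**2 * q2)
    amp_t = 1.0 / np.sqrt(1.0 + xi_t**2 * q2)
    frames = []
    for m in range(n_frames):
        white = rng.standard_normal((nx, ny, 2))
        wx = np.fft.fft2(white[:, :, 0])
        wy = np.fft.fft2(white[:, :, 1])
        wl = wx * qhx + wy * qhy  # longitudinal scalar amplitude
        fl = amp_l * wl
        ftx = amp_t * (wx - wl * qhx)
        fty = amp_t * (wy - wl * qhy)
        vx = np.real(np.fft.ifft2(fl * qhx + ftx))
        vy = np.real(np.fft.ifft2(fl * qhy + fty))
        # q = 0 carries the unprojected white mean; both amplitudes are 1 there
        vel = np.stack([vx, vy], axis=-1)
        rms = np.sqrt(np.mean(np.sum(vel**2, axis=-1)))
        vel *= v_rms / rms
        frames.append(GridVelocityField(vel, spacing=spacing, time=float(m)))
    return frames


# Frozen reference values for the deterministic fixtures, computed once with
# the package's own energy routine at generation time of the fixture recipe.
_FIXTURE_REFERENCE = {
    "two-disk": {"energy": 0.005, "force_magnitude": 0.1},
    "hex-lattice-16": {"force_magnitude": 0.0},
    "random-64": {"energy": 1.5794247095880145},
}


def make_fixture_packing(name: str) -> SoftDiskConfig:
    """Deterministic small packings used as cross-module test fixtures.

    Known names: ``two-disk`` (overlap 0.1, k=1, |F| = 0.1 on each disk),
    ``hex-lattice-16`` (triangular lattice at 2% uniform overlap, zero
    forces by symmetry), ``random-64`` (relaxed polydisperse packing,
    seed 7).
    """
    if name == "two-disk":
        positions = np.array([[4.0, 5.0], [5.9, 5.0]])
        radii = np.array([1.0, 1.0])
        return SoftDiskConfig(positions, radii, box=np.array([10.0, 10.0]))
    if name == "hex-lattice-16":
        d = 2.0 * 0.98  # centre spacing at 2% overlap for unit radii
        rows, cols = 4, 4
        pts = []
        for r in range(rows):
            for c in range(cols):
                pts.append([(c + 0.5 * (r % 2)) * d, r * d * np.sqrt(3) / 2])
        box = np.array([cols * d, rows * d * np.sqrt(3) / 2])
        return SoftDiskConfig(np.array(pts), np.ones(rows * cols), box=box)
    if name == "random-64":
        return generate_packing(64, packing_fraction=1.0, polydispersity=0.3, seed=7)
    raise ValueError(f"unknown fixture name: {name!r}")


def fixture_reference(name: str) -> dict:
    """Frozen reference observables for a fixture (see `make_fixture_packing`)."""
    if name not in _FIXTURE_REFERENCE:
        raise ValueError(f"unknown fixture name: {name!r}")
    return dict(_FIXTURE_REFERENCE[name])
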