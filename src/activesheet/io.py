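"""Plain-text readers/writers for trajectories, PIV grids, configs and results.

All interchange formats are diff-able columnar text with ``# key=value``
metadata headers, written at full float precision so that write -> read is
a lossless round trip.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

import numpy as np

from . import __version__
from .softdisk import Trajectory
from .synthfields import GridVelocityField

__all__ = [
    "RunConfig",
    "read_config",
    "write_snapshots",
    "read_snapshots",
    "write_grid",
    "read_grid",
    "write_keyvalues",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


SNAPSHOT_COLUMNS = ["id", "x", "y", "vx", "vy", "theta", "radius"]


@dataclass
class RunConfig:
    """Validated flat key-value simulation configuration."""

    model: str = "disks"  # disks | spv
    n: int = 1000
    phi: float = 1.0
    poly: float = 0.3
    v0: float = 0.05
    tau: float = 1.0
    k: float = 1.0
    zeta: float = 1.0
    dt: float = 0.01
    steps: int = 10000
    save_every: int = 100
    seed: int = 0
    discard: float = 0.0
    eps: float = 0.0  # attraction range (disks)
    p0: float = 3.6  # SPV shape factor
    area_k: float = 1.0  # SPV area stiffness K
    gamma: float = 1.0  # SPV perimeter stiffness
    lam: float = 0.3  # SPV boundary line tension
    boundary: str = "periodic"
    tau_div: float = 0.0  # division cycle time (0 = off)

    def __post_init__(self):
        if self.model not in ("disks", "spv"):
            raise ValueError("model must be 'disks' or 'spv'")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")
        for name in ("n", "steps", "save_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("phi", "tau", "k", "zeta", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.poly < 1:
            raise ValueError("poly must be in [0, 1)")
        if self.v0 < 0 or self.discard < 0 or self.tau_div < 0:
            raise ValueError("v0, discard and tau_div must be >= 0")

    def digest(self) -> str:
        items = sorted(
            (f.name, getattr(self, f.name)) for f in fields(self)
        )
        return hashlib.sha256(repr(items).encode()).hexdigest()[:12]


def read_config(path) -> RunConfig:
    """Parse a flat ``key=value`` config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(RunConfig)}
    casts = {f.name: type(getattr(RunConfig(), f.name)) for f in fields(RunConfig)}
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
            try:
                values[key] = casts[key](val)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    return RunConfig(**values)


def _provenance_lines(seed=None, extra=None):
    lines = [f"# activesheet={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if extra:
        lines.append(f"# config_hash={extra}")
    return lines


def write_snapshots(path, trajectory: Trajectory):
    """Write a trajectory in the columnar snapshot format.

    Header carries the box, radii-defining metadata and provenance; each
    frame starts with ``# t=<time>`` and holds one row per particle:
    id x y vx vy theta radius [a0].
    """
    meta = trajectory.metadata
    has_a0 = "preferred_areas" in meta
    columns = SNAPSHOT_COLUMNS + (["a0"] if has_a0 else [])
    with open(path, "w") as fh:
        fh.write("# activesheet trajectory\n")
        for line in _provenance_lines(meta.get("seed")):
            fh.write(line + "\n")
        for key in sorted(meta):
            if key in ("seed", "preferred_areas"):
                continue
            fh.write(f"# {key}={meta[key]!r}\n")
        fh.write(f"# box={float(trajectory.box[0])!r},{float(trajectory.box[1])!r}\n")
        fh.write("# columns: " + " ".join(columns) + "\n")
        a0 = meta.get("preferred_areas")
        for f in range(trajectory.n_frames):
            fh.write(f"# t={float(trajectory.times[f])!r}\n")
            pos = trajectory.positions[f]
            vel = trajectory.velocities[f]
            ang = trajectory.angles[f]
            for j in range(trajectory.n):
                row = [
                    str(j),
                    repr(float(pos[j, 0])),
                    repr(float(pos[j, 1])),
                    repr(float(vel[j, 0])),
                    repr(float(vel[j, 1])),
                    repr(float(ang[j])),
                    repr(float(trajectory.radii[j])),
                ]
                if has_a0:
                    row.append(repr(float(a0[j])))
                fh.write(" ".join(row) + "\n")


def read_snapshots(path) -> Trajectory:
    """Read the columnar snapshot format back into a Trajectory."""
    meta = {}
    box = None
    columns = None
    times, frames = [], []
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("t="):
                    if current is not None:
                        frames.append(current)
                    times.append(float(body[2:]))
                    current = []
                elif body.startswith("columns:"):
                    columns = body.split(":", 1)[1].split()
                    missing = [c for c in SNAPSHOT_COLUMNS if c not in columns]
                    if missing:
                        raise ParseError(
                            f"{path}:{lineno}: missing column(s) {', '.join(missing)}"
                        )
                elif body.startswith("box="):
                    box = np.array([float(x) for x in body[4:].split(",")])
                elif "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if current is None or columns is None:
                raise ParseError(f"{path}:{lineno}: data row before frame header")
            parts = line.split()
            if len(parts) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
                )
            current.append([float(x) for x in parts])
    if current is not None:
        frames.append(current)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    if box is None:
        raise ParseError(f"{path}: missing box metadata")
    n = len(frames[0])
    for f, rows in enumerate(frames):
        if len(rows) != n:
            raise ParseError(
                f"{path}: frame {f} (t={times[f]}) has {len(rows)} rows, expected {n}"
            )
    data = np.array(frames)  # (F, N, ncol)
    col = {c: m for m, c in enumerate(columns)}
    radii = data[0, :, col["radius"]]
    out_meta = dict(meta)
    if "a0" in col:
        out_meta["preferred_areas"] = data[0, :, col["a0"]]
    return Trajectory(
        times=np.array(times),
        positions=data[:, :, [col["x"], col["y"]]],
        velocities=data[:, :, [col["vx"], col["vy"]]],
        angles=data[:, :, col["theta"]],
        box=box,
        radii=radii,
        metadata=out_meta,
    )


def write_grid(path, fields_seq, seed=None):
    """Write a sequence of GridVelocityField frames as columnar text."""
    if not fields_seq:
        raise ValueError("empty frame list")
    first = fields_seq[0]
    with open(path, "w") as fh:
        fh.write("# activesheet grid\n")
        for line in _provenance_lines(seed):
            fh.write(line + "\n")
        fh.write(
            f"# nx={first.shape[0]} ny={first.shape[1]} spacing={float(first.spacing)!r} "
            f"origin_x={float(first.origin[0])!r} origin_y={float(first.origin[1])!r}\n"
        )
        fh.write("# columns: frame x y u v\n")
        for m, fld in enumerate(fields_seq):
            pos = fld.positions()
            vel = fld.flat_velocities()
            for p, v in zip(pos, vel):
                fh.write(f"{m} {float(p[0])!r} {float(p[1])!r} {float(v[0])!r} {float(v[1])!r}\n")


def read_grid(path) -> list:
    """Read the PIV grid format; validates the grid geometry."""
    geom = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        geom[key] = val
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields")
            rows.append([float(x) for x in parts])
    if not rows:
        raise ParseError(f"{path}: empty frame list")
    try:
        nx, ny = int(geom["nx"]), int(geom["ny"])
        spacing = float(geom["spacing"])
        origin = np.array([float(geom.get("origin_x", 0)), float(geom.get("origin_y", 0))])
    except KeyError as exc:
        raise ParseError(f"{path}: missing grid geometry key {exc}") from exc
    data = np.array(rows)
    frame_ids = data[:, 0].astype(int)
    out = []
    for m in np.unique(frame_ids):
        sub = data[frame_ids == m]
        if sub.shape[0] != nx * ny:
            raise ParseError(
                f"{path}: frame {m} has {sub.shape[0]} nodes, expected {nx * ny}"
            )
        expected = GridVelocityField(
            np.zeros((nx, ny, 2)), spacing, origin=origin
        ).positions()
        order = np.lexsort((sub[:, 2], sub[:, 1]))
        sub = sub[order]
        if not np.allclose(sub[:, 1:3], expected, atol=1e-9 * spacing):
            raise ParseError(f"{path}: frame {m} grid nodes are irregular")
        vel = sub[:, 3:5].reshape(nx, ny, 2)
        out.append(GridVelocityField(vel, spacing, origin=origin, time=float(m)))
    return out


def write_keyvalues(path, mapping, seed=None, config_hash=None):
    """Write result key-value pairs with a provenance header."""
    with open(path, "w") as fh:
        fh.write("# activesheet results\n")
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        for key, val in mapping.items():
            fh.write(f"{key}={val!r}\n")
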