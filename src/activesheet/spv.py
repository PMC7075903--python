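"""Self-propelled Voronoi (SPV) model of a confluent tissue.

Every cell is the Voronoi tile of its centre r_i; the tissue energy is

    E = sum_i [ K/2 (A_i - A0_i)^2 + Gamma/2 (P_i - P0_i)^2 ]  (+ lambda * boundary length)

with tile area A_i, perimeter P_i, preferred area A0_i and preferred
perimeter P0_i = p0bar sqrt(A0_i).  The dimensionless shape factor p0bar
controls tissue rigidity (solid below roughly 3.812).  Forces on the cell
centres are the exact analytic gradients of E, obtained by chaining the
polygon area/perimeter derivatives through the Voronoi vertices, which are
circumcenters of Delaunay triangles.

Boundary modes:

* ``periodic`` - tiles computed with 3 x 3 minimum-image replication;
  tile areas partition the box exactly (reference-tested default).
* ``open`` - tiles of convex-hull cells are closed by the chain of
  circumcenters of hull-edge triangles; a line tension lambda acts on the
  resulting outer contour (it suppresses the fingering instability of
  strongly active open sheets).

Dynamics are the same overdamped active Brownian equations as the disk
model, with the tessellation refreshed every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import TessellationDegeneracyError
from .softdisk import ActiveDriveState, Trajectory, wrap

__all__ = [
    "SPVConfig",
    "TessellationResult",
    "tessellate",
    "spv_energy_forces",
    "run_spv",
]


@dataclass
class SPVConfig:
    """State and parameters of the self-propelled Voronoi model."""

    centers: np.ndarray
    preferred_areas: np.ndarray
    box: np.ndarray = None  # required for periodic mode
    area_stiffness: float = 1.0
    perimeter_stiffness: float = 1.0
    shape_factor: float = 3.6
    boundary_tension: float = 0.3
    boundary_mode: str = "periodic"
    friction: float = 1.0

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float)).copy()
        self.preferred_areas = np.asarray(self.preferred_areas, dtype=float).copy()
        if self.boundary_mode not in ("periodic", "open"):
            raise ValueError("boundary_mode must be 'periodic' or 'open'")
        if self.centers.shape[0] < 3:
            raise ValueError("need at least 3 cell centers")
        if self.preferred_areas.shape != (self.n,):
            raise ValueError("preferred_areas must have shape (N,)")
        if np.any(self.preferred_areas <= 0):
            raise ValueError("preferred areas must be positive")
        if self.area_stiffness < 0 or self.perimeter_stiffness < 0:
            raise ValueError("stiffnesses must be >= 0")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.boundary_mode == "periodic":
            if self.box is None:
                raise ValueError("periodic mode requires a box")
            box = np.asarray(self.box, dtype=float)
            if box.ndim == 0:
                box = np.array([float(box), float(box)])
            self.box = box
            self.centers = wrap(self.centers, self.box)

    @property
    def n(self) -> int:
        return self.centers.shape[0]

    @property
    def preferred_perimeters(self) -> np.ndarray:
        return self.shape_factor * np.sqrt(self.preferred_areas)

    def copy(self) -> "SPVConfig":
        return replace(
            self,
            centers=self.centers.copy(),
            preferred_areas=self.preferred_areas.copy(),
        )


@dataclass
class TessellationResult:
    """Voronoi tiles with the bookkeeping needed for analytic forces."""

    polygons: list  # per-cell (m_i, 2) vertex arrays, ordered CCW
    areas: np.ndarray
    perimeters: np.ndarray
    neighbors: list
    boundary: np.ndarray  # bool flags
    # internals for force assembly
    rings: list = field(repr=False, default=None)  # per-cell triangle ids
    tri_corners: np.ndarray = field(repr=False, default=None)  # (T, 3) base ids
    tri_positions: np.ndarray = field(repr=False, default=None)  # (T, 3, 2)
    circumcenters: np.ndarray = field(repr=False, default=None)  # (T, 2)


def _circumcenters(p1, p2, p3):
    """Circumcenters of triangles given corner position arrays (T, 2)."""
    u = p2 - p1
    v = p3 - p1
    d = 2.0 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    if np.any(np.abs(d) < 1e-14):
        raise TessellationDegeneracyError("degenerate (collinear) Delaunay triangle")
    uu = np.einsum("ij,ij->i", u, u)
    vv = np.einsum("ij,ij->i", v, v)
    cx = (v[:, 1] * uu - u[:, 1] * vv) / d
    cy = (u[:, 0] * vv - v[:, 0] * uu) / d
    return p1 + np.column_stack([cx, cy])


def tessellate(config: SPVConfig) -> TessellationResult:
    """Voronoi tessellation of the cell centres.

    Periodic mode replicates the centres over the 8 neighbouring images so
    that every central tile is correctly closed; tile areas then sum to the
    box area.  Open mode flags convex-hull cells as boundary cells and
    closes their tiles with the chain of circumcenters of hull-edge
    triangles.
    """
    n = config.n
    pts = config.centers
    if config.boundary_mode == "periodic":
        offsets = np.array(
            [[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1]],
            dtype=float,
        )
        cloud = np.concatenate([pts + off * config.box for off in offsets])
        base = np.tile(np.arange(n), 9)
    else:
        cloud = pts
        base = np.arange(n)
    try:
        tri = Delaunay(cloud)
    except QhullError as exc:  # pragma: no cover - rare degenerate input
        raise TessellationDegeneracyError(str(exc)) from exc
    simplices = tri.simplices  # (T, 3)
    # triangles incident to at least one central point
    central_mask = np.any(simplices < n, axis=1)
    simplices = simplices[central_mask]
    tri_pos = cloud[simplices]  # (T, 3, 2)
    centers_c = _circumcenters(tri_pos[:, 0], tri_pos[:, 1], tri_pos[:, 2])
    tri_corners = base[simplices]

    # per-cell incident triangle lists
    incident = [[] for _ in range(n)]
    for t in range(simplices.shape[0]):
        for corner in simplices[t]:
            if corner < n:
                incident[int(corner)].append(t)

    if config.boundary_mode == "open":
        hull_points = np.unique(tri.convex_hull)
        boundary = np.zeros(n, dtype=bool)
        boundary[hull_points] = True
    else:
        boundary = np.zeros(n, dtype=bool)

    rings, polygons, neighbors = [], [], []
    areas = np.empty(n)
    perims = np.empty(n)
    for i in range(n):
        tris = np.array(incident[i], dtype=int)
        min_verts = 2 if boundary[i] else 3
        if tris.size < min_verts:
            raise TessellationDegeneracyError(
                f"cell {i} has fewer than {min_verts} Voronoi vertices"
            )
        verts = centers_c[tris]
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        order = np.argsort(ang)
        if boundary[i]:
            # start the ring after the largest angular gap (the outward side)
            a_sorted = ang[order]
            gaps = np.diff(np.concatenate([a_sorted, [a_sorted[0] + 2 * np.pi]]))
            order = np.roll(order, -(int(np.argmax(gaps)) + 1))
        tris = tris[order]
        verts = verts[order]
        rings.append(tris)
        polygons.append(verts)
        areas[i] = _polygon_area(verts)
        perims[i] = _polygon_perimeter(verts)
        nbrs = np.unique(tri_corners[tris])
        neighbors.append(nbrs[nbrs != i])
    return TessellationResult(
        polygons=polygons,
        areas=areas,
        perimeters=perims,
        neighbors=neighbors,
        boundary=boundary,
        rings=[r for r in rings],
        tri_corners=tri_corners,
        tri_positions=tri_pos,
        circumcenters=centers_c,
    )


def _polygon_area(verts):
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def _polygon_perimeter(verts):
    return float(np.sum(np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)))


def _circumcenter_jacobians(p1, p2, p3, c):
    """d(circumcenter)/d(corner) for each triangle.

    Returns (J1, J2, J3), each (T, 2, 2) with J[t, a, b] = dc_a / dp_b.
    """
    u = p2 - p1
    v = p3 - p1
    cp = c - p1
    det = 4.0 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    # inverse of M = 2 [u^T; v^T]
    minv = np.empty((len(u), 2, 2))
    minv[:, 0, 0] = 2.0 * v[:, 1]
    minv[:, 0, 1] = -2.0 * u[:, 1]
    minv[:, 1, 0] = -2.0 * v[:, 0]
    minv[:, 1, 1] = 2.0 * u[:, 0]
    minv /= det[:, None, None]
    # dc'/du_b = Minv @ [2 (u_b - c'_b), 0]; dc'/dv_b = Minv @ [0, 2 (v_b - c'_b)]
    j2 = 2.0 * minv[:, :, 0][:, :, None] * (u - cp)[:, None, :]
    j3 = 2.0 * minv[:, :, 1][:, :, None] * (v - cp)[:, None, :]
    j1 = np.eye(2)[None, :, :] - j2 - j3
    return j1, j2, j3


def spv_energy_forces(config: SPVConfig, tess: TessellationResult | None = None):
    """Total SPV energy and exact analytic forces on the cell centres.

    The gradient is assembled per Voronoi vertex: each vertex position is
    the circumcenter of a Delaunay triangle and moves with that triangle's
    three generating centres.
    """
    if tess is None:
        tess = tessellate(config)
    n = config.n
    a0 = config.preferred_areas
    p0 = config.preferred_perimeters
    da = tess.areas - a0
    dp = tess.perimeters - p0
    energy = float(
        0.5 * config.area_stiffness * np.sum(da**2)
        + 0.5 * config.perimeter_stiffness * np.sum(dp**2)
    )
    n_tri = tess.circumcenters.shape[0]
    g = np.zeros((n_tri, 2))  # dE/d(circumcenter)
    lam = config.boundary_tension if config.boundary_mode == "open" else 0.0
    for i in range(n):
        tris = tess.rings[i]
        verts = tess.polygons[i]
        nxt = np.roll(verts, -1, axis=0)
        prv = np.roll(verts, 1, axis=0)
        grad_a = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
        e_prev = verts - prv
        e_next = verts - nxt
        len_prev = np.linalg.norm(e_prev, axis=1)
        len_next = np.linalg.norm(e_next, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u_prev = np.where(len_prev[:, None] > 1e-12, e_prev / len_prev[:, None], 0.0)
            u_next = np.where(len_next[:, None] > 1e-12, e_next / len_next[:, None], 0.0)
        grad_p = u_prev + u_next
        contrib = (
            config.area_stiffness * da[i] * grad_a
            + config.perimeter_stiffness * dp[i] * grad_p
        )
        if lam != 0.0 and tess.boundary[i]:
            # line tension on the closing edge (last vertex -> first vertex)
            edge = verts[0] - verts[-1]
            ln = np.linalg.norm(edge)
            if ln > 1e-12:
                contrib[0] += lam * edge / ln
                contrib[-1] -= lam * edge / ln
        np.add.at(g, tris, contrib)
        if lam != 0.0 and tess.boundary[i]:
            edge = np.linalg.norm(tess.polygons[i][0] - tess.polygons[i][-1])
            energy += lam * edge
    # chain through the circumcenters to the generating centres
    p1, p2, p3 = (tess.tri_positions[:, m] for m in range(3))
    jacs = _circumcenter_jacobians(p1, p2, p3, tess.circumcenters)
    forces = np.zeros((n, 2))
    for m in range(3):
        contrib = np.einsum("ta,tab->tb", g, jacs[m])
        np.add.at(forces, tess.tri_corners[:, m], -contrib)
    return energy, forces


def run_spv(
    config: SPVConfig,
    drive: ActiveDriveState,
    dt: float,
    n_steps: int,
    save_every: int,
    seed: int = 0,
    include_initial: bool = False,
) -> Trajectory:
    """Overdamped active Brownian dynamics of the SPV model.

    First-order integration with the tessellation rebuilt every step;
    deterministic for a fixed seed.  Exact Delaunay degeneracies are
    resolved by retrying with a deterministic 1e-10-scale jitter.
    """
    if n_steps < save_every:
        raise ValueError("n_steps must be >= save_every")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    config = config.copy()
    drive = drive.copy()
    zeta = config.friction
    box = config.box if config.boundary_mode == "periodic" else None
    pos_unwrapped = config.centers.copy()
    sqrt_var = np.sqrt(2.0 * dt / drive.persistence)

    def forces_with_retry():
        for attempt in range(3):
            try:
                return spv_energy_forces(config)[1]
            except TessellationDegeneracyError:
                jitter_rng = np.random.default_rng(seed + 7919 * (attempt + 1))
                config.centers = config.centers + 1e-10 * jitter_rng.standard_normal(
                    config.centers.shape
                )
        raise TessellationDegeneracyError("tessellation failed after jitter retries")

    times, frames_p, frames_v, frames_a = [], [], [], []

    def snapshot(t, velocities):
        times.append(t)
        frames_p.append(pos_unwrapped.copy())
        frames_v.append(velocities.copy())
        frames_a.append(drive.angles.copy())

    if include_initial:
        snapshot(0.0, drive.speed * drive.directions + forces_with_retry() / zeta)
    for step in range(1, n_steps + 1):
        forces = forces_with_retry()
        velocities = drive.speed * drive.directions + forces / zeta
        disp = dt * velocities
        pos_unwrapped = pos_unwrapped + disp
        config.centers = config.centers + disp
        if box is not None:
            config.centers = wrap(config.centers, box)
        drive.angles = drive.angles + sqrt_var * rng.standard_normal(config.n)
        if step % save_every == 0 or step == n_steps:
            snapshot(step * dt, velocities)
    radii = np.sqrt(config.preferred_areas / np.pi)
    return Trajectory(
        np.array(times),
        np.array(frames_p),
        np.array(frames_v),
        np.array(frames_a),
        box if box is not None else np.array([np.inf, np.inf]),
        radii,
        metadata={
            "dt": dt,
            "n_steps": n_steps,
            "save_every": save_every,
            "seed": seed,
            "v0": drive.speed,
            "tau": drive.persistence,
            "model": "spv",
            "p0bar": config.shape_factor,
            "K": config.area_stiffness,
            "Gamma": config.perimeter_stiffness,
            "preferred_areas": config.preferred_areas.copy(),
        },
    )


def hexagonal_spv(
    n_side: int = 6,
    area: float = 1.0,
    shape_factor: float | None = None,
    **kwargs,
) -> SPVConfig:
    """Periodic hexagonal (honeycomb-tiled) reference configuration.

    With ``shape_factor`` left at the regular-hexagon value
    p_hex = 6 / (3 sqrt(3)/2)^(1/2) ~ 3.722 and A0 equal to the tile area,
    the configuration has exactly zero energy and zero forces.
    """
    p_hex = 6.0 / np.sqrt(1.5 * np.sqrt(3.0))
    if shape_factor is None:
        shape_factor = p_hex
    spacing = np.sqrt(2.0 * area / np.sqrt(3.0))  # triangular lattice constant
    pts = []
    for r in range(n_side):
        for c in range(n_side):
            pts.append([(c + 0.5 * (r % 2)) * spacing, r * spacing * np.sqrt(3) / 2])
    box = np.array([n_side * spacing, n_side * spacing * np.sqrt(3) / 2])
    return SPVConfig(
        np.array(pts),
        preferred_areas=np.full(n_side * n_side, area),
        box=box,
        shape_factor=shape_factor,
        **kwargs,
    )
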