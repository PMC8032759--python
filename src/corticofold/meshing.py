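"""Tetrahedral meshes of ellipsoidal geometries.

This module is the pipeline's synthetic-geometry factory.  It builds
tetrahedral volume meshes of ellipsoids of prescribed semi-axes at a
controllable mesh density (tetrahedra per cm^3), extracts their boundary
surface, and handles the coordinate conventions the growth simulation relies
on: millimetre coordinates for geometry definition, and normalized
coordinates (longest axis spanning [-1, 1]) for the mechanics.

The tetrahedralizer is lattice-based: interior vertices sit on a
body-centered cubic lattice with a small deterministic jitter (the
symmetry-breaking perturbation any buckling simulation needs), boundary
vertices come from a subdivided icosahedron mapped onto the exact ellipsoid
surface, and the connectivity is the Delaunay tetrahedralization of the
combined point set — for a convex body this fills the geometry exactly and
its boundary faces are well-shaped chords of the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _geometry

__all__ = [
    "EllipsoidSpec",
    "TetMesh",
    "NormalizationRecord",
    "InvalidSpecError",
    "DegenerateGeometryError",
    "build_ellipsoid_tetmesh",
    "elongation_family",
    "normalize",
    "denormalize",
    "scaled_initial_thickness",
    "mesh_spacing",
    "mesh_density",
    "material_depth",
]

MM3_PER_CM3 = 1000.0

# Reference geometry used throughout: two equatorial radii and a polar radius
# of about 10, 9 and 7 mm, i.e. a 20 mm longitudinal length.
REFERENCE_SEMI_AXES = (10.0, 9.0, 7.0)


class InvalidSpecError(ValueError):
    """Raised for degenerate ellipsoid specifications (non-positive axes)."""


class DegenerateGeometryError(ValueError):
    """Raised when a mesh has zero extent and cannot be normalized."""


@dataclass(frozen=True)
class EllipsoidSpec:
    """Ellipsoid semi-axes in millimetres."""

    semi_axis_x: float
    semi_axis_y: float
    semi_axis_z: float

    def __post_init__(self) -> None:
        if min(self.semi_axis_x, self.semi_axis_y, self.semi_axis_z) <= 0:
            raise InvalidSpecError(
                f"all semi-axes must be positive, got "
                f"({self.semi_axis_x}, {self.semi_axis_y}, {self.semi_axis_z})"
            )

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.semi_axis_x, self.semi_axis_y, self.semi_axis_z])

    @property
    def volume(self) -> float:
        """Analytic volume (4/3)*pi*a*b*c in mm^3."""
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    @classmethod
    def reference(cls) -> "EllipsoidSpec":
        return cls(*REFERENCE_SEMI_AXES)


@dataclass(frozen=True)
class NormalizationRecord:
    """Maps millimetre coordinates to the normalized simulation frame.

    Coordinates are centered on ``center_mm`` and scaled by ``2 / length_mm``
    so the longest axis spans [-1, 1].  ``length_mm`` is the *full*
    longitudinal length L; the cortical-thickness parameter fed to the growth
    sigmoid is H_mm / L (so a 0.83 mm cortex on a 20 mm geometry enters the
    model as 0.042), which is deliberately half the coordinate-unit thickness
    H_mm * 2 / L.  Both conventions are exposed here.
    """

    length_mm: float
    center_mm: np.ndarray

    def to_normalized(self, coords_mm: np.ndarray) -> np.ndarray:
        return (coords_mm - self.center_mm) * (2.0 / self.length_mm)

    def to_mm(self, coords_normalized: np.ndarray) -> np.ndarray:
        return coords_normalized * (self.length_mm / 2.0) + self.center_mm

    def thickness_parameter(self, thickness_mm: float,
                            convention: str = "longitudinal") -> float:
        """Normalized cortical thickness for the growth law.

        ``longitudinal`` (default): H/L, matching the convention that a
        0.83 mm cortex normalizes to 0.042.  ``coordinate``: H * 2/L, the
        thickness measured in the [-1, 1] coordinate units.
        """
        if convention == "longitudinal":
            return thickness_mm / self.length_mm
        if convention == "coordinate":
            return 2.0 * thickness_mm / self.length_mm
        raise ValueError(f"unknown thickness convention: {convention!r}")


# Outward-oriented faces of a positively oriented tetrahedron (0, 1, 2, 3).
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with its extracted boundary surface.

    ``vertices`` are in the units named by ``units`` ("mm" or "normalized").
    Every tetrahedron has positive signed volume; ``boundary_faces`` are the
    faces belonging to exactly one tetrahedron, wound so their normals point
    outward.
    """

    vertices: np.ndarray
    tets: np.ndarray
    units: str = "mm"
    boundary_faces: np.ndarray = field(init=False)
    is_boundary_vertex: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.tets.size and self.tets.max() >= len(self.vertices):
            raise ValueError("tetrahedron refers to a vertex index out of range")
        vols = self.tet_volumes()
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise ValueError(
                f"{bad.size} tetrahedra have non-positive volume "
                f"(first indices {bad[:5].tolist()}); fix the vertex ordering"
            )
        self.boundary_faces = _boundary_faces(self.tets)
        self.is_boundary_vertex = np.zeros(len(self.vertices), dtype=bool)
        if self.boundary_faces.size:
            self.is_boundary_vertex[np.unique(self.boundary_faces)] = True

    # -- basic measures ----------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        ) / 6.0

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def edges(self) -> np.ndarray:
        """Unique undirected tetrahedron edges as (n_edges, 2) indices."""
        pairs = self.tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
        return np.unique(np.sort(pairs, axis=1), axis=0)

    def surface(self):
        """Boundary surface as a trimesh.Trimesh (shares vertex indexing)."""
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(),
            faces=self.boundary_faces.copy(),
            process=False,
        )

    def with_vertices(self, vertices: np.ndarray, units: str | None = None) -> "TetMesh":
        return TetMesh(vertices=vertices, tets=self.tets.copy(),
                       units=self.units if units is None else units)


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one tet, outward-wound."""
    if not len(tets):
        return np.empty((0, 3), dtype=np.int64)
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return np.ascontiguousarray(faces[counts[inverse] == 1])


# -- mesh generation -------------------------------------------------------

def build_ellipsoid_tetmesh(
    spec: EllipsoidSpec,
    target_density: float,
    seed: int = 0,
    jitter: float = 0.15,
) -> TetMesh:
    """Mesh an ellipsoid at approximately ``target_density`` tets/cm^3.

    Interior vertices form a body-centered cubic lattice of pitch h chosen
    from the target density, jittered by ``jitter``*h (deterministic given
    ``seed``) to break the lattice symmetry; surface vertices come from a
    subdivided icosahedron mapped onto the ellipsoid with a matching
    spacing.  The connectivity is the Delaunay tetrahedralization of the
    combined points: for a convex body it tiles the inscribed volume exactly
    and the boundary triangles are chords of the analytic surface.
    Near-degenerate boundary slivers are dropped.
    """
    if not isinstance(spec, EllipsoidSpec):
        spec = EllipsoidSpec(*spec)
    if not (1e2 <= target_density <= 1e7):
        raise ValueError(
            f"target_density must be within [1e2, 1e7] tets/cm^3, got {target_density}"
        )
    from scipy.spatial import Delaunay

    axes = spec.semi_axes
    rho_mm = target_density / MM3_PER_CM3
    # BCC lattice: 2 points per h^3; Delaunay yields ~6 tets per point.
    # The leading constant is an empirical calibration of the realized
    # density against the request.
    h = (14.0 / rho_mm) ** (1.0 / 3.0)

    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, h, size=3)
    n_cells = np.ceil(axes / h).astype(int) + 2
    ax = [np.arange(-n, n + 1) for n in n_cells]
    cubic = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3) * h
    points = np.vstack([cubic, cubic + h / 2.0]) + offset
    points += rng.uniform(-jitter * h, jitter * h, size=points.shape)

    # Keep interior points a safety margin below the surface so boundary
    # triangles connect cleanly to the icosphere sampling.
    f = np.sqrt(np.einsum("ij,ij->i", points / axes, points / axes))
    r = np.linalg.norm(points, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.where(f > 0, r * (1.0 / np.maximum(f, 1e-12) - 1.0), axes.min())
    interior = points[(f < 1.0) & (gap > 0.45 * h)]

    surface = _icosphere_points(axes, h, rng)
    if len(interior):
        # Interface quality: interior points crowding a surface point breed
        # near-coplanar tets; keep a clear gap to the surface sampling.
        d, _ = cKDTree(surface).query(interior, k=1)
        interior = interior[d > 0.55 * h]
    if len(interior) == 0:
        verts = surface
    else:
        verts = np.vstack([interior, surface])

    tri = Delaunay(verts)
    tets = tri.simplices.astype(np.int64)
    v = verts[tets]
    vols = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    ) / 6.0
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    # Drop degenerate tets and flat hull caps: tets whose four vertices all
    # lie on the surface and whose smallest altitude is a tiny fraction of
    # the lattice pitch (coplanar surface quadruples).  Removing them leaves
    # at most shallow dents on the hull, never interior holes.
    keep = vols > 1e-9 * np.median(vols)
    n_interior = len(interior)
    all_surface = (tets >= n_interior).all(axis=1)
    cand = np.flatnonzero(all_surface & keep)
    if cand.size:
        vc = verts[tets[cand]]
        amax = np.zeros(cand.size)
        for fidx in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
            a = 0.5 * np.linalg.norm(
                np.cross(vc[:, fidx[1]] - vc[:, fidx[0]],
                         vc[:, fidx[2]] - vc[:, fidx[0]]), axis=1)
            amax = np.maximum(amax, a)
        altitude = 3.0 * vols[cand] / np.maximum(amax, 1e-300)
        keep[cand[altitude < 0.05 * h]] = False
    tets = tets[keep]
    used, tets = np.unique(tets, return_inverse=True)
    tets = tets.reshape(-1, 4)
    verts = verts[used]
    verts = _smooth_interior(verts, tets, used < n_interior)
    return TetMesh(vertices=verts, tets=tets, units="mm")


def _smooth_interior(verts, tets, interior_mask, n_iter=4, step=0.4):
    """Laplacian smoothing of interior vertices (surface fixed): thickens
    the thin interface tets between the surface shell and the lattice.
    Vertex updates that would invert a tetrahedron are rolled back."""
    import scipy.sparse as sp

    pairs = tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2)
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    n = len(verts)
    adj = sp.coo_matrix(
        (np.ones(2 * len(pairs)),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    floor = 0.1 * np.median(_signed_volumes(verts, tets))
    for _ in range(n_iter):
        prev = verts.copy()
        prev_vols = _signed_volumes(verts, tets)
        mean = adj @ verts / deg[:, None]
        verts = verts.copy()
        verts[interior_mask] = ((1 - step) * verts[interior_mask]
                                + step * mean[interior_mask])
        # A move may not push any tet below the quality floor (tets already
        # below it may only grow).
        limit = np.minimum(floor, 0.999 * prev_vols)
        for _guard in range(8):
            bad = _signed_volumes(verts, tets) <= limit
            if not bad.any():
                break
            rb = np.unique(tets[bad])
            verts[rb] = prev[rb]
    return verts


def _icosphere_points(axes, h, rng, jitter: float = 0.1):
    """Ellipsoid surface sampling at spacing ~h: subdivided icosahedron
    mapped through the unit sphere, with a small tangential jitter
    (reprojected) so the Delaunay connectivity avoids coplanar fans."""
    import trimesh

    mean_radius = float(np.prod(axes)) ** (1.0 / 3.0)
    subdiv = int(np.clip(np.ceil(np.log2(max(1.1 * mean_radius / h, 1.0))), 0, 8))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    pts = np.asarray(ico.vertices) * axes
    pts += rng.uniform(-jitter * h, jitter * h, size=pts.shape)
    lv = np.sqrt(np.einsum("ij,ij->i", pts / axes, pts / axes))
    return pts / lv[:, None]


def _signed_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = verts[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    ) / 6.0


# Default elongation family: y-axis length fixed at 18 mm, x from 19 to
# 27 mm and z from 18 down to 12 mm, elongation ratio x/z from ~1.06 to 2.25.
DEFAULT_Y_LENGTH = 18.0
DEFAULT_X_LENGTHS = (19.0, 21.0, 23.0, 25.0, 27.0)
DEFAULT_Z_LENGTHS = (18.0, 16.5, 15.0, 13.5, 12.0)


def elongation_family(
    y_length_mm: float = DEFAULT_Y_LENGTH,
    x_lengths_mm=DEFAULT_X_LENGTHS,
    z_lengths_mm=DEFAULT_Z_LENGTHS,
    target_density: float = 5e4,
    seed: int = 0,
    preserve_volume: bool = False,
    volume_mm3: float | None = None,
) -> list[tuple[float, TetMesh]]:
    """Build the elongated-geometry family, one mesh per (x, z) axis pair.

    Returns ``(elongation_ratio, mesh)`` pairs with ratio = x_length /
    z_length.  With ``preserve_volume`` the z length is recomputed so every
    member matches ``volume_mm3`` (default: the first member's analytic
    volume) exactly instead of using the prescribed z length.
    """
    x_lengths = list(x_lengths_mm)
    z_lengths = list(z_lengths_mm)
    if len(x_lengths) != len(z_lengths):
        raise ValueError("x and z length lists must have equal length")
    out = []
    for i, (lx, lz) in enumerate(zip(x_lengths, z_lengths)):
        if preserve_volume:
            if volume_mm3 is None:
                volume_mm3 = EllipsoidSpec(
                    x_lengths[0] / 2, y_length_mm / 2, z_lengths[0] / 2
                ).volume
            lz = 6.0 * volume_mm3 / (np.pi * lx * y_length_mm)
        spec = EllipsoidSpec(lx / 2.0, y_length_mm / 2.0, lz / 2.0)
        mesh = build_ellipsoid_tetmesh(spec, target_density, seed=seed + i)
        out.append((lx / lz, mesh))
    return out


# -- normalization and thickness conventions -------------------------------

def normalize(mesh: TetMesh) -> tuple[TetMesh, NormalizationRecord]:
    """Center the mesh and scale so the longest axis spans [-1, 1].

    The record stores L = the full longitudinal length (the largest
    axis-aligned extent, in mm), used both for the coordinate scale 2/L and
    for the thickness parameter H/L.
    """
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    extent = hi - lo
    L = float(extent.max())
    if L <= 0:
        raise DegenerateGeometryError("mesh has zero spatial extent")
    record = NormalizationRecord(length_mm=L, center_mm=(lo + hi) / 2.0)
    return mesh.with_vertices(record.to_normalized(mesh.vertices),
                              units="normalized"), record


def denormalize(mesh: TetMesh, record: NormalizationRecord) -> TetMesh:
    return mesh.with_vertices(record.to_mm(mesh.vertices), units="mm")


def scaled_initial_thickness(
    reference_thickness_mm: float,
    brain_longitudinal_length_mm: float,
    mesh_longitudinal_length_mm: float,
) -> float:
    """Scale a cortical thickness to a smaller geometry.

    Preserves the thickness-to-longitudinal-length ratio: a 2.5 mm cortex on
    a 60 mm fetal brain maps to 0.83 mm on a 20 mm ellipsoid.
    """
    if min(reference_thickness_mm, brain_longitudinal_length_mm,
           mesh_longitudinal_length_mm) <= 0:
        raise ValueError("all lengths must be positive")
    return reference_thickness_mm * (
        mesh_longitudinal_length_mm / brain_longitudinal_length_mm
    )


# -- mesh measures ---------------------------------------------------------

def mesh_spacing(mesh: TetMesh) -> float:
    """Mean edge length over the unique tetrahedron edges (the ``a`` of the
    stability time step)."""
    e = mesh.edges()
    return float(
        np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean()
    )


def mesh_density(mesh: TetMesh) -> float:
    """Tetrahedron count per cm^3 (mm meshes) or per unit volume cubed."""
    vol = mesh.total_volume
    if vol <= 0:
        raise DegenerateGeometryError("mesh has non-positive volume")
    if mesh.units == "mm":
        return mesh.n_tets / (vol / MM3_PER_CM3)
    return mesh.n_tets / vol


def material_depth(mesh: TetMesh) -> np.ndarray:
    """Per-vertex Euclidean distance to the boundary surface (material frame).

    Boundary vertices are exactly 0; interior vertices use the exact
    point-to-nearest-boundary-triangle distance.
    """
    tri = mesh.vertices[mesh.boundary_faces]
    depth = np.zeros(mesh.n_vertices)
    interior = ~mesh.is_boundary_vertex
    if interior.any():
        d, _ = nearest_triangle(mesh.vertices[interior], tri)
        depth[interior] = d
    return depth


def nearest_triangle(points: np.ndarray, triangles: np.ndarray,
                     n_candidates: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Distance and index of the nearest triangle for each query point.

    KD-tree on triangle centroids prefilters candidates; the exact
    point-triangle distance decides among them.  The candidate set is grown
    with a safety radius so the result equals the exhaustive answer.
    """
    centroids = triangles.mean(axis=1)
    radii = np.linalg.norm(triangles - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(radii.max()) if len(radii) else 0.0
    tree = cKDTree(centroids)
    k = min(n_candidates, len(centroids))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    if idx.ndim == 1:
        idx = idx[:, None]
    d, j = _geometry.point_triangle_nearest(
        np.ascontiguousarray(points, dtype=np.float64),
        np.ascontiguousarray(triangles, dtype=np.float64),
        np.ascontiguousarray(idx, dtype=np.int64),
    )
    # Verify against the tree with the exact distance as radius: any centroid
    # closer than d + rmax could host a closer triangle.
    miss = tree.query_ball_point(points, r=d + rmax, return_sorted=False)
    need = np.array([len(m) > k for m in miss])
    if need.any():
        pts = np.flatnonzero(need)
        for p in pts:
            cand = np.asarray(miss[p], dtype=np.int64)[None, :]
            dd, jj = _geometry.point_triangle_nearest(
                points[p : p + 1], triangles, cand
            )
            if dd[0] < d[p]:
                d[p], j[p] = dd[0], jj[0]
    return d, j
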