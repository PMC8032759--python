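"""Surface morphometry: curvature tensors, gyrification index, sulcal depth.

Curvature follows the Rusinkiewicz estimator: a per-face second-fundamental
tensor is fit by least squares from the face's three edge directions and the
per-vertex normal differences along them, rotated into each vertex's tangent
frame, and accumulated with mixed-Voronoi corner-area weights.  The sign
convention gives positive principal curvatures on convex surfaces with
outward normals.

The folding descriptors are a dimensionless curvature statistic (mean
absolute mean-curvature times the square root of total area, scale
invariant), the 3D gyrification index (folded area over the area of its
smooth enclosing reference surface), and a ray-cast sulcal depth against
that reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _geometry

__all__ = [
    "CurvatureField",
    "DepthField",
    "vertex_normals",
    "corner_areas",
    "curvature_field",
    "dimensionless_curvature_stat",
    "convex_hull_reference",
    "gyrification_index",
    "sulcal_depth",
    "curvature_correlation",
]


def _as_vf(surface):
    if hasattr(surface, "vertices"):
        return (np.asarray(surface.vertices, dtype=np.float64),
                np.asarray(surface.faces, dtype=np.int64))
    v, f = surface
    return np.asarray(v, dtype=np.float64), np.asarray(f, dtype=np.int64)


def _face_geometry(verts, faces):
    tri = verts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas2 = np.linalg.norm(fn, axis=1)
    degenerate = areas2 <= 1e-300
    if degenerate.any():
        warnings.warn(f"excluding {degenerate.sum()} zero-area faces")
    fn = np.where(degenerate[:, None], 0.0, fn / np.where(degenerate, 1.0, areas2)[:, None])
    return tri, fn, areas2 / 2.0, degenerate


def corner_areas(verts, faces):
    """Mixed Voronoi corner areas (Meyer et al.): per (face, corner) weight
    whose per-vertex sums are the lumped vertex areas."""
    tri = verts[faces]
    # edge vectors opposite each corner: e[i] = v[(i+2)] - v[(i+1)]
    e = np.stack([tri[:, 2] - tri[:, 1],
                  tri[:, 0] - tri[:, 2],
                  tri[:, 1] - tri[:, 0]], axis=1)
    l2 = np.einsum("fij,fij->fi", e, e)
    area = 0.5 * np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)
    # cot(angle at corner i) = -e[i+1].e[i+2] / (2 A)
    cot = np.empty_like(l2)
    for i in range(3):
        cot[:, i] = -np.einsum(
            "fj,fj->f", e[:, (i + 1) % 3], e[:, (i + 2) % 3]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = cot / (2.0 * area)[:, None]
    ca = np.empty_like(l2)
    for i in range(3):
        ca[:, i] = (l2[:, (i + 1) % 3] * cot[:, (i + 1) % 3]
                    + l2[:, (i + 2) % 3] * cot[:, (i + 2) % 3]) / 8.0
    obtuse = cot < 0.0
    any_obtuse = obtuse.any(axis=1)
    for i in range(3):
        sel = any_obtuse
        ca[sel, i] = np.where(obtuse[sel, i], area[sel] / 2.0, area[sel] / 4.0)
    ca[~np.isfinite(ca)] = 0.0
    return ca


def vertex_normals(surface):
    """Outward unit vertex normals: corner-area-weighted average of the
    adjacent face normals."""
    verts, faces = _as_vf(surface)
    _, fn, _, _ = _face_geometry(verts, faces)
    ca = corner_areas(verts, faces)
    vn = np.zeros_like(verts)
    for i in range(3):
        np.add.at(vn, faces[:, i], ca[:, i][:, None] * fn)
    norms = np.linalg.norm(vn, axis=1)
    if (norms == 0).any():
        raise ValueError("vertex with degenerate normal (non-manifold patch?)")
    return vn / norms[:, None]


@dataclass
class CurvatureField:
    """Per-vertex second-fundamental form and its eigenstructure.

    ``k1 >= k2`` by value; ``dir1``/``dir2`` are the corresponding unit
    tangent directions; ``mean`` = (k1 + k2) / 2.  ``frame_u``/``frame_v``
    span each vertex's tangent plane and ``II`` is expressed in that frame.
    """

    k1: np.ndarray
    k2: np.ndarray
    dir1: np.ndarray
    dir2: np.ndarray
    normals: np.ndarray
    II: np.ndarray
    frame_u: np.ndarray
    frame_v: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.k1 + self.k2)

    def max_abs_direction(self) -> np.ndarray:
        """Principal direction of the larger-|K| curvature (the across-fold
        direction on folded surfaces)."""
        pick1 = np.abs(self.k1) >= np.abs(self.k2)
        return np.where(pick1[:, None], self.dir1, self.dir2)


def _rotate_frame(u, v, old_n, new_n):
    """Rotate tangent frames (u, v) taking old_n to new_n (vectorized)."""
    ndot = np.einsum("ij,ij->i", old_n, new_n)
    flip = ndot <= -1.0 + 1e-12
    safe = np.where(flip, 1.0, 1.0 + ndot)
    perp = new_n - ndot[:, None] * old_n
    dperp = (old_n + new_n) / safe[:, None]
    u_new = u - dperp * np.einsum("ij,ij->i", u, perp)[:, None]
    v_new = v - dperp * np.einsum("ij,ij->i", v, perp)[:, None]
    u_new[flip] = -u[flip]
    v_new[flip] = -v[flip]
    return u_new, v_new


def curvature_field(surface) -> CurvatureField:
    """Rusinkiewicz per-vertex curvature tensor estimation."""
    verts, faces = _as_vf(surface)
    tri, fn, fareas, degenerate = _face_geometry(verts, faces)
    vnorm = vertex_normals(surface)
    ca = corner_areas(verts, faces)
    point_area = np.zeros(len(verts))
    for i in range(3):
        np.add.at(point_area, faces[:, i], ca[:, i])

    # Face frames: t along first edge, b = n x t.
    e0 = tri[:, 2] - tri[:, 1]
    e1 = tri[:, 0] - tri[:, 2]
    e2 = tri[:, 1] - tri[:, 0]
    tf = e0 / np.linalg.norm(e0, axis=1)[:, None]
    bf = np.cross(fn, tf)

    # Least-squares fit of the per-face tensor [[a, b], [b, c]] from the
    # three (edge, normal difference) pairs.
    edges = np.stack([e0, e1, e2], axis=1)
    dn = np.stack(
        [vnorm[faces[:, 2]] - vnorm[faces[:, 1]],
         vnorm[faces[:, 0]] - vnorm[faces[:, 2]],
         vnorm[faces[:, 1]] - vnorm[faces[:, 0]]], axis=1)
    x = np.einsum("fej,fj->fe", edges, tf)
    y = np.einsum("fej,fj->fe", edges, bf)
    du = np.einsum("fej,fj->fe", dn, tf)
    dv = np.einsum("fej,fj->fe", dn, bf)
    # Normal equations for rows (x, y, 0; 0, x, y) per edge.
    ata = np.zeros((len(faces), 3, 3))
    atb = np.zeros((len(faces), 3))
    ata[:, 0, 0] = (x * x).sum(axis=1)
    ata[:, 0, 1] = (x * y).sum(axis=1)
    ata[:, 1, 1] = (x * x + y * y).sum(axis=1)
    ata[:, 1, 2] = (x * y).sum(axis=1)
    ata[:, 2, 2] = (y * y).sum(axis=1)
    ata[:, 1, 0] = ata[:, 0, 1]
    ata[:, 2, 1] = ata[:, 1, 2]
    atb[:, 0] = (du * x).sum(axis=1)
    atb[:, 1] = (du * y + dv * x).sum(axis=1)
    atb[:, 2] = (dv * y).sum(axis=1)
    good = ~degenerate & (np.linalg.det(ata) > 1e-300)
    abc = np.zeros((len(faces), 3))
    abc[good] = np.linalg.solve(ata[good], atb[good][..., None])[..., 0]

    # Vertex frames: any unit tangent and its normal-cross complement.
    ref = np.zeros_like(vnorm)
    smallest = np.argmin(np.abs(vnorm), axis=1)
    ref[np.arange(len(verts)), smallest] = 1.0
    up = np.cross(vnorm, ref)
    up /= np.linalg.norm(up, axis=1)[:, None]
    vp = np.cross(vnorm, up)

    vert_tensor = np.zeros((len(verts), 3))  # (ku, kuv, kv) in vertex frame
    for i in range(3):
        vi = faces[:, i]
        ru, rv = _rotate_frame(up[vi], vp[vi], vnorm[vi], fn)
        u1 = np.einsum("fj,fj->f", ru, tf)
        v1 = np.einsum("fj,fj->f", ru, bf)
        u2 = np.einsum("fj,fj->f", rv, tf)
        v2 = np.einsum("fj,fj->f", rv, bf)
        a, b, c = abc[:, 0], abc[:, 1], abc[:, 2]
        ku = a * u1 * u1 + 2.0 * b * u1 * v1 + c * v1 * v1
        kuv = a * u1 * u2 + b * (u1 * v2 + u2 * v1) + c * v1 * v2
        kv = a * u2 * u2 + 2.0 * b * u2 * v2 + c * v2 * v2
        with np.errstate(divide="ignore", invalid="ignore"):
            wt = np.where(point_area[vi] > 0, ca[:, i] / point_area[vi], 0.0)
        wt = np.where(good, wt, 0.0)
        np.add.at(vert_tensor, vi, wt[:, None] * np.stack([ku, kuv, kv], axis=1))

    ku, kuv, kv = vert_tensor[:, 0], vert_tensor[:, 1], vert_tensor[:, 2]
    # Eigen-decomposition of [[ku, kuv], [kuv, kv]].
    half_tr = 0.5 * (ku + kv)
    disc = np.sqrt(np.maximum(0.25 * (ku - kv) ** 2 + kuv**2, 0.0))
    k1 = half_tr + disc
    k2 = half_tr - disc
    # Eigenvector for k1 in the (up, vp) frame.
    c1 = np.stack([kuv, k1 - ku], axis=1)
    alt = np.stack([k1 - kv, kuv], axis=1)
    use_alt = np.linalg.norm(c1, axis=1) < 1e-12
    c1[use_alt] = alt[use_alt]
    iso = np.linalg.norm(c1, axis=1) < 1e-12
    c1[iso] = [1.0, 0.0]
    c1 /= np.linalg.norm(c1, axis=1)[:, None]
    dir1 = c1[:, 0:1] * up + c1[:, 1:2] * vp
    dir2 = np.cross(vnorm, dir1)

    II = np.empty((len(verts), 2, 2))
    II[:, 0, 0] = ku
    II[:, 0, 1] = kuv
    II[:, 1, 0] = kuv
    II[:, 1, 1] = kv
    return CurvatureField(k1=k1, k2=k2, dir1=dir1, dir2=dir2, normals=vnorm,
                          II=II, frame_u=up, frame_v=vp)


def surface_area(surface) -> float:
    verts, faces = _as_vf(surface)
    tri = verts[faces]
    return float(
        0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
    )


def dimensionless_curvature_stat(surface, field: CurvatureField | None = None) -> float:
    """Mean over vertices of |mean curvature| times sqrt(total surface
    area): a scale-invariant folding-complexity statistic."""
    if field is None:
        field = curvature_field(surface)
    return float(np.mean(np.abs(field.mean)) * np.sqrt(surface_area(surface)))


def convex_hull_reference(initial_smooth_surface, deformed_surface,
                          mode: str = "bbox"):
    """Smooth enclosing reference ("convex hull") for the GI and depth.

    ``bbox`` (default): the initial smooth surface scaled per axis so its
    axis-aligned bounding-box lengths equal the deformed surface's, then
    recentred on the deformed bounding box.  ``true``: the computational
    convex hull of the deformed points (for externally supplied meshes).
    """
    import trimesh

    dv, _ = _as_vf(deformed_surface)
    if mode == "true":
        from scipy.spatial import ConvexHull

        hull = ConvexHull(dv)
        return trimesh.Trimesh(vertices=hull.points,
                               faces=hull.simplices, process=True)
    if mode != "bbox":
        raise ValueError(f"unknown hull mode: {mode!r}")
    iv, iface = _as_vf(initial_smooth_surface)
    ext_i = iv.max(axis=0) - iv.min(axis=0)
    ext_d = dv.max(axis=0) - dv.min(axis=0)
    if (ext_i <= 0).any() or (ext_d <= 0).any():
        raise ValueError("degenerate (zero) bounding-box extent")
    scale = ext_d / ext_i
    center_i = (iv.max(axis=0) + iv.min(axis=0)) / 2.0
    center_d = (dv.max(axis=0) + dv.min(axis=0)) / 2.0
    hv = (iv - center_i) * scale + center_d
    return trimesh.Trimesh(vertices=hv, faces=iface.copy(), process=False)


def gyrification_index(deformed_surface, hull) -> float:
    """3D GI = area(deformed) / area(hull); ~1 for convex surfaces."""
    return surface_area(deformed_surface) / surface_area(hull)


@dataclass
class DepthField:
    """Per-vertex sulcal depth with hull intersection points.

    ``missed`` flags vertices whose ray did not intersect the hull (their
    depth falls back to the nearest point on the hull)."""

    depth: np.ndarray
    intersections: np.ndarray
    missed: np.ndarray


def sulcal_depth(deformed_surface, initial_surface, hull) -> DepthField:
    """Ray-cast depth from the deformed surface to the enclosing hull.

    For each vertex the ray starts at its *initial* (smooth-surface)
    position and passes through its deformed position; the first hull
    triangle hit along that ray defines the intersection, and the depth is
    the distance from the deformed vertex to it.  Vertices whose deformed
    position coincides with the initial one (or whose ray misses) fall back
    to the nearest point on the hull.
    """
    dv, _ = _as_vf(deformed_surface)
    iv, _ = _as_vf(initial_surface)
    if len(dv) != len(iv):
        raise ValueError("deformed and initial surfaces must share vertices")
    hv, hf = _as_vf(hull)
    tris = np.ascontiguousarray(hv[hf])
    scale = float(np.linalg.norm(hv.max(axis=0) - hv.min(axis=0)))

    direction = dv - iv
    lens = np.linalg.norm(direction, axis=1)
    degenerate = lens < 1e-9 * scale
    dirs = direction.copy()
    dirs[degenerate] = [1.0, 0.0, 0.0]  # placeholder; treated as a miss below
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]

    t_hit, j_hit = _geometry.first_ray_hits(
        np.ascontiguousarray(iv), np.ascontiguousarray(dirs), tris,
        -1e-9 * scale,
    )
    missed = ~np.isfinite(t_hit) | degenerate
    inter = np.where(missed[:, None], np.nan, iv + t_hit[:, None] * dirs)
    depth = np.where(missed, np.nan, np.linalg.norm(inter - dv, axis=1))
    if missed.any():
        from .meshing import nearest_triangle

        d, j = nearest_triangle(dv[missed], tris)
        depth[missed] = d
        inter[missed] = tris[j].mean(axis=1)
    return DepthField(depth=depth, intersections=inter, missed=missed)


def curvature_correlation(field_a, field_b) -> float:
    """Pearson correlation of per-vertex mean curvature between two surfaces
    sharing a mesh topology; NaN if either field has zero variance."""
    a = field_a.mean if isinstance(field_a, CurvatureField) else np.asarray(field_a)
    b = field_b.mean if isinstance(field_b, CurvatureField) else np.asarray(field_b)
    if a.shape != b.shape:
        raise ValueError("curvature fields must share vertex correspondence")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance curvature field; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
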