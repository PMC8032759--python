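"""Fold-orientation anisotropy via the Laplace-Beltrami Fiedler vector.

The Fiedler vector (first non-constant eigenfunction of the surface
Laplace-Beltrami operator) varies monotonically along a shape's longest
extension, so its tangent gradient encodes the elongation axis.  The angle
between that gradient and the principal curvature direction of largest |K|
(the across-fold direction) measures each fold's orientation relative to
the elongation axis; the distribution of these angles over the surface,
scored with a KL divergence against uniform, quantifies how anisotropic the
folding pattern is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .curvature import CurvatureField, _as_vf, corner_areas

__all__ = [
    "SpectralField",
    "AngleDistribution",
    "cotangent_laplacian",
    "laplace_beltrami_fiedler",
    "fiedler_gradient",
    "fold_angles",
    "angle_distribution",
    "kl_uniformity",
]


@dataclass
class SpectralField:
    """Fiedler eigenpair of a closed surface with its per-face gradient."""

    phi: np.ndarray
    eigenvalue: float
    face_gradients: np.ndarray
    face_gradient_valid: np.ndarray
    degenerate: bool = False
    residual: float = 0.0


def cotangent_laplacian(surface):
    """Cotangent-weight stiffness matrix L and lumped (mixed Voronoi) mass
    matrix M, both sparse, such that -Delta phi = lambda phi discretizes to
    L phi = lambda M phi with L positive semi-definite."""
    verts, faces = _as_vf(surface)
    n = len(verts)
    tri = verts[faces]
    e = np.stack([tri[:, 2] - tri[:, 1],
                  tri[:, 0] - tri[:, 2],
                  tri[:, 1] - tri[:, 0]], axis=1)
    area2 = np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)
    rows, cols, vals = [], [], []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        with np.errstate(divide="ignore", invalid="ignore"):
            cot = -np.einsum("fc,fc->f", e[:, j], e[:, k]) / area2
        cot = np.where(np.isfinite(cot), cot, 0.0)
        w = 0.5 * cot
        rows += [faces[:, j], faces[:, k]]
        cols += [faces[:, k], faces[:, j]]
        vals += [-w, -w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    ca = corner_areas(verts, faces)
    mass = np.zeros(n)
    for i in range(3):
        np.add.at(mass, faces[:, i], ca[:, i])
    return L, sp.diags(mass)


def laplace_beltrami_fiedler(surface, degeneracy_rtol: float = 0.01) -> SpectralField:
    """Fiedler vector of a connected closed surface.

    Deterministic: a fixed starting vector is used and the sign is set so
    phi is positive at the vertex of largest x-coordinate.  Shapes whose
    lambda_1 has near-multiplicity (the sphere's threefold l = 1 eigenvalue)
    are returned with ``degenerate`` set.
    """
    verts, faces = _as_vf(surface)
    L, M = cotangent_laplacian(surface)
    adj = sp.csr_matrix((np.ones(L.nnz), L.nonzero()), shape=L.shape)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(f"surface is disconnected ({n_comp} components)")

    v0 = np.cos(np.arange(len(verts), dtype=float))  # fixed, non-constant
    k = min(4, len(verts) - 1)
    vals, vecs = eigsh(L, k=k, M=M, sigma=-1e-8, which="LM", v0=v0)
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    lam = float(vals[1])
    phi = vecs[:, 1]
    degenerate = k >= 3 and (vals[2] - lam) <= degeneracy_rtol * abs(lam)

    top = int(np.argmax(verts[:, 0]))
    if phi[top] < 0:
        phi = -phi
    residual = float(
        np.linalg.norm(L @ phi - lam * (M @ phi)) / np.linalg.norm(M @ phi)
    )
    grad, valid = _face_gradients(verts, faces, phi)
    return SpectralField(phi=phi, eigenvalue=lam, face_gradients=grad,
                         face_gradient_valid=valid, degenerate=bool(degenerate),
                         residual=residual)


def _face_gradients(verts, faces, phi):
    tri = verts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    a2 = np.linalg.norm(fn, axis=1)
    ok = a2 > 1e-300
    fn = fn / np.where(ok, a2, 1.0)[:, None]
    grad = np.zeros((len(faces), 3))
    # grad phi = sum_i phi_i * (n x e_opposite_i) / (2 A)
    for i in range(3):
        e_opp = tri[:, (i + 2) % 3] - tri[:, (i + 1) % 3]
        grad += phi[faces[:, i]][:, None] * np.cross(fn, e_opp)
    grad /= np.where(ok, a2, 1.0)[:, None]
    norms = np.linalg.norm(grad, axis=1)
    ref = norms[ok].mean() if ok.any() else 0.0
    valid = ok & (norms > 1e-8 * max(ref, 1e-300))
    unit = grad.copy()
    unit[valid] /= norms[valid][:, None]
    unit[~valid] = 0.0
    return unit, valid


def fiedler_gradient(surface, phi: np.ndarray):
    """Per-face unit tangent gradient of a vertex field (linear shape
    functions); zero-gradient faces are flagged invalid."""
    verts, faces = _as_vf(surface)
    return _face_gradients(verts, faces, np.asarray(phi, dtype=float))


def fold_angles(surface, curv: CurvatureField, spectral: SpectralField,
                isotropy_rtol: float = 0.05) -> np.ndarray:
    """Per-vertex fold angle in [0, 90] degrees (NaN where excluded).

    The face gradients of the Fiedler vector are averaged onto each vertex,
    projected into the vertex tangent plane and renormalized; the angle is
    arccos |<g, d>| with d the principal direction of larger |K|.  Vertices
    with a vanishing gradient or near-isotropic curvature (|K1| ~ |K2|
    within ``isotropy_rtol``) are excluded.
    """
    verts, faces = _as_vf(surface)
    n = len(verts)
    gsum = np.zeros((n, 3))
    gcount = np.zeros(n)
    valid_faces = spectral.face_gradient_valid
    for i in range(3):
        np.add.at(gsum, faces[:, i],
                  np.where(valid_faces[:, None], spectral.face_gradients, 0.0))
        np.add.at(gcount, faces[:, i], valid_faces.astype(float))
    g = gsum
    # project into tangent plane and renormalize
    g -= np.einsum("ij,ij->i", g, curv.normals)[:, None] * curv.normals
    gnorm = np.linalg.norm(g, axis=1)
    ok = (gcount > 0) & (gnorm > 1e-10)
    g[ok] /= gnorm[ok][:, None]

    kmax = np.maximum(np.abs(curv.k1), np.abs(curv.k2))
    aniso = np.abs(np.abs(curv.k1) - np.abs(curv.k2)) > isotropy_rtol * np.maximum(
        kmax, 1e-300
    )
    ok &= aniso & (kmax > 0)

    d = curv.max_abs_direction()
    dots = np.abs(np.einsum("ij,ij->i", g, d))
    angles = np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))
    angles[~ok] = np.nan
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded}/{n} vertices excluded from fold angles")
    return angles


@dataclass
class AngleDistribution:
    """Normalized histogram of fold angles with its uniform reference."""

    bin_edges: np.ndarray
    p: np.ndarray
    q: np.ndarray
    kl: float = field(init=False)

    def __post_init__(self) -> None:
        self.kl = float(np.sum(self.p * np.log(self.p / self.q)))


def angle_distribution(angles, n_bins: int = 18,
                       epsilon: float = 1e-12) -> AngleDistribution:
    """Histogram fold angles over [0, 90] degrees (default 5-degree bins).

    ``epsilon`` is added to each bin count before normalization so the KL
    divergence stays finite on empty bins.  The reference Q is uniform.
    """
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise ValueError("no valid fold angles: distribution undefined")
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(angles, 0.0, 90.0), bins=edges)
    p = counts.astype(float) + epsilon
    p /= p.sum()
    q = np.full(n_bins, 1.0 / n_bins)
    return AngleDistribution(bin_edges=edges, p=p, q=q)


def kl_uniformity(dist: AngleDistribution) -> float:
    """KL divergence (nats) of the angle distribution from uniform."""
    return dist.kl
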