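"""Low-level geometric kernels (numba).

Exact point-triangle closest-point queries and watertight-enough
ray-triangle intersection, used for material depth, penalty contact and
sulcal-depth ray casting.  All kernels are serial and deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _closest_point_on_triangle(p, a, b, c):
    """Closest point on triangle (a, b, c) to p, with barycentric coords.

    Region-based algorithm (Ericson, Real-Time Collision Detection).
    Returns (q, u, v, w) with q = u*a + v*b + w*c.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab[0] * ap[0] + ab[1] * ap[1] + ab[2] * ap[2]
    d2 = ac[0] * ap[0] + ac[1] * ap[1] + ac[2] * ap[2]
    if d1 <= 0.0 and d2 <= 0.0:
        return a, 1.0, 0.0, 0.0
    bp = p - b
    d3 = ab[0] * bp[0] + ab[1] * bp[1] + ab[2] * bp[2]
    d4 = ac[0] * bp[0] + ac[1] * bp[1] + ac[2] * bp[2]
    if d3 >= 0.0 and d4 <= d3:
        return b, 0.0, 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        den = d1 - d3
        v = d1 / den if den != 0.0 else 0.0
        return a + v * ab, 1.0 - v, v, 0.0
    cp = p - c
    d5 = ab[0] * cp[0] + ab[1] * cp[1] + ab[2] * cp[2]
    d6 = ac[0] * cp[0] + ac[1] * cp[1] + ac[2] * cp[2]
    if d6 >= 0.0 and d5 <= d6:
        return c, 0.0, 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        den = d2 - d6
        w = d2 / den if den != 0.0 else 0.0
        return a + w * ac, 1.0 - w, 0.0, w
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        den = (d4 - d3) + (d5 - d6)
        w = (d4 - d3) / den if den != 0.0 else 0.0
        return b + w * (c - b), 0.0, 1.0 - w, w
    s = va + vb + vc
    if s == 0.0:
        return a, 1.0, 0.0, 0.0
    denom = 1.0 / s
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w, 1.0 - v - w, v, w


@njit(cache=True)
def point_triangle_nearest(points, triangles, candidates):
    """Nearest triangle among per-point candidate lists.

    points: (n, 3); triangles: (m, 3, 3); candidates: (n, k) indices into
    triangles.  Returns (distance (n,), index (n,)).
    """
    n = points.shape[0]
    k = candidates.shape[1]
    dist = np.empty(n)
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        best = np.inf
        bestj = -1
        p = points[i]
        for kk in range(k):
            j = candidates[i, kk]
            if j < 0:
                continue
            q, _, _, _ = _closest_point_on_triangle(
                p, triangles[j, 0], triangles[j, 1], triangles[j, 2]
            )
            dx = p[0] - q[0]
            dy = p[1] - q[1]
            dz = p[2] - q[2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
                bestj = j
        dist[i] = np.sqrt(best)
        idx[i] = bestj
    return dist, idx


@njit(cache=True)
def first_ray_hits(origins, directions, triangles, t_min):
    """First intersection parameter t >= t_min of each ray with any triangle.

    Moller-Trumbore over all triangles (exhaustive, deterministic).
    Returns (t (n,), tri index (n,)); t = inf where the ray misses.
    """
    n = origins.shape[0]
    m = triangles.shape[0]
    eps = 1e-12
    t_out = np.full(n, np.inf)
    j_out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        o = origins[i]
        d = directions[i]
        best = np.inf
        bestj = -1
        for j in range(m):
            v0 = triangles[j, 0]
            e1 = triangles[j, 1] - v0
            e2 = triangles[j, 2] - v0
            # h = d x e2
            hx = d[1] * e2[2] - d[2] * e2[1]
            hy = d[2] * e2[0] - d[0] * e2[2]
            hz = d[0] * e2[1] - d[1] * e2[0]
            det = e1[0] * hx + e1[1] * hy + e1[2] * hz
            if -eps < det < eps:
                continue
            inv = 1.0 / det
            sx = o[0] - v0[0]
            sy = o[1] - v0[1]
            sz = o[2] - v0[2]
            u = (sx * hx + sy * hy + sz * hz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = sy * e1[2] - sz * e1[1]
            qy = sz * e1[0] - sx * e1[2]
            qz = sx * e1[1] - sy * e1[0]
            v = (d[0] * qx + d[1] * qy + d[2] * qz) * inv
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2[0] * qx + e2[1] * qy + e2[2] * qz) * inv
            if t >= t_min and t < best:
                best = t
                bestj = j
        t_out[i] = best
        j_out[i] = bestj
    return t_out, j_out
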