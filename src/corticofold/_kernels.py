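"""Numba kernels for the growth FEM: neo-Hookean elastic nodal forces and
vertex-triangle penalty contact.  Serial, deterministic, float64."""

from __future__ import annotations

import numpy as np
from numba import njit

from ._geometry import _closest_point_on_triangle


@njit(cache=True)
def _inv3(m):
    a, b, c = m[0, 0], m[0, 1], m[0, 2]
    d, e, f = m[1, 0], m[1, 1], m[1, 2]
    g, h, i = m[2, 0], m[2, 1], m[2, 2]
    A = e * i - f * h
    B = -(d * i - f * g)
    C = d * h - e * g
    det = a * A + b * B + c * C
    out = np.empty((3, 3))
    inv = 1.0 / det
    out[0, 0] = A * inv
    out[0, 1] = -(b * i - c * h) * inv
    out[0, 2] = (b * f - c * e) * inv
    out[1, 0] = B * inv
    out[1, 1] = (a * i - c * g) * inv
    out[1, 2] = -(a * f - c * d) * inv
    out[2, 0] = C * inv
    out[2, 1] = -(a * h - b * g) * inv
    out[2, 2] = (a * e - b * d) * inv
    return out, det


@njit(cache=True)
def _adj3(m):
    """Adjugate (det * inverse) and determinant; polynomial in the entries,
    finite for singular and inverted matrices."""
    a, b, c = m[0, 0], m[0, 1], m[0, 2]
    d, e, f = m[1, 0], m[1, 1], m[1, 2]
    g, h, i = m[2, 0], m[2, 1], m[2, 2]
    A = e * i - f * h
    B = -(d * i - f * g)
    C = d * h - e * g
    det = a * A + b * B + c * C
    out = np.empty((3, 3))
    out[0, 0] = A
    out[0, 1] = -(b * i - c * h)
    out[0, 2] = b * f - c * e
    out[1, 0] = B
    out[1, 1] = a * i - c * g
    out[1, 2] = -(a * f - c * d)
    out[2, 0] = C
    out[2, 1] = -(a * h - b * g)
    out[2, 2] = a * e - b * d
    return out, det


@njit(cache=True, fastmath=True)
def elastic_forces(pos, tets, bhat, normals, g_tet, vol_mat, mu, K, forces,
                  j_floor):
    """Accumulate neo-Hookean elastic nodal forces; return (energy, min J,
    argmin, n_rescued).

    Per tetrahedron: F = A (G Ahat)^{-1} = A @ (bhat @ Ginv) with bhat =
    Ahat^{-1} and Ginv the analytic inverse of the tangential growth tensor
    G = g I + (1-g) n (x) n.  The strain energy is the modestly compressible
    isochoric/volumetric split
        W = (mu/2) (J^{-2/3} tr(F F^T) - 3) + (K/2) (J - 1)^2,
    integrated over the grown reference volume det(G) * V_material = g^2 V.
    Forces are the exact negative gradient of the total energy.

    With ``j_floor`` > 0 the singular J^{-2/3} factors are evaluated at
    max(J, j_floor) and the volumetric term (written with the cofactor, which
    is polynomial in F) keeps its true J, so forces stay finite and restoring
    through transient element inversion; elements below the floor are counted
    in n_rescued.  With j_floor <= 0 inverted elements are skipped (the
    caller raises).
    """
    m = tets.shape[0]
    energy = 0.0
    minJ = np.inf
    argmin = -1
    n_rescued = 0
    F = np.empty((3, 3))
    B = np.empty((3, 3))
    for e in range(m):
        i0, i1, i2, i3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        g = g_tet[e]
        nx, ny, nz = normals[e, 0], normals[e, 1], normals[e, 2]
        # Ginv = (1/g) I + (1 - 1/g) n (x) n
        ig = 1.0 / g
        cg = 1.0 - ig
        # B = bhat @ Ginv
        bh = bhat[e]
        for r in range(3):
            brx, bry, brz = bh[r, 0], bh[r, 1], bh[r, 2]
            dot = brx * nx + bry * ny + brz * nz
            B[r, 0] = brx * ig + cg * dot * nx
            B[r, 1] = bry * ig + cg * dot * ny
            B[r, 2] = brz * ig + cg * dot * nz
        # A columns = deformed edges
        ax0 = pos[i1, 0] - pos[i0, 0]
        ay0 = pos[i1, 1] - pos[i0, 1]
        az0 = pos[i1, 2] - pos[i0, 2]
        ax1 = pos[i2, 0] - pos[i0, 0]
        ay1 = pos[i2, 1] - pos[i0, 1]
        az1 = pos[i2, 2] - pos[i0, 2]
        ax2 = pos[i3, 0] - pos[i0, 0]
        ay2 = pos[i3, 1] - pos[i0, 1]
        az2 = pos[i3, 2] - pos[i0, 2]
        # F = A @ B  (A columns are edges => A[0, :] = (ax0, ax1, ax2) etc.)
        for col in range(3):
            F[0, col] = ax0 * B[0, col] + ax1 * B[1, col] + ax2 * B[2, col]
            F[1, col] = ay0 * B[0, col] + ay1 * B[1, col] + ay2 * B[2, col]
            F[2, col] = az0 * B[0, col] + az1 * B[1, col] + az2 * B[2, col]
        adj, J = _adj3(F)
        if J < minJ:
            minJ = J
            argmin = e
        if j_floor <= 0.0:
            if J <= 0.0:
                continue
            Jc = J
        else:
            if J < j_floor:
                n_rescued += 1
            Jc = max(J, j_floor)
        I1 = 0.0
        for r in range(3):
            for c in range(3):
                I1 += F[r, c] * F[r, c]
        Jm23 = Jc ** (-2.0 / 3.0)
        vg = g * g * vol_mat[e]
        energy += vg * (0.5 * mu * (Jm23 * I1 - 3.0) + 0.5 * K * (J - 1.0) ** 2)
        c1 = mu * Jm23
        # F^{-T} = cof(F)/J = adj(F)^T / J; evaluate the singular 1/J at Jc.
        c2 = -mu * Jm23 * I1 / (3.0 * Jc) + K * (J - 1.0)
        # P = c1 * F + c2 * cof(F); H = vg * P @ B^T ; force on node j (1..3)
        # is -H[:, j-1], node 0 gets +sum.
        for j in range(3):
            hx = 0.0
            hy = 0.0
            hz = 0.0
            for r in range(3):
                Pxr = c1 * F[0, r] + c2 * adj[r, 0]
                Pyr = c1 * F[1, r] + c2 * adj[r, 1]
                Pzr = c1 * F[2, r] + c2 * adj[r, 2]
                hx += Pxr * B[j, r]
                hy += Pyr * B[j, r]
                hz += Pzr * B[j, r]
            hx *= vg
            hy *= vg
            hz *= vg
            node = tets[e, j + 1]
            forces[node, 0] -= hx
            forces[node, 1] -= hy
            forces[node, 2] -= hz
            forces[i0, 0] += hx
            forces[i0, 1] += hy
            forces[i0, 2] += hz
    return energy, minJ, argmin, n_rescued


@njit(cache=True, fastmath=True)
def contact_forces(pos, faces, pair_vert, pair_face, threshold, stiffness, forces):
    """Vertex-triangle penalty contact over precomputed candidate pairs.

    For each candidate (vertex, boundary triangle) pair closer than
    ``threshold``, a penalty force of magnitude stiffness * (threshold -
    separation) acts on the vertex along the face normal (oriented toward
    the vertex side); the opposite force is spread over the triangle nodes
    by the barycentric coordinates of the closest point, so each pair's
    total is zero.  Returns the number of active contacts.
    """
    n_active = 0
    for p in range(pair_vert.shape[0]):
        vi = pair_vert[p]
        fi = pair_face[p]
        a = pos[faces[fi, 0]]
        b = pos[faces[fi, 1]]
        c = pos[faces[fi, 2]]
        pt = pos[vi]
        # bounding-sphere reject: the triangle lies within the circumradius
        # of its centroid, so a vertex farther than that + threshold cannot
        # be in contact
        cx = (a[0] + b[0] + c[0]) / 3.0
        cy = (a[1] + b[1] + c[1]) / 3.0
        cz = (a[2] + b[2] + c[2]) / 3.0
        dcx = pt[0] - cx
        dcy = pt[1] - cy
        dcz = pt[2] - cz
        d2c = dcx * dcx + dcy * dcy + dcz * dcz
        r2 = 0.0
        for vtx in (a, b, c):
            rx = vtx[0] - cx
            ry = vtx[1] - cy
            rz = vtx[2] - cz
            rr = rx * rx + ry * ry + rz * rz
            if rr > r2:
                r2 = rr
        lim = np.sqrt(r2) + threshold
        if d2c > lim * lim:
            continue
        q, u, v, w = _closest_point_on_triangle(pt, a, b, c)
        dx = pt[0] - q[0]
        dy = pt[1] - q[1]
        dz = pt[2] - q[2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= threshold:
            continue
        # face normal
        e1x, e1y, e1z = b[0] - a[0], b[1] - a[1], b[2] - a[2]
        e2x, e2y, e2z = c[0] - a[0], c[1] - a[1], c[2] - a[2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-30:
            continue
        nx /= nn
        ny /= nn
        nz /= nn
        side = nx * dx + ny * dy + nz * dz
        if side < 0.0:
            nx, ny, nz = -nx, -ny, -nz
        mag = stiffness * (threshold - d)
        fx, fy, fz = mag * nx, mag * ny, mag * nz
        forces[vi, 0] += fx
        forces[vi, 1] += fy
        forces[vi, 2] += fz
        forces[faces[fi, 0], 0] -= u * fx
        forces[faces[fi, 0], 1] -= u * fy
        forces[faces[fi, 0], 2] -= u * fz
        forces[faces[fi, 1], 0] -= v * fx
        forces[faces[fi, 1], 1] -= v * fy
        forces[faces[fi, 1], 2] -= v * fz
        forces[faces[fi, 2], 0] -= w * fx
        forces[faces[fi, 2], 1] -= w * fy
        forces[faces[fi, 2], 2] -= w * fz
        n_active += 1
    return n_active


@njit(cache=True)
def min_pair_separation(pos, faces, pair_vert, pair_face):
    """Minimum vertex-triangle separation over candidate pairs (diagnostic)."""
    best = np.inf
    for p in range(pair_vert.shape[0]):
        vi = pair_vert[p]
        fi = pair_face[p]
        q, _, _, _ = _closest_point_on_triangle(
            pos[vi], pos[faces[fi, 0]], pos[faces[fi, 1]], pos[faces[fi, 2]]
        )
        dx = pos[vi, 0] - q[0]
        dy = pos[vi, 1] - q[1]
        dz = pos[vi, 2] - q[2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < best:
            best = d
    return best
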