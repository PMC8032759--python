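"""Mesh file IO: Netgen neutral (read/write), legacy ASCII VTK and ASCII STL
(write).  A JSON sidecar records the units flag for written artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .meshing import TetMesh

__all__ = [
    "MeshFormatError",
    "read_netgen_neutral",
    "write_netgen_neutral",
    "write_vtk",
    "write_stl",
]


class MeshFormatError(ValueError):
    """Malformed mesh file; the message names the offending line."""


def _tokens(path: Path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if line:
                out.append((lineno, line.split()))
    return out


def read_netgen_neutral(path, units: str = "mm") -> TetMesh:
    """Read a Netgen neutral file (point count, coordinates, element count,
    4-index rows with an optional leading material tag, 1-based indices).

    Negative-volume tetrahedra are reordered to the positive convention on
    read; the surface-element block, if present, is ignored (the boundary is
    re-extracted from the volume elements).
    """
    path = Path(path)
    rows = _tokens(path)
    if not rows:
        raise MeshFormatError(f"{path}: empty file")
    pos = 0

    def take():
        nonlocal pos
        if pos >= len(rows):
            raise MeshFormatError(f"{path}: unexpected end of file")
        row = rows[pos]
        pos += 1
        return row

    lineno, tok = take()
    try:
        npoints = int(tok[0])
    except ValueError:
        raise MeshFormatError(f"{path}:{lineno}: expected point count, got {tok[0]!r}")
    verts = np.empty((npoints, 3))
    for i in range(npoints):
        lineno, tok = take()
        if len(tok) < 3:
            raise MeshFormatError(f"{path}:{lineno}: expected 3 coordinates")
        try:
            verts[i] = [float(t) for t in tok[:3]]
        except ValueError:
            raise MeshFormatError(f"{path}:{lineno}: bad coordinate in {tok}")
    lineno, tok = take()
    try:
        ntets = int(tok[0])
    except ValueError:
        raise MeshFormatError(f"{path}:{lineno}: expected element count, got {tok[0]!r}")
    tets = np.empty((ntets, 4), dtype=np.int64)
    for i in range(ntets):
        lineno, tok = take()
        if len(tok) == 5:
            tok = tok[1:]  # leading material/subdomain tag
        if len(tok) != 4:
            raise MeshFormatError(
                f"{path}:{lineno}: expected 4 vertex indices (plus optional tag)"
            )
        try:
            tets[i] = [int(t) - 1 for t in tok]
        except ValueError:
            raise MeshFormatError(f"{path}:{lineno}: bad vertex index in {tok}")
        if tets[i].min() < 0 or tets[i].max() >= npoints:
            raise MeshFormatError(
                f"{path}:{lineno}: vertex index out of range 1..{npoints}"
            )
    # Enforce positive orientation.
    v = verts[tets]
    vol = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    )
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return TetMesh(vertices=verts, tets=tets, units=units)


def write_netgen_neutral(mesh: TetMesh, path, sidecar: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_vertices}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"{mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"1 {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")
        fh.write(f"{len(mesh.boundary_faces)}\n")
        for f in mesh.boundary_faces:
            fh.write(f"1 {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    if sidecar:
        _write_sidecar(path, mesh.units)


def write_vtk(mesh: TetMesh, path, point_data: dict | None = None,
              sidecar: bool = True) -> None:
    """Legacy ASCII VTK unstructured grid with optional scalar point data."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncorticofold tet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        n = mesh.n_tets
        fh.write(f"CELLS {n} {5 * n}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {n}\n")
        fh.write("\n".join(["10"] * n) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values)
                if values.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{x:.17g}" for x in values) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in values:
                        fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
    if sidecar:
        _write_sidecar(path, mesh.units)


def write_stl(surface, path, units: str = "mm", sidecar: bool = True) -> None:
    """ASCII STL of a triangulated surface (trimesh.Trimesh or (V, F))."""
    path = Path(path)
    if hasattr(surface, "vertices"):
        verts = np.asarray(surface.vertices)
        faces = np.asarray(surface.faces)
    else:
        verts, faces = surface
        verts = np.asarray(verts)
        faces = np.asarray(faces)
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    normals = normals / lens[:, None]
    with open(path, "w") as fh:
        fh.write("solid corticofold\n")
        for nrm, t in zip(normals, tri):
            fh.write(f"facet normal {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}\n")
            fh.write(" outer loop\n")
            for p in t:
                fh.write(f"  vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid corticofold\n")
    if sidecar:
        _write_sidecar(path, units)


def _write_sidecar(path: Path, units: str) -> None:
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"units": units}, fh)
        fh.write("\n")
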