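"""Surface, centerline and report I/O.  All coordinates are millimetres.

Surfaces: ASCII/binary STL read, ASCII STL write, ASCII PLY and OBJ
read/write.  Simplex meshes are written as polygonal ASCII PLY plus a JSON
adjacency sidecar.  Centerlines are CSV with x,y,z columns.
"""

from __future__ import annotations

import csv
import json
import struct
from pathlib import Path

import numpy as np

from .centerline import Centerline
from .simplex import SimplexMesh, TriMesh

__all__ = [
    "read_surface",
    "write_surface",
    "read_centerline",
    "write_centerline",
    "write_simplex",
    "write_history_csv",
    "write_profile_csv",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- surfaces


def read_surface(path) -> TriMesh:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        return _read_stl(path)
    if suffix == ".obj":
        return _read_obj(path)
    if suffix == ".ply":
        return _read_ply(path)
    raise FormatError(f"unsupported surface format: {path.suffix}")


def write_surface(mesh: TriMesh, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _write_stl(mesh, path)
    elif suffix == ".obj":
        _write_obj(mesh, path)
    elif suffix == ".ply":
        _write_ply(mesh.vertices, [list(f) for f in mesh.faces], path)
    else:
        raise FormatError(f"unsupported surface format: {path.suffix}")


def _dedupe(tri_points: np.ndarray) -> TriMesh:
    """Weld per-facet STL vertices into an indexed mesh."""
    verts, inv = np.unique(tri_points.round(decimals=8), axis=0, return_inverse=True)
    faces = inv.reshape(-1, 3)
    return TriMesh(verts, faces)


def _read_stl(path: Path) -> TriMesh:
    raw = path.read_bytes()
    if raw[:5] == b"solid" and b"facet" in raw[:500]:
        pts = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                pts.append([float(x) for x in line.split()[1:4]])
        if not pts or len(pts) % 3:
            raise FormatError(f"malformed ASCII STL: {path}")
        return _dedupe(np.asarray(pts))
    # binary STL
    if len(raw) < 84:
        raise FormatError(f"truncated STL: {path}")
    (n,) = struct.unpack_from("<I", raw, 80)
    rec = np.frombuffer(raw, dtype=np.uint8, count=n * 50, offset=84).reshape(n, 50)
    tris = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    return _dedupe(tris.reshape(-1, 3))


def _write_stl(mesh: TriMesh, path: Path) -> None:
    lines = ["solid stentsim  units=mm"]
    normals = mesh.face_normals()
    for f, n in zip(mesh.faces, normals):
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in mesh.vertices[f]:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid stentsim")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> TriMesh:
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise FormatError(f"non-triangular face in {path}")
            faces.append(idx)
    if not faces:
        raise FormatError(f"no faces in OBJ file {path}")
    return TriMesh(np.asarray(verts), np.asarray(faces))


def _write_obj(mesh: TriMesh, path: Path) -> None:
    lines = ["# stentsim surface, units mm"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> TriMesh:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"not a PLY file: {path}")
    nv = nf = None
    i = 1
    if "ascii" not in lines[1]:
        raise FormatError("only ASCII PLY supported")
    while i < len(lines):
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            i += 1
            break
        i += 1
    if nv is None or nf is None:
        raise FormatError(f"malformed PLY header: {path}")
    verts = np.asarray([[float(x) for x in lines[i + k].split()[:3]] for k in range(nv)])
    faces = []
    for k in range(nf):
        parts = [int(x) for x in lines[i + nv + k].split()]
        if parts[0] != 3:
            raise FormatError("non-triangular PLY face; use write_simplex for polygons")
        faces.append(parts[1:4])
    return TriMesh(verts, np.asarray(faces))


def _write_ply(verts: np.ndarray, faces: list[list[int]], path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        "comment stentsim, units mm",
        f"element vertex {len(verts)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in verts:
        lines.append(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
    for f in faces:
        lines.append(" ".join([str(len(f))] + [str(int(i)) for i in f]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_simplex(mesh: SimplexMesh, path) -> None:
    """Polygonal PLY plus ``<stem>.adjacency.json`` sidecar."""
    path = Path(path)
    _write_ply(mesh.vertices, mesh.faces, path)
    sidecar = path.with_suffix(".adjacency.json")
    sidecar.write_text(
        json.dumps(
            {
                "units": "mm",
                "neighbors": mesh.neighbors.tolist(),
                "constrained": mesh.constrained.astype(int).tolist(),
                "source_face": mesh.source_face.tolist(),
            }
        )
    )


# -------------------------------------------------------------- centerline


def read_centerline(path) -> Centerline:
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh):
            if len(rec) < 3:
                continue
            try:
                rows.append([float(x) for x in rec[:3]])
            except ValueError:
                continue  # header / comment line
    if len(rows) < 2:
        raise FormatError(f"centerline needs at least 2 points: {path}")
    return Centerline(np.asarray(rows))


def write_centerline(cl: Centerline, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm", "z_mm"])
        for p in cl.points:
            w.writerow([f"{c:.12e}" for c in p])


# ----------------------------------------------------------------- tables


def write_history_csv(history, path) -> None:
    cols = history.as_columns()
    keys = list(cols)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(keys)
        for row in zip(*(cols[k] for k in keys)):
            w.writerow(row)


def write_profile_csv(profile, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["s_mm", "mld_mm"])
        for s, d in zip(profile.stations, profile.mld):
            w.writerow([f"{s:.6f}", f"{d:.6f}"])
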