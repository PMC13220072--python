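"""Triangulated surfaces and their dual 2-simplex meshes.

A 2-simplex mesh is the polygonal dual of a triangulation: one simplex
vertex per triangle, two simplex vertices adjacent iff their source
triangles share an edge.  Every interior vertex therefore has exactly
three neighbours, which is what makes per-vertex normals, circumscribed
elements and the simplex angle well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriMesh",
    "SimplexMesh",
    "SimplexGeometry",
    "DegenerateGeometryError",
    "NonManifoldError",
    "triangulation_to_simplex",
    "vertex_normal",
    "circumscribed_elements",
    "simplex_angle",
]

# cross-product norm below this (mm^2) counts as degenerate
DEGENERACY_TOL = 1e-12


class NonManifoldError(ValueError):
    """An edge of the input triangulation is used by more than two faces."""

    def __init__(self, edges):
        self.edges = list(edges)
        super().__init__(f"non-manifold edges (used by >2 faces): {self.edges[:10]}")


class DegenerateGeometryError(ValueError):
    """Collinear neighbours or a degenerate circumscribed element."""


@dataclass
class TriMesh:
    """Triangulated surface, vertices in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    # -- derived connectivity -------------------------------------------------

    def edge_face_map(self) -> dict[tuple[int, int], list[int]]:
        """Map sorted edge -> list of incident face indices."""
        emap: dict[tuple[int, int], list[int]] = {}
        for f, (a, b, c) in enumerate(self.faces):
            for i, j in ((a, b), (b, c), (c, a)):
                key = (i, j) if i < j else (j, i)
                emap.setdefault(key, []).append(f)
        return emap

    @property
    def boundary_edges(self) -> list[tuple[int, int]]:
        """Edges used by exactly one face."""
        return [e for e, fs in self.edge_face_map().items() if len(fs) == 1]

    def validate(self, area_tol: float = DEGENERACY_TOL) -> None:
        """Reject non-manifold, degenerate or inconsistently wound surfaces."""
        emap = self.edge_face_map()
        bad = [e for e, fs in emap.items() if len(fs) > 2]
        if bad:
            raise NonManifoldError(bad)
        areas = self.face_areas()
        if np.any(areas * 2.0 < area_tol):
            raise DegenerateGeometryError(
                f"zero-area faces: {np.nonzero(areas * 2.0 < area_tol)[0].tolist()[:10]}"
            )
        # orientation: each interior edge must be traversed once per direction
        directed: dict[tuple[int, int], int] = {}
        for a, b, c in self.faces:
            for i, j in ((a, b), (b, c), (c, a)):
                directed[(i, j)] = directed.get((i, j), 0) + 1
        for (i, j), n in directed.items():
            if n > 1:
                raise ValueError(f"inconsistent orientation: directed edge {(i, j)} used {n} times")
            key = (i, j) if i < j else (j, i)
            if len(emap[key]) == 2 and (j, i) not in directed:
                raise ValueError(f"inconsistent orientation at edge {key}")

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def euler_counts(self) -> tuple[int, int, int]:
        """(V, E, F) of the triangulation."""
        return len(self.vertices), len(self.edge_face_map()), len(self.faces)


@dataclass
class SimplexMesh:
    """Dual polygonal mesh: one vertex per source triangle.

    ``neighbors[i]`` holds up to three dual-adjacent vertex indices (−1 where
    the source triangle borders the surface boundary).  ``constrained``
    flags vertices whose source triangle touches a boundary edge; such
    vertices are never displaced by the dynamics.
    """

    vertices: np.ndarray
    neighbors: np.ndarray  # (n, 3) int, -1 = missing (boundary)
    constrained: np.ndarray  # (n,) bool
    source_face: np.ndarray  # (n,) int, dual round-trip
    faces: list[list[int]] = field(default_factory=list)  # dual polygons (closed only)
    normal_sign: np.ndarray | None = None  # +-1 per vertex so eq-normal is outward

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.neighbors = np.ascontiguousarray(self.neighbors, dtype=np.int64)
        self.constrained = np.ascontiguousarray(self.constrained, dtype=bool)
        self.source_face = np.ascontiguousarray(self.source_face, dtype=np.int64)
        if self.normal_sign is None:
            self.normal_sign = np.ones(len(self.vertices))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def free(self) -> np.ndarray:
        return ~self.constrained

    def degree(self) -> np.ndarray:
        return (self.neighbors >= 0).sum(axis=1)

    def edges(self) -> set[tuple[int, int]]:
        out = set()
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if j >= 0:
                    out.add((i, j) if i < j else (int(j), i))
        return out

    def normals(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Per-vertex unit normals for all degree-3 vertices (vectorised).

        Constrained / degree<3 vertices get a zero vector.
        """
        P = self.vertices if positions is None else positions
        n = np.zeros_like(P)
        full = self.degree() == 3
        nb = self.neighbors[full]
        a, b, c = P[nb[:, 0]], P[nb[:, 1]], P[nb[:, 2]]
        cr = np.cross(b - a, c - a)
        nrm = np.linalg.norm(cr, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        n[full] = cr / nrm * self.normal_sign[full, None]
        return n

    def to_trimesh(self, positions: np.ndarray | None = None) -> TriMesh:
        """Fan-triangulate the dual polygons (closed ones only)."""
        P = self.vertices if positions is None else positions
        verts = [P]
        tris = []
        base = len(P)
        centroids = []
        for k, poly in enumerate(self.faces):
            centroids.append(P[poly].mean(axis=0))
            m = len(poly)
            for t in range(m):
                tris.append([poly[t], poly[(t + 1) % m], base + k])
        if not tris:
            raise ValueError("simplex mesh has no closed dual faces to triangulate")
        verts.append(np.asarray(centroids))
        return TriMesh(np.vstack(verts), np.asarray(tris))


@dataclass
class SimplexGeometry:
    """Circumscribed elements and simplex angle at one vertex."""

    normal: np.ndarray
    r: float
    C: np.ndarray
    R: float
    O: np.ndarray
    phi: float
    degenerate_sphere: bool = False


# -----------------------------------------------------------------------------


def _dual_faces(tri: TriMesh, emap) -> list[list[int]]:
    """Closed dual polygons: the ordered triangle fans around interior vertices.

    Walking rule: in face (v, a, b) the successor around v is the face across
    edge (v, b), which keeps the polygon winding consistent with the face
    orientation.
    """
    nv = len(tri.vertices)
    incident: list[list[int]] = [[] for _ in range(nv)]
    for f, face in enumerate(tri.faces):
        for v in face:
            incident[v].append(f)
    boundary_verts = set()
    for (i, j), fs in emap.items():
        if len(fs) == 1:
            boundary_verts.add(i)
            boundary_verts.add(j)

    def across(v, w, f):
        key = (v, w) if v < w else (w, v)
        fs = emap[key]
        if len(fs) != 2:
            return -1
        return fs[0] if fs[1] == f else fs[1]

    polys = []
    for v in range(nv):
        if v in boundary_verts or not incident[v]:
            continue
        f0 = incident[v][0]
        poly = [f0]
        face = tri.faces[f0]
        i = int(np.where(face == v)[0][0])
        nxt_vert = int(face[(i + 2) % 3])  # edge (v, b) with b two steps ahead
        f = across(v, nxt_vert, f0)
        while f != f0 and f != -1:
            poly.append(f)
            face = tri.faces[f]
            i = int(np.where(face == v)[0][0])
            nxt_vert = int(face[(i + 2) % 3])
            f = across(v, nxt_vert, f)
        if f == f0 and len(poly) >= 3:
            polys.append(poly)
    return polys


def triangulation_to_simplex(tri: TriMesh) -> SimplexMesh:
    """Build the dual 2-simplex mesh of a triangulation.

    Dual vertices sit at triangle centroids.  Vertices whose source triangle
    touches a boundary edge are flagged ``constrained`` and keep degree < 3.
    The per-vertex ``normal_sign`` is set so that the three-neighbour normal
    agrees with the source triangle's face normal.
    """
    emap = tri.edge_face_map()
    bad = [e for e, fs in emap.items() if len(fs) > 2]
    if bad:
        raise NonManifoldError(bad)

    nf = len(tri.faces)
    neighbors = -np.ones((nf, 3), dtype=np.int64)
    count = np.zeros(nf, dtype=int)
    touches_boundary = np.zeros(nf, dtype=bool)
    for e, fs in emap.items():
        if len(fs) == 2:
            a, b = fs
            neighbors[a, count[a]] = b
            count[a] += 1
            neighbors[b, count[b]] = a
            count[b] += 1
        else:
            touches_boundary[fs[0]] = True

    verts = tri.face_centroids()
    sm = SimplexMesh(
        vertices=verts,
        neighbors=neighbors,
        constrained=touches_boundary,
        source_face=np.arange(nf),
    )
    # orient: flip where the 3-neighbour normal disagrees with the face normal
    fn = tri.face_normals()
    full = sm.degree() == 3
    nb = neighbors[full]
    cr = np.cross(verts[nb[:, 1]] - verts[nb[:, 0]], verts[nb[:, 2]] - verts[nb[:, 0]])
    sign = np.ones(nf)
    dots = np.einsum("ij,ij->i", cr, fn[full])
    s = np.where(dots < 0, -1.0, 1.0)
    sign[full] = s
    sm.normal_sign = sign
    sm.faces = _dual_faces(tri, emap)
    return sm


def vertex_normal(P, N1, N2, N3) -> np.ndarray:
    """Unit normal of the neighbour plane: normalised N1^N2 + N2^N3 + N3^N1.

    Algebraically identical to the normalised (N2-N1)x(N3-N1); ``P`` does not
    enter the formula but is kept in the signature for error reporting.
    """
    N1, N2, N3 = (np.asarray(x, dtype=float) for x in (N1, N2, N3))
    s = np.cross(N1, N2) + np.cross(N2, N3) + np.cross(N3, N1)
    nrm = np.linalg.norm(s)
    if nrm < DEGENERACY_TOL:
        raise DegenerateGeometryError(f"collinear neighbours at vertex P={np.asarray(P)}")
    return s / nrm


def circumscribed_elements(P, N1, N2, N3):
    """Circumcircle of (N1,N2,N3) and circumsphere of all four points.

    Returns ``(r, C, R, O, degenerate)``.  When the four points are coplanar
    the sphere is undefined: ``degenerate`` is True and (R, O) fall back to
    (inf, nan).
    """
    P, N1, N2, N3 = (np.asarray(x, dtype=float) for x in (P, N1, N2, N3))
    u = N2 - N1
    v = N3 - N1
    w = np.cross(u, v)
    w2 = np.dot(w, w)
    if np.sqrt(w2) < DEGENERACY_TOL:
        raise DegenerateGeometryError("collinear neighbours: circumcircle undefined")
    # standard closed form for the 3-point circumcenter
    C = N1 + (np.dot(u, u) * np.cross(v, w) + np.dot(v, v) * np.cross(w, u)) / (2.0 * w2)
    r = float(np.linalg.norm(C - N1))

    # sphere through 4 points: solve the linearised |X - O|^2 = R^2 system
    A = 2.0 * np.array([N2 - N1, N3 - N1, P - N1])
    rhs = np.array(
        [
            np.dot(N2, N2) - np.dot(N1, N1),
            np.dot(N3, N3) - np.dot(N1, N1),
            np.dot(P, P) - np.dot(N1, N1),
        ]
    )
    det = np.linalg.det(A)
    scale = max(float(np.abs(A).max()), 1.0)
    if abs(det) < 1e-12 * scale**3:
        return r, C, float("inf"), np.full(3, np.nan), True
    O = np.linalg.solve(A, rhs)
    R = float(np.linalg.norm(O - N1))
    return r, C, R, O, False


def simplex_angle(P, N1, N2, N3, n=None) -> float:
    """Signed simplex angle phi in [-pi, pi].

    sin(phi) = (r/R) sign((N1-P).n),  cos(phi) = |C-O|/R sign((C-O).n);
    recovered via atan2.  Exactly coplanar-concyclic quadruples (infinite
    circumsphere) return phi = 0.
    """
    P, N1, N2, N3 = (np.asarray(x, dtype=float) for x in (P, N1, N2, N3))
    if n is None:
        n = vertex_normal(P, N1, N2, N3)
    r, C, R, O, degenerate = circumscribed_elements(P, N1, N2, N3)
    if degenerate:
        return 0.0
    if R < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate circumsphere (R ~ 0)")
    s = (r / R) * np.sign(np.dot(N1 - P, n))
    d = C - O
    c = (np.linalg.norm(d) / R) * np.sign(np.dot(d, n)) if np.linalg.norm(d) > 0 else 0.0
    return float(np.arctan2(s, c))
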