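import numpy as np
import pytest

from stentsim.simplex import TriMesh


def convex_hull_mesh(points: np.ndarray) -> TriMesh:
    """Closed, outward-oriented triangulation of the convex hull of points."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    verts = points[hull.vertices]
    remap = {v: i for i, v in enumerate(hull.vertices)}
    faces = np.array([[remap[v] for v in f] for f in hull.simplices])
    center = verts.mean(axis=0)
    mesh = TriMesh(verts, faces)
    n = mesh.face_normals()
    c = mesh.face_centroids()
    flip = np.einsum("ij,ij->i", n, c - center) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriMesh(verts, faces)


def icosahedron() -> TriMesh:
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    return convex_hull_mesh(verts)


@pytest.fixture
def ico():
    return icosahedron()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def straight_tube():
    from stentsim.fixtures import TubeSpec, make_tube

    return make_tube(TubeSpec(length=40.0, diameter=3.0, n_axial=50, n_circ=32))


@pytest.fixture
def stenotic_tube():
    from stentsim.fixtures import TubeSpec, make_stenotic_tube

    return make_stenotic_tube(
        TubeSpec(
            length=40.0,
            diameter=3.0,
            n_axial=60,
            n_circ=32,
            stenosis_severity=0.5,
            stenosis_center=20.0,
            stenosis_width=4.0,
        )
    )
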