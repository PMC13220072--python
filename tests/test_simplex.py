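import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentsim.fixtures import TubeSpec, make_tube
from stentsim.simplex import (
    DegenerateGeometryError,
    NonManifoldError,
    TriMesh,
    circumscribed_elements,
    simplex_angle,
    triangulation_to_simplex,
    vertex_normal,
)

from conftest import convex_hull_mesh


class TestDualConstruction:
    def test_icosahedron_counts(self, ico):
        sm = triangulation_to_simplex(ico)
        assert sm.n_vertices == 20
        assert np.all(sm.degree() == 3)
        assert len(sm.edges()) == 30
        assert len(sm.faces) == 12

    def test_closed_mesh_all_degree_three(self, rng):
        tri = convex_hull_mesh(rng.normal(size=(40, 3)))
        sm = triangulation_to_simplex(tri)
        assert np.all(sm.degree() == 3)
        assert not sm.constrained.any()

    def test_dual_counts_random_hulls(self, rng):
        for _ in range(10):
            tri = convex_hull_mesh(rng.normal(size=(rng.integers(8, 60), 3)))
            V, E, F = tri.euler_counts()
            sm = triangulation_to_simplex(tri)
            assert sm.n_vertices == F
            assert len(sm.edges()) == E
            assert len(sm.faces) == V

    def test_vertices_at_centroids(self, ico):
        sm = triangulation_to_simplex(ico)
        np.testing.assert_allclose(sm.vertices, ico.face_centroids())

    def test_source_face_round_trip(self, ico):
        sm = triangulation_to_simplex(ico)
        assert np.array_equal(sm.source_face, np.arange(len(ico.faces)))

    def test_open_tube_constrained_count_matches_enumeration(self):
        tri, _, _ = make_tube(TubeSpec(length=20.0, diameter=3.0, n_axial=10, n_circ=16))
        sm = triangulation_to_simplex(tri)
        # oracle: brute-force enumeration of triangles touching a boundary edge
        boundary = set(tri.boundary_edges)
        expected = set()
        for f, (a, b, c) in enumerate(tri.faces):
            for e in ((a, b), (b, c), (c, a)):
                if tuple(sorted(e)) in boundary:
                    expected.add(f)
        assert set(np.nonzero(sm.constrained)[0]) == expected
        assert np.all(sm.degree()[sm.constrained] < 3)
        assert np.all(sm.degree()[sm.free] == 3)

    def test_nonmanifold_rejected(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0], [0, 0, -1]],
            dtype=float,
        )
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
        with pytest.raises(NonManifoldError) as exc:
            triangulation_to_simplex(TriMesh(verts, faces))
        assert (0, 1) in exc.value.edges

    def test_normals_point_outward_on_hull(self, ico):
        sm = triangulation_to_simplex(ico)
        n = sm.normals()
        center = ico.vertices.mean(axis=0)
        assert np.all(np.einsum("ij,ij->i", n, sm.vertices - center) > 0)


class TestVertexNormal:
    def test_symmetric_plane(self):
        n = vertex_normal([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        np.testing.assert_allclose(n, np.ones(3) / np.sqrt(3), atol=1e-15)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            vertex_normal([0, 0, 1], [0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_matches_cross_product_identity(self, rng):
        for _ in range(1000):
            N1, N2, N3 = rng.normal(size=(3, 3))
            cr = np.cross(N2 - N1, N3 - N1)
            if np.linalg.norm(cr) < 1e-6:
                continue
            got = vertex_normal(rng.normal(size=3), N1, N2, N3)
            np.testing.assert_allclose(got, cr / np.linalg.norm(cr), atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_unit_norm_property(self, seed):
        r = np.random.default_rng(seed)
        N1, N2, N3 = r.normal(size=(3, 3))
        if np.linalg.norm(np.cross(N2 - N1, N3 - N1)) < 1e-6:
            return
        n = vertex_normal(r.normal(size=3), N1, N2, N3)
        assert abs(np.linalg.norm(n) - 1.0) < 1e-10


class TestCircumscribed:
    def test_unit_sphere_pole(self):
        th = 2 * np.pi * np.arange(3) / 3
        N = np.column_stack([np.cos(th), np.sin(th), np.zeros(3)])
        r, C, R, O, deg = circumscribed_elements([0, 0, 1], *N)
        assert not deg
        assert r == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(C, 0, atol=1e-12)
        assert R == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(O, 0, atol=1e-12)

    def test_equilateral_closed_form(self):
        s = 2.7
        h = s / np.sqrt(3)
        th = 2 * np.pi * np.arange(3) / 3
        N = np.column_stack([h * np.cos(th), h * np.sin(th), np.zeros(3)])
        assert np.linalg.norm(N[0] - N[1]) == pytest.approx(s, rel=1e-12)
        r, C, *_ = circumscribed_elements([0, 0, 1], *N)
        assert r == pytest.approx(s / np.sqrt(3), rel=1e-12)

    def test_equidistance_residual(self, rng):
        for _ in range(200):
            P, N1, N2, N3 = rng.normal(size=(4, 3)) * 5
            try:
                r, C, R, O, deg = circumscribed_elements(P, N1, N2, N3)
            except DegenerateGeometryError:
                continue
            if deg:
                continue
            for X in (P, N1, N2, N3):
                assert abs(np.linalg.norm(O - X) - R) < 1e-9
            for X in (N1, N2, N3):
                assert abs(np.linalg.norm(C - X) - r) < 1e-9

    def test_coplanar_flagged(self):
        r, C, R, O, deg = circumscribed_elements(
            [1, 1, 0], [0, 0, 0], [1, 0, 0], [0, 1, 0]
        )
        assert deg
        assert np.isinf(R)


class TestSimplexAngle:
    def test_pole_over_circle_is_half_pi(self):
        th = 2 * np.pi * np.arange(3) / 3
        N = np.column_stack([np.cos(th), np.sin(th), np.zeros(3)])
        phi = simplex_angle([0, 0, 1], *N)
        assert abs(phi) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_identity_random(self, rng):
        checked = 0
        while checked < 1000:
            P, N1, N2, N3 = rng.normal(size=(4, 3)) * 3
            try:
                r, C, R, O, deg = circumscribed_elements(P, N1, N2, N3)
            except DegenerateGeometryError:
                continue
            if deg:
                continue
            n = vertex_normal(P, N1, N2, N3)
            s = (r / R) * np.sign(np.dot(N1 - P, n))
            c = (np.linalg.norm(C - O) / R) * np.sign(np.dot(C - O, n))
            assert abs(s * s + c * c - 1.0) < 1e-10
            checked += 1

    def test_reflection_antisymmetry(self, rng):
        # under the printed sign conventions a mirror image negates both
        # sin(phi) and cos(phi): the angle moves to its antipode phi +- pi
        M = np.diag([1.0, 1.0, -1.0])
        for _ in range(50):
            P, N1, N2, N3 = rng.normal(size=(4, 3))
            try:
                phi = simplex_angle(P, N1, N2, N3)
            except DegenerateGeometryError:
                continue
            phi_m = simplex_angle(P @ M, N1 @ M, N2 @ M, N3 @ M)
            assert np.sin(phi_m) == pytest.approx(-np.sin(phi), abs=1e-9)
            assert np.cos(phi_m) == pytest.approx(-np.cos(phi), abs=1e-9)

    def test_rigid_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2
            try:
                phi = simplex_angle(*pts)
            except DegenerateGeometryError:
                continue
            Rm = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
            tr = rng.normal(size=3) * 10
            moved = [p @ Rm.T + tr for p in pts]
            assert simplex_angle(*moved) == pytest.approx(phi, abs=1e-9)


class TestTriMeshValidation:
    def test_zero_area_face_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2], [0, 1, 3]])
        with pytest.raises(DegenerateGeometryError):
            TriMesh(verts, faces).validate()

    def test_inconsistent_winding_rejected(self, ico):
        faces = ico.faces.copy()
        faces[0] = faces[0][[0, 2, 1]]
        with pytest.raises(ValueError):
            TriMesh(ico.vertices, faces).validate()

    def test_fixture_meshes_valid(self, straight_tube, stenotic_tube, ico):
        for tri in (straight_tube[0], stenotic_tube[0], ico):
            tri.validate()
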