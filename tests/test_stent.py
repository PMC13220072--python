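import numpy as np
import pytest

from stentsim.centerline import Centerline
from stentsim.fixtures import TubeSpec, make_stenotic_tube, make_tube
from stentsim.simplex import triangulation_to_simplex
from stentsim.stent import ATM_TO_MPA, StentSpec, build_stent_mesh, internal_force

# independent hand evaluations (frozen before the build):
#   I      = pi * 2.15^4 / 64                  = 1.0488750103208435 mm^4
#   k      = 3 * 233000 * I / 34^3             = 18.653664568854815 N/mm
#   F_unit = 9 * 0.101325 * 2.15               = 1.96063875 N/mm
#   F_RF   = F_unit * 34                       = 66.6617175 N
#   delta  = 34 / (2 pi * 0.08 * k * 0.5)      = 7.252285529674679
K_ORACLE = 18.653664568854815
F_UNIT_ORACLE = 1.96063875
F_RF_ORACLE = 66.6617175
DELTA_ORACLE = 7.252285529674679


@pytest.fixture
def spec():
    return StentSpec()  # paper device: 233 GPa, D 2.15, L 34, 9 atm


class TestDerivedQuantities:
    def test_radial_rigidity_oracle(self, spec):
        assert spec.k == pytest.approx(K_ORACLE, rel=1e-12)

    def test_rigidity_cubic_in_length(self, spec):
        doubled = StentSpec(L=2 * spec.L, T=0.0)
        assert doubled.k == pytest.approx(spec.k / 8.0, rel=1e-12)

    def test_rigidity_vanishes_with_diameter(self):
        assert StentSpec(D=1e-4, T=0.0).k < 1e-12

    def test_radial_force_oracle(self, spec):
        assert spec.F_unit == pytest.approx(F_UNIT_ORACLE, rel=1e-12)
        assert spec.F_RF == pytest.approx(F_RF_ORACLE, rel=1e-12)

    def test_radial_force_linear_in_length(self, spec):
        assert StentSpec(L=68.0, T=0.0).F_RF == pytest.approx(2.0 * spec.F_RF, rel=1e-12)

    def test_pressure_conversion(self):
        assert StentSpec.from_pressure_atm(9.0).P_nom == pytest.approx(0.911925)

    def test_delta_oracle(self, spec):
        assert spec.delta == pytest.approx(DELTA_ORACLE, rel=1e-12)

    def test_delta_inverse_in_strut(self, spec):
        assert StentSpec(t_strut=0.16).delta == pytest.approx(spec.delta / 2.0, rel=1e-12)

    def test_zero_threshold_gives_nominal_equilibrium(self):
        s = StentSpec(T=0.0)
        assert s.chi == 0.0
        assert s.equilibrium_diameter == s.D

    def test_chi_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            StentSpec(T=1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            StentSpec(L=0.0)
        with pytest.raises(ValueError):
            StentSpec(P_nom=-1.0)

    def test_device_substitution_through_derived_values(self, spec):
        # doubling E while scaling L by 2^(1/3) leaves k (hence the force
        # prefactor) unchanged: forces see the device only through k, F_RF, chi
        other = StentSpec(E=spec.E * 2, L=spec.L * 2 ** (1 / 3))
        assert other.k == pytest.approx(spec.k, rel=1e-9)
        n = np.array([[0.0, 0.0, 1.0]])
        d = np.array([1.7])
        f1 = internal_force(d, n, other)
        coeff = other.k / (other.F_RF * other.D)
        expected = coeff * ((1 - other.chi) * other.D - d[0])
        assert f1[0, 2] == pytest.approx(expected, rel=1e-12)


class TestInternalForce:
    def test_zero_at_equilibrium(self, spec):
        n = np.array([[1.0, 0.0, 0.0]])
        d = np.array([spec.equilibrium_diameter])
        np.testing.assert_allclose(internal_force(d, n, spec), 0.0, atol=1e-15)

    def test_crimped_magnitude(self):
        s = StentSpec(T=0.0)
        n = np.array([[0.0, 1.0, 0.0]])
        F = internal_force(np.array([0.0]), n, s)
        assert F[0, 1] == pytest.approx(s.k / s.F_RF, rel=1e-12)

    def test_linearity_in_deficit(self, spec):
        n = np.array([[0.0, 0.0, 1.0]])
        full = internal_force(np.array([spec.equilibrium_diameter - 0.8]), n, spec)
        half = internal_force(np.array([spec.equilibrium_diameter - 0.4]), n, spec)
        assert full[0, 2] == pytest.approx(2 * half[0, 2], rel=1e-12)

    def test_sign_flips_past_equilibrium(self, spec):
        n = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        d = np.array([spec.equilibrium_diameter - 0.1, spec.equilibrium_diameter + 0.1])
        F = internal_force(d, n, spec)
        assert F[0, 2] > 0 > F[1, 2]

    def test_constrained_receive_zero(self, spec):
        n = np.tile([0.0, 0.0, 1.0], (3, 1))
        d = np.zeros(3)
        free = np.array([True, False, True])
        F = internal_force(d, n, spec, free=free)
        assert np.all(F[1] == 0) and F[0, 2] != 0


class TestBuildStentMesh:
    def test_crimped_radius(self, spec):
        tri, cl, _ = make_tube(TubeSpec(length=40.0, diameter=4.0, n_axial=50, n_circ=24))
        artery = triangulation_to_simplex(tri)
        stent, pairing = build_stent_mesh(artery, cl, spec)
        _, _, dist = cl.project(stent.vertices)
        np.testing.assert_allclose(dist, spec.r_crimp, atol=1e-9)

    def test_axial_extent_within_segment(self, spec):
        tri, cl, _ = make_tube(TubeSpec(length=40.0, diameter=4.0, n_axial=50, n_circ=24))
        artery = triangulation_to_simplex(tri)
        stent, _ = build_stent_mesh(artery, cl, spec, s0=3.0)
        s, _, _ = cl.project(stent.vertices)
        assert s.min() >= 3.0 - 1e-6
        assert s.max() <= 3.0 + spec.L + 1e-6

    def test_pairing_injective_and_nearest(self, spec):
        tri, cl, _ = make_tube(TubeSpec(length=40.0, diameter=4.0, n_axial=40, n_circ=16))
        artery = triangulation_to_simplex(tri)
        stent, pairing = build_stent_mesh(artery, cl, spec)
        assert len(np.unique(pairing)) == len(pairing)
        # brute-force: each stent vertex's nearest artery vertex is its pair
        d2 = ((stent.vertices[:, None, :] - artery.vertices[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        assert np.mean(nearest == pairing) > 0.99  # ties at symmetric points only

    def test_connectivity_inherited(self, spec):
        tri, cl, _ = make_tube(TubeSpec(length=40.0, diameter=4.0, n_axial=40, n_circ=16))
        artery = triangulation_to_simplex(tri)
        stent, pairing = build_stent_mesh(artery, cl, spec)
        remap = -np.ones(artery.n_vertices, dtype=int)
        remap[pairing] = np.arange(len(pairing))
        for j in range(stent.n_vertices):
            expected = {remap[x] for x in artery.neighbors[pairing[j]] if x >= 0 and remap[x] >= 0}
            got = {int(x) for x in stent.neighbors[j] if x >= 0}
            assert got == expected

    def test_too_long_stent_rejected(self, spec):
        tri, cl, _ = make_tube(TubeSpec(length=20.0, diameter=4.0, n_axial=20, n_circ=16))
        artery = triangulation_to_simplex(tri)
        with pytest.raises(ValueError, match="length"):
            build_stent_mesh(artery, cl, spec)

    def test_preloaded_contact_warns(self):
        spec = StentSpec(D=2.15, r_crimp=0.5)
        tri, cl, _ = make_stenotic_tube(
            TubeSpec(
                length=40.0, diameter=3.0, n_axial=50, n_circ=24,
                stenosis_severity=0.7, stenosis_center=20.0, stenosis_width=3.0,
            )
        )
        artery = triangulation_to_simplex(tri)
        with pytest.warns(UserWarning, match="pre-loaded"):
            build_stent_mesh(artery, cl, spec)
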