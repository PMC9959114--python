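"""Unit and property tests for the pure electromechanical relations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bilayermech as bm
from bilayermech import model
from bilayermech.errors import DomainError

AREAS = st.floats(1e-9, 1e-4)
THICKNESSES = st.floats(1e-10, 1e-7)
EPS_R = st.floats(1.0, 10.0)


def geom(a, d, er=2.5):
    return bm.MembraneGeometry(area=a, thickness=d, dielectric_constant=er)


class TestCapacitancePlanar:
    def test_dopc_disc_value(self):
        # 0.9 mm-diameter disc of 2.69 nm DOPC core
        c = bm.capacitance_planar(geom(6.36e-7, 2.69e-9))
        assert c == pytest.approx(5.23e-9, rel=2e-3)

    def test_vanishing_area_limit(self):
        assert bm.capacitance_planar(geom(1e-20, 2.69e-9)) < 1e-21

    @given(a=AREAS, d=THICKNESSES, k=st.floats(0.5, 5.0))
    @settings(max_examples=50, derandomize=True)
    def test_aspect_ratio_invariance(self, a, d, k):
        assert bm.capacitance_planar(geom(k * a, k * d)) == pytest.approx(
            bm.capacitance_planar(geom(a, d)), rel=1e-12)

    @given(a=AREAS, d=THICKNESSES)
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_area_and_thickness(self, a, d):
        c = bm.capacitance_planar(geom(a, d))
        assert bm.capacitance_planar(geom(a * 1.1, d)) > c
        assert bm.capacitance_planar(geom(a, d * 1.1)) < c

    @pytest.mark.parametrize("field,kwargs", [
        ("area", dict(area=-1e-7, thickness=2.7e-9)),
        ("thickness", dict(area=1e-7, thickness=0.0)),
    ])
    def test_invalid_geometry_names_field(self, field, kwargs):
        with pytest.raises(DomainError, match=field):
            bm.MembraneGeometry(**kwargs)


class TestThicknessInversion:
    def test_dopc_thickness(self):
        d = bm.thickness_from_capacitance(5.23e-9, 6.36e-7, 2.5)
        assert d == pytest.approx(2.69e-9, rel=2e-3)

    @given(a=AREAS, d=THICKNESSES, er=EPS_R)
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_identity(self, a, d, er):
        g = geom(a, d, er)
        c = bm.capacitance_planar(g)
        assert bm.thickness_from_capacitance(c, a, er) == pytest.approx(
            d, rel=1e-12)

    def test_reciprocal_scaling(self):
        g = geom(6.36e-7, 2.69e-9)
        c = bm.capacitance_planar(g)
        assert bm.thickness_from_capacitance(2 * c, g.area, 2.5) == pytest.approx(
            g.thickness / 2, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            bm.thickness_from_capacitance(-1e-9, 1e-7)


class TestVolumeForm:
    @given(a=AREAS, d=THICKNESSES, er=EPS_R)
    @settings(max_examples=100, derandomize=True)
    def test_equivalent_to_planar_form(self, a, d, er):
        c_planar = bm.capacitance_planar(geom(a, d, er))
        c_volume = bm.capacitance_from_volume(a * d, d, er)
        assert c_volume == pytest.approx(c_planar, rel=1e-12)

    def test_inverse_square_thickness_law(self):
        v = 1.711e-15
        c1 = bm.capacitance_from_volume(v, 2.69e-9)
        c2 = bm.capacitance_from_volume(v, 2.69e-9 / 2)
        assert c2 == pytest.approx(4 * c1, rel=1e-12)
        assert c1 == pytest.approx(5.23e-9, rel=2e-3)


class TestConstantVolumeCapacitance:
    def test_zero_field_identity(self):
        d0, a0 = 2.69e-9, 6.36e-7
        c0 = bm.capacitance_planar(geom(a0, d0))
        assert bm.constant_volume_capacitance(a0 * d0, d0) == pytest.approx(
            c0, rel=1e-12)

    def test_thinning_scales_inverse_square(self):
        d0, a0 = 2.69e-9, 6.36e-7
        v0 = a0 * d0
        c0 = bm.constant_volume_capacitance(v0, d0)
        c = bm.constant_volume_capacitance(v0, d0 / np.sqrt(1.02))
        assert c == pytest.approx(1.02 * c0, rel=1e-12)

    def test_dopc_compressed_value(self):
        c = bm.constant_volume_capacitance(6.36e-7 * 2.69e-9, 2.60e-9)
        assert c == pytest.approx(5.60e-9, rel=2e-3)


class TestModulusEstimators:
    def test_legacy_single_step_value(self):
        e = bm.young_modulus_hianik(8.23e-3, 0.15, 1.0e-10)
        assert e == pytest.approx(9.26e5, rel=2e-3)

    def test_legacy_quadratic_voltage_scaling(self):
        e1 = bm.young_modulus_hianik(8.23e-3, 0.1, 1e-10)
        e2 = bm.young_modulus_hianik(8.23e-3, 0.2, 1e-10)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_legacy_rejects_no_compression(self):
        with pytest.raises(DomainError):
            bm.young_modulus_hianik(8.23e-3, 0.15, 0.0)
        with pytest.raises(DomainError):
            bm.young_modulus_hianik(8.23e-3, 0.0, 1e-10)

    def test_alpha_from_slope_value(self):
        a = bm.alpha_from_slope(2.733e-9, 5.233e-9)
        assert a == pytest.approx(0.1741, rel=1e-3)

    def test_alpha_zero_slope(self):
        assert bm.alpha_from_slope(0.0, 5.23e-9) == 0.0

    def test_alpha_unit_factor_recovers_literal_slope(self):
        # with factor 1 the fitted slope C0*alpha inverts to alpha exactly
        c0, alpha_true = 5.23e-9, 0.2
        assert bm.alpha_from_slope(c0 * alpha_true, c0, slope_factor=1.0) == \
            pytest.approx(alpha_true, rel=1e-12)

    def test_constant_volume_modulus_value(self):
        e = bm.young_modulus_alvarez(8.23e-3, 0.1741, 2.69e-9)
        assert e == pytest.approx(1.76e7, rel=2e-3)

    @given(alpha=st.floats(1e-3, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_constant_volume_modulus_reciprocal_in_alpha(self, alpha):
        e1 = bm.young_modulus_alvarez(8.23e-3, alpha, 2.69e-9)
        e2 = bm.young_modulus_alvarez(8.23e-3, 2 * alpha, 2.69e-9)
        assert e2 == pytest.approx(e1 / 2, rel=1e-12)

    def test_constant_volume_modulus_rejects_nonpositive_alpha(self):
        with pytest.raises(DomainError, match="alpha"):
            bm.young_modulus_alvarez(8.23e-3, -0.1, 2.69e-9)


class TestThinPlateConversion:
    @pytest.mark.parametrize("e,d,expected", [
        (1.757e7, 2.69e-9, 9.45e-2),
        (6.29e6, 2.84e-9, 3.57e-2),
    ])
    def test_area_expansion_modulus_values(self, e, d, expected):
        assert bm.area_expansion_modulus(e, d, 0.5) == pytest.approx(
            expected, rel=2e-3)

    def test_poisson_free_limit(self):
        assert bm.area_expansion_modulus(1e7, 3e-9, 0.0) == pytest.approx(
            1e7 * 3e-9, rel=1e-12)

    @pytest.mark.parametrize("ka,d,expected", [
        (9.45e-2, 2.69e-9, 1.9e-20),
        (3.57e-2, 2.84e-9, 0.80e-20),
    ])
    def test_bending_rigidity_published_values(self, ka, d, expected):
        assert bm.bending_rigidity(ka, d, 0.5) == pytest.approx(
            expected, rel=5e-3)

    @given(e=st.floats(1e5, 1e8), d=THICKNESSES)
    @settings(max_examples=100, derandomize=True)
    def test_composed_incompressible_identity(self, e, d):
        # k_c = E d^3 / 18 for v = 0.5
        ka = bm.area_expansion_modulus(e, d, 0.5)
        kc = bm.bending_rigidity(ka, d, 0.5)
        assert kc == pytest.approx(e * d**3 / 18.0, rel=1e-12)

    def test_cubic_thickness_scaling(self):
        def composed(d):
            return bm.bending_rigidity(
                bm.area_expansion_modulus(1e7, d, 0.5), d, 0.5)
        assert composed(6e-9) == pytest.approx(8 * composed(3e-9), rel=1e-12)

    def test_rejects_poisson_ratio_of_one(self):
        with pytest.raises(DomainError, match="poisson"):
            bm.area_expansion_modulus(1e7, 3e-9, 1.0)


@given(a=AREAS, d=THICKNESSES)
@settings(max_examples=25, derandomize=True)
def test_operations_are_pure(a, d):
    g = geom(a, d)
    assert bm.capacitance_planar(g) == bm.capacitance_planar(g)
    c = bm.capacitance_planar(g)
    assert bm.thickness_from_capacitance(c, a) == \
        bm.thickness_from_capacitance(c, a)


def test_constants():
    assert model.VACUUM_PERMITTIVITY == 8.8542e-12
    assert model.DEFAULT_DIELECTRIC_CONSTANT == 2.5
    assert model.DEFAULT_SLOPE_FACTOR == 3.0
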