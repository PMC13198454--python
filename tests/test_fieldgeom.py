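import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from magwalk import fieldgeom as fg


class TestConversions:
    @pytest.mark.parametrize(
        "xyz, dec, inc, inten",
        [
            ((26.824, -0.022, 39.922), 0.0, 56.0, 48.095),
            ((26.551, 0.015, 37.955), 0.0, 55.0, 46.323),
        ],
    )
    def test_measured_component_rows_match_displayed_dib(self, xyz, dec, inc, inten):
        d = fg.dib_from_xyz(fg.FieldXYZ(*xyz))
        assert d.intensity_ut == pytest.approx(inten, abs=0.01)
        assert d.declination_deg == pytest.approx(dec, abs=0.1)
        assert d.inclination_deg == pytest.approx(inc, abs=0.2)
        assert d.declination_defined

    def test_pure_vertical_field_flags_declination_undefined(self):
        d = fg.dib_from_xyz(fg.FieldXYZ(0.0, 0.0, 10.0))
        assert d.inclination_deg == pytest.approx(90.0)
        assert d.intensity_ut == pytest.approx(10.0)
        assert not d.declination_defined

    @pytest.mark.parametrize(
        "dib, xyz",
        [
            ((0.0, 0.0, 1.0), (1.0, 0.0, 0.0)),
            ((90.0, 0.0, 1.0), (0.0, 1.0, 0.0)),
        ],
    )
    def test_dib_to_components_cardinal_cases(self, dib, xyz):
        f = fg.xyz_from_dib(fg.FieldDIB(*dib))
        assert (f.x, f.y, f.z) == pytest.approx(xyz, abs=1e-12)

    def test_dib_to_components_forward_trigonometry(self):
        f = fg.xyz_from_dib(fg.FieldDIB(0.0, 56.11, 48.097))
        assert f.x == pytest.approx(26.824, abs=0.01)
        assert f.z == pytest.approx(39.922, abs=0.01)

    @given(
        dec=st.floats(-179.9, 180.0),
        inc=st.floats(-89.0, 89.0),
        inten=st.floats(1.0, 100.0),
    )
    def test_round_trip(self, dec, inc, inten):
        d0 = fg.FieldDIB(dec, inc, inten)
        d1 = fg.dib_from_xyz(fg.xyz_from_dib(d0))
        assert d1.intensity_ut == pytest.approx(inten, rel=1e-9)
        assert d1.inclination_deg == pytest.approx(inc, abs=1e-9)
        assert abs((d1.declination_deg - dec + 180.0) % 360.0 - 180.0) < 1e-9


class TestCoilDesign:
    def test_half_turn_needs_twice_the_horizontal_component(self):
        plan = fg.coil_field_for_alteration(180.0, 26.824)
        assert plan.b_coil == pytest.approx(2.0 * 26.824, rel=1e-9)

    def test_120_degrees_needs_twice_cos30(self):
        plan = fg.coil_field_for_alteration(120.0, 1.0)
        assert plan.b_coil == pytest.approx(2.0 * math.cos(math.radians(30.0)),
                                            rel=1e-9)

    def test_zero_alteration_needs_no_coil_field(self):
        assert fg.coil_field_for_alteration(0.0, 26.824).b_coil == 0.0

    def test_coil_frame_sits_60_degrees_from_north_south_for_120(self):
        plan = fg.coil_field_for_alteration(120.0, 1.0)
        assert plan.axis_azimuth_deg == pytest.approx(150.0)
        assert plan.axis_from_ns_deg == pytest.approx(30.0)
        assert plan.frame_from_ns_deg == pytest.approx(60.0)

    def test_coil_field_strictly_increases_with_alteration_angle(self):
        thetas = np.linspace(1.0, 180.0, 60)
        b = [fg.coil_field_for_alteration(t, 3.0).b_coil for t in thetas]
        assert np.all(np.diff(b) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fg.coil_field_for_alteration(120.0, 0.0)
        with pytest.raises(ValueError):
            fg.coil_field_for_alteration(400.0, 1.0)


class TestSuperposition:
    def test_componentwise_sum(self):
        s = fg.superpose(fg.FieldXYZ(1, 0, 0), fg.FieldXYZ(0, 1, 0))
        assert (s.x, s.y, s.z) == (1, 1, 0)
        z = fg.superpose(fg.FieldXYZ(1, 0, 0), fg.FieldXYZ(-1, 0, 0))
        assert (z.x, z.y, z.z) == (0, 0, 0)

    def test_gmf_plus_designed_coil_field_rotates_horizontal_component(self):
        # measured GMF with a slight eastward declination: adding the coil
        # vector oriented relative to that declination shifts it by exactly
        # the design angle
        gmf = fg.FieldXYZ(26.551, 0.015, 37.955)
        d0 = fg.dib_from_xyz(gmf).declination_deg
        plan = fg.coil_field_for_alteration(120.0, gmf.horizontal)
        total = fg.superpose(gmf, fg.coil_vector(plan, gmf_declination_deg=d0))
        dib = fg.dib_from_xyz(total)
        assert dib.declination_deg == pytest.approx(120.03, abs=0.1)
        assert total.horizontal == pytest.approx(26.551, abs=0.01)


class TestPredictAlteredField:
    def test_zero_alteration_is_identity(self):
        gmf = fg.FieldXYZ(23.0, 4.0, 31.0)
        assert fg.predict_altered_field(gmf, 0.0) is gmf

    def test_half_turn_reflects_horizontal_component(self):
        out = fg.predict_altered_field(fg.FieldXYZ(26.824, 0.0, 39.922), 180.0)
        assert out.x == pytest.approx(-26.824, abs=1e-9)
        assert out.y == pytest.approx(0.0, abs=1e-9)
        assert out.z == pytest.approx(39.922)

    def test_120_matches_rotation_matrix(self):
        out = fg.predict_altered_field(fg.FieldXYZ(1.0, 0.0, 0.0), 120.0)
        assert out.x == pytest.approx(math.cos(math.radians(120.0)), abs=1e-12)
        assert out.y == pytest.approx(math.sin(math.radians(120.0)), abs=1e-12)

    @given(
        dec=st.floats(-179.0, 179.0),
        bh=st.floats(1.0, 60.0),
        z=st.floats(-60.0, 60.0),
        theta=st.floats(-359.0, 359.0).filter(lambda t: abs(t) > 1e-6),
    )
    def test_rotation_preserves_magnitudes_and_shifts_declination(
            self, dec, bh, z, theta):
        gmf = fg.FieldXYZ(bh * math.cos(math.radians(dec)),
                          bh * math.sin(math.radians(dec)), z)
        out = fg.predict_altered_field(gmf, theta)
        assert out.horizontal == pytest.approx(bh, rel=1e-9)
        assert out.z == gmf.z
        shift = (fg.dib_from_xyz(out).declination_deg
                 - fg.dib_from_xyz(gmf).declination_deg) % 360.0
        diff = (shift - theta) % 360.0
        assert min(diff, 360.0 - diff) == pytest.approx(0.0, abs=1e-7)

    def test_vertical_field_rejected(self):
        with pytest.raises(ValueError):
            fg.predict_altered_field(fg.FieldXYZ(0.0, 0.0, 40.0), 120.0)


class TestVerification:
    BEFORE = fg.FieldXYZ(26.551, 0.015, 37.955)
    AFTER = fg.FieldXYZ(-13.130, 25.035, 37.505)

    def test_identity_pair_passes(self):
        f = fg.FieldXYZ(20.0, 1.0, 30.0)
        assert fg.verify_alteration(f, f, 0.0, 1.0, 1.0).passed

    def test_measured_120_pair_passes_at_field_tolerances(self):
        rep = fg.verify_alteration(self.BEFORE, self.AFTER, 120.0,
                                   tol_deg=3.0, tol_ut=2.0)
        assert rep.passed
        assert rep.check("declination_shift").deviation == pytest.approx(
            120.0 - 117.64, abs=0.05)

    def test_measured_120_pair_horizontal_magnitude_grew(self):
        # the measured after-field's horizontal component is ~1.7 µT larger
        # than before; a 1 µT tolerance catches it
        rep = fg.verify_alteration(self.BEFORE, self.AFTER, 120.0,
                                   tol_deg=3.0, tol_ut=1.0)
        assert not rep.passed
        assert not rep.check("horizontal_magnitude").passed
        assert rep.check("horizontal_magnitude").deviation == pytest.approx(
            1.718, abs=0.01)

    def test_tight_angle_tolerance_fails_on_declination(self):
        rep = fg.verify_alteration(self.BEFORE, self.AFTER, 120.0,
                                   tol_deg=0.5, tol_ut=5.0)
        assert not rep.passed
        assert not rep.check("declination_shift").passed


class TestIO:
    def test_json_records_in_both_forms(self, tmp_path):
        p = tmp_path / "f.json"
        p.write_text(
            '{"a": {"x": 1.0, "y": 0.0, "z": 2.0},'
            ' "b": {"declination": 90.0, "inclination": 0.0, "intensity": 2.0}}')
        rec = fg.read_field_records(p)
        assert rec["a"].z == 2.0
        assert rec["b"].y == pytest.approx(2.0)

    def test_csv_records(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text("label,x,y,z\ngmf,26.824,-0.022,39.922\n")
        rec = fg.read_field_records(p)
        assert rec["gmf"].x == pytest.approx(26.824)

    def test_bundled_reference_readings(self):
        rec = fg.reference_readings()
        assert len(rec) == 4
        before = rec["exp1_before_180"]
        assert before["xyz"].intensity == pytest.approx(
            before["displayed"].intensity_ut, abs=0.01)
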