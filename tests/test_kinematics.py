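import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_track
from magwalk import kinematics as km
from magwalk.trackmodel import CoilEvent, PirouetteAnnotation, TrackFrame


def frame(mand, thor):
    return TrackFrame(0, 0.0, mand, thor)


class TestHeadingsAndBearings:
    @pytest.mark.parametrize("mand, thor, expected", [
        ((0, 1), (0, 0), 0.0),     # facing north
        ((1, 0), (0, 0), 90.0),    # facing east
        ((0, 0), (1, 1), 225.0),
    ])
    def test_heading_azimuth(self, mand, thor, expected):
        assert km.heading_azimuth(frame(mand, thor)) == pytest.approx(expected)

    def test_degenerate_frame_raises(self):
        with pytest.raises(km.DegenerateFrameError):
            km.heading_azimuth(frame((1, 1), (1, 1)))

    @pytest.mark.parametrize("a, b, expected", [
        ((0, 0), (0, 5), 0.0),
        ((0, 0), (-1, 0), 270.0),
        ((2, 3), (5, 3), 90.0),
    ])
    def test_bearing(self, a, b, expected):
        assert km.bearing(a, b) == pytest.approx(expected)

    def test_bearing_coincident_raises(self):
        with pytest.raises(ValueError):
            km.bearing((1, 2), (1, 2))


class TestRelativeGaze:
    def test_fixating_the_goal_reads_180(self):
        f = frame((0, 1), (0, 0))     # facing north
        assert km.relative_gaze(f, (0, 10)) == pytest.approx(180.0)

    def test_goal_due_east_of_north_facing_ant_reads_90(self):
        f = frame((0, 1), (0, 0))
        assert km.relative_gaze(f, (10, 1)) == pytest.approx(90.0)

    def test_anti_goal_gaze_reads_0(self):
        f = frame((0, 1), (0, 0))     # facing north, goal due south
        assert km.relative_gaze(f, (0, -10)) == pytest.approx(0.0)

    @given(
        phi=st.floats(0.0, 360.0),
        hx=st.floats(-5.0, 5.0), hy=st.floats(-5.0, 5.0),
        gx=st.floats(-20.0, 20.0), gy=st.floats(-20.0, 20.0),
    )
    def test_invariant_under_global_rotation(self, phi, hx, hy, gx, gy):
        mand = (hx + 0.5, hy + 0.3)
        if math.dist(mand, (gx, gy)) < 1e-3:
            return
        base = km.relative_gaze(frame(mand, (hx, hy)), (gx, gy))

        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))

        def rot(p):
            return (p[0] * c + p[1] * s, -p[0] * s + p[1] * c)

        rotated = km.relative_gaze(frame(rot(mand), rot((hx, hy))),
                                   rot((gx, gy)))
        assert abs((rotated - base + 180.0) % 360.0 - 180.0) < 1e-7


class TestFictiveNest:
    def test_half_turn_reflects_nest_through_the_ant(self):
        assert km.fictive_nest((10, 0), (0, 0), 180.0) == pytest.approx((20, 0))

    def test_full_turn_is_identity(self):
        assert km.fictive_nest((3, 4), (1, -2), 360.0) == pytest.approx((1, -2))

    def test_plus_120_matches_rotation_matrix(self):
        out = km.fictive_nest((0, 0), (0, 10), 120.0)
        assert out == pytest.approx((10 * math.sin(math.radians(120)),
                                     10 * math.cos(math.radians(120))))

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError):
            km.fictive_nest((1, 1), (1, 1), 90.0)

    @given(
        mx=st.floats(-10, 10), my=st.floats(-10, 10),
        t1=st.floats(-360, 360), t2=st.floats(-360, 360),
    )
    def test_preserves_distance_and_composes(self, mx, my, t1, t2):
        m, nest = (mx, my), (0.0, 2.0)
        if math.dist(m, nest) < 1e-6:
            return
        f1 = km.fictive_nest(m, nest, t1)
        assert math.dist(m, f1) == pytest.approx(math.dist(m, nest), rel=1e-9)
        two_step = km.fictive_nest(m, f1, t2)
        one_step = km.fictive_nest(m, nest, t1 + t2)
        assert two_step == pytest.approx(one_step, abs=1e-7)

    def test_induced_gaze_shift_rarely_equals_the_field_alteration(self):
        # the angular offset between nest-relative and fictive-nest-relative
        # gaze depends on where the ant stands; it matches the 120° field
        # alteration only on a measure-zero locus
        rng = np.random.default_rng(7)
        theta, hits = 120.0, 0
        n = 1000
        for _ in range(n):
            switch = tuple(rng.uniform(-20, 20, 2))
            fict = km.fictive_nest(switch, (0.0, 0.0), theta)
            thor = tuple(rng.uniform(-20, 20, 2))
            h = rng.uniform(0, 360)
            mand = (thor[0] + 0.6 * math.sin(math.radians(h)),
                    thor[1] + 0.6 * math.cos(math.radians(h)))
            f = frame(mand, thor)
            diff = km.relative_gaze(f, (0.0, 0.0)) - km.relative_gaze(f, fict)
            d = abs((abs((diff + 180) % 360 - 180)) - theta)
            if d < 0.1:
                hits += 1
        assert hits / n < 0.01


class TestSpeeds:
    def test_stationary_thorax_has_zero_speed(self):
        track = make_track(np.zeros(10))
        assert np.allclose(km.forward_speeds(track), 0.0)

    def test_uniform_motion_speed(self):
        pos = np.column_stack([np.arange(10.0), np.zeros(10)])  # 1 cm/frame
        track = make_track(np.zeros(10), pos, fps=50.0)
        assert np.allclose(km.forward_speeds(track), 50.0)

    def test_constant_heading_zero_angular_speed(self):
        track = make_track(np.full(10, 33.0))
        assert np.allclose(km.angular_speeds(track), 0.0, atol=1e-9)

    def test_steady_rotation_rate(self):
        track = make_track(np.arange(0, 40, 2.0), fps=50.0)  # +2 deg/frame
        assert np.allclose(km.angular_speeds(track), 100.0)

    def test_wraparound_uses_circular_difference(self):
        track = make_track([357.0, 359.0, 1.0, 3.0], fps=50.0)
        assert np.allclose(km.angular_speeds(track), 100.0)

    def test_degenerate_frame_flagged_in_angular_speed(self):
        track = make_track(np.zeros(5))
        f = track.frames[2]
        track.frames[2] = TrackFrame(f.index, f.t, f.thorax, f.thorax)
        w = km.angular_speeds(track)
        assert np.isnan(w[1]) and np.isnan(w[2]) and np.isnan(w[3])


class TestPirouetteSelection:
    def _track(self):
        # 100 frames: thorax far from nest, nest at origin
        return make_track(np.zeros(100), np.tile([8.0, 0.0], (100, 1)))

    def test_straddling_pirouettes_selected(self):
        track = self._track()
        anns = [PirouetteAnnotation(0, 20), PirouetteAnnotation(60, 90)]
        sel = km.select_pirouettes(track, anns, CoilEvent(1.0, 180.0))
        assert sel.before == anns[0]
        assert sel.after == anns[1]

    def test_distance_rule_excludes_close_pirouettes(self):
        headings = np.zeros(100)
        thorax = np.tile([8.0, 0.0], (100, 1))
        thorax[:30] = [2.0, 0.0]   # first pirouette too close to the nest
        track = make_track(headings, thorax)
        anns = [PirouetteAnnotation(0, 25), PirouetteAnnotation(35, 45),
                PirouetteAnnotation(60, 90)]
        sel = km.select_pirouettes(track, anns, CoilEvent(1.0, 180.0),
                                   min_dist_cm=5.0)
        assert sel.before == anns[1]

    def test_missing_after_is_reported_not_raised(self):
        track = self._track()
        sel = km.select_pirouettes(track, [PirouetteAnnotation(0, 20)],
                                   CoilEvent(1.0, 180.0))
        assert sel.after is None
        assert "no candidate after switch-on" in sel.after_reason

    def test_before_is_last_qualifying_pre_switch_pirouette(self):
        track = self._track()
        anns = [PirouetteAnnotation(0, 10), PirouetteAnnotation(20, 40)]
        sel = km.select_pirouettes(track, anns, CoilEvent(1.5, 180.0))
        assert sel.before == anns[1]


def test_heuristic_pirouette_detector_finds_in_place_rotations():
    # walk - rotate in place 400 deg - walk
    headings = np.concatenate([np.zeros(30), np.arange(0, 400, 8.0),
                               np.full(30, 40.0)])
    n = headings.size
    thorax = np.zeros((n, 2))
    thorax[:30, 0] = np.linspace(0, 14.5, 30)
    thorax[30:80] = [14.5, 0.0]
    thorax[80:, 0] = np.linspace(14.5, 29.0, n - 80)
    track = make_track(headings, thorax)
    found = km.detect_pirouettes(track)
    assert any(a.start_index < 55 < a.end_index for a in found)
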