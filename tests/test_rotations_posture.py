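import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofpheno import kinematics as kin
from ofpheno import rotations_posture as rot

from .oracles import meander_oracle, rotation_oracle


class TestCountRotations:
    def test_monotone_two_turns_ccw(self):
        h = np.linspace(0.0, 720.0, 500)
        r = rot.count_rotations(h, threshold=30.0)
        assert (r.ccw, r.cw) == (2, 0)

    def test_subthreshold_wiggle_counts_nothing(self):
        t = np.linspace(0, 60, 1500)
        h = 20.0 * np.sin(2 * np.pi * t / 5.0)
        r = rot.count_rotations(h, threshold=30.0)
        assert (r.ccw, r.cw) == (0, 0)

    def test_tolerated_counter_excursion_does_not_reset(self):
        # 350 up, 20 back (under the 30 deg tolerance), 30 up again -> 1 CCW
        h = np.concatenate(
            (np.linspace(0, 350, 100), np.linspace(350, 330, 10),
             np.linspace(330, 365, 10))
        )
        r = rot.count_rotations(h, threshold=30.0)
        assert (r.ccw, r.cw) == (1, 0)

    def test_large_counter_excursion_resets(self):
        # 350 up, 40 back (over tolerance): the CCW progress is forfeited
        h = np.concatenate(
            (np.linspace(0, 350, 100), np.linspace(350, 310, 20),
             np.linspace(310, 365, 20))
        )
        r = rot.count_rotations(h, threshold=30.0)
        assert (r.ccw, r.cw) == (0, 0)

    @given(
        st.lists(st.floats(-60, 60, allow_nan=False), min_size=2, max_size=300),
        st.sampled_from([30.0, 50.0]),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_extremum_oracle(self, increments, threshold):
        h = np.cumsum([0.0] + increments)
        r = rot.count_rotations(h, threshold=threshold)
        assert (r.cw, r.ccw) == rotation_oracle(h, threshold)

    @given(st.lists(st.floats(-60, 60, allow_nan=False), min_size=2, max_size=200))
    @settings(max_examples=80, deadline=None)
    def test_reflection_swaps_cw_and_ccw(self, increments):
        h = np.cumsum([0.0] + increments)
        r1 = rot.count_rotations(h, threshold=30.0)
        r2 = rot.count_rotations(-h, threshold=30.0)
        assert (r1.cw, r1.ccw) == (r2.ccw, r2.cw)

    @given(
        st.lists(st.floats(-60, 60, allow_nan=False), min_size=2, max_size=200),
        st.floats(-1000, 1000, allow_nan=False),
    )
    @settings(max_examples=80, deadline=None)
    def test_invariant_to_constant_offset(self, increments, offset):
        h = np.cumsum([0.0] + increments)
        r1 = rot.count_rotations(h, threshold=50.0)
        r2 = rot.count_rotations(h + offset, threshold=50.0)
        assert (r1.cw, r1.ccw) == (r2.cw, r2.ccw)


class TestMapDirection:
    def test_left_lesion_ccw_is_ipsilesional(self):
        r = rot.RotationCount("arena", cw=2, ccw=5)
        m = rot.map_direction(r, "left")
        assert (m.ipsilesional, m.contralesional) == (5, 2)

    def test_right_lesion_mirrors(self):
        r = rot.RotationCount("arena", cw=2, ccw=5)
        m = rot.map_direction(r, "right")
        assert (m.ipsilesional, m.contralesional) == (2, 5)

    def test_equal_counts_side_independent(self):
        r = rot.RotationCount("body_axis", cw=3, ccw=3)
        for side in ("left", "right"):
            m = rot.map_direction(r, side)
            assert m.ipsilesional == m.contralesional == 3


class TestMeander:
    def _filtered(self, xy):
        t = np.arange(len(xy)) / 25.0
        return kin.mdm_filter(np.asarray(xy, float), t, 0.0)

    def test_straight_line_is_zero(self):
        xy = np.column_stack((np.arange(20.0), np.zeros(20)))
        per_step, agg = rot.absolute_meander(self._filtered(xy))
        assert per_step == pytest.approx(0.0)
        assert agg == pytest.approx(0.0)

    def test_circle_closed_form(self):
        # 180 / (pi * r) deg/cm for r = 10
        th = np.linspace(0, 4 * np.pi, 400)
        xy = np.column_stack((10 * np.cos(th), 10 * np.sin(th)))
        per_step, agg = rot.absolute_meander(self._filtered(xy))
        assert per_step == pytest.approx(180 / (np.pi * 10), rel=1e-3)
        assert agg == pytest.approx(per_step, rel=1e-6)

    def test_reversals_every_5cm(self):
        # back-and-forth 180 deg turns every 5 cm -> 36 deg/cm
        xy = np.array([[0.0, 0], [5, 0], [0, 0], [5, 0], [0, 0]])
        per_step, agg = rot.absolute_meander(self._filtered(xy))
        assert per_step == pytest.approx(36.0)
        assert agg == pytest.approx(36.0)

    def test_too_few_samples_undefined(self):
        xy = np.array([[0.0, 0], [5, 0]])
        per_step, agg = rot.absolute_meander(self._filtered(xy))
        assert np.isnan(per_step) and np.isnan(agg)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_rigid_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.uniform(-1.5, 1.5, size=(30, 2)), axis=0)
        theta = rng.uniform(0, 2 * np.pi)
        rotm = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        m1 = rot.absolute_meander(self._filtered(xy))
        m2 = rot.absolute_meander(self._filtered(xy @ rotm.T))
        assert m1[0] == pytest.approx(m2[0], rel=1e-9, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.uniform(-2, 2, size=(25, 2)), axis=0)
        ft = self._filtered(xy)
        per_step, agg = rot.absolute_meander(ft)
        o_step, o_agg = meander_oracle(ft.xy)
        assert per_step == pytest.approx(o_step, rel=1e-9)
        assert agg == pytest.approx(o_agg, rel=1e-9)


class TestBodyTorsion:
    def _mk(self, nose, center, tail, n=5):
        rep = lambda p: np.tile(np.asarray(p, float), (n, 1))
        return rep(nose), rep(center), rep(tail)

    def test_collinear_is_zero(self):
        nose, center, tail = self._mk([2, 0], [1, 0], [0, 0])
        assert rot.body_torsion(nose, center, tail, "left") == pytest.approx(0.0)

    def test_nose_right_of_axis_left_lesion_positive(self):
        # body axis points east; nose 90 deg to the animal's right (south).
        # With a left lesion the right side is contralesional -> +90.
        nose, center, tail = self._mk([1, -1], [1, 0], [0, 0])
        assert rot.body_torsion(nose, center, tail, "left") == pytest.approx(90.0)
        assert rot.body_torsion(nose, center, tail, "right") == pytest.approx(-90.0)

    def test_mirroring_negates_torsion(self):
        rng = np.random.default_rng(3)
        tail = rng.uniform(0, 10, (20, 2))
        center = tail + rng.uniform(-1, 1, (20, 2)) + [2, 0]
        nose = center + rng.uniform(-1, 1, (20, 2)) + [2, 0]
        flip = np.array([1.0, -1.0])
        t1 = rot.body_torsion(nose, center, tail, "left")
        t2 = rot.body_torsion(nose * flip, center * flip, tail * flip, "left")
        assert t1 == pytest.approx(-t2, rel=1e-9, abs=1e-9)

    def test_degenerate_body_vector_skipped(self):
        nose = np.array([[1.0, 0], [1, 1]])
        center = np.array([[1.0, 0], [0.5, 0]])
        tail = np.array([[0.0, 0], [0, 0]])
        # first sample: zero-length center->nose vector -> skipped
        val = rot.body_torsion(nose, center, tail, "right")
        expected = np.degrees(np.arctan2(1.0, 0.5))  # second sample only
        assert val == pytest.approx(expected)
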