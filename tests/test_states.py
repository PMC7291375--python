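import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofpheno import AnalysisProfile
from ofpheno import states as stt
from ofpheno.kinematics import ScalarSeries

from .oracles import events_oracle, hysteresis_oracle

FS = 25.0


def series(vals, units="cm/s", fs=FS):
    vals = np.asarray(vals, dtype=float)
    return ScalarSeries(np.arange(len(vals)) / fs, vals, units)


class TestMovementHysteresis:
    def test_hand_traced_sequence(self, profile):
        v = [0, 1, 3, 3, 1.8, 1.8, 1.5, 3]
        labels = stt.movement_labels(np.array(v, float), 2.00, 1.75)
        expected = [
            stt.NOT_MOVING, stt.NOT_MOVING, stt.MOVING, stt.MOVING,
            stt.MOVING, stt.MOVING, stt.NOT_MOVING, stt.MOVING,
        ]
        assert labels.tolist() == expected

    def test_constant_speed_one_interval_full_session(self, profile):
        moving, not_moving = stt.movement_states(
            series(np.full(100, 10.0)), profile
        )
        assert moving.count == 1
        assert moving.percent_of_session == pytest.approx(100.0)
        assert not_moving.count == 0

    def test_in_band_oscillation_never_resolves(self, profile):
        v = np.tile([1.8, 1.95], 50).astype(float)
        labels = stt.movement_labels(v, 2.00, 1.75)
        assert (labels == stt.UNDEFINED).all()

    def test_in_band_oscillation_after_resolution_has_no_chatter(self, profile):
        v = np.concatenate(([0.0], np.tile([1.8, 1.95], 50)))
        moving, not_moving = stt.movement_states(series(v), profile)
        assert moving.count == 0
        assert not_moving.count == 1
        assert not_moving.percent_of_session == pytest.approx(100.0)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            stt.movement_labels(np.zeros(3), 1.0, 2.0)

    @given(
        st.lists(
            st.one_of(st.floats(0, 5, allow_nan=False), st.just(float("nan"))),
            min_size=1,
            max_size=100,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scan_oracle(self, vals):
        labels = stt.movement_labels(np.asarray(vals, float), 2.00, 1.75)
        codes = {"U": stt.UNDEFINED, "N": stt.NOT_MOVING, "M": stt.MOVING}
        expected = [codes[c] for c in hysteresis_oracle(vals, 2.00, 1.75)]
        assert labels.tolist() == expected


class TestMobility:
    def test_threshold_bands(self, profile):
        imm, mob, high, glob = stt.mobility_states(
            series([0.5, 3.0, 7.0], units="%"), profile
        )
        assert imm.total_duration_s == pytest.approx(1 / FS)
        assert mob.total_duration_s == pytest.approx(1 / FS)
        assert high.total_duration_s == pytest.approx(1 / FS)
        assert glob == pytest.approx(200.0 / 3.0)

    def test_boundaries_belong_to_mobile(self, profile):
        labels = stt.mobility_labels(np.array([1.0, 5.0]), 1.0, 5.0)
        assert (labels == stt.MOBILE).all()

    def test_all_zeros_fully_immobile(self, profile):
        imm, mob, high, glob = stt.mobility_states(
            series(np.zeros(50), units="%"), profile
        )
        assert imm.percent_of_session == pytest.approx(100.0)
        assert glob == pytest.approx(0.0)

    @given(
        vals=st.lists(
            st.one_of(
                st.floats(0, 12, allow_nan=False), st.just(float("nan"))
            ),
            min_size=1,
            max_size=120,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_defined_samples(self, vals):
        s = series(vals, units="%")
        if not np.isfinite(s.v).any():
            return
        imm, mob, high, glob = stt.mobility_states(s, AnalysisProfile())
        total = (
            imm.percent_of_session
            + mob.percent_of_session
            + high.percent_of_session
        )
        assert total == pytest.approx(100.0)
        assert glob == pytest.approx(100.0 - imm.percent_of_session)


class TestAccelerationEvents:
    def test_ramp_gives_one_high_event(self, profile):
        # 0 -> 60 cm/s over 1 s: interior acceleration ~60, long enough
        from ofpheno import kinematics as kin

        t = np.arange(int(3 * FS)) / FS
        speed = np.clip(60.0 * (t - 1.0), 0, 60.0)
        x = np.concatenate(([0.0], np.cumsum(speed[1:] / FS)))
        a = kin.acceleration(kin.velocity(np.column_stack((x, 0 * x)), t))
        high, low = stt.acceleration_events(a, profile)
        assert high.count == 1
        assert low.count == 0

    def test_constant_speed_no_events(self, profile):
        a = series(np.zeros(100), units="cm/s2")
        high, low = stt.acceleration_events(a, profile)
        assert high.count == 0 and low.count == 0

    def test_short_burst_excluded_by_min_duration(self, profile):
        a = np.zeros(100)
        a[50:53] = 80.0  # 0.12 s at 25 Hz, below the 0.20 s floor
        high, _ = stt.acceleration_events(series(a, "cm/s2"), profile)
        assert high.count == 0
        # the same burst counts once the exclusion is relaxed
        relaxed = profile.replace(accel_min_duration=0.04)
        high2, _ = stt.acceleration_events(series(a, "cm/s2"), relaxed)
        assert high2.count == 1

    @given(
        st.lists(st.floats(-80, 120, allow_nan=False), min_size=5, max_size=150),
        st.sampled_from([0.04, 0.12, 0.20, 0.40]),
    )
    @settings(max_examples=80, deadline=None)
    def test_counts_match_scan_oracle(self, vals, min_dur):
        prof = AnalysisProfile(accel_min_duration=min_dur)
        a = series(vals, "cm/s2")
        high, low = stt.acceleration_events(a, prof)
        min_samples = int(np.ceil(min_dur * FS - 1e-9))
        assert high.count == events_oracle(vals, 50.0, min_samples, above=True)
        assert low.count == events_oracle(vals, 50.0, min_samples, above=False)

    @given(st.lists(st.floats(-80, 120, allow_nan=False), min_size=5, max_size=150))
    @settings(max_examples=60, deadline=None)
    def test_raising_min_duration_never_increases_counts(self, vals):
        a = series(vals, "cm/s2")
        counts = []
        for dur in (0.04, 0.12, 0.20, 0.40):
            high, low = stt.acceleration_events(
                a, AnalysisProfile(accel_min_duration=dur)
            )
            counts.append((high.count, low.count))
        for (h1, l1), (h2, l2) in zip(counts, counts[1:]):
            assert h2 <= h1 and l2 <= l1


class TestSignedAccelerationMean:
    def test_sign_split(self):
        a = series([-10.0, 10.0, 30.0], "cm/s2")
        assert stt.mean_signed_accel(a, "positive") == pytest.approx(20.0)
        assert stt.mean_signed_accel(a, "negative") == pytest.approx(-10.0)

    def test_all_zero_undefined(self):
        a = series(np.zeros(5), "cm/s2")
        assert np.isnan(stt.mean_signed_accel(a, "positive"))
        assert np.isnan(stt.mean_signed_accel(a, "negative"))

    def test_triangular_profile_symmetry(self):
        from ofpheno import kinematics as kin

        t = np.arange(int(2 * FS) + 1) / FS
        speed = np.where(t <= 1.0, 40 * t, 40 * (2 - t))
        x = np.concatenate(([0.0], np.cumsum(speed[1:] / FS)))
        a = kin.acceleration(kin.velocity(np.column_stack((x, 0 * x)), t))
        pos = stt.mean_signed_accel(a, "positive")
        neg = stt.mean_signed_accel(a, "negative")
        assert pos == pytest.approx(-neg, rel=0.15)


class TestBobbing:
    def test_two_separated_runs_count_two(self, profile):
        v = np.full(100, 20.0)
        v[10:15] = 130.0
        v[60:62] = 150.0
        ev = stt.bobbing_events(series(v), profile)
        assert ev.count == 2

    def test_subthreshold_counts_zero(self, profile):
        ev = stt.bobbing_events(series(np.full(100, 99.9)), profile)
        assert ev.count == 0

    def test_threshold_is_inclusive(self, profile):
        v = np.zeros(20)
        v[5:8] = 100.0
        assert stt.bobbing_events(series(v), profile).count == 1
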