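"""I-VT classification, saccadic-intrusion detection and event rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_recording
from ocuload.events import (
    IVTParams,
    OcularEvent,
    SIParams,
    detect_intrusions,
    event_rate,
    gaze_velocity,
    ivt_classify,
    windowed_counts,
)
from ocuload.exceptions import InsufficientDataError, ValidationError
from ocuload.synth import WorkloadProfile, simulate_gaze

RATE = 100.0


def two_epoch_recording(jump_deg=5.0, epoch_s=1.0, jump_s=0.04):
    """Two stationary epochs joined by a fast linear jump in x."""
    n_epoch = int(epoch_s * RATE)
    n_jump = int(jump_s * RATE)
    x = np.concatenate(
        [np.zeros(n_epoch), np.linspace(0, jump_deg, n_jump + 2)[1:-1], np.full(n_epoch, jump_deg)]
    )
    t = np.arange(len(x)) / RATE
    return make_recording(t, x)


# ---------------------------------------------------------------------------
# velocity estimation
# ---------------------------------------------------------------------------


class TestGazeVelocity:
    def test_stationary_gaze_has_zero_speed(self, stationary_recording):
        speed = gaze_velocity(stationary_recording)
        np.testing.assert_allclose(speed, 0.0)

    def test_linear_ramp_speed(self):
        t = np.arange(200) / RATE
        rec = make_recording(t, 10.0 * t)  # 10 deg/s in x, constant y
        speed = gaze_velocity(rec)
        np.testing.assert_allclose(speed[2:-2], 10.0, rtol=1e-9)

    def test_invalid_sample_masks_window_neighbours(self):
        t = np.arange(100) / RATE
        x = 10.0 * t
        valid = np.ones(100, bool)
        valid[50] = False
        x_in = x.copy()
        x_in[50] = np.nan
        rec = make_recording(t, x_in, valid=valid)
        speed = gaze_velocity(rec, window=3)
        assert np.isnan(speed[49:52]).all()
        assert np.isfinite(speed[48]) and np.isfinite(speed[52])

    def test_too_few_valid_samples(self):
        t = np.arange(5) / RATE
        rec = make_recording(t, np.zeros(5), valid=[True, False, False, False, False])
        with pytest.raises(InsufficientDataError):
            gaze_velocity(rec)


# ---------------------------------------------------------------------------
# I-VT classification
# ---------------------------------------------------------------------------


def brute_force_ivt(rec, params):
    """Independent oracle: per-sample thresholding then run merging.

    Implemented with explicit loops, no shared code with the classifier
    beyond the velocity primitive it checks against.
    """
    speed = gaze_velocity(rec, params.velocity_window)
    t = rec.t
    n = len(t)
    labels = ["F" if s < params.velocity_threshold else "S" for s in speed]
    out = []
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        t0 = t[i]
        t1 = t[j] if j < n else t[-1] + 1.0 / rec.nominal_rate
        if labels[i] == "F":
            if t1 - t0 >= params.min_fixation_duration:
                out.append(("fixation", t0, t1))
        else:
            out.append(("saccade", t0, t1))
        i = j
    return out


class TestIVT:
    def test_stationary_gaze_is_one_fixation(self, stationary_recording):
        events = ivt_classify(stationary_recording)
        assert [e.kind for e in events] == ["fixation"]
        assert events[0].duration == pytest.approx(2.0, abs=0.02)
        assert events[0].centroid_x == pytest.approx(3.0)
        assert events[0].centroid_y == pytest.approx(-1.0)

    def test_two_epochs_with_jump(self):
        events = ivt_classify(two_epoch_recording(jump_deg=5.0))
        kinds = [e.kind for e in events]
        assert kinds.count("fixation") == 2
        assert kinds.count("saccade") == 1
        sac = next(e for e in events if e.kind == "saccade")
        assert sac.amplitude == pytest.approx(5.0, abs=0.05)
        assert sac.peak_velocity > 30.0

    def test_generator_ground_truth_count(self):
        rec, truth = simulate_gaze(
            WorkloadProfile(duration_s=60.0, fixation_rate=2.0), noise_sd=0.01, seed=11
        )
        detected = sum(1 for e in ivt_classify(rec) if e.kind == "fixation")
        assert detected == pytest.approx(truth.count("fixation"), rel=0.05)

    def test_all_invalid_gives_empty_with_warning(self):
        t = np.arange(10) / RATE
        rec = make_recording(t, np.full(10, np.nan), valid=np.zeros(10, bool))
        with pytest.warns(UserWarning):
            assert ivt_classify(rec) == []

    def test_matches_brute_force_oracle_on_random_streams(self):
        """Classification equals per-sample thresholding + run merging on
        gap-free streams (no minimum-duration pruning, no gap fill)."""
        rng = np.random.default_rng(42)
        params = IVTParams(min_fixation_duration=0.0, max_gap_fill=0.0)
        for _ in range(50):
            n = int(rng.integers(20, 300))
            x = np.cumsum(rng.normal(0, 0.25, n))
            y = np.cumsum(rng.normal(0, 0.25, n))
            rec = make_recording(np.arange(n) / RATE, x, y)
            got = [(e.kind, e.t_start, e.t_end) for e in ivt_classify(rec, params)]
            expected = brute_force_ivt(rec, params)
            assert len(got) == len(expected)
            for (gk, g0, g1), (ek, e0, e1) in zip(got, expected):
                assert gk == ek
                assert g0 == pytest.approx(e0) and g1 == pytest.approx(e1)

    def test_events_tile_without_overlap(self):
        rng = np.random.default_rng(3)
        n = 500
        rec = make_recording(
            np.arange(n) / RATE, np.cumsum(rng.normal(0, 0.3, n)), np.cumsum(rng.normal(0, 0.3, n))
        )
        events = sorted(ivt_classify(rec), key=lambda e: e.t_start)
        for a, b in zip(events, events[1:]):
            assert a.t_end <= b.t_start + 1e-9

    def test_raising_threshold_never_reduces_fixation_time(self):
        rng = np.random.default_rng(5)
        n = 1000
        rec = make_recording(
            np.arange(n) / RATE, np.cumsum(rng.normal(0, 0.3, n)), np.cumsum(rng.normal(0, 0.3, n))
        )
        totals = []
        for thr in (10.0, 20.0, 30.0, 50.0, 80.0):
            events = ivt_classify(rec, IVTParams(velocity_threshold=thr))
            totals.append(sum(e.duration for e in events if e.kind == "fixation"))
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_short_gap_does_not_split_fixation(self):
        t = np.arange(200) / RATE
        x = np.zeros(200)
        valid = np.ones(200, bool)
        valid[100:104] = False  # 40 ms dropout < 75 ms gap-fill limit
        x_in = x.copy()
        x_in[100:104] = np.nan
        rec = make_recording(t, x_in, valid=valid)
        events = ivt_classify(rec)
        assert sum(1 for e in events if e.kind == "fixation") == 1


# ---------------------------------------------------------------------------
# saccadic intrusions
# ---------------------------------------------------------------------------


def square_excursion(amp=1.0, hold_s=0.2, pre_s=1.0, post_s=1.0):
    n_pre, n_hold, n_post = (int(s * RATE) for s in (pre_s, hold_s, post_s))
    x = np.concatenate([np.zeros(n_pre), np.full(n_hold, amp), np.zeros(n_post)])
    t = np.arange(len(x)) / RATE
    return make_recording(t, x)


class TestIntrusions:
    def test_constant_x_has_no_intrusions(self, stationary_recording):
        assert detect_intrusions(stationary_recording) == []

    def test_square_excursion_detected(self):
        events = detect_intrusions(square_excursion(amp=1.0, hold_s=0.2))
        assert len(events) == 1
        assert events[0].kind == "intrusion"
        assert events[0].amplitude == pytest.approx(1.0, abs=0.05)
        assert 0.060 <= events[0].duration <= 0.870

    def test_excursion_too_long_rejected(self):
        assert detect_intrusions(square_excursion(amp=1.0, hold_s=1.0)) == []

    def test_excursion_too_small_rejected(self):
        assert detect_intrusions(square_excursion(amp=0.3, hold_s=0.2)) == []

    def test_excursion_too_fast_rejected(self):
        # returns after 30 ms, below the 60 ms minimum
        assert detect_intrusions(square_excursion(amp=1.0, hold_s=0.03)) == []

    def test_oversized_excursion_rejected_as_saccade(self):
        assert detect_intrusions(square_excursion(amp=5.0, hold_s=0.2)) == []

    def test_detections_never_overlap(self):
        rec, _ = simulate_gaze(
            WorkloadProfile(duration_s=120, fixation_rate=0.5, intrusion_rate=0.4),
            noise_sd=0.05,
            seed=9,
        )
        events = sorted(detect_intrusions(rec), key=lambda e: e.t_start)
        for a, b in zip(events, events[1:]):
            assert a.t_end <= b.t_start + 1e-9

    def test_sensitivity_and_fdr_on_synthetic_stream(self):
        """Injected intrusions are recovered at >= 0.9 sensitivity and
        <= 0.1 false-discovery at 0.05 deg RMS position noise."""
        prof = WorkloadProfile(duration_s=240, fixation_rate=0.5, intrusion_rate=0.3)
        rec, truth = simulate_gaze(prof, noise_sd=0.05, seed=4)
        truth_si = [e for e in truth.events if e.kind == "intrusion"]
        detected = detect_intrusions(rec)
        used = set()
        tp = 0
        for d in detected:
            for k, tr in enumerate(truth_si):
                if k not in used and min(d.t_end, tr.t_end) > max(d.t_start, tr.t_start):
                    used.add(k)
                    tp += 1
                    break
        assert tp / len(truth_si) >= 0.9
        assert (len(detected) - tp) / len(detected) <= 0.1


# ---------------------------------------------------------------------------
# rates and windowed counts
# ---------------------------------------------------------------------------


def fix_event(onset, dur=0.2):
    return OcularEvent("fixation", onset, onset + dur)


class TestRates:
    def test_rate_arithmetic(self):
        events = [fix_event(2 * k) for k in range(30)]
        assert event_rate(events, "fixation", 60.0) == pytest.approx(0.5)
        assert event_rate(events, "fixation", 60.0, per="minute") == pytest.approx(30.0)

    def test_empty_events_rate_zero(self):
        assert event_rate([], "fixation", 10.0) == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            event_rate([], "fixation", 0.0)

    def test_windowed_rate_conservation(self):
        rng = np.random.default_rng(0)
        events = [fix_event(float(o)) for o in rng.uniform(0, 50, 37)]
        counts = windowed_counts(events, window=5.0, span=50.0, kind="fixation")
        assert counts["count"].sum() == 37

    def test_uniform_placement(self):
        events = [fix_event(5 * k + 2.5) for k in range(10)]
        counts = windowed_counts(events, window=5.0, span=50.0)
        assert list(counts["count"]) == [1] * 10
        assert counts["complete"].all()

    def test_window_equal_to_span(self):
        events = [fix_event(float(k)) for k in range(7)]
        counts = windowed_counts(events, window=10.0, span=10.0)
        assert len(counts) == 1 and counts["count"].iloc[0] == 7

    def test_partial_last_window_flagged(self):
        counts = windowed_counts([], window=5.0, span=12.0)
        assert list(counts["complete"]) == [True, True, False]
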