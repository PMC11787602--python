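"""Segmentation: smoothing, speed, event detection, binning, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachatten.config import ParticipantParams, SegmentationParams
from reachatten.kinematics import (
    KinematicTrace,
    NoOffsetError,
    NoOnsetError,
    SegmentedTrial,
    bin_trial,
    compute_phase_crossings,
    compute_speed,
    detect_movement_onset,
    detect_reach_offset,
    find_peak_velocity,
    segment_cohort,
    segment_trial,
    smooth_positions,
)
from reachatten.synthetic_data import simulate_reach_trace

SNAP = SegmentationParams(interpolate_crossings=False)
INTERP = SegmentationParams()

DT = 1000.0 / 240.0


def make_trace(x, t0=0.0, tap=None, condition="self_touch", trigger=None):
    x = np.asarray(x, dtype=float)
    n = x.size
    t = t0 + np.arange(n) * DT
    pos = np.zeros((n, 3))
    pos[:, 0] = x
    return KinematicTrace(
        t_ms=t,
        position_cm=pos,
        tap_force_n=tap,
        condition=condition,
        distance_trigger_ms=trigger,
    )


def speed_trace(speed, t0=0.0):
    """Timestamps + 1D position whose central-difference speed is known."""
    return t0 + np.arange(len(speed)) * DT, np.asarray(speed, dtype=float)


# ---------------------------------------------------------------------------
# oracles (independent brute-force reimplementations)


def onset_oracle(t, speed, params, search_from=0.0):
    hold = params.onset_hold_samples
    for i in range(len(speed) - hold + 1):
        if t[i] < search_from:
            continue
        if all(speed[i + j] > params.onset_speed_threshold for j in range(hold)):
            return t[i]
    return None


def offset_oracle(t, force, onset, thr):
    for i in range(len(force)):
        if t[i] > onset and force[i] > thr:
            return t[i]
    return None


def crossings_oracle(t, speed, onset, offset, peak_t, peak_v, frac):
    level = frac * peak_v
    ascend = peak_t
    for i in range(len(speed)):
        if onset <= t[i] <= peak_t and speed[i] >= level:
            ascend = t[i]
            break
    descend = offset
    for i in range(len(speed)):
        if t[i] > peak_t and speed[i] < level and t[i] <= offset:
            descend = t[i]
            break
    return max(ascend, onset), max(min(descend, offset), ascend)


class TestSmoothing:
    def test_constant_unchanged(self):
        trace = make_trace(np.full(50, 3.3))
        out = smooth_positions(trace, SNAP)
        np.testing.assert_allclose(out.position_cm, trace.position_cm)

    def test_unit_impulse_box_response(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = smooth_positions(make_trace(x), SNAP)
        np.testing.assert_allclose(out.position_cm[18:23, 0], np.full(5, 0.2))
        assert np.all(out.position_cm[:18, 0] == 0)

    def test_linear_ramp_preserved_everywhere(self):
        # the symmetric (shrinking at edges) window preserves affine signals
        x = 0.7 * np.arange(60) - 4.0
        out = smooth_positions(make_trace(x), SNAP)
        np.testing.assert_allclose(out.position_cm[:, 0], x, atol=1e-12)

    def test_too_short_trace_rejected(self):
        from reachatten.kinematics import KinematicsError

        with pytest.raises(KinematicsError):
            smooth_positions(make_trace([0.0, 1.0, 2.0]), SNAP)


class TestSpeed:
    def test_static_trace_zero(self):
        assert np.all(compute_speed(make_trace(np.full(30, 2.0))) < 1e-10)

    def test_uniform_motion(self):
        # 10 cm/s along x; derivative is exact for linear signals
        x = 10.0 * (np.arange(100) * DT / 1000.0)
        np.testing.assert_allclose(compute_speed(make_trace(x)), 10.0, rtol=1e-9)

    def test_circular_motion_speed_r_omega(self):
        r, omega = 3.0, 4.0  # cm, rad/s
        t_s = np.arange(200) * DT / 1000.0
        pos = np.zeros((200, 3))
        pos[:, 0] = r * np.cos(omega * t_s)
        pos[:, 1] = r * np.sin(omega * t_s)
        trace = KinematicTrace(t_ms=t_s * 1000.0, position_cm=pos)
        speed = compute_speed(trace)
        np.testing.assert_allclose(speed[1:-1], r * omega, rtol=2e-4)

    def test_nonuniform_timestamps_rejected(self):
        from reachatten.kinematics import KinematicsError

        t = np.array([0.0, 1.0, 3.0, 7.0, 8.0])
        trace = KinematicTrace(t_ms=t, position_cm=np.zeros((5, 3)))
        with pytest.raises(KinematicsError):
            compute_speed(trace)


class TestOnset:
    def test_all_zero_speed_no_onset(self):
        t, v = speed_trace(np.zeros(100))
        with pytest.raises(NoOnsetError):
            detect_movement_onset(t, v, SNAP)

    def test_short_excursion_disqualified(self):
        # 12 samples (50 ms) above threshold is not a 100 ms hold
        v = np.zeros(100)
        v[30:42] = 10.0
        t, v = speed_trace(v)
        with pytest.raises(NoOnsetError):
            detect_movement_onset(t, v, SNAP)

    def test_exact_hold_accepted(self):
        v = np.zeros(100)
        v[30:54] = 10.0  # exactly 24 samples = 100 ms at 240 Hz
        t, v = speed_trace(v)
        assert detect_movement_onset(t, v, SNAP) == pytest.approx(30 * DT)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        # piecewise-constant random speeds hovering around the threshold
        v = np.repeat(rng.uniform(0, 12, size=25), rng.integers(1, 8, size=25))
        t = np.arange(v.size) * DT
        expected = onset_oracle(t, v, SNAP)
        if expected is None:
            with pytest.raises(NoOnsetError):
                detect_movement_onset(t, v, SNAP)
        else:
            assert detect_movement_onset(t, v, SNAP) == pytest.approx(expected)

    def test_interpolated_onset_subsample(self):
        v = np.zeros(100)
        v[30:] = 10.0
        v[29] = 0.0
        t = np.arange(100) * DT
        got = detect_movement_onset(t, v, INTERP)
        # crossing of 5 cm/s midway between samples 29 (0) and 30 (10)
        assert got == pytest.approx(29 * DT + 0.5 * DT)


class TestOffset:
    def test_step_crossing(self):
        force = np.zeros(100)
        force[60:] = 1.0
        trace = make_trace(np.zeros(100), tap=force)
        assert detect_reach_offset(trace, 10.0, SNAP) == pytest.approx(60 * DT)

    def test_never_exceeds_threshold(self):
        trace = make_trace(np.zeros(100), tap=np.full(100, 0.25))
        with pytest.raises(NoOffsetError):
            detect_reach_offset(trace, 10.0, SNAP)

    def test_bounce_returns_first_crossing(self):
        force = np.zeros(120)
        force[50:55] = 1.0  # first tap
        force[70:80] = 2.0  # bounce
        trace = make_trace(np.zeros(120), tap=force)
        got = detect_reach_offset(trace, 10.0, SNAP)
        assert got == pytest.approx(offset_oracle(trace.t_ms, force, 10.0, 0.3))
        assert got == pytest.approx(50 * DT)

    def test_distance_trigger_returned(self):
        trace = make_trace(
            np.zeros(100), condition="no_self_touch", trigger=333.0
        )
        assert detect_reach_offset(trace, 10.0, SNAP) == 333.0

    def test_missing_trigger_errors(self):
        trace = make_trace(np.zeros(100), condition="no_self_touch")
        with pytest.raises(NoOffsetError):
            detect_reach_offset(trace, 10.0, SNAP)


class TestPeak:
    def test_symmetric_profile_peak_at_midpoint(self):
        n = 121
        t = np.arange(n) * DT
        onset, offset = 0.0, t[-1]
        v = np.sin(np.pi * t / t[-1])  # symmetric, peak at midpoint
        pt, pv = find_peak_velocity(t, v, onset, offset, SNAP)
        assert pt == pytest.approx(t[n // 2])

    def test_global_max_outside_window_ignored(self):
        t = np.arange(100) * DT
        v = np.zeros(100)
        v[30] = 5.0  # in-window peak
        v[90] = 50.0  # terminal tap spike, after 67% of the movement
        pt, pv = find_peak_velocity(t, v, 0.0, t[-1], SNAP)
        unrestricted = t[int(np.argmax(v))]
        assert pt == pytest.approx(t[30]) and pv == 5.0
        assert pt != unrestricted

    def test_monotone_speed_peak_at_window_end(self):
        t = np.arange(100) * DT
        v = np.linspace(0, 50, 100)
        pt, _ = find_peak_velocity(t, v, 0.0, t[-1], SNAP)
        in_window = t[t <= 0.67 * t[-1]]
        assert pt == pytest.approx(in_window[-1])

    def test_tie_breaks_to_earliest(self):
        t = np.arange(50) * DT
        v = np.zeros(50)
        v[10] = v[20] = 7.0
        pt, _ = find_peak_velocity(t, v, 0.0, t[-1], SNAP)
        assert pt == pytest.approx(t[10])


class TestPhaseCrossings:
    def test_triangular_profile_linear_interpolation(self):
        # rise 0->100 over 48 samples, fall 100->0 over 48: 85% crossings lie
        # exactly at 85% of each ramp when interpolated
        up = np.linspace(0, 100, 49)
        down = np.linspace(100, 0, 49)[1:]
        v = np.concatenate([up, down])
        t = np.arange(v.size) * DT
        peak_t, peak_v = t[48], 100.0
        a, d = compute_phase_crossings(t, v, 0.0, t[-1], peak_t, peak_v, INTERP)
        assert a == pytest.approx(0.85 * t[48], rel=1e-9)
        assert d == pytest.approx(t[48] + 0.15 * (t[-1] - t[48]), rel=1e-9)

    def test_flat_top_first_crossing_rule(self):
        v = np.concatenate([np.zeros(10), np.full(20, 50.0), np.zeros(10)])
        t = np.arange(v.size) * DT
        a, d = compute_phase_crossings(t, v, 0.0, t[-1], t[15], 50.0, SNAP)
        assert a == pytest.approx(t[10])  # first sample at >= 85% of peak
        assert d == pytest.approx(t[30])  # first sample after plateau below

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        peak_i = rng.integers(20, 50)
        v = np.concatenate(
            [np.sort(rng.uniform(0, 100, peak_i)), [100.0],
             np.sort(rng.uniform(0, 100, n - peak_i - 1))[::-1]]
        )
        t = np.arange(n) * DT
        onset, offset = t[2], t[-2]
        pt, pv = find_peak_velocity(t, v, onset, offset, SNAP)
        got = compute_phase_crossings(t, v, onset, offset, pt, pv, SNAP)
        want = crossings_oracle(t, v, onset, offset, pt, pv, 0.85)
        assert got == pytest.approx(want)

    def test_scale_covariance(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([np.sort(rng.uniform(0, 90, 40)), [95.0],
                            np.sort(rng.uniform(0, 90, 39))[::-1]])
        t = np.arange(80) * DT
        pt, pv = find_peak_velocity(t, v, 0.0, t[-1], SNAP)
        base = compute_phase_crossings(t, v, 0.0, t[-1], pt, pv, SNAP)
        for c in (0.1, 3.7):
            pt_c, pv_c = find_peak_velocity(t, c * v, 0.0, t[-1], SNAP)
            got = compute_phase_crossings(t, c * v, 0.0, t[-1], pt_c, pv_c, SNAP)
            assert got == pytest.approx(base)


class TestBinning:
    def seg(self, onset=200.0, ascend=320.0, descend=450.0, offset=700.0):
        return SegmentedTrial(
            onset_ms=onset, ascend85_ms=ascend, descend85_ms=descend,
            offset_ms=offset, peak_time_ms=(ascend + descend) / 2,
            peak_speed_cms=90.0,
        )

    def test_peak_time_is_mid(self):
        seg = self.seg()
        label, reason, pct = bin_trial("t370", seg.peak_time_ms, seg)
        assert label == "mid" and reason is None

    def test_before_onset_invalid_e(self):
        label, reason, _ = bin_trial("t250", 150.0, self.seg())
        assert label == "invalid" and reason == "e"

    def test_after_offset_invalid_e(self):
        label, reason, _ = bin_trial("t550", 701.0, self.seg())
        assert label == "invalid" and reason == "e"

    def test_hardware_labels_pass_through(self):
        assert bin_trial("target", 735.0, self.seg())[0] == "target"
        assert bin_trial("post_reach", 1000.0, self.seg())[0] == "post_reach"

    def test_missing_landmarks_tag_b(self):
        seg = SegmentedTrial()
        label, reason, _ = bin_trial("t250", 300.0, seg)
        assert label == "invalid" and reason == "b"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_interval_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        onset = rng.uniform(100, 300)
        a, d, off = np.sort(rng.uniform(onset + 1, 900, 3))
        seg = self.seg(onset, a, d, off)
        test_t = rng.uniform(0, 1100)
        label, reason, pct = bin_trial("t370", test_t, seg)
        # independent interval-membership check
        if test_t < onset or test_t >= off:
            assert label == "invalid" and reason == "e"
        elif onset <= test_t < a:
            assert label == "early"
        elif a <= test_t < d:
            assert label == "mid"
        else:
            assert label == "late"
        if label != "invalid":
            assert 0.0 <= pct < 100.0

    def test_partition_of_movement_interval(self):
        # early/mid/late exactly partition [onset, offset): every time maps
        # to exactly one label, boundaries included on the left
        seg = self.seg()
        times = np.linspace(seg.onset_ms, seg.offset_ms, 1001)[:-1]
        labels = [bin_trial("t370", t, seg)[0] for t in times]
        assert set(labels) == {"early", "mid", "late"}
        changes = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert len(changes) == 2  # contiguous, ordered, no gaps


class TestSegmentTrial:
    def test_ordering_invariant_on_simulated_reaches(self, rng):
        params = ParticipantParams()
        for _ in range(20):
            rt = rng.uniform(150, 300)
            dur = rng.uniform(400, 700)
            trace = simulate_reach_trace(params, rng, rt, dur, rt + 150.0)
            seg = segment_trial(trace, "t370", rt + 150.0, INTERP)
            assert seg.label != "invalid"
            assert (
                seg.onset_ms
                < seg.ascend85_ms
                <= seg.peak_time_ms
                <= seg.descend85_ms
                <= seg.offset_ms
            )

    def test_shift_equivariance(self, rng):
        params = ParticipantParams(kinematic_noise_sd_cm=0.0)
        trace = simulate_reach_trace(params, rng, 220.0, 540.0, 400.0)
        seg = segment_trial(trace, "t370", 400.0, INTERP)
        delta = 80.0
        seg_shift = segment_trial(trace.shifted(delta), "t370", 400.0 + delta, INTERP)
        for attr in ("onset_ms", "offset_ms", "peak_time_ms", "ascend85_ms",
                     "descend85_ms"):
            assert getattr(seg_shift, attr) == pytest.approx(
                getattr(seg, attr) + delta, abs=1e-6
            )
        assert seg_shift.label == seg.label

    def test_default_simulator_phase_percentages_ordered(self, default_lm_cohort):
        seg = segment_cohort(default_lm_cohort)
        merged = default_lm_cohort.trials.merge(
            seg, on=["participant", "trial_id"]
        )
        means = merged.groupby("label", observed=True)["percent_time"].mean()
        assert 0 < means["early"] < means["mid"] < means["late"] < 100
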