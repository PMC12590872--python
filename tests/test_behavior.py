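"""Movement-bout segmentation against exhaustive criterion oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from locopop.behavior import (bout_kinematic_similarity,
                              detect_motion_events, motion_mask,
                              session_summary, speed_event_rate_curve)
from locopop.synthgen import BehaviorParams, generate_behavior

from oracles import first_stop_frame, verify_motion_events

RATE = 25.0


def step_trace(segments, rate=RATE):
    """Concatenate (duration_s, speed) segments into a velocity trace."""
    return np.concatenate([np.full(int(round(d * rate)), v)
                           for d, v in segments])


class TestDetectMotionEvents:
    def test_quiescent_trace_has_no_events(self):
        b = detect_motion_events(np.zeros(500), RATE)
        assert len(b.onsets) == 0 and len(b.offsets) == 0

    def test_single_bout_onset_and_offset_frames(self):
        # 3 s still, 4 s at 0.5 cm/s, 3 s still: the rising transition at
        # t=3 s and falling transition at t=7 s both satisfy the window
        # criteria, and no other frame is a candidate
        v = step_trace([(3, 0.0), (4, 0.5), (3, 0.0)])
        b = detect_motion_events(v, RATE)
        assert list(b.onsets) == [75]
        assert list(b.offsets) == [175]
        verify_motion_events(v, b.onsets, b.offsets, RATE)

    def test_brief_dip_does_not_split_bout(self):
        # a 0.2 s sub-threshold dip inside a 6 s run: its quiescence is far
        # shorter than 2 s, so both the second onset's pre-criterion and
        # the first offset's post-criterion fail
        v = step_trace([(3, 0.0), (3, 0.5), (0.2, 0.04), (2.8, 0.5), (3, 0.0)])
        b = detect_motion_events(v, RATE)
        assert len(b.onsets) == 1 and b.onsets[0] == 75
        assert len(b.offsets) == 1 and b.offsets[0] == 225
        verify_motion_events(v, b.onsets, b.offsets, RATE)

    def test_edge_candidates_excluded(self):
        # motion starting 1 s into the trace: pre-window would cross the
        # start, so the onset cannot be evaluated and is dropped
        v = step_trace([(1, 0.0), (4, 0.5), (3, 0.0)])
        b = detect_motion_events(v, RATE)
        assert len(b.onsets) == 0
        assert list(b.offsets) == [125]

    def test_emitted_events_pass_oracle_on_noisy_traces(self):
        params = BehaviorParams(speed_noise_sd=0.05)
        for seed in range(6):
            day = seed % 8 + 1
            v, _ = generate_behavior(params, day, seed)
            b = detect_motion_events(v, RATE)
            verify_motion_events(v, b.onsets, b.offsets, RATE)

    def test_clean_trace_recovers_planted_bouts(self):
        params = BehaviorParams(speed_noise_sd=0.0)
        for seed in range(4):
            v, bouts = generate_behavior(params, 5, seed)
            b = detect_motion_events(v, RATE)
            assert len(b.onsets) == len(bouts)
            assert len(b.offsets) == len(bouts)
            for det, (true_on, true_off) in zip(
                    zip(b.onsets, b.offsets), bouts):
                assert abs(det[0] - true_on) <= 2
                assert abs(det[1] - true_off) <= 2

    def test_thresholds_are_absolute_not_relative(self):
        # velocity hovering at 0.2 cm/s: below the onset excursion
        # threshold, so nothing is detected; doubled (0.4 cm/s) the same
        # trace produces a bout, exactly as the oracle predicts
        v = step_trace([(3, 0.0), (4, 0.2), (3, 0.0)])
        assert len(detect_motion_events(v, RATE).onsets) == 0
        b2 = detect_motion_events(2 * v, RATE)
        assert list(b2.onsets) == [75]
        verify_motion_events(2 * v, b2.onsets, b2.offsets, RATE)

    def test_nan_velocity_rejected(self):
        v = np.zeros(300)
        v[10] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            detect_motion_events(v, RATE)

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            b = detect_motion_events(np.zeros(60), RATE)
        assert len(b.onsets) == 0

    @given(st.integers(0, 2**31 - 1))
    def test_every_emitted_event_passes_criteria(self, seed):
        rng = np.random.default_rng(seed)
        # random piecewise-constant trace with occasional quiescent gaps
        segs = []
        for _ in range(rng.integers(3, 8)):
            segs.append((float(rng.uniform(0.5, 4.0)),
                         float(rng.choice([0.0, 0.05, 0.2, 0.6, 1.5]))))
        v = step_trace(segs)
        if len(v) <= 100:
            return
        b = detect_motion_events(v, RATE)
        verify_motion_events(v, b.onsets, b.offsets, RATE)


class TestMotionMask:
    def test_no_onsets_all_false(self):
        m = motion_mask(np.random.default_rng(0).random(200), np.array([]), RATE)
        assert not m.any()

    def test_stop_frame_matches_windowed_mean_oracle(self):
        v = step_trace([(3, 0.0), (4, 0.5), (3, 0.0)])
        b = detect_motion_events(v, RATE)
        stop = first_stop_frame(v, 75, RATE)
        expected = np.zeros(len(v), bool)
        expected[75:stop] = True
        assert np.array_equal(b.motion_mask, expected)
        # direct evaluation of the 17-frame centered means puts the stop
        # 5 frames after the plateau ends
        assert stop == 180

    def test_mask_ignores_velocity_before_first_onset(self):
        v = step_trace([(3, 0.0), (4, 0.5), (3, 0.0)])
        m1 = motion_mask(v, np.array([75]), RATE)
        v2 = v.copy()
        v2[:40] = 3.0  # garbage before the onset's window
        m2 = motion_mask(v2, np.array([75]), RATE)
        assert np.array_equal(m1, m2)


class TestSessionSummary:
    @pytest.mark.parametrize("velocity, mask, expected", [
        (np.full(100, 2.0), np.ones(100, bool), (2.0, 1.0)),
        (np.full(50, 7.0), np.zeros(50, bool), (7.0, 0.0)),
        (np.array([0.0, 0, 4, 4]), np.array([0, 0, 1, 1], bool), (2.0, 0.5)),
    ])
    def test_examples(self, velocity, mask, expected):
        assert session_summary(velocity, mask) == pytest.approx(expected)


class TestSpeedEventRateCurve:
    def test_no_events_zero_curve(self):
        v = np.linspace(0, 1, 250)
        rates, occ = speed_event_rate_curve([np.array([], int)], v,
                                            [0, 0.5, 1.1], RATE)
        assert np.allclose(rates, 0.0)
        assert occ.sum() == pytest.approx(10.0)

    def test_events_land_in_their_speed_bin(self):
        v = np.concatenate([np.zeros(100), np.ones(100)])
        events = [np.array([150, 160, 170])]
        rates, _ = speed_event_rate_curve(events, v, [0, 0.5, 1.5], RATE)
        assert rates[0] == 0.0
        assert rates[1] == pytest.approx(3 / 4.0)  # 3 events in 4 s occupancy

    def test_zero_occupancy_bin_flagged_nan(self):
        v = np.zeros(200)
        with pytest.warns(UserWarning, match="zero occupancy"):
            rates, _ = speed_event_rate_curve([np.array([5])], v,
                                              [0, 0.5, 1.0], RATE)
        assert np.isnan(rates[1])

    def test_uniform_events_flat_curve(self, rng):
        # occupancy uniform across bins and events uniform in time: the
        # per-bin rates match the global rate within sampling error
        v = rng.uniform(0, 4, 40000)
        events = [np.sort(rng.choice(40000, 800, replace=False))]
        rates, occ = speed_event_rate_curve(events, v, [0, 1, 2, 3, 4], RATE)
        global_rate = 800 / (40000 / RATE)
        assert np.all(np.abs(rates - global_rate) < 0.25 * global_rate)


class TestBoutKinematicSimilarity:
    def test_identical_bouts_give_one(self):
        traj = np.column_stack([np.sin(np.linspace(0, 6, 80)),
                                np.cos(np.linspace(0, 6, 80))])
        assert bout_kinematic_similarity([traj, traj.copy(), traj.copy()]) \
            == pytest.approx(1.0)

    def test_mirrored_x_identical_y_averages_to_zero(self):
        t = np.linspace(0, 6, 60)
        b1 = np.column_stack([np.sin(t), np.cos(t)])
        b2 = np.column_stack([-np.sin(t), np.cos(t)])
        assert bout_kinematic_similarity([b1, b2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pairwise_mean(self):
        # three X-series built on an orthonormal mean-zero basis so their
        # pairwise Pearson correlations are exactly 0.9, 0.6 and 0.3;
        # identical non-constant Y contributes 1 for each pair: mean 0.8
        t_hat = np.array([-3.0, -1, 1, 3]) / np.sqrt(20)
        s_hat = np.array([1.0, -1, -1, 1]) / 2.0
        u_hat = np.array([-1.0, 3, -3, 1]) / np.sqrt(20)
        x1 = t_hat
        x2 = 0.9 * t_hat + np.sqrt(1 - 0.81) * s_hat
        g = (0.3 - 0.9 * 0.6) / np.sqrt(0.19)
        x3 = 0.6 * t_hat + g * s_hat + np.sqrt(1 - 0.36 - g**2) * u_hat
        y = np.array([0.0, 1, 2, 3])
        bouts = [np.column_stack([x, y]) for x in (x1, x2, x3)]
        assert bout_kinematic_similarity(bouts) == pytest.approx(0.8)

    def test_constant_trajectory_pair_skipped(self):
        t = np.linspace(0, 6, 50)
        good = np.column_stack([np.sin(t), np.cos(t)])
        flat = np.column_stack([np.ones(50), np.cos(t)])
        with pytest.warns(UserWarning, match="constant"):
            val = bout_kinematic_similarity([good, flat])
        assert -1.0 <= val <= 1.0
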