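"""Detrending, control signal, threshold classification, adaptive thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtattn import decode
from rtattn.decode import (
    FeedbackState,
    ThresholdSet,
    adaptive_thresholds,
    classify,
    control_signal,
    detrend,
)
from rtattn.synth import Condition, label_mask, make_schedule, simulate_cs_trace


class TestDetrend:
    def test_constant_maps_to_zero(self):
        out = detrend(np.full(50, 7.3), lam=500.0)
        assert np.max(np.abs(out)) < 1e-10

    def test_linear_ramp_strongly_suppressed(self):
        ramp = np.linspace(0, 10, 200)
        out = detrend(ramp, lam=500.0)
        assert np.max(np.abs(out)) < 0.01 * np.ptp(ramp)

    def test_lambda_zero_returns_zero(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(30)
        assert np.array_equal(detrend(z, lam=0.0), np.zeros(30))

    def test_matches_dense_solve_oracle(self):
        """Banded solver agrees with an explicit dense linear solve of
        (I + lam^2 D2'D2) trend = z."""
        rng = np.random.default_rng(1)
        z = rng.standard_normal(40)
        lam = 50.0
        n = len(z)
        d2 = np.zeros((n - 2, n))
        for i in range(n - 2):
            d2[i, i : i + 3] = [1.0, -2.0, 1.0]
        trend = np.linalg.solve(np.eye(n) + lam**2 * d2.T @ d2, z)
        assert np.allclose(detrend(z, lam), z - trend, atol=1e-10)

    def test_matrix_input_detrended_columnwise(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((60, 5))
        out = detrend(z, 100.0)
        for k in range(5):
            assert np.allclose(out[:, k], detrend(z[:, k], 100.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detrend(np.ones(10), lam=-1.0)
        with pytest.raises(ValueError):
            detrend(np.ones(2), lam=10.0)

    def test_preserves_fast_oscillation(self):
        """Task-frequency content (13 s blocks) survives the detrender."""
        t = np.arange(300)
        sig = np.sin(2 * np.pi * t / 16.0)
        out = detrend(sig, 500.0)
        assert np.corrcoef(out, sig)[0, 1] > 0.95


class TestControlSignal:
    def test_at_baseline_is_zero(self):
        assert control_signal(100.0, 200.0, 100.0, 200.0) == 0.0

    def test_single_sided_two_percent(self):
        assert control_signal(102.0, 200.0, 100.0, 200.0) == pytest.approx(2.0)

    def test_activation_plus_deactivation_add(self):
        assert control_signal(101.0, 99.0, 100.0, 100.0) == pytest.approx(2.0)

    def test_sd_normalized_variant(self):
        cs = control_signal(102.0, 100.0, 100.0, 100.0, normalize_sd=True,
                            sd_r=2.0, sd_l=1.0)
        assert cs == pytest.approx(1.0)  # 2% / 2.0 - 0

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            control_signal(1.0, 1.0, 0.0, 1.0)


class TestThresholdSet:
    def test_fixed_scheme(self):
        th = ThresholdSet.fixed()
        assert th.pos == (1.5, 2.5, 4.0)
        assert th.neg == (-1.5, -2.5, -4.0)

    def test_from_theta1_reproduces_fixed_scheme(self):
        th = ThresholdSet.from_theta1(1.5, -1.5)
        assert th.pos == pytest.approx((1.5, 2.5, 4.0))
        assert th.neg == pytest.approx((-1.5, -2.5, -4.0))

    def test_sign_crossed_estimate_keeps_ordering(self):
        # a biased CS can push the left threshold above zero
        th = ThresholdSet.from_theta1(0.4, 0.01)
        assert th.pos[0] < th.pos[1] < th.pos[2]
        assert th.neg[0] > th.neg[1] > th.neg[2]

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet((2.0, 1.0, 3.0), (-1.5, -2.5, -4.0))


class TestClassify:
    TH = ThresholdSet((1.5, 2.5, 4.0), (-1.5, -2.5, -4.0))

    @pytest.mark.parametrize(
        "cs,context,side,state,color",
        [
            (3.0, Condition.RIGHT, Condition.RIGHT,
             FeedbackState.STRONG_R, "green_strong"),
            (2.0, Condition.RIGHT, Condition.RIGHT,
             FeedbackState.WEAK_R, "green_weak"),
            (0.0, Condition.CENTER, None, FeedbackState.OFF, "green_weak"),
            (-2.0, Condition.RIGHT, Condition.RIGHT,
             FeedbackState.WEAK_L, "red_weak"),
            (-5.0, Condition.LEFT, Condition.LEFT,
             FeedbackState.STRONG_L, "green_strong"),
            (3.0, Condition.CENTER, None,
             FeedbackState.STRONG_R, "red_strong"),
            (0.5, Condition.RIGHT, Condition.RIGHT,
             FeedbackState.OFF, "red_weak"),
        ],
    )
    def test_band_lookup_and_coloring(self, cs, context, side, state, color):
        got_state, got_color = classify(cs, context, side, self.TH)
        assert got_state is state
        assert got_color == color


def brute_force_thresholds(cs, labels, target_fpr, shift):
    """Exhaustive sweep over every observed CS value (independent oracle)."""
    cs_v = cs[shift:]
    lab_v = labels[: len(cs) - shift]
    non_r = cs_v[~label_mask(lab_v, Condition.RIGHT)]
    non_l = cs_v[~label_mask(lab_v, Condition.LEFT)]
    pos_ok = [c for c in sorted(set(cs_v))
              if np.mean(non_r > c) <= target_fpr]
    neg_ok = [c for c in sorted(set(cs_v))
              if np.mean(non_l < c) <= target_fpr]
    return min(pos_ok), max(neg_ok)


class TestAdaptiveThresholds:
    def test_matches_brute_force_sweep(self):
        sched = make_schedule(8, 8, seed=11, extra_initial_center=True)
        cs = simulate_cs_trace(sched, seed=11)
        th = adaptive_thresholds(cs, sched, target_fpr=0.2, shift_trs=3)
        t_pos, t_neg = brute_force_thresholds(cs, sched.labels(), 0.2, 3)
        assert th.pos[0] == t_pos
        assert th.neg[0] == t_neg

    def test_clean_separation_gives_zero_training_fpr(self):
        sched = make_schedule(2, 5, seed=0)
        labels = sched.labels()
        cs = np.zeros(sched.n_scans_total)
        cs[label_mask(labels, Condition.RIGHT)] = 3.0
        cs[label_mask(labels, Condition.LEFT)] = -3.0
        th = adaptive_thresholds(cs, sched, target_fpr=0.2, shift_trs=0)
        assert np.mean(cs[~label_mask(labels, Condition.RIGHT)] > th.pos[0]) == 0.0

    def test_target_one_admits_everything(self):
        sched = make_schedule(2, 5, seed=1)
        cs = simulate_cs_trace(sched, seed=1)
        th = adaptive_thresholds(cs, sched, target_fpr=1.0, shift_trs=0)
        assert th.pos[0] == np.min(cs)

    @given(seed=st.integers(0, 2_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_training_fpr_bound_holds_on_every_trace(self, seed):
        """For any seeded localizer trace the estimated theta_1 keeps the
        shifted training FPR at or below the 0.2 target on both sides."""
        sched = make_schedule(8, 8, seed=seed, extra_initial_center=True)
        cs = simulate_cs_trace(sched, seed=seed)
        th = adaptive_thresholds(cs, sched, target_fpr=0.2, shift_trs=3)
        labels = sched.labels()
        cs_v, lab_v = cs[3:], labels[:-3]
        fpr_r = np.mean(cs_v[~label_mask(lab_v, Condition.RIGHT)] > th.pos[0])
        fpr_l = np.mean(cs_v[~label_mask(lab_v, Condition.LEFT)] < th.neg[0])
        assert fpr_r <= 0.2
        assert fpr_l <= 0.2

    def test_monotonicity_of_training_fpr(self):
        sched = make_schedule(8, 8, seed=5, extra_initial_center=True)
        cs = simulate_cs_trace(sched, seed=5)
        labels = sched.labels()
        cs_v, lab_v = cs[3:], labels[:-3]
        non_r = cs_v[~label_mask(lab_v, Condition.RIGHT)]
        grid = np.linspace(cs.min(), cs.max(), 50)
        fprs = [np.mean(non_r > g) for g in grid]
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))


class TestFeedbackLoop:
    def test_trace_and_states_consistent(self, bold_run, run_schedule,
                                         localized):
        pair = localized["pair"]
        th = ThresholdSet.fixed()
        trace = decode.feedback_loop(bold_run.data, pair, run_schedule, 200,
                                     th)
        assert len(trace.cs) == 300
        assert trace.scan_offset == 200
        # states re-derivable from cs and thresholds at every scan
        for cs, st_, lab in zip(trace.cs, trace.states, trace.labels):
            expect, _ = classify(
                cs, Condition.CENTER if lab is Condition.CENTER else lab,
                lab if lab.is_attention else None, th)
            assert st_ is expect

    def test_shifted_labels_reach_into_localizer(self, bold_run, run_schedule,
                                                 localized):
        trace = decode.feedback_loop(bold_run.data, localized["pair"],
                                     run_schedule, 200, ThresholdSet.fixed())
        shifted, valid = trace.shifted_labels(3)
        assert valid.all()  # offset 200 leaves room for the shift
        assert shifted[0] is run_schedule.labels()[197]

    def test_sliding_window_mode_close_to_reference(self, bold_run,
                                                    run_schedule, localized):
        pair = localized["pair"]
        th = ThresholdSet.fixed()
        ref = decode.feedback_loop(bold_run.data, pair, run_schedule, 200, th)
        win = decode.feedback_loop(bold_run.data, pair, run_schedule, 200, th,
                                   window_scans=150)
        assert np.corrcoef(ref.cs, win.cs)[0, 1] > 0.9
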