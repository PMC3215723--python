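"""Gamma band power, margin-based channel selection, LOO cross-validation."""

import numpy as np
import pytest


import rtattn as r
from rtattn import ecog
from rtattn.ecog import (
    bandpower,
    classify_trial,
    optimize_and_crossvalidate,
    select_channels,
)
from rtattn.synth import CLASSES, Condition, label_mask


FS = 512.0


def sinusoid(freq, seconds=5.0, fs=FS):
    t = np.arange(0, seconds, 1 / fs)
    return np.sin(2 * np.pi * freq * t)


class TestBandpower:
    def test_in_band_tone_dominates(self):
        """80 Hz tone: nearly all (non-DC) power lands in the 65-95 Hz band
        (Parseval-style check against the full-band Welch power)."""
        sig = sinusoid(80.0)[None, :]
        from scipy.signal import welch
        nperseg = int(FS)
        f, psd = welch(sig, fs=FS, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, axis=1)
        total = psd[0, f > 0.5].sum()
        in_band = psd[0, (f >= 65) & (f <= 95)].sum()
        assert in_band / total >= 0.95
        assert bandpower(sig, car=False)[0] > 0

    def test_out_of_band_tone_rejected(self):
        sig30 = sinusoid(30.0)[None, :]
        sig80 = sinusoid(80.0)[None, :]
        bp30 = bandpower(sig30, car=False)[0]
        bp80 = bandpower(sig80, car=False)[0]
        assert bp30 < 0.05 * bp80

    def test_zero_signal(self):
        assert bandpower(np.zeros((3, int(4 * FS))), car=False).sum() == 0.0

    def test_short_trial_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            bandpower(np.zeros((2, 100)))

    def test_common_average_reference_removes_shared_component(self):
        rng = np.random.default_rng(0)
        shared = sinusoid(80.0)
        private = rng.standard_normal(len(shared)) * 0.01
        raw = np.vstack([shared + private, shared, shared])
        bp = bandpower(raw, car=True)
        bp_nocar = bandpower(raw, car=False)
        assert bp.max() < 0.05 * bp_nocar.max()


class TestSelectChannels:
    def _features(self, means_by_class, n_per=40, sd=1e-6, seed=0):
        """Build a normalized-looking feature set with exact class means."""
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for cls_, m in means_by_class.items():
            block = np.tile(m, (n_per, 1)) + sd * rng.standard_normal(
                (n_per, len(m)))
            rows.append(block)
            labels += [cls_] * n_per
        return np.vstack(rows), np.array(labels, dtype=object)

    def test_activation_channel_selected_with_sign(self):
        X, y = self._features({Condition.RIGHT: [2.0], Condition.LEFT: [0.0],
                               Condition.CENTER: [0.0]})
        sets = select_channels(X, y, margin_threshold=1.0)
        assert sets.channels(Condition.RIGHT) == [(0, 1)]
        assert sets.channels(Condition.LEFT) == []

    def test_bipolar_channel_selected_for_two_directions(self):
        """Gamma increase for one direction and decrease for another selects
        the same channel in both sets with opposite signs."""
        X, y = self._features({Condition.RIGHT: [1.0], Condition.LEFT: [-1.0],
                               Condition.CENTER: [0.0]})
        sets = select_channels(X, y, margin_threshold=0.5)
        assert sets.channels(Condition.RIGHT) == [(0, 1)]
        assert sets.channels(Condition.LEFT) == [(0, -1)]

    def test_equal_means_never_selected(self):
        X, y = self._features({c: [0.5, 0.5] for c in CLASSES})
        sets = select_channels(X, y, margin_threshold=0.01)
        assert all(not sets.channels(c) for c in CLASSES)

    def test_amplitude_criterion_blocks_weak_means(self):
        # clear margin but |mean| below half the pooled SD
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 1)) * 3.0
        y = np.array([CLASSES[i % 3] for i in range(120)], dtype=object)
        X[label_mask(y, Condition.RIGHT), 0] += 0.4
        sets = select_channels(X, y, margin_threshold=0.05)
        assert sets.channels(Condition.RIGHT) == []

    def test_selection_monotone_in_margin(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((90, 16))
        y = np.array([CLASSES[i % 3] for i in range(90)], dtype=object)
        X[label_mask(y, Condition.RIGHT), :5] += 1.5
        X[label_mask(y, Condition.LEFT), 8:11] -= 1.2
        prev = None
        for margin in np.linspace(0.0, 3.0, 13):
            sets = select_channels(X, y, margin)
            flat = {(c, ch, s) for c in CLASSES
                    for ch, s in sets.channels(c)}
            if prev is not None:
                assert flat <= prev
            prev = flat


class TestClassifyTrial:
    def test_single_right_channel(self):
        sets = ecog.ChannelSets({Condition.RIGHT: [(0, 1)]}, 0.5)
        assert classify_trial(np.array([3.0]), sets) is Condition.RIGHT

    def test_matches_exhaustive_score_computation(self):
        sets = ecog.ChannelSets(
            {Condition.RIGHT: [(0, 1), (1, 1)],
             Condition.LEFT: [(2, 1)],
             Condition.CENTER: [(0, -1), (2, -1)]}, 0.5)
        x = np.array([1.0, 2.0, -0.5])
        scores = {
            Condition.RIGHT: (1.0 + 2.0) / 2,
            Condition.LEFT: -0.5,
            Condition.CENTER: (-1.0 + 0.5) / 2,
        }
        assert classify_trial(x, sets) is max(scores, key=scores.get)

    def test_deactivation_sign_contributes_positively(self):
        sets = ecog.ChannelSets({Condition.LEFT: [(0, -1)],
                                 Condition.RIGHT: [(1, 1)]}, 0.5)
        x = np.array([-4.0, 1.0])  # strongly negative deactivation channel
        assert classify_trial(x, sets) is Condition.LEFT

    def test_all_empty_falls_back_to_majority(self):
        sets = ecog.ChannelSets({}, 0.5)
        assert classify_trial(np.ones(4), sets,
                              majority=Condition.CENTER) is Condition.CENTER


class TestLeaveOneOut:
    def test_separable_noiseless_set_is_perfect(self):
        """Disjoint channel signatures with zero noise: every class TPR 1.0."""
        cmap = {Condition.RIGHT: {0: 3.0}, Condition.LEFT: {1: 3.0},
                Condition.CENTER: {2: 3.0}}
        ts = r.simulate_ecog(class_channel_map=cmap, noise_sd=0.0, seed=0)
        res = optimize_and_crossvalidate(ts.features, ts.labels)
        assert all(v == 1.0 for v in res.per_class_tpr.values())

    def test_default_map_beats_majority_class_rate(self):
        ts = r.simulate_ecog(seed=0)
        res = optimize_and_crossvalidate(ts.features, ts.labels)
        assert res.accuracy > 39 / 79 + 0.1

    def test_confusion_rows_sum_to_class_counts(self):
        ts = r.simulate_ecog(seed=1)
        res = optimize_and_crossvalidate(ts.features, ts.labels)
        assert res.confusion.loc["left"].sum() == 20
        assert res.confusion.loc["right"].sum() == 20
        assert res.confusion.loc["center"].sum() == 39

    def test_normalization_uses_training_rows_only(self):
        """Leakage check: per-fold mean/SD recomputed from the training rows
        alone must match the internal running-sum shortcut."""
        ts = r.simulate_ecog(seed=2)
        X = ts.features
        total, total_sq = X.sum(axis=0), (X * X).sum(axis=0)
        for i in [0, 17, 78]:
            m = len(X) - 1
            mu_fast = (total - X[i]) / m
            var_fast = (total_sq - X[i] * X[i]) / m - mu_fast**2
            train = np.delete(X, i, axis=0)
            assert np.allclose(mu_fast, train.mean(axis=0))
            assert np.allclose(var_fast, train.var(axis=0), atol=1e-10)

    def test_label_permutation_null_is_chance(self):
        """LOO accuracy with permuted labels is statistically
        indistinguishable from the agreement expected when predictions are
        independent of the labels (alpha = 0.01), and the real-label
        accuracy clears the permutation distribution.

        Trials within one permutation share training sets, so pooled counts
        are overdispersed relative to a binomial; the test therefore treats
        the 100 per-permutation accuracies as i.i.d. draws.
        """
        from scipy.stats import ttest_1samp

        ts = r.simulate_ecog(seed=3)
        rng = np.random.default_rng(3)
        n_perm = 100
        accs = []
        pred_counts = np.zeros(3)
        prior = np.array([20, 20, 39]) / 79
        for _ in range(n_perm):
            y = ts.labels.copy()
            rng.shuffle(y)
            res = optimize_and_crossvalidate(ts.features, y)
            accs.append(res.accuracy)
            pred_counts += res.confusion.to_numpy().sum(axis=0)
        # expected agreement when prediction _|_ label: sum_c P(y=c) P(yhat=c)
        p0 = float(prior @ (pred_counts / pred_counts.sum()))
        assert ttest_1samp(accs, p0).pvalue > 0.01
        real = optimize_and_crossvalidate(ts.features, ts.labels).accuracy
        assert real > np.quantile(accs, 0.99)

    def test_degenerate_labels_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        y = np.array([Condition.LEFT] * 9 + [Condition.RIGHT], dtype=object)
        with pytest.raises(ValueError):
            optimize_and_crossvalidate(X, y)
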