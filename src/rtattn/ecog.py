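"""Gamma-band ECoG attention classifier.

A 64-channel subdural grid is decoded trial-by-trial from high-gamma
(65-95 Hz) band power over the first 4 s of each trial, after common-average
referencing.  Evaluation is leave-one-out: for each held-out trial the
remaining trials (1) supply the normalization statistics (zero mean, unit
variance per channel — the test trial never leaks into them), (2) drive
margin-based selection of per-direction channel sets (with sign, since a
channel may activate for one direction and deactivate for another), the
margin itself picked by nested optimization on the training trials, and
(3) the held-out trial is classified as the direction whose channel set has
the highest sign-adjusted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import welch

from .synth import CLASSES, Condition, label_mask

logger = logging.getLogger(__name__)

#: Tie-break precedence for equal class scores (highest first).
TIE_PRECEDENCE = (Condition.CENTER, Condition.RIGHT, Condition.LEFT)


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

def common_average_reference(raw: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean from every sample."""
    raw = np.asarray(raw, dtype=float)
    return raw - raw.mean(axis=0, keepdims=True)


def bandpower(
    raw_trial: np.ndarray,
    fs: float = 512.0,
    band: tuple[float, float] = (65.0, 95.0),
    window_seconds: float = 4.0,
    car: bool = True,
    segment_seconds: float = 1.0,
) -> np.ndarray:
    """Mean spectral power per channel within ``band`` over the first
    ``window_seconds`` of a (channels, samples) trial.

    The signal is common-average referenced first (unless ``car=False``),
    then Welch's method (Hann window, ``segment_seconds`` segments, 50%
    overlap) estimates the PSD, which is averaged over in-band frequencies.
    """
    raw = np.asarray(raw_trial, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw_trial must be 2D (channels, samples)")
    n_need = int(round(window_seconds * fs))
    if raw.shape[1] < n_need:
        raise ValueError(
            f"trial has {raw.shape[1]} samples, needs {n_need} "
            f"({window_seconds} s at {fs} Hz)"
        )
    seg = raw[:, :n_need]
    if car:
        seg = common_average_reference(seg)
    nperseg = int(round(segment_seconds * fs))
    freqs, psd = welch(seg, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("band contains no FFT bins")
    return psd[:, sel].mean(axis=1)


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------

@dataclass
class ChannelSets:
    """Per-direction channel lists with signs (+ activation, - deactivation)."""

    sets: dict[Condition, list[tuple[int, int]]]
    margin_threshold: float

    def channels(self, direction: Condition) -> list[tuple[int, int]]:
        return self.sets.get(direction, [])


def _class_stats(features: np.ndarray, labels: np.ndarray):
    """Per-class channel means (n_classes, n_channels) in CLASSES order,
    plus the pooled per-channel SD and the SD of the class means."""
    means = np.stack(
        [features[label_mask(labels, c)].mean(axis=0) for c in CLASSES]
    )
    pooled_sd = features.std(axis=0, ddof=0)
    class_mean_sd = means.std(axis=0, ddof=0)
    return means, pooled_sd, class_mean_sd


def _selection_signs(
    means: np.ndarray, sd: np.ndarray, margins: np.ndarray
) -> np.ndarray:
    """Vectorized selection rule.

    Returns int8 signs of shape (n_margins, n_classes, n_channels): +1 where
    the channel is selected as activation for that direction, -1 as
    deactivation, 0 not selected.  A channel is selected for direction d
    when its mean under d is beyond both other class means with a gap to the
    closest one larger than the margin, and |mean under d| exceeds half the
    SD.  Selection shrinks monotonically as the margin grows.
    """
    n_cls, n_ch = means.shape
    margins = np.asarray(margins, dtype=float).reshape(-1, 1, 1)
    others_max = np.empty_like(means)
    others_min = np.empty_like(means)
    for i in range(n_cls):
        others = np.delete(means, i, axis=0)
        others_max[i] = others.max(axis=0)
        others_min[i] = others.min(axis=0)
    amp_ok = np.abs(means) > 0.5 * sd  # (cls, ch)
    act = ((means - others_max) > margins) & amp_ok
    deact = ((others_min - means) > margins) & amp_ok
    return act.astype(np.int8) - deact.astype(np.int8)


def select_channels(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    margin_threshold: float,
    sd_mode: str = "pooled",
) -> ChannelSets:
    """Select per-direction channel sets from normalized training features.

    ``sd_mode`` chooses the "standard deviation over all three directions"
    in the amplitude criterion: ``"pooled"`` (SD of all training values of
    the channel, the default) or ``"class_means"`` (SD of the three class
    means).  Empty sets are allowed.
    """
    feats = np.asarray(train_features, dtype=float)
    labels = np.asarray(train_labels, dtype=object)
    means, pooled_sd, cm_sd = _class_stats(feats, labels)
    sd = {"pooled": pooled_sd, "class_means": cm_sd}[sd_mode]
    signs = _selection_signs(means, sd, np.array([margin_threshold]))[0]
    sets = {
        cls_: [(int(ch), int(signs[i, ch]))
               for ch in np.flatnonzero(signs[i])]
        for i, cls_ in enumerate(CLASSES)
    }
    return ChannelSets(sets, margin_threshold)


def _scores(features: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Sign-adjusted mean score per (margin, class) for each trial.

    ``features`` (n_trials, n_channels), ``signs`` (n_margins, n_classes,
    n_channels).  Empty sets score -inf.  Returns (n_margins, n_trials,
    n_classes)."""
    counts = np.abs(signs).sum(axis=2)  # (m, cls)
    raw = np.einsum("tc,mkc->mtk", features, signs.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = raw / counts[:, None, :]
    out[np.broadcast_to((counts == 0)[:, None, :], out.shape)] = -np.inf
    return out


_PRECEDENCE_IDX = np.array([CLASSES.index(c) for c in TIE_PRECEDENCE])


def _predict(scores: np.ndarray, majority_idx: int) -> np.ndarray:
    """Argmax with CENTER > RIGHT > LEFT tie precedence; all-empty rows fall
    back to the training-majority class.  ``scores``: (..., n_classes)."""
    reordered = scores[..., _PRECEDENCE_IDX]
    pick = reordered.argmax(axis=-1)
    pred = _PRECEDENCE_IDX[pick]
    all_empty = np.all(np.isneginf(scores), axis=-1)
    pred = np.where(all_empty, majority_idx, pred)
    return pred


def classify_trial(
    test_features: np.ndarray,
    sets: ChannelSets,
    majority: Condition | None = None,
) -> Condition:
    """Classify one normalized trial as the direction whose channel set has
    the highest sign-adjusted mean value.  Ties resolve by the fixed
    precedence center > right > left; if every set is empty the
    training-majority class is returned (logged)."""
    x = np.asarray(test_features, dtype=float).reshape(-1)
    n_ch = x.shape[0]
    signs = np.zeros((1, len(CLASSES), n_ch), dtype=np.int8)
    for i, cls_ in enumerate(CLASSES):
        for ch, sign in sets.channels(cls_):
            signs[0, i, ch] = sign
    scores = _scores(x[None, :], signs)[0, 0]
    if np.all(np.isneginf(scores)):
        fallback = majority if majority is not None else Condition.CENTER
        logger.info("all channel sets empty; predicting majority class %s",
                    fallback.value)
        return fallback
    return CLASSES[int(_predict(scores[None, :],
                                CLASSES.index(majority or Condition.CENTER))[0])]


# ---------------------------------------------------------------------------
# Nested optimization + leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EcogCvResult:
    per_class_tpr: dict[Condition, float]
    confusion: pd.DataFrame          # rows true, columns predicted
    chosen_margins: np.ndarray
    accuracy: float

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.confusion.to_csv(directory / "confusion.tsv", sep="\t")
        pd.DataFrame(
            {
                "class": [c.value for c in self.per_class_tpr],
                "tpr": list(self.per_class_tpr.values()),
            }
        ).to_csv(directory / "per_class_tpr.tsv", sep="\t", index=False)


def default_margin_grid(
    means: np.ndarray, n: int = 50, pctile: float = 95.0
) -> np.ndarray:
    """Evenly spaced margins from 0 to the ``pctile``-th percentile of the
    between-class mean gaps observed on the training data."""
    gaps = []
    for i in range(len(CLASSES)):
        for j in range(i + 1, len(CLASSES)):
            gaps.append(np.abs(means[i] - means[j]))
    hi = float(np.percentile(np.concatenate(gaps), pctile))
    return np.linspace(0.0, hi, n)


def optimize_and_crossvalidate(
    features: np.ndarray,
    labels: np.ndarray,
    margin_grid: np.ndarray | None = None,
    sd_mode: str = "pooled",
) -> EcogCvResult:
    """Leave-one-out evaluation with nested margin optimization.

    Per fold: normalize all trials with the training trials' mean/SD; for
    each candidate margin select channel sets on the training trials and
    classify those same training trials; keep the margin with the most
    training-correct decisions (ties break toward the smallest margin);
    classify the held-out trial with that selection.  Aggregates a confusion
    matrix and per-class TPRs over all folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    n_trials, n_ch = X.shape
    counts = {c: int(label_mask(y, c).sum()) for c in CLASSES}
    if any(v < 2 for v in counts.values()):
        raise ValueError(f"need >= 2 trials per class, got {counts}")
    majority_idx = int(np.argmax([counts[c] for c in CLASSES]))

    total = X.sum(axis=0)
    total_sq = (X * X).sum(axis=0)
    preds = np.empty(n_trials, dtype=int)
    chosen = np.empty(n_trials)
    for i in range(n_trials):
        m = n_trials - 1
        mu = (total - X[i]) / m
        var = (total_sq - X[i] * X[i]) / m - mu * mu
        sd = np.sqrt(np.maximum(var, 0.0))
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd_safe
        train = np.ones(n_trials, dtype=bool)
        train[i] = False
        means, pooled_sd, cm_sd = _class_stats(Z[train], y[train])
        crit_sd = {"pooled": pooled_sd, "class_means": cm_sd}[sd_mode]
        grid = (default_margin_grid(means) if margin_grid is None
                else np.asarray(margin_grid, dtype=float))
        signs = _selection_signs(means, crit_sd, grid)  # (m, cls, ch)
        train_scores = _scores(Z[train], signs)          # (m, n-1, cls)
        train_pred = _predict(train_scores, majority_idx)
        true_idx = np.array([CLASSES.index(c) for c in y[train]])
        n_correct = (train_pred == true_idx[None, :]).sum(axis=1)
        best = int(np.argmax(n_correct))  # first max -> smallest margin
        chosen[i] = grid[best]
        test_scores = _scores(Z[i][None, :], signs[best][None])[0, 0]
        if np.all(np.isneginf(test_scores)):
            preds[i] = majority_idx
        else:
            preds[i] = int(_predict(test_scores[None, :], majority_idx)[0])

    true_idx = np.array([CLASSES.index(c) for c in y])
    n_cls = len(CLASSES)
    conf = np.zeros((n_cls, n_cls), dtype=int)
    np.add.at(conf, (true_idx, preds), 1)
    names = [c.value for c in CLASSES]
    confusion = pd.DataFrame(conf, index=names, columns=names)
    tpr = {
        c: float(conf[k, k] / conf[k].sum()) for k, c in enumerate(CLASSES)
    }
    acc = float((preds == true_idx).mean())
    return EcogCvResult(tpr, confusion, chosen, acc)
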