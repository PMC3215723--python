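"""Performance metrics for the decoded control signal.

Per-scan true/false positive rates after the 3-TR hemodynamic shift (with an
option to exclude center blocks from the FPR denominator, removing BOLD
rebound effects), ROC sweeps over threshold grids, single-time-point 3-way
trial classification, the Wolpaw information transfer rate, and the Dice
overlap used to compare incrementally and batch-derived ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decode import ControlTrace, ThresholdSet
from .synth import Condition, Schedule, label_mask


def _shifted(trace: ControlTrace, shift_trs: int):
    labels, valid = trace.shifted_labels(shift_trs)
    return trace.cs[valid], labels[valid]


def rates(
    trace: ControlTrace,
    thresholds: ThresholdSet,
    shift_trs: int = 3,
    exclude_center: bool = False,
) -> dict[str, float]:
    """Per-scan TPR/FPR for both sides at the first-level thresholds.

    A scan counts right-positive when CS exceeds theta_1 and left-positive
    when CS falls below theta_-1; instruction labels are shifted
    ``shift_trs`` scans later than the control signal (scans whose shifted
    label would precede the run are dropped from all counts).  With
    ``exclude_center``, center scans leave the FPR denominators.
    """
    cs, labels = _shifted(trace, shift_trs)
    th_r, th_l = thresholds.pos[0], thresholds.neg[0]
    out: dict[str, float] = {}
    for side, key in ((Condition.RIGHT, "r"), (Condition.LEFT, "l")):
        positive = cs > th_r if side is Condition.RIGHT else cs < th_l
        is_side = label_mask(labels, side)
        non_side = ~is_side
        if exclude_center:
            non_side &= ~label_mask(labels, Condition.CENTER)
        if not is_side.any():
            raise ValueError(f"no {side.value} scans after shifting")
        if not non_side.any():
            raise ValueError(f"empty FPR denominator for {side.value}")
        out[f"tpr_{key}"] = float(positive[is_side].mean())
        out[f"fpr_{key}"] = float(positive[non_side].mean())
    return out


def roc(
    trace: ControlTrace,
    threshold_grid_r: np.ndarray | None = None,
    threshold_grid_l: np.ndarray | None = None,
    shift_trs: int = 3,
    exclude_center: bool = False,
) -> dict[str, pd.DataFrame]:
    """TPR/FPR swept over threshold grids, one curve per side.

    Defaults follow the offline analysis: thresholds from -1 to 5 for
    right-sided and from 1 to -5 for left-sided attention.
    """
    if threshold_grid_r is None:
        threshold_grid_r = np.linspace(-1.0, 5.0, 61)
    if threshold_grid_l is None:
        threshold_grid_l = np.linspace(1.0, -5.0, 61)
    cs, labels = _shifted(trace, shift_trs)
    curves: dict[str, pd.DataFrame] = {}
    for side, key, grid, direction in (
        (Condition.RIGHT, "r", np.asarray(threshold_grid_r, float), 1),
        (Condition.LEFT, "l", np.asarray(threshold_grid_l, float), -1),
    ):
        is_side = label_mask(labels, side)
        non_side = ~is_side
        if exclude_center:
            non_side &= ~label_mask(labels, Condition.CENTER)
        rows = []
        for th in grid:
            positive = cs > th if direction > 0 else cs < th
            rows.append(
                (float(th), float(positive[non_side].mean()),
                 float(positive[is_side].mean()))
            )
        curves[key] = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    return curves


def classify_scan_3way(cs: float, thresholds: ThresholdSet) -> Condition:
    """Three-way single-scan decision: right beyond theta_1, left beyond
    theta_-1, center otherwise.  (With theta_1 > theta_-1 the two side
    conditions cannot both hold for a scalar CS.)"""
    if cs > thresholds.pos[0]:
        return Condition.RIGHT
    if cs < thresholds.neg[0]:
        return Condition.LEFT
    return Condition.CENTER


def trial_accuracy_by_timepoint(
    trace: ControlTrace,
    schedule: Schedule,
    thresholds: ThresholdSet,
    timepoint: int,
) -> dict[Condition, float]:
    """Classify every trial from the single scan at within-trial position
    ``timepoint`` (1-based, not shifted for the hemodynamic delay) and
    return the fraction of correctly classified trials per condition."""
    if timepoint < 1:
        raise ValueError("timepoint is 1-based")
    start = trace.scan_offset
    stop = start + len(trace.cs)
    correct: dict[Condition, list[bool]] = {c: [] for c in Condition}
    for tr in schedule.trials:
        if tr.onset_scan < start or tr.onset_scan + tr.length_scans > stop:
            continue
        if timepoint > tr.length_scans:
            raise ValueError(
                f"timepoint {timepoint} exceeds trial length {tr.length_scans}"
            )
        scan = tr.onset_scan + timepoint - 1
        pred = classify_scan_3way(float(trace.cs[scan - start]), thresholds)
        correct[tr.condition].append(pred is tr.condition)
    return {
        c: float(np.mean(v)) if v else float("nan") for c, v in correct.items()
    }


def wolpaw_bitrate(
    accuracy: float, n_classes: int, trial_seconds: float
) -> float:
    """Wolpaw information transfer rate in bits per minute.

    bits/trial = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with the
    P in {0, 1} limits taken by continuity, scaled by decisions per minute.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if trial_seconds <= 0:
        raise ValueError("trial_seconds must be positive")
    p, n = float(accuracy), int(n_classes)
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(bits * 60.0 / trial_seconds)


def dice(set_a, set_b) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); 1.0 when both sets are empty
    (documented convention)."""
    a = set(np.asarray(list(set_a)).ravel().tolist()) if not isinstance(set_a, set) else set_a
    b = set(np.asarray(list(set_b)).ravel().tolist()) if not isinstance(set_b, set) else set_b
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


@dataclass
class PerfReport:
    """Flat summary of a scored feedback run."""

    tpr_l: float
    tpr_r: float
    fpr_l: float
    fpr_r: float
    fpr_l_excl_center: float
    fpr_r_excl_center: float
    trial_accuracy_by_timepoint: dict[int, dict[Condition, float]] = field(
        default_factory=dict
    )
    bitrate_bits_per_min: float | None = None
    dice_r: float | None = None
    dice_l: float | None = None

    def to_table(self, path: str | Path) -> None:
        rows: list[tuple[str, float]] = [
            ("tpr_l", self.tpr_l), ("tpr_r", self.tpr_r),
            ("fpr_l", self.fpr_l), ("fpr_r", self.fpr_r),
            ("fpr_l_excl_center", self.fpr_l_excl_center),
            ("fpr_r_excl_center", self.fpr_r_excl_center),
        ]
        for tp in sorted(self.trial_accuracy_by_timepoint):
            for cond, acc in self.trial_accuracy_by_timepoint[tp].items():
                rows.append((f"trial_acc_t{tp}_{cond.value}", acc))
        if self.bitrate_bits_per_min is not None:
            rows.append(("bitrate_bits_per_min", self.bitrate_bits_per_min))
        if self.dice_r is not None:
            rows.append(("dice_r", self.dice_r))
        if self.dice_l is not None:
            rows.append(("dice_l", self.dice_l))
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            path, sep="\t", index=False
        )


def score_feedback_run(
    trace: ControlTrace,
    schedule: Schedule,
    thresholds: ThresholdSet,
    shift_trs: int = 3,
    timepoints: tuple[int, ...] = tuple(range(1, 11)),
) -> PerfReport:
    """Full scoring pass: shifted rates (both FPR variants), per-timepoint
    trial accuracies, and the Wolpaw bit rate of the two-class (left/right)
    5th-time-point decision."""
    base = rates(trace, thresholds, shift_trs, exclude_center=False)
    excl = rates(trace, thresholds, shift_trs, exclude_center=True)
    acc_by_tp: dict[int, dict[Condition, float]] = {}
    max_len = max(t.length_scans for t in schedule.trials)
    for tp in timepoints:
        if tp <= max_len:
            acc_by_tp[tp] = trial_accuracy_by_timepoint(
                trace, schedule, thresholds, tp
            )
    bitrate = None
    if 5 in acc_by_tp:
        # two-class accuracy: center trials excluded, side trials classified
        # left/right by CS sign beyond the nearer threshold
        start, stop = trace.scan_offset, trace.scan_offset + len(trace.cs)
        n_ok = n_all = 0
        trial_len = None
        for tr in schedule.trials:
            if (tr.onset_scan < start or tr.onset_scan + tr.length_scans > stop
                    or not tr.condition.is_attention):
                continue
            trial_len = tr.length_scans
            cs = float(trace.cs[tr.onset_scan + 4 - start])
            pred = (Condition.RIGHT if cs > 0 else Condition.LEFT)
            n_ok += pred is tr.condition
            n_all += 1
        if n_all:
            bitrate = wolpaw_bitrate(
                n_ok / n_all, 2, trial_len * schedule.tr_seconds
            )
    return PerfReport(
        tpr_l=base["tpr_l"], tpr_r=base["tpr_r"],
        fpr_l=base["fpr_l"], fpr_r=base["fpr_r"],
        fpr_l_excl_center=excl["fpr_l"], fpr_r_excl_center=excl["fpr_r"],
        trial_accuracy_by_timepoint=acc_by_tp,
        bitrate_bits_per_min=bitrate,
    )
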