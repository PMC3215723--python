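"""Real-time feedback decoding.

At every feedback scan the pipeline (1) detrends each ROI voxel's full
available time series (localizer plus feedback so far) with a
smoothness-priors detrender, (2) averages the detrended values per ROI,
(3) forms the differential control signal

    CS = 100 (S_R - B_R)/B_R - 100 (S_L - B_L)/B_L ,

percent change of the right-vs-left ROI minus that of the left-vs-right ROI
from their localizer baselines, and (4) classifies CS against a set of
magnitude thresholds to drive the feedback display.  Thresholds are either
the fixed scheme (+-1.5 / +-2.5 / +-4) or estimated adaptively from the
localizer data so the training false-positive rate does not exceed a target
(0.2), with instruction labels shifted 3 TRs for the hemodynamic delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .roi import RoiPair
from .synth import Condition, Schedule, label_mask

logger = logging.getLogger(__name__)

#: Fixed threshold ladder used online for the first subject group.
FIXED_POS = (1.5, 2.5, 4.0)
FIXED_NEG = (-1.5, -2.5, -4.0)

#: Ratios deriving the second and third threshold from the first,
#: reproducing the fixed scheme when theta1 = 1.5.
THRESHOLD_RATIOS = (2.5 / 1.5, 4.0 / 1.5)


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------

def _penalty_system(n: int, lam: float):
    """A = I + lam^2 D2'D2 (D2 = second difference): sparse matrix plus its
    upper banded form for :func:`scipy.linalg.solveh_banded`."""
    from scipy import sparse

    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    a = (sparse.identity(n) + lam * lam * (d2.T @ d2)).tocsr()
    ab = np.zeros((3, n))
    for u in range(3):  # diagonals 0..2 above main
        ab[2 - u, u:] = a.diagonal(u)
    return a, ab


def detrend(series: np.ndarray, lam: float = 500.0) -> np.ndarray:
    """Smoothness-priors detrending.

    The trend is ``(I + lam^2 D2'D2)^{-1} z`` with ``D2`` the second-order
    difference operator; the detrended signal is ``z - trend``.  Constants
    and (as lam grows) linear ramps lie in the trend's null space, and
    ``lam = 0`` returns identically zero (trend = data).  ``series`` may be
    a vector (n,) or a matrix (n, k) detrended column-wise.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    z = np.asarray(series, dtype=float)
    squeeze = z.ndim == 1
    if squeeze:
        z = z[:, None]
    n = z.shape[0]
    if n < 3:
        raise ValueError("series must have length >= 3")
    if lam == 0:
        out = np.zeros_like(z)
        return out[:, 0] if squeeze else out
    # The affine family lies exactly in the null space of D2, so A maps it
    # to itself and the trend absorbs it entirely.  Splitting it off before
    # the banded solve makes that exact in floating point as well (the
    # penalty matrix is stiff for the default lambda): constants and ramps
    # detrend to zero identically, not just to solver precision.
    g = np.column_stack([np.ones(n), np.arange(n) - (n - 1) / 2.0])
    coef, *_ = np.linalg.lstsq(g, z, rcond=None)
    resid = z - g @ coef
    a, ab = _penalty_system(n, lam)
    trend = solveh_banded(ab, resid)
    trend += solveh_banded(ab, resid - a @ trend)  # iterative refinement
    out = resid - trend
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Control signal
# ---------------------------------------------------------------------------

def control_signal(
    s_r: np.ndarray | float,
    s_l: np.ndarray | float,
    baseline_r: float,
    baseline_l: float,
    normalize_sd: bool = False,
    sd_r: float | None = None,
    sd_l: float | None = None,
) -> np.ndarray | float:
    """Differential percent-signal-change control signal.

    With ``normalize_sd`` each percentage term is additionally divided by its
    localizer-derived standard deviation before subtraction, yielding a more
    laterally symmetric signal when the two ROIs respond with unequal
    strength.
    """
    if baseline_r <= 0 or baseline_l <= 0:
        raise ValueError("baselines must be positive")
    pct_r = 100.0 * (np.asarray(s_r, float) - baseline_r) / baseline_r
    pct_l = 100.0 * (np.asarray(s_l, float) - baseline_l) / baseline_l
    if normalize_sd:
        if sd_r is None or sd_l is None or sd_r <= 0 or sd_l <= 0:
            raise ValueError("normalize_sd requires positive sd_r and sd_l")
        pct_r = pct_r / sd_r
        pct_l = pct_l / sd_l
    return pct_r - pct_l


# ---------------------------------------------------------------------------
# Thresholds and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Three ascending positive-side and three descending negative-side
    thresholds.  Ordering is enforced strictly; signs are not, because an
    adaptive estimate on a laterally biased control signal can legitimately
    cross zero (as observed in practice)."""

    pos: tuple[float, float, float] = FIXED_POS
    neg: tuple[float, float, float] = FIXED_NEG

    def __post_init__(self) -> None:
        if not (self.pos[0] < self.pos[1] < self.pos[2]):
            raise ValueError("positive thresholds must be strictly ascending")
        if not (self.neg[0] > self.neg[1] > self.neg[2]):
            raise ValueError("negative thresholds must be strictly descending")
        if not self.pos[0] >= self.neg[0]:
            raise ValueError("theta_1 must not fall below theta_-1")

    @classmethod
    def fixed(cls) -> "ThresholdSet":
        return cls(FIXED_POS, FIXED_NEG)

    @classmethod
    def from_theta1(cls, theta1_pos: float, theta1_neg: float) -> "ThresholdSet":
        """Derive the full ladder from the two first-level thresholds using
        the fixed-scheme ratios (2.5/1.5 and 4/1.5).  If a first-level
        threshold has crossed zero, the higher rungs are offset using the
        opposite side's magnitude so ordering still holds."""
        r2, r3 = THRESHOLD_RATIOS
        if theta1_pos > 0:
            pos = (theta1_pos, theta1_pos * r2, theta1_pos * r3)
        else:
            scale = abs(theta1_neg) if theta1_neg < 0 else 1.0
            pos = (theta1_pos, theta1_pos + (r2 - 1) * scale,
                   theta1_pos + (r3 - 1) * scale)
        if theta1_neg < 0:
            neg = (theta1_neg, theta1_neg * r2, theta1_neg * r3)
        else:
            scale = theta1_pos if theta1_pos > 0 else 1.0
            neg = (theta1_neg, theta1_neg - (r2 - 1) * scale,
                   theta1_neg - (r3 - 1) * scale)
        return cls(pos, neg)


class FeedbackState(str, Enum):
    STRONG_R = "strong_r"
    WEAK_R = "weak_r"
    OFF = "off"
    WEAK_L = "weak_l"
    STRONG_L = "strong_l"

    @property
    def side(self) -> Condition | None:
        if self in (FeedbackState.STRONG_R, FeedbackState.WEAK_R):
            return Condition.RIGHT
        if self in (FeedbackState.STRONG_L, FeedbackState.WEAK_L):
            return Condition.LEFT
        return None


def classify(
    cs: float,
    condition_context: Condition,
    instructed_side: Condition | None,
    thresholds: ThresholdSet,
) -> tuple[FeedbackState, str]:
    """Magnitude-banded feedback state and display color.

    Beyond the second threshold = strong, between first and second = weak,
    inside (theta_-1, theta_1) = off.  Green tones mark a state matching the
    instruction (or near-baseline during center attention), red tones the
    wrong or absent direction; the tone follows the band.
    """
    p, n = thresholds.pos, thresholds.neg
    if cs > p[1]:
        state = FeedbackState.STRONG_R
    elif cs > p[0]:
        state = FeedbackState.WEAK_R
    elif cs < n[1]:
        state = FeedbackState.STRONG_L
    elif cs < n[0]:
        state = FeedbackState.WEAK_L
    else:
        state = FeedbackState.OFF
    if condition_context is Condition.CENTER:
        correct = state is FeedbackState.OFF
    else:
        correct = state.side is instructed_side
    tone = "strong" if state in (FeedbackState.STRONG_R,
                                 FeedbackState.STRONG_L) else "weak"
    return state, f"{'green' if correct else 'red'}_{tone}"


def adaptive_thresholds(
    localizer_cs: np.ndarray,
    schedule: Schedule,
    target_fpr: float = 0.2,
    shift_trs: int = 3,
) -> ThresholdSet:
    """Estimate first-level thresholds from the retrospective localizer CS.

    With instruction labels shifted ``shift_trs`` scans (hemodynamic delay),
    the right-side threshold is the smallest observed CS value such that the
    fraction of non-right (left or center) scans exceeding it is at most
    ``target_fpr``; the left side is mirrored (largest value such that the
    fraction of non-left scans below it meets the target).  Because the
    empirical FPR is a step function with steps only at observed values, the
    search over observed CS values is exact.  Second and third levels follow
    the fixed-scheme ratios.
    """
    if not 0 <= target_fpr <= 1:
        raise ValueError("target_fpr must be in [0, 1]")
    cs = np.asarray(localizer_cs, dtype=float)
    labels = schedule.labels()[: len(cs)]
    if len(labels) < len(cs):
        raise ValueError("schedule shorter than control-signal trace")
    if shift_trs >= len(cs):
        raise ValueError("shift exceeds trace length")
    cs_v = cs[shift_trs:]
    lab_v = labels[: len(cs) - shift_trs]

    cands = np.unique(cs_v)
    is_r = label_mask(lab_v, Condition.RIGHT)
    is_l = label_mask(lab_v, Condition.LEFT)

    non_r = np.sort(cs_v[~is_r])
    if non_r.size == 0:
        raise ValueError("no non-right scans for FPR estimation")
    fpr_r = (non_r.size - np.searchsorted(non_r, cands, side="right")) / non_r.size
    ok = np.flatnonzero(fpr_r <= target_fpr)
    theta1_pos = float(cands[ok[0]])  # smallest qualifying candidate

    non_l = np.sort(cs_v[~is_l])
    if non_l.size == 0:
        raise ValueError("no non-left scans for FPR estimation")
    fpr_l = np.searchsorted(non_l, cands, side="left") / non_l.size
    ok = np.flatnonzero(fpr_l <= target_fpr)
    theta1_neg = float(cands[ok[-1]])  # largest qualifying candidate
    # degenerate targets (near 1) can invert the pair; keep bands ordered
    theta1_neg = min(theta1_neg, theta1_pos)

    # by-construction check: the training FPR meets the target
    got_r = float(np.mean(cs_v[~is_r] > theta1_pos))
    got_l = float(np.mean(cs_v[~is_l] < theta1_neg))
    if got_r > target_fpr or got_l > target_fpr:  # pragma: no cover
        raise RuntimeError("estimated thresholds violate the FPR target")
    logger.info("adaptive thresholds: theta1=%.3f (FPR %.3f), "
                "theta-1=%.3f (FPR %.3f)", theta1_pos, got_r, theta1_neg, got_l)
    return ThresholdSet.from_theta1(theta1_pos, theta1_neg)


# ---------------------------------------------------------------------------
# Traces and the feedback loop
# ---------------------------------------------------------------------------

@dataclass
class ControlTrace:
    """Per-scan control signal with its run context.

    ``cs[i]`` belongs to absolute scan ``scan_offset + i`` of the run whose
    full per-scan labels are ``run_labels``; keeping the whole run's labels
    lets the 3-TR shift reach back into the localizer part for the first
    feedback scans."""

    cs: np.ndarray
    scan_offset: int
    run_labels: np.ndarray
    states: list[FeedbackState] | None = None
    colors: list[str] | None = None

    def __post_init__(self) -> None:
        self.cs = np.asarray(self.cs, dtype=float)
        end = self.scan_offset + len(self.cs)
        if end > len(self.run_labels):
            raise ValueError("trace extends past run labels")

    @property
    def labels(self) -> np.ndarray:
        return self.run_labels[self.scan_offset:
                               self.scan_offset + len(self.cs)]

    def shifted_labels(self, shift_trs: int) -> tuple[np.ndarray, np.ndarray]:
        """Instruction labels shifted ``shift_trs`` scans later relative to
        the CS, plus a validity mask (False where the shift reaches before
        the run start)."""
        n = len(self.cs)
        idx = self.scan_offset + np.arange(n) - shift_trs
        valid = idx >= 0
        out = np.empty(n, dtype=object)
        out[valid] = self.run_labels[idx[valid]]
        return out, valid

    def to_table(self, path: str | Path, shift_trs: int = 3) -> None:
        shifted, valid = self.shifted_labels(shift_trs)
        df = pd.DataFrame(
            {
                "scan": self.scan_offset + np.arange(len(self.cs)),
                "cs": self.cs,
                "condition": [c.value for c in self.labels],
                "shifted_condition": [
                    s.value if v else "" for s, v in zip(shifted, valid)
                ],
                "state": [s.value for s in self.states] if self.states
                else [""] * len(self.cs),
                "color": self.colors if self.colors else [""] * len(self.cs),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def localizer_cs_trace(
    pair: RoiPair,
    lam: float = 500.0,
    normalize_sd: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Retrospective control signal over the localizer scans.

    The stored per-voxel localizer series are detrended, averaged per ROI
    and passed through the control-signal formula.  Returns the trace plus
    the localizer-derived standard deviations of the two percentage terms
    (used by the SD-normalized CS variant).
    """
    if pair.series_r is None or pair.baseline_r is None:
        raise ValueError("RoiPair needs baselines and stored series")
    s_r = detrend(pair.series_r, lam).mean(axis=1) + pair.baseline_r
    s_l = detrend(pair.series_l, lam).mean(axis=1) + pair.baseline_l
    pct_r = 100.0 * (s_r - pair.baseline_r) / pair.baseline_r
    pct_l = 100.0 * (s_l - pair.baseline_l) / pair.baseline_l
    sd_r = float(pct_r.std(ddof=1))
    sd_l = float(pct_l.std(ddof=1))
    if normalize_sd:
        cs = pct_r / sd_r - pct_l / sd_l
    else:
        cs = pct_r - pct_l
    return cs, sd_r, sd_l


def feedback_loop(
    series: np.ndarray,
    pair: RoiPair,
    schedule: Schedule,
    n_localizer: int,
    thresholds: ThresholdSet,
    lam: float = 500.0,
    normalize_sd: bool = False,
    sd_r: float | None = None,
    sd_l: float | None = None,
    window_scans: int | None = None,
) -> ControlTrace:
    """Causal feedback pass over the scans after the localizer.

    At each feedback scan the full available per-voxel series (localizer +
    feedback so far) is re-detrended — the reference path, matching the
    accumulate-and-detrend online design; ``window_scans`` switches to a
    cheaper sliding-window detrend over only the most recent scans.  The
    detrended ROI means are offset by the stored baselines before the
    percent-change formula, so the baseline subtraction acts on the same
    scale as during the localizer.
    """
    data = series.reshape(series.shape[0], -1)
    n_total = data.shape[0]
    labels = schedule.labels()
    if n_total > len(labels):
        raise ValueError("series longer than schedule")
    vox = np.concatenate([pair.roi_r, pair.roi_l])
    n_r = pair.roi_r.size
    cs_out = np.empty(n_total - n_localizer)
    states: list[FeedbackState] = []
    colors: list[str] = []
    for n in range(n_localizer, n_total):
        start = 0 if window_scans is None else max(0, n + 1 - window_scans)
        seg = data[start : n + 1, :][:, vox]
        det = detrend(seg, lam)
        s_r = det[-1, :n_r].mean() + pair.baseline_r
        s_l = det[-1, n_r:].mean() + pair.baseline_l
        cs = float(
            control_signal(s_r, s_l, pair.baseline_r, pair.baseline_l,
                           normalize_sd, sd_r, sd_l)
        )
        cs_out[n - n_localizer] = cs
        cond = labels[n]
        state, color = classify(
            cs, Condition.CENTER if cond is Condition.CENTER else cond,
            cond if cond.is_attention else None, thresholds)
        states.append(state)
        colors.append(color)
    return ControlTrace(cs_out, n_localizer, labels, states, colors)
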