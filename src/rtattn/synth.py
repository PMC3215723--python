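"""Synthetic experiment generation.

Everything downstream of this module (realignment, incremental GLM, ROI
selection, feedback decoding, scoring, ECoG classification) is exercised on
data produced here, with known ground truth.  Three generators are provided:

* :func:`make_schedule` — pseudo-random block schedules for the three-condition
  covert-attention task (attend left / right / center), under the constraint
  that no two adjacent attention trials share a direction.
* :func:`simulate_bold` — 4D BOLD phantoms: condition-locked responses
  convolved with a canonical double-gamma HRF, planted contralateral
  activations and ipsilateral occipital-pole deactivations, slow drift,
  Gaussian noise and optional rigid-body motion.
* :func:`simulate_ecog` — trial x channel gamma-band-power feature sets with
  class-dependent mean shifts on known channel subsets.

All randomness flows through explicit integer seeds; there is no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class Condition(str, Enum):
    """Trial condition: direction of covert attention."""

    LEFT = "left"
    RIGHT = "right"
    CENTER = "center"

    @property
    def is_attention(self) -> bool:
        return self in (Condition.LEFT, Condition.RIGHT)


#: Canonical class ordering used throughout (confusion matrices, ECoG scores).
CLASSES = (Condition.LEFT, Condition.RIGHT, Condition.CENTER)


def label_mask(labels: np.ndarray, condition: Condition) -> np.ndarray:
    """Boolean mask of entries equal to ``condition``.

    Enum members are singletons, so identity comparison is exact; a plain
    numpy ``==`` against a str-backed Enum scalar is unreliable (numpy
    coerces the scalar through ``str()``).
    """
    return np.fromiter((l is condition for l in labels), bool, count=len(labels))

#: Repetition time of the emulated EPI sequence, seconds.
DEFAULT_TR_S = 1.62


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    condition: Condition
    onset_scan: int
    length_scans: int


@dataclass
class Schedule:
    """Ordered block design tiling a run contiguously.

    Invariants (checked by :meth:`validate`): blocks tile the run with no
    gaps or overlaps, and no two adjacent attention (left/right) trials share
    the same direction.
    """

    trials: list[Trial]
    tr_seconds: float = DEFAULT_TR_S

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_scans_total(self) -> int:
        last = self.trials[-1]
        return last.onset_scan + last.length_scans

    def validate(self) -> None:
        if not self.trials:
            raise ValueError("schedule has no trials")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        expected_onset = self.trials[0].onset_scan
        if expected_onset != 0:
            raise ValueError("first trial must start at scan 0")
        prev: Trial | None = None
        for tr in self.trials:
            if tr.length_scans < 1:
                raise ValueError("trial length must be >= 1 scan")
            if tr.onset_scan != expected_onset:
                raise ValueError("trial blocks must tile the run contiguously")
            expected_onset += tr.length_scans
            if (
                prev is not None
                and prev.condition.is_attention
                and tr.condition is prev.condition
            ):
                raise ValueError(
                    "adjacent attention trials share direction "
                    f"({tr.condition.value} at scan {tr.onset_scan})"
                )
            prev = tr

    def labels(self) -> np.ndarray:
        """Per-scan condition labels, shape (n_scans_total,), dtype object."""
        out = np.empty(self.n_scans_total, dtype=object)
        for tr in self.trials:
            out[tr.onset_scan : tr.onset_scan + tr.length_scans] = tr.condition
        return out

    def boxcar(self, condition: Condition) -> np.ndarray:
        """0/1 indicator of ``condition`` per scan."""
        return label_mask(self.labels(), condition).astype(float)

    def concat(self, other: "Schedule") -> "Schedule":
        """Append ``other`` after this schedule (single continuous run)."""
        offset = self.n_scans_total
        shifted = [
            Trial(t.condition, t.onset_scan + offset, t.length_scans)
            for t in other.trials
        ]
        return Schedule(self.trials + shifted, self.tr_seconds)

    # -- serialization ------------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "condition": [t.condition.value for t in self.trials],
                "onset_scan": [t.onset_scan for t in self.trials],
                "length_scans": [t.length_scans for t in self.trials],
            }
        )
        df.attrs["tr_seconds"] = self.tr_seconds
        with open(path, "w") as fh:
            fh.write(f"# tr_seconds={self.tr_seconds}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "Schedule":
        with open(path) as fh:
            header = fh.readline()
            tr_seconds = DEFAULT_TR_S
            if header.startswith("# tr_seconds="):
                tr_seconds = float(header.split("=", 1)[1])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        trials = [
            Trial(Condition(row.condition), int(row.onset_scan), int(row.length_scans))
            for row in df.itertuples()
        ]
        return cls(trials, tr_seconds)


def make_schedule(
    n_per_condition: int,
    trial_len_scans: int,
    seed: int = 0,
    extra_initial_center: bool = False,
    tr_seconds: float = DEFAULT_TR_S,
    max_tries: int = 100_000,
) -> Schedule:
    """Draw a pseudo-random constraint-satisfying block schedule.

    ``n_per_condition`` trials of each condition are shuffled until no two
    adjacent attention trials share a direction (rejection sampling; the
    acceptance probability is large for the design sizes used here).  With
    ``extra_initial_center`` an additional center trial is prepended, giving
    the localizer composition of 8+8+9 trials.

    Parameters
    ----------
    n_per_condition : trials per condition (>= 1).
    trial_len_scans : scans per trial block.
    seed : RNG seed; the draw is reproducible for a fixed seed.
    extra_initial_center : prepend one extra center-attention trial.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if trial_len_scans < 1:
        raise ValueError("trial_len_scans must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = (
        [Condition.LEFT] * n_per_condition
        + [Condition.RIGHT] * n_per_condition
        + [Condition.CENTER] * n_per_condition
    )
    order = np.array(conditions, dtype=object)
    for _ in range(max_tries):
        rng.shuffle(order)
        ok = all(
            not (order[i].is_attention and order[i + 1] is order[i])
            for i in range(len(order) - 1)
        )
        if ok:
            seq = list(order)
            if extra_initial_center:
                seq = [Condition.CENTER] + seq
            trials = [
                Trial(c, i * trial_len_scans, trial_len_scans)
                for i, c in enumerate(seq)
            ]
            return Schedule(trials, tr_seconds)
    raise RuntimeError(
        "could not draw a constraint-satisfying schedule "
        f"in {max_tries} tries (n_per_condition={n_per_condition})"
    )


def localizer_schedule(seed: int = 0, tr_seconds: float = DEFAULT_TR_S) -> Schedule:
    """Default localizer: 8 trials/condition + 1 initial center, 8 scans each
    (200 scans total)."""
    return make_schedule(8, 8, seed=seed, extra_initial_center=True,
                         tr_seconds=tr_seconds)


def feedback_schedule(seed: int = 0, tr_seconds: float = DEFAULT_TR_S) -> Schedule:
    """Default feedback part: 10 trials/condition, 10 scans each (300 scans)."""
    return make_schedule(10, 10, seed=seed, extra_initial_center=False,
                         tr_seconds=tr_seconds)


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t_seconds: np.ndarray,
    peak_s: float = 5.0,
    undershoot_s: float = 15.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Difference of two gamma densities with modes at ``peak_s`` and
    ``undershoot_s`` (shape-1 = mode for unit scale), the undershoot scaled by
    ``undershoot_ratio``.  The 5 s peak matches the 3-TR (4.86 s) hemodynamic
    delay compensation used by the decoder.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t_seconds, dtype=float)
    h = gamma_dist.pdf(t, peak_s + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_s + 1.0
    )
    h = np.where(t < 0, 0.0, h)
    m = h.max()
    return h / m if m > 0 else h


def condition_regressor(
    schedule: Schedule,
    condition: Condition,
    convolve: bool = True,
    n_scans: int | None = None,
) -> np.ndarray:
    """Per-scan task regressor: boxcar of ``condition``, optionally convolved
    with the canonical HRF and rescaled to unit peak (so a planted effect
    amplitude maps one-to-one onto the fitted coefficient)."""
    box = schedule.boxcar(condition)
    if n_scans is not None:
        box = box[:n_scans] if len(box) >= n_scans else np.pad(
            box, (0, n_scans - len(box))
        )
    if not convolve:
        return box
    t = np.arange(0, 32.0, schedule.tr_seconds)
    h = double_gamma_hrf(t)
    reg = np.convolve(box, h)[: len(box)]
    m = reg.max()
    return reg / m if m > 0 else reg


# ---------------------------------------------------------------------------
# BOLD phantoms
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """A 4D BOLD series: ``data`` indexed (scan, x, y, z).

    ``slice_axis`` identifies the coronal (posterior->anterior) direction of
    the grid; ``anterior_high`` says whether increasing index along that axis
    moves anteriorly.  Synthetic data declares this explicitly rather than
    relying on a NIfTI affine.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.848, 2.0, 1.848)
    slice_axis: int = 1
    anterior_high: bool = True

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (scan, x, y, z)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def mean_volume(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def to_nifti(self, path: str | Path) -> None:
        # NIfTI stores (x, y, z, t)
        arr = np.moveaxis(self.data, 0, -1).astype(np.float32)
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(arr, aff)
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls, path: str | Path, slice_axis: int = 1, anterior_high: bool = True
    ) -> "VolumeSeries":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError(f"{path} is not a 4D image")
        data = np.moveaxis(arr, -1, 0)
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.ascontiguousarray(data), vs, slice_axis, anterior_high)


def _sphere_indices(
    shape: Sequence[int], center: Sequence[float], radius: float
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.flatnonzero((d2 <= radius**2).ravel())


def _ellipsoid_mask(shape: Sequence[int], semi_frac: float = 0.45) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    semi = [semi_frac * s for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


@dataclass
class PhantomSpec:
    """Ground-truth layout and noise model of a synthetic BOLD run.

    Attention to one side activates the contralateral truth set
    (``roi_truth_right`` responds to RIGHT attention) and deactivates the
    ipsilateral occipital-pole set (``deact_right`` responds to LEFT attention
    with the nonpositive ``deact_pct``), emulating the
    activation/deactivation pattern of covert visuospatial attention.

    ``noise_sd`` and drift amplitudes are fractions of the local baseline;
    the default noise (1.5% of baseline, i.e. temporal SNR ~ 67) is typical
    of high-field EPI, where a 2% single-trial effect is detectable.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    roi_truth_left: np.ndarray | None = None
    roi_truth_right: np.ndarray | None = None
    deact_left: np.ndarray | None = None
    deact_right: np.ndarray | None = None
    effect_pct: float = 2.0
    deact_pct: float = -1.0
    drift_pct_per_min: float = 0.3
    drift_cosine_pct: float = 0.1
    drift_cosine_period_s: float = 300.0
    drift_spatial_jitter: float = 0.5
    noise_sd: float = 0.015
    baseline: float = 1000.0
    motion_series: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        nvox = int(np.prod(self.grid_shape))
        if self.roi_truth_right is None:
            self._default_geometry()
        for name in ("roi_truth_left", "roi_truth_right", "deact_left",
                     "deact_right"):
            idx = np.asarray(getattr(self, name), dtype=np.intp).ravel()
            if idx.size and (idx.min() < 0 or idx.max() >= nvox):
                raise ValueError(f"{name} indices outside grid")
            setattr(self, name, idx)
        truth = np.concatenate([self.roi_truth_left, self.roi_truth_right])
        deact = np.concatenate([self.deact_left, self.deact_right])
        if np.intersect1d(truth, deact).size:
            raise ValueError("truth and deactivation sets must be disjoint")
        if self.effect_pct <= 0:
            raise ValueError("effect_pct must be positive")
        if self.deact_pct > 0:
            raise ValueError("deact_pct must be nonpositive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for v in (self.effect_pct, self.deact_pct, self.drift_pct_per_min,
                  self.noise_sd, self.baseline):
            if not np.isfinite(v):
                raise ValueError("phantom parameters must be finite")

    def _default_geometry(self) -> None:
        """Plant bilateral posterior activation blobs plus small ipsilateral
        pole deactivation blobs, all inside the brain ellipsoid and clear of
        the two most anterior coronal slices."""
        nx, ny, nz = self.grid_shape
        r_act = max(2.0, 0.09 * nx)
        r_deact = max(1.5, 0.06 * nx)
        zmid = (nz - 1) / 2.0
        # x is left-right; attention to RIGHT activates the left hemisphere.
        self.roi_truth_right = _sphere_indices(
            self.grid_shape, (0.25 * nx, 0.40 * ny, zmid), r_act)
        self.roi_truth_left = _sphere_indices(
            self.grid_shape, (0.75 * nx, 0.40 * ny, zmid), r_act)
        # occipital-pole (posterior, low y) deactivations, ipsilateral side;
        # on very small grids the spheres can touch, so clip to keep the
        # truth/deactivation disjointness invariant
        truth = np.concatenate([self.roi_truth_left, self.roi_truth_right])
        self.deact_right = np.setdiff1d(_sphere_indices(
            self.grid_shape, (0.68 * nx, 0.18 * ny, zmid), r_deact), truth)
        self.deact_left = np.setdiff1d(_sphere_indices(
            self.grid_shape, (0.32 * nx, 0.18 * ny, zmid), r_deact), truth)

    def brain_mask(self) -> np.ndarray:
        return _ellipsoid_mask(self.grid_shape)


def simulate_bold(spec: PhantomSpec, schedule: Schedule) -> VolumeSeries:
    """Simulate a 4D BOLD run for ``schedule`` under ``spec``.

    Voxel model (fractions of the voxel baseline)::

        y(t) = B * (1 + drift(t) + effect * x_cond(t) + noise_sd * eps(t))

    where ``x_cond`` is the HRF-convolved boxcar of the condition driving the
    voxel (unit peak), drift is linear plus a slow cosine with a per-voxel
    slope jitter, and ``eps`` is unit white Gaussian noise.  Background
    (non-brain) voxels sit at 2% of the brain baseline.  Optional rigid-body
    motion is applied per scan after signal generation.
    """
    rng = np.random.default_rng(spec.seed)
    n = schedule.n_scans_total
    shape = spec.grid_shape
    nvox = int(np.prod(shape))

    reg_r = condition_regressor(schedule, Condition.RIGHT)
    reg_l = condition_regressor(schedule, Condition.LEFT)

    t_min = np.arange(n) * schedule.tr_seconds / 60.0
    drift = (spec.drift_pct_per_min / 100.0) * t_min
    if spec.drift_cosine_pct:
        drift = drift + (spec.drift_cosine_pct / 100.0) * np.cos(
            2 * np.pi * np.arange(n) * schedule.tr_seconds
            / spec.drift_cosine_period_s
        )

    brain = spec.brain_mask().ravel()
    base = np.where(brain, spec.baseline, 0.02 * spec.baseline)

    frac = np.zeros((n, nvox))
    slope_jitter = 1.0 + spec.drift_spatial_jitter * rng.standard_normal(nvox)
    frac += drift[:, None] * slope_jitter[None, :]
    amp = spec.effect_pct / 100.0
    damp = spec.deact_pct / 100.0
    frac[:, spec.roi_truth_right] += amp * reg_r[:, None]
    frac[:, spec.roi_truth_left] += amp * reg_l[:, None]
    frac[:, spec.deact_right] += damp * reg_l[:, None]
    frac[:, spec.deact_left] += damp * reg_r[:, None]
    if spec.noise_sd > 0:
        frac += spec.noise_sd * rng.standard_normal((n, nvox))

    data = (base[None, :] * (1.0 + frac)).reshape((n,) + tuple(shape))

    if spec.motion_series is not None:
        from .realign import RigidTransform, apply_transform

        motion = np.asarray(spec.motion_series, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError("motion_series must have shape (n_scans, 6)")
        for i in range(n):
            t = RigidTransform(rotations=motion[i, :3],
                               translations=motion[i, 3:])
            data[i] = apply_transform(data[i], t, interpolation="linear")

    return VolumeSeries(data)


def simulate_cs_trace(
    schedule: Schedule,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    bias: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic differential control-signal trace (percent units).

    The noiseless trace is ``effect * (x_R(t) - x_L(t)) + bias`` with
    HRF-convolved unit-peak regressors — the shape the ROI-difference signal
    takes when both sides respond symmetrically.  ``noise_sd`` ~ 0.5% matches
    the scan-to-scan variability of ROI-averaged high-field data.
    """
    rng = np.random.default_rng(seed)
    cs = effect * (
        condition_regressor(schedule, Condition.RIGHT)
        - condition_regressor(schedule, Condition.LEFT)
    ) + bias
    if noise_sd > 0:
        cs = cs + noise_sd * rng.standard_normal(len(cs))
    return cs


# ---------------------------------------------------------------------------
# ECoG feature sets
# ---------------------------------------------------------------------------

@dataclass
class EcogTrialSet:
    """Per-trial, per-channel gamma-band-power features with class labels."""

    features: np.ndarray  # (n_trials, n_channels)
    labels: np.ndarray    # (n_trials,) of Condition
    fs_hz: float = 512.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError("features must be 2D (trials x channels)")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("one label per trial required")
        for lab in self.labels:
            if not isinstance(lab, Condition):
                raise ValueError(f"label {lab!r} is not a Condition")

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.features,
            columns=[f"ch{i:02d}" for i in range(self.n_channels)],
        )
        df.insert(0, "label", [c.value for c in self.labels])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path: str | Path, fs_hz: float = 512.0) -> "EcogTrialSet":
        df = pd.read_csv(path, sep="\t")
        labels = np.array([Condition(v) for v in df.pop("label")], dtype=object)
        return cls(df.to_numpy(float), labels, fs_hz)


def default_ecog_channel_map(shift: float = 1.0) -> dict[Condition, dict[int, float]]:
    """Default ground-truth map: a handful of channels per direction with
    mean shifts of +-``shift`` (activation and one deactivation each for the
    lateral classes), the rest uninformative."""
    return {
        Condition.RIGHT: {0: shift, 1: shift, 2: shift, 3: shift, 5: -shift},
        Condition.LEFT: {8: shift, 9: shift, 10: shift, 11: shift, 13: -shift},
        Condition.CENTER: {16: shift, 17: shift, 18: shift, 19: shift},
    }


def simulate_ecog(
    n_channels: int = 64,
    class_channel_map: Mapping[Condition, Mapping[int, float]] | None = None,
    n_per_class: Mapping[Condition, int] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EcogTrialSet:
    """Simulate band-power features: trial composition 20 left / 20 right /
    39 center by default; features ~ Normal(class-dependent mean, 1) per
    channel, means nonzero only on the mapped channel subsets.
    ``noise_sd = 0`` gives the noiseless (perfectly separable) limit."""
    if class_channel_map is None:
        class_channel_map = default_ecog_channel_map()
    if n_per_class is None:
        n_per_class = {Condition.LEFT: 20, Condition.RIGHT: 20,
                       Condition.CENTER: 39}
    n_trials = sum(n_per_class.values())
    if n_trials == 0:
        raise ValueError("empty trial composition")
    for cls_, chmap in class_channel_map.items():
        for ch in chmap:
            if not 0 <= ch < n_channels:
                raise ValueError(f"channel {ch} outside range for {cls_}")
    rng = np.random.default_rng(seed)
    labels = np.array(
        [c for c, k in n_per_class.items() for _ in range(k)], dtype=object
    )
    rng.shuffle(labels)
    means = np.zeros((n_trials, n_channels))
    for cls_, chmap in class_channel_map.items():
        rows = np.flatnonzero(label_mask(labels, cls_))
        for ch, shift in chmap.items():
            means[rows, ch] = shift
    features = means + noise_sd * rng.standard_normal((n_trials, n_channels))
    return EcogTrialSet(features, labels)
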