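"""Brain masking, ROI selection and baseline computation.

After the localizer (200 scans) the two differential t-maps are reduced to
two voxel sets: per map, restrict to a brain mask, keep the 500 highest
t-values, and drop connected clusters smaller than five voxels
(6-connectivity, i.e. face-adjacent).  The brain mask is a smoothed,
thresholded, hole-filled mean volume with the two most anterior coronal
slices removed (registration boundary artifacts).  Each ROI then gets a
baseline: the ROI-averaged signal over center-condition scans, excluding the
first three scans (4.86 s) of any center trial preceded by an attention
trial so the BOLD response can return to baseline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .iglm import TMap
from .synth import Condition, Schedule, VolumeSeries

logger = logging.getLogger(__name__)


@dataclass
class BrainMask:
    """Boolean include-grid with its coronal-axis annotation."""

    include: np.ndarray
    slice_axis: int = 1
    anterior_high: bool = True

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


def make_mask(
    mean_volume: np.ndarray,
    blur_sigma: float = 2.0,
    threshold: float | None = None,
    slice_axis: int = 1,
    anterior_high: bool = True,
    n_anterior_exclude: int = 2,
) -> BrainMask:
    """Brain mask: smooth, threshold, fill holes, drop anterior slices.

    ``threshold`` is an absolute intensity cut on the smoothed volume; if
    ``None`` it defaults to 30% of the smoothed volume's 98th percentile.
    Raises if the resulting mask is empty.
    """
    vol = np.asarray(mean_volume, dtype=float)
    if not np.all(np.isfinite(vol)):
        raise ValueError("mean volume must be finite")
    sm = ndimage.gaussian_filter(vol, blur_sigma) if blur_sigma > 0 else vol
    if threshold is None:
        threshold = 0.3 * np.percentile(sm, 98)
    mask = sm > threshold
    mask = ndimage.binary_fill_holes(mask)
    if n_anterior_exclude > 0:
        sl = [slice(None)] * vol.ndim
        if anterior_high:
            sl[slice_axis] = slice(vol.shape[slice_axis] - n_anterior_exclude,
                                   None)
        else:
            sl[slice_axis] = slice(0, n_anterior_exclude)
        mask[tuple(sl)] = False
    if not mask.any():
        raise ValueError("brain mask is empty")
    return BrainMask(mask, slice_axis, anterior_high)


@dataclass
class RoiPair:
    """The two differential-contrast ROIs and their feedback-time context.

    ``roi_r``/``roi_l`` are sorted linear voxel indices of the right-vs-left
    and left-vs-right ROIs; ``threshold_t_*`` records the t-value at the
    500-voxel cut (before cluster filtering).  ``baseline_*`` and the stored
    per-voxel localizer series are filled by :func:`compute_baselines`.
    """

    roi_r: np.ndarray
    roi_l: np.ndarray
    grid_shape: tuple[int, ...]
    threshold_t_r: float
    threshold_t_l: float
    baseline_r: float | None = None
    baseline_l: float | None = None
    series_r: np.ndarray | None = None  # (n_scans, |roi_r|)
    series_l: np.ndarray | None = None

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        mr = np.zeros(self.grid_shape, dtype=bool)
        ml = np.zeros(self.grid_shape, dtype=bool)
        mr.ravel()[self.roi_r] = True
        ml.ravel()[self.roi_l] = True
        return mr, ml

    def save(self, directory: str | Path,
             voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
             ) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = np.diag(list(voxel_size_mm) + [1.0])
        mr, ml = self.masks()
        nib.save(nib.Nifti1Image(mr.astype(np.uint8), aff),
                 str(directory / "roi_r.nii"))
        nib.save(nib.Nifti1Image(ml.astype(np.uint8), aff),
                 str(directory / "roi_l.nii"))
        meta = {
            "grid_shape": list(self.grid_shape),
            "threshold_t_r": self.threshold_t_r,
            "threshold_t_l": self.threshold_t_l,
            "baseline_r": self.baseline_r,
            "baseline_l": self.baseline_l,
        }
        (directory / "roi_meta.json").write_text(json.dumps(meta, indent=2))
        if self.series_r is not None:
            np.savetxt(directory / "series_r.tsv", self.series_r,
                       delimiter="\t")
        if self.series_l is not None:
            np.savetxt(directory / "series_l.tsv", self.series_l,
                       delimiter="\t")


def _top_k_then_cluster(
    t: np.ndarray,
    mask: np.ndarray,
    k: int,
    min_cluster: int,
) -> tuple[np.ndarray, float]:
    """Top-``k`` t-values inside ``mask``, then remove 6-connected clusters
    smaller than ``min_cluster``.  Ties in t are broken by ascending linear
    voxel index (stable, documented ordering)."""
    flat_t = t.ravel()
    cand = np.flatnonzero(mask.ravel())
    if cand.size < k:
        raise ValueError(f"masked voxel count {cand.size} < k={k}")
    # lexsort: primary key -t (descending t), secondary ascending index
    order = np.lexsort((cand, -flat_t[cand]))
    top = cand[order[:k]]
    threshold_t = float(flat_t[top[-1]])

    sel = np.zeros(t.shape, dtype=bool)
    sel.ravel()[top] = True
    structure = ndimage.generate_binary_structure(t.ndim, 1)  # face-adjacent
    labels, n_clusters = ndimage.label(sel, structure=structure)
    if n_clusters:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_cluster)
        keep = keep[keep != 0]
        sel = np.isin(labels, keep)
    voxels = np.flatnonzero(sel.ravel())
    if voxels.size == 0:
        warnings.warn(
            f"ROI empty after removing clusters < {min_cluster} voxels",
            RuntimeWarning,
        )
    return voxels, threshold_t


def select_rois(
    tmap_r: TMap,
    tmap_l: TMap,
    mask: BrainMask,
    k: int = 500,
    min_cluster: int = 5,
) -> RoiPair:
    """Build the right-vs-left and left-vs-right ROIs from their t-maps."""
    if tmap_r.t.shape != mask.include.shape or tmap_l.t.shape != mask.include.shape:
        raise ValueError("t-maps and mask must share shape")
    roi_r, thr_r = _top_k_then_cluster(tmap_r.t, mask.include, k, min_cluster)
    roi_l, thr_l = _top_k_then_cluster(tmap_l.t, mask.include, k, min_cluster)
    logger.info("selected ROIs: |roi_r|=%d (t>=%.3f), |roi_l|=%d (t>=%.3f)",
                roi_r.size, thr_r, roi_l.size, thr_l)
    return RoiPair(roi_r, roi_l, tmap_r.t.shape, thr_r, thr_l)


def baseline_scan_mask(
    schedule: Schedule, n_scans: int, n_exclude: int = 3
) -> np.ndarray:
    """Boolean per-scan mask of center scans usable for baselines.

    Center-trial scans qualify except the first ``n_exclude`` scans of center
    trials that directly follow an attention trial; an initial center trial
    (not preceded by attention) keeps all its scans.
    """
    keep = np.zeros(n_scans, dtype=bool)
    prev_attention = False
    for tr in schedule.trials:
        if tr.onset_scan >= n_scans:
            break
        if tr.condition is Condition.CENTER:
            start = tr.onset_scan + (n_exclude if prev_attention else 0)
            stop = min(tr.onset_scan + tr.length_scans, n_scans)
            if start < stop:
                keep[start:stop] = True
        prev_attention = tr.condition.is_attention
    return keep


def compute_baselines(
    series: VolumeSeries | np.ndarray,
    schedule: Schedule,
    pair: RoiPair,
    n_scans: int | None = None,
    n_exclude: int = 3,
) -> RoiPair:
    """Fill ``pair`` with baselines and stored per-voxel localizer series.

    The baseline is the mean of the raw (motion-corrected, un-detrended)
    signal over ROI voxels and qualifying center scans.  Raises if no
    qualifying scans remain or a baseline is nonpositive.
    """
    data = series.data if isinstance(series, VolumeSeries) else np.asarray(series)
    n = data.shape[0] if n_scans is None else n_scans
    flat = data[:n].reshape(n, -1)
    keep = baseline_scan_mask(schedule, n, n_exclude)
    if not keep.any():
        raise ValueError("no qualifying center scans for baseline")
    for side, roi in (("r", pair.roi_r), ("l", pair.roi_l)):
        if roi.size == 0:
            raise ValueError(f"roi_{side} is empty; cannot compute baseline")
        sub = flat[:, roi]
        baseline = float(sub[keep].mean())
        if baseline <= 0:
            raise ValueError(f"baseline_{side} is nonpositive ({baseline})")
        setattr(pair, f"baseline_{side}", baseline)
        setattr(pair, f"series_{side}", sub.copy())
    return pair
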