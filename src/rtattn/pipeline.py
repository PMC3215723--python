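"""Run configuration and stage orchestration.

The experiment is one continuous run: localizer scans first (default 200),
feedback scans directly after (default 300), so ROIs selected at the end of
the localizer apply without re-registration and the detrender sees the whole
drift history.  Stages communicate through on-disk artifacts in a single run
directory so each is independently testable and re-runnable:

    simulate  -> bold.nii, schedule.tsv, truth.json
    localize  -> tmap_r.nii, tmap_l.nii, roi/ (masks, baselines, series),
                 motion.tsv (when realignment is enabled)
    feedback  -> trace.tsv, thresholds.json
    score     -> report.tsv, roc_r.tsv, roc_l.tsv
    ecog-cv   -> ecog_features.tsv, ecog/ (confusion, per-class TPR)

Every stage writes ``provenance.json`` entries (config hash, seeds) for
reproducibility; with fixed seeds repeat invocations are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import decode, ecog, iglm, perf, roi, synth
from .synth import Schedule, VolumeSeries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the pipeline; defaults reproduce the published design
    constants exactly (TR 1.62 s, 8x8-scan localizer trials + initial
    center, 10x10-scan feedback trials, fixed thresholds +-1.5/2.5/4,
    target FPR 0.2, 3-TR shift, top-500 ROIs, 5-voxel cluster floor)."""

    tr_seconds: float = synth.DEFAULT_TR_S
    localizer_n_per_condition: int = 8
    localizer_trial_len: int = 8
    localizer_extra_initial_center: bool = True
    feedback_n_per_condition: int = 10
    feedback_trial_len: int = 10
    lam: float = 500.0
    fixed_thresholds_pos: tuple[float, float, float] = decode.FIXED_POS
    fixed_thresholds_neg: tuple[float, float, float] = decode.FIXED_NEG
    adaptive: bool = True
    target_fpr: float = 0.2
    shift_trs: int = 3
    roi_k: int = 500
    min_cluster: int = 5
    baseline_exclude_scans: int = 3
    normalize_sd: bool = False
    # phantom
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    effect_pct: float = 2.0
    deact_pct: float = -1.0
    noise_sd: float = 0.015
    realign: bool = False
    # ecog
    ecog_n_channels: int = 64
    ecog_shift: float = 1.0
    seed: int = 0
    out_dir: str = "rtattn_run"

    @property
    def n_localizer_scans(self) -> int:
        n_trials = 3 * self.localizer_n_per_condition + int(
            self.localizer_extra_initial_center
        )
        return n_trials * self.localizer_trial_len

    @property
    def n_feedback_scans(self) -> int:
        return 3 * self.feedback_n_per_condition * self.feedback_trial_len

    def thresholds(self) -> decode.ThresholdSet:
        return decode.ThresholdSet(tuple(self.fixed_thresholds_pos),
                                   tuple(self.fixed_thresholds_neg))

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("fixed_thresholds_pos", "fixed_thresholds_neg",
                     "grid_shape"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _log_provenance(out: Path, stage: str, config: RunConfig) -> None:
    path = out / "provenance.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append({"stage": stage, "config_sha": config.digest(),
                    "seed": config.seed})
    path.write_text(json.dumps(entries, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run the producing stage first"
            f" (missing: {path})"
        )
    return path


def make_run_schedule(config: RunConfig) -> Schedule:
    """Localizer followed by feedback as one continuous run; the two parts
    draw from decorrelated seeds derived from ``config.seed``."""
    loc = synth.make_schedule(
        config.localizer_n_per_condition, config.localizer_trial_len,
        seed=config.seed, extra_initial_center=config.localizer_extra_initial_center,
        tr_seconds=config.tr_seconds,
    )
    # the adjacency constraint also holds across the localizer/feedback
    # junction of the continuous run; redraw feedback until it does
    for j in range(1000):
        fb = synth.make_schedule(
            config.feedback_n_per_condition, config.feedback_trial_len,
            seed=config.seed + 1_000_003 + j, extra_initial_center=False,
            tr_seconds=config.tr_seconds,
        )
        if not (loc.trials[-1].condition.is_attention
                and fb.trials[0].condition is loc.trials[-1].condition):
            return loc.concat(fb)
    raise RuntimeError("could not draw a junction-compatible feedback schedule")


def stage_simulate(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = make_run_schedule(config)
    spec = synth.PhantomSpec(
        grid_shape=tuple(config.grid_shape),
        effect_pct=config.effect_pct,
        deact_pct=config.deact_pct,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    series = synth.simulate_bold(spec, schedule)
    series.to_nifti(out / "bold.nii")
    schedule.to_table(out / "schedule.tsv")
    truth = {
        "roi_truth_right": spec.roi_truth_right.tolist(),
        "roi_truth_left": spec.roi_truth_left.tolist(),
        "deact_right": spec.deact_right.tolist(),
        "deact_left": spec.deact_left.tolist(),
        "grid_shape": list(spec.grid_shape),
    }
    (out / "truth.json").write_text(json.dumps(truth))
    _log_provenance(out, "simulate", config)
    logger.info("simulated %d scans on grid %s", series.n_scans,
                spec.grid_shape)
    return out


def stage_localize(config: RunConfig) -> roi.RoiPair:
    out = Path(config.out_dir)
    series = VolumeSeries.from_nifti(_require(out / "bold.nii", "localize"))
    schedule = Schedule.from_table(_require(out / "schedule.tsv", "localize"))
    data = series.data
    n_loc = config.n_localizer_scans
    if config.realign:
        from .realign import realign_series, save_motion_log

        data, motion_log = realign_series(data, seed=config.seed)
        save_motion_log(motion_log, out / "motion.tsv")
    tmap_r, tmap_l, _ = iglm.fit_localizer(data, schedule, n_scans=n_loc)
    tmap_r.to_nifti(out / "tmap_r.nii", series.voxel_size_mm)
    tmap_l.to_nifti(out / "tmap_l.nii", series.voxel_size_mm)
    mask = roi.make_mask(
        data[:n_loc].mean(axis=0),
        slice_axis=series.slice_axis,
        anterior_high=series.anterior_high,
    )
    pair = roi.select_rois(tmap_r, tmap_l, mask, k=config.roi_k,
                           min_cluster=config.min_cluster)
    pair = roi.compute_baselines(data, schedule, pair, n_scans=n_loc,
                                 n_exclude=config.baseline_exclude_scans)
    pair.save(out / "roi", series.voxel_size_mm)
    if config.realign:
        np.save(out / "realigned.npy", data)  # scratch reuse by feedback
    _log_provenance(out, "localize", config)
    return pair


def _load_pair(out: Path) -> roi.RoiPair:
    import nibabel as nib

    meta = json.loads(_require(out / "roi" / "roi_meta.json", "feedback")
                      .read_text())
    shape = tuple(meta["grid_shape"])
    mr = np.asarray(nib.load(str(out / "roi" / "roi_r.nii")).dataobj) > 0
    ml = np.asarray(nib.load(str(out / "roi" / "roi_l.nii")).dataobj) > 0
    pair = roi.RoiPair(
        np.flatnonzero(mr.ravel()), np.flatnonzero(ml.ravel()), shape,
        meta["threshold_t_r"], meta["threshold_t_l"],
        meta["baseline_r"], meta["baseline_l"],
    )
    pair.series_r = np.loadtxt(out / "roi" / "series_r.tsv", ndmin=2)
    pair.series_l = np.loadtxt(out / "roi" / "series_l.tsv", ndmin=2)
    return pair


def stage_feedback(config: RunConfig) -> decode.ControlTrace:
    out = Path(config.out_dir)
    schedule = Schedule.from_table(_require(out / "schedule.tsv", "feedback"))
    pair = _load_pair(out)
    if config.realign and (out / "realigned.npy").exists():
        data = np.load(out / "realigned.npy")
    else:
        data = VolumeSeries.from_nifti(
            _require(out / "bold.nii", "feedback")).data
    loc_cs, sd_r, sd_l = decode.localizer_cs_trace(
        pair, config.lam, config.normalize_sd
    )
    if config.adaptive:
        thresholds = decode.adaptive_thresholds(
            loc_cs, schedule, config.target_fpr, config.shift_trs
        )
    else:
        thresholds = config.thresholds()
    trace = decode.feedback_loop(
        data, pair, schedule, config.n_localizer_scans, thresholds,
        lam=config.lam, normalize_sd=config.normalize_sd,
        sd_r=sd_r, sd_l=sd_l,
    )
    trace.to_table(out / "trace.tsv", config.shift_trs)
    np.savetxt(out / "localizer_cs.tsv", loc_cs, delimiter="\t")
    (out / "thresholds.json").write_text(json.dumps(
        {"pos": list(thresholds.pos), "neg": list(thresholds.neg),
         "adaptive": config.adaptive, "sd_r": sd_r, "sd_l": sd_l}, indent=2))
    _log_provenance(out, "feedback", config)
    return trace


def _load_trace(out: Path, schedule: Schedule) -> decode.ControlTrace:
    import pandas as pd

    df = pd.read_csv(_require(out / "trace.tsv", "score"), sep="\t")
    offset = int(df["scan"].iloc[0])
    return decode.ControlTrace(df["cs"].to_numpy(float), offset,
                               schedule.labels())


def stage_score(config: RunConfig) -> perf.PerfReport:
    out = Path(config.out_dir)
    schedule = Schedule.from_table(_require(out / "schedule.tsv", "score"))
    trace = _load_trace(out, schedule)
    th = json.loads(_require(out / "thresholds.json", "score").read_text())
    thresholds = decode.ThresholdSet(tuple(th["pos"]), tuple(th["neg"]))
    report = perf.score_feedback_run(trace, schedule, thresholds,
                                     config.shift_trs)
    report.to_table(out / "report.tsv")
    curves = perf.roc(trace, shift_trs=config.shift_trs)
    curves["r"].to_csv(out / "roc_r.tsv", sep="\t", index=False)
    curves["l"].to_csv(out / "roc_l.tsv", sep="\t", index=False)
    _log_provenance(out, "score", config)
    return report


def stage_ecog_cv(config: RunConfig) -> ecog.EcogCvResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feat_path = out / "ecog_features.tsv"
    if feat_path.exists():
        trials = synth.EcogTrialSet.from_table(feat_path)
    else:
        trials = synth.simulate_ecog(
            n_channels=config.ecog_n_channels,
            class_channel_map=synth.default_ecog_channel_map(config.ecog_shift),
            seed=config.seed,
        )
        trials.to_table(feat_path)
    result = ecog.optimize_and_crossvalidate(trials.features, trials.labels)
    result.save(out / "ecog")
    _log_provenance(out, "ecog-cv", config)
    return result


STAGES = {
    "simulate": stage_simulate,
    "localize": stage_localize,
    "feedback": stage_feedback,
    "score": stage_score,
    "ecog-cv": stage_ecog_cv,
}


def run_pipeline(config: RunConfig, mode: str):
    """Run one stage, or ``"all"`` for simulate -> localize -> feedback ->
    score (the ECoG arm is separate: its data are not fMRI artifacts)."""
    if mode == "all":
        last = None
        for stage in ("simulate", "localize", "feedback", "score"):
            last = STAGES[stage](config)
        return last
    if mode not in STAGES:
        raise ValueError(f"unknown mode {mode!r}; choose from "
                         f"{sorted(STAGES)} or 'all'")
    return STAGES[mode](config)
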