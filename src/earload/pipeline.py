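"""End-to-end orchestration: synthesis -> preprocessing -> features ->
statistics + classification, reproducible from a config and a seed."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .classify import assign_folds, chance_level, crossvalidate
from .containers import EpochSet, FeatureMatrix, Recording
from .preprocess import (
    bandpass,
    epoch_fixed_windows,
    epoch_stimulus_locked,
    reject_artifact_epochs,
    remove_blinks,
    resample,
)
from .spectral import band_power, make_scheme, periodogram_psd
from .stats import permutation_z_cells, subject_heatmap
from .synth import (
    CHANNEL_SUBSETS,
    EffectProfile,
    TaskDesign,
    default_montage,
    make_arithmetic_schedule,
    make_nback_schedule,
    synthesize_recording,
)
from .temporal import erp_features, fuse_features

__all__ = ["RunConfig", "RunResult", "run", "simulate_subject", "subject_features"]

logger = logging.getLogger(__name__)

#: class mapping per task: levels pooled into the low / high condition
DEFAULT_CLASSES = {
    "nback": {"low": [0], "high": [2]},
    "arithmetic": {"low": [1, 2], "high": [4, 5]},
}


@dataclass
class RunConfig:
    task: str = "nback"  # "nback" | "arithmetic"
    montage_subset: str = "cap12"  # cap12 | ear12 | cap2 | ear2
    feature_model: str = "bin1"
    cutoff: float = 100.0
    classes: Optional[dict] = None  # {"low": [...], "high": [...]}
    n_perm: int = 5000
    alpha: float = 0.01
    seed: int = 0
    k_folds: int = 10
    n_subjects: int = 1
    ptp_limit: float = 200.0
    blink_removal: bool = True
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.task not in ("nback", "arithmetic"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.montage_subset not in CHANNEL_SUBSETS:
            raise ValueError(
                f"unknown montage subset {self.montage_subset!r}; "
                f"expected one of {sorted(CHANNEL_SUBSETS)}"
            )
        if self.classes is None:
            self.classes = {k: list(v) for k, v in DEFAULT_CLASSES[self.task].items()}
        pooled = list(self.classes["low"]) + list(self.classes["high"])
        if len(set(pooled)) != len(pooled):
            raise ValueError("class mapping pools a level into both conditions")
        if self.task == "arithmetic" and 3 in pooled:
            raise ValueError(
                "arithmetic level 3 is excluded from the binary mapping "
                "(kept out to balance the classes)"
            )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def simulate_subject(
    task: str, seed: int, effect: Optional[EffectProfile] = None
) -> Recording:
    """Schedule + continuous EEG for one synthetic subject at task defaults."""
    if task == "nback":
        design = TaskDesign.nback_default()
        events = make_nback_schedule(design, seed)
        effect = effect or EffectProfile.nback_default()
    else:
        design = TaskDesign.arithmetic_default()
        events = make_arithmetic_schedule(design, seed)
        effect = effect or EffectProfile.arithmetic_default()
    return synthesize_recording(events, default_montage(), effect, seed=seed + 1)


def preprocess_subject(
    rec: Recording, task: str, ptp_limit: float = 200.0, blink_removal: bool = True
):
    """Standard offline chain: band-pass 0.5-100 Hz, blink removal,
    resample to 256 Hz, task-specific epoching, artifact rejection."""
    rec = bandpass(rec, 0.5, 100.0)
    blink_report = None
    if blink_removal:
        rec, blink_report = remove_blinks(rec)
    rec = resample(rec, 256.0)
    if task == "nback":
        ep = epoch_stimulus_locked(rec)
    else:
        ep = epoch_fixed_windows(rec)
    ep, rejection = reject_artifact_epochs(ep, ptp_limit)
    return ep, rejection, blink_report


def binary_epochs(ep: EpochSet, classes: dict) -> tuple[EpochSet, np.ndarray]:
    """Subset trials to the pooled low/high conditions; returns the epochs
    and a string label array ('low'/'high')."""
    low = np.isin(ep.labels, classes["low"])
    high = np.isin(ep.labels, classes["high"])
    keep = low | high
    sub = ep.select_trials(keep)
    y = np.where(np.isin(sub.labels, classes["high"]), "high", "low")
    return sub, y


def subject_features(
    ep: EpochSet,
    channel_names: list[str],
    model: str,
    cutoff: float = 100.0,
    subject_id: str = "s01",
) -> FeatureMatrix:
    """Feature matrix for one subject under one feature model.

    ``model`` is a spectral model id, ``"temporal"`` or ``"fusion"``
    (1 Hz spectral bins + temporal amplitudes).
    """
    sub = ep.select_channels(channel_names)
    if model == "temporal":
        return erp_features(sub, subject_id=subject_id)
    if model == "fusion":
        psd, freqs = periodogram_psd(sub)
        spec_fm = band_power(
            psd, freqs, make_scheme("bin1", cutoff), sub.channel_names, sub.labels,
            subject_id=subject_id,
        )
        return fuse_features(spec_fm, erp_features(sub, subject_id=subject_id))
    psd, freqs = periodogram_psd(sub)
    return band_power(
        psd, freqs, make_scheme(model, cutoff), sub.channel_names, sub.labels,
        subject_id=subject_id,
    )


@dataclass
class SubjectResult:
    subject_id: str
    n_epochs: int
    n_binary: int
    rejection_fraction: float
    z_matrix: np.ndarray  # channels x cells
    cv: object  # CVResult
    n_blink_components: int


@dataclass
class RunResult:
    config: RunConfig
    subjects: list[SubjectResult]
    heatmap: object  # SubjectHeatmap
    summary: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis for ``config.n_subjects`` synthetic
    subjects and aggregate the cross-subject outputs."""
    channel_names = CHANNEL_SUBSETS[config.montage_subset]
    subject_results = []
    root = np.random.SeedSequence(config.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.n_subjects)]
    for si, sseed in enumerate(subject_seeds):
        t0 = time.time()
        sid = f"s{si + 1:02d}"
        rec = simulate_subject(config.task, sseed)
        ep, rejection, blink_report = preprocess_subject(
            rec, config.task, config.ptp_limit, config.blink_removal
        )
        n_epochs = ep.n_trials + rejection.n_removed
        bin_ep, y = binary_epochs(ep, config.classes)
        fm = subject_features(bin_ep, channel_names, config.feature_model, config.cutoff, sid)

        n_cells = fm.n_features // len(channel_names)
        z = permutation_z_cells(
            fm.values[y == "low"], fm.values[y == "high"],
            n_perm=config.n_perm, seed=sseed + 7,
        ).reshape(len(channel_names), n_cells)

        partition = assign_folds(fm.n_trials, config.k_folds)
        cv = crossvalidate(fm.values, y, partition)
        subject_results.append(
            SubjectResult(
                subject_id=sid,
                n_epochs=n_epochs,
                n_binary=fm.n_trials,
                rejection_fraction=rejection.fraction,
                z_matrix=z,
                cv=cv,
                n_blink_components=0 if blink_report is None else blink_report.n_removed,
            )
        )
        logger.info("subject %s done in %.1fs", sid, time.time() - t0)

    heatmap = subject_heatmap([s.z_matrix for s in subject_results], alpha=config.alpha)
    summary = pd.DataFrame(
        {
            "subject": [s.subject_id for s in subject_results],
            "n_epochs": [s.n_epochs for s in subject_results],
            "n_binary_trials": [s.n_binary for s in subject_results],
            "rejection_fraction": [s.rejection_fraction for s in subject_results],
            "mean_accuracy_pct": [s.cv.mean_accuracy for s in subject_results],
            "chance_threshold_pct": [s.cv.chance_threshold for s in subject_results],
            "n_features_final": [s.cv.n_features_final for s in subject_results],
            "n_blink_components": [s.n_blink_components for s in subject_results],
        }
    )
    result = RunResult(config=config, subjects=subject_results, heatmap=heatmap, summary=summary)
    if config.out_dir:
        result.manifest = _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: RunResult, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    summary_path = out / "summary.tsv"
    result.summary.to_csv(summary_path, sep="\t", index=False)
    paths.append(summary_path)
    heat_path = out / "heatmap.tsv"
    channel_names = CHANNEL_SUBSETS[result.config.montage_subset]
    pd.DataFrame(result.heatmap.counts, index=channel_names).to_csv(heat_path, sep="\t")
    paths.append(heat_path)
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(asdict(result.config), indent=1, default=str))
    paths.append(cfg_path)
    meta_path = out / "stats.json"
    meta_path.write_text(
        json.dumps(
            {
                "alpha": result.heatmap.alpha,
                "n_subjects": result.heatmap.n_subjects,
                "per_subject_thresholds": result.heatmap.per_subject_thresholds,
            },
            indent=1,
        )
    )
    paths.append(meta_path)
    manifest = {p.name: _io.sha256_file(p) for p in paths}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
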