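"""Patient-specific evaluation protocol.

For one case (one patient's file set), training and scoring follow a
file-wise k-fold scheme where k is the number of files containing at least
one seizure: each such file is held out once for event-level evaluation;
the classifier is trained on ictal windows from the remaining k-1 seizure
files plus interictal windows from the seizure-free files, split 7:2:1 into
train/validation/test for segment-level scoring.  Detection parameters
(Th, L) are tuned on the training files' probability traces only, never on
the held-out file.  Per-case results aggregate fold values as mean +/- SD
(sample SD, n-1).

The default 7:2:1 split assigns contiguous time blocks ("grouped_blocks") so
that overlapping windows never span two parts; a "random_segments" mode that
splits individual windows at random is available for comparison, but with
heavily overlapping windows it leaks near-duplicates between parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnn import ModelConfig, build_model, train_model, predict_proba
from .detect import (
    DetectionParams,
    EventMetrics,
    event_metrics,
    extract_events,
    match_events,
    savgol_smooth,
    sliding_probabilities,
    tune_postprocessing,
)
from .errors import MonoseizeError
from .io import ChannelSubsetPolicy, Recording, SeizureAnnotation, \
    ensure_montaged, select_channels
from .preprocess import FilterSpec, SegmentSet, bandpass, segment_and_label

__all__ = [
    "FoldPlan", "SegmentMetrics", "RunConfig", "FoldResult", "CaseResult",
    "make_fold_plan", "split_train_val_test", "segment_level_metrics",
    "run_case", "summarize_manifest", "load_reference_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "case_id", "age_yr", "sex", "n_seizures", "seizure_length_mean_s",
    "seizure_length_sd_s", "total_seizure_length_s", "recording_length_h",
    "single_channel",
]


@dataclass(frozen=True)
class FoldPlan:
    """File-wise cross-validation plan: each seizure file is the test file
    exactly once; seizure-free files feed interictal data to every fold."""

    k: int
    folds: tuple[tuple[str, tuple[str, ...]], ...]
    seizure_free_file_ids: tuple[str, ...]


@dataclass(frozen=True)
class SegmentMetrics:
    """Segment-level scores in percent."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float


def make_fold_plan(
    files: Sequence[tuple[str, SeizureAnnotation]]
) -> FoldPlan:
    """Build the k-fold plan from per-file annotations."""
    seizure_ids = [fid for fid, ann in files if len(ann) >= 1]
    free_ids = [fid for fid, ann in files if len(ann) == 0]
    if not seizure_ids:
        raise MonoseizeError("no file contains a seizure; k-fold undefined")
    if len(seizure_ids) == 1:
        warnings.warn(
            "only one seizure file: k=1, its fold trains without held-out "
            "ictal data", stacklevel=2,
        )
    folds = tuple(
        (test, tuple(s for s in seizure_ids if s != test))
        for test in seizure_ids
    )
    return FoldPlan(k=len(seizure_ids), folds=folds,
                    seizure_free_file_ids=tuple(free_ids))


def _part_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    total = float(sum(ratios))
    raw = [n * r / total for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in rema[: n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def split_train_val_test(
    segs: SegmentSet,
    ratios: Sequence[float] = (7, 2, 1),
    mode: str = "grouped_blocks",
    seed: int = 0,
) -> tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Split segments 7:2:1 into train/validation/test.

    ``random_segments`` permutes windows and cuts at the exact proportions.
    ``grouped_blocks`` (default) cuts each contiguous same-class run per
    source file into three consecutive time blocks, discarding windows at
    block boundaries that would overlap the previous block in time, so no
    window in one part overlaps any window in another.
    """
    n = len(segs)
    if n < 3:
        raise MonoseizeError("too few segments to split")
    if mode == "random_segments":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        s0, s1, _ = _part_sizes(n, ratios)
        return (segs.subset(perm[:s0]),
                segs.subset(perm[s0:s0 + s1]),
                segs.subset(perm[s0 + s1:]))
    if mode != "grouped_blocks":
        raise MonoseizeError(f"unknown split mode {mode!r}")

    window_s = segs.window_samples / segs.fs
    order = np.lexsort((segs.window_starts, segs.labels,
                        segs.source_ids.astype(str)))
    runs: list[list[int]] = []
    for idx in order:
        if runs:
            prev = runs[-1][-1]
            same = (segs.source_ids[prev] == segs.source_ids[idx]
                    and segs.labels[prev] == segs.labels[idx])
            if same:
                runs[-1].append(int(idx))
                continue
        runs.append([int(idx)])
    parts: list[list[int]] = [[], [], []]
    for run in runs:
        sizes = _part_sizes(len(run), ratios)
        cursor = 0
        prev_end_time: float | None = None
        for p, size in enumerate(sizes):
            chunk = run[cursor:cursor + size]
            cursor += size
            if prev_end_time is not None:
                chunk = [
                    i for i in chunk
                    if segs.window_starts[i] >= prev_end_time - 1e-9
                ]
            if chunk:
                prev_end_time = segs.window_starts[chunk[-1]] + window_s
            parts[p].extend(chunk)
    return tuple(segs.subset(np.array(sorted(p), dtype=int)) for p in parts)


def segment_level_metrics(
    labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5
) -> SegmentMetrics:
    """Sensitivity/specificity/accuracy at the threshold rule (ictal iff
    probability >= threshold) and rank-based AUC with tie averaging."""
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=float)
    pos = labels == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise MonoseizeError("both classes required for segment metrics/AUC")
    preds = probs >= threshold
    tp = int(np.sum(preds & pos))
    tn = int(np.sum(~preds & neg))
    from scipy.stats import rankdata

    ranks = rankdata(probs)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return SegmentMetrics(
        sensitivity=100.0 * tp / n_pos,
        specificity=100.0 * tn / n_neg,
        accuracy=100.0 * (tp + tn) / len(labels),
        auc=100.0 * float(auc),
    )


@dataclass
class RunConfig:
    """Everything run_case needs besides the data and channel policy."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    window_s: float = 4.0
    train_step_samples: int = 64
    split_mode: str = "grouped_blocks"
    split_ratios: tuple[float, float, float] = (7, 2, 1)
    th_grid: tuple[float, ...] = tuple(np.round(np.arange(0.2, 0.91, 0.1), 2))
    run_length_grid: tuple[int, ...] = tuple(range(5, 11))
    merge_gap_s: float = 10.0
    sg_window: int = 10
    sg_order: int = 3
    seed: int = 0


@dataclass
class FoldResult:
    test_file_id: str
    segment: SegmentMetrics
    events: EventMetrics
    params: DetectionParams


@dataclass
class CaseResult:
    """Per-fold results and mean +/- SD aggregates for one case."""

    folds: list[FoldResult]
    aggregate: dict[str, tuple[float, float]]
    policy: ChannelSubsetPolicy

    @property
    def mean_event_sensitivity(self) -> float:
        return self.aggregate["event_sensitivity"][0]


def _aggregate(folds: list[FoldResult]) -> dict[str, tuple[float, float]]:
    def stat(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            return float("nan"), float("nan")
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return float(np.mean(arr)), sd

    return {
        "segment_sensitivity": stat([f.segment.sensitivity for f in folds]),
        "segment_specificity": stat([f.segment.specificity for f in folds]),
        "segment_accuracy": stat([f.segment.accuracy for f in folds]),
        "segment_auc": stat([f.segment.auc for f in folds]),
        "event_sensitivity": stat([f.events.sensitivity for f in folds]),
        "event_far_per_h": stat([f.events.far_per_h for f in folds]),
        "event_latency_s": stat([f.events.mean_latency_s for f in folds]),
        "correct": stat([f.events.correct for f in folds]),
        "missed": stat([f.events.missed for f in folds]),
        "false_alarms": stat([f.events.false_alarms for f in folds]),
    }


def run_case(
    files: Sequence[tuple[Recording, SeizureAnnotation]],
    policy: ChannelSubsetPolicy,
    config: RunConfig | None = None,
) -> CaseResult:
    """Run the full patient-specific protocol on one case.

    ``files`` pairs raw (referential or bipolar) recordings with their
    annotations.  Returns per-fold segment- and event-level results plus
    mean +/- SD aggregates.
    """
    config = config or RunConfig()
    prepped: dict[str, Recording] = {}
    anns: dict[str, SeizureAnnotation] = {}
    for rec, ann in files:
        ann.validate_against(rec)
        sel = select_channels(ensure_montaged(rec), policy)
        prepped[rec.source_id] = bandpass(sel, config.filter_spec)
        anns[rec.source_id] = ann
    plan = make_fold_plan([(fid, anns[fid]) for fid in prepped])

    folds: list[FoldResult] = []
    for test_id, train_ids in plan.folds:
        parts: list[SegmentSet] = []
        for fid in train_ids:
            segs = segment_and_label(
                prepped[fid], anns[fid], config.window_s,
                config.train_step_samples,
            )
            parts.append(segs.subset(np.flatnonzero(segs.labels == 1)))
        inter_sources = plan.seizure_free_file_ids or train_ids
        for fid in inter_sources:
            segs = segment_and_label(
                prepped[fid], anns[fid], config.window_s,
                config.train_step_samples,
            )
            parts.append(segs.subset(np.flatnonzero(segs.labels == 0)))
        all_segs = SegmentSet.concatenate(parts)
        if all_segs.n_ictal == 0 or all_segs.n_interictal == 0:
            raise MonoseizeError(
                f"fold {test_id}: training data lacks a class "
                f"({all_segs.n_ictal} ictal / {all_segs.n_interictal} interictal)"
            )
        train, val, test = split_train_val_test(
            all_segs, config.split_ratios, config.split_mode, config.seed,
        )
        model = build_model(config.model, train.windows.shape[1])
        trained = train_model(model, train, val, config.model)
        if test.n_ictal > 0 and test.n_interictal > 0:
            test_probs = predict_proba(trained, test.windows)
            seg_metrics = segment_level_metrics(test.labels, test_probs)
        else:
            # short seizures can leave the 10% test block without ictal
            # windows after boundary-overlap dropping; flag, don't fail
            warnings.warn(
                f"fold {test_id}: test split is single-class; segment "
                "metrics undefined for this fold", stacklevel=2,
            )
            nan = float("nan")
            seg_metrics = SegmentMetrics(nan, nan, nan, nan)

        traces = [sliding_probabilities(trained, prepped[fid])
                  for fid in train_ids]
        params = tune_postprocessing(
            traces, [anns[fid] for fid in train_ids],
            th_grid=config.th_grid,
            run_length_grid=config.run_length_grid,
            merge_gap_s=config.merge_gap_s,
            sg_window=config.sg_window,
            sg_order=config.sg_order,
        )
        trace = sliding_probabilities(trained, prepped[test_id])
        detected = extract_events(savgol_smooth(trace, params), params)
        match = match_events(detected, anns[test_id])
        ev = event_metrics(match, prepped[test_id].duration_s / 3600.0)
        folds.append(FoldResult(test_id, seg_metrics, ev, params))
    return CaseResult(folds=folds, aggregate=_aggregate(folds), policy=policy)


# ---------------------------------------------------------------------------
# Manifest summaries (Table-1-style arithmetic)
# ---------------------------------------------------------------------------

def load_reference_manifest() -> pd.DataFrame:
    """The 13 CHB-MIT cases used for wearable-channel seizure detection,
    with per-case seizure counts, lengths and the neurologist-assigned
    single channel."""
    path = Path(__file__).parent / "data" / "chbmit_cases.csv"
    return pd.read_csv(path)


def summarize_manifest(manifest: pd.DataFrame) -> dict[str, float]:
    """Totals and mean +/- SD summaries of a case manifest.

    Per-case columns are averaged with sample SD (n-1).  The seizure-length
    summary is pooled over individual seizures: mean = total seizure time /
    total seizures, SD reconstructed from per-case means and SDs.  Also
    reports mean ictal and interictal hours per case.
    """
    if len(manifest) == 0:
        raise MonoseizeError("empty manifest")
    df = manifest
    n_cases = len(df)

    def stat(col: pd.Series) -> tuple[float, float]:
        arr = col.to_numpy(dtype=float)
        sd = float(np.std(arr, ddof=1)) if n_cases > 1 else 0.0
        return float(np.mean(arr)), sd

    counts = df["n_seizures"].to_numpy(dtype=float)
    means = df["seizure_length_mean_s"].to_numpy(dtype=float)
    sds = (df["seizure_length_sd_s"].to_numpy(dtype=float)
           if "seizure_length_sd_s" in df else np.zeros(n_cases))
    total_seizures = counts.sum()
    total_seizure_s = float(df["total_seizure_length_s"].sum())
    pooled_mean = total_seizure_s / total_seizures
    ss = float(np.sum((counts - 1) * sds**2 + counts * (means - pooled_mean) ** 2))
    pooled_sd = (np.sqrt(ss / (total_seizures - 1))
                 if total_seizures > 1 else 0.0)

    out: dict[str, float] = {
        "n_cases": float(n_cases),
        "total_seizures": float(total_seizures),
        "total_seizure_length_s": total_seizure_s,
        "total_recording_h": float(df["recording_length_h"].sum()),
        "seizure_length_mean_s": float(pooled_mean),
        "seizure_length_sd_s": float(pooled_sd),
    }
    for key, col in [
        ("seizures_per_case", "n_seizures"),
        ("total_seizure_length_per_case_s", "total_seizure_length_s"),
        ("recording_h_per_case", "recording_length_h"),
        ("age_yr", "age_yr"),
    ]:
        m, s = stat(df[col])
        out[f"{key}_mean"], out[f"{key}_sd"] = m, s
    ictal_h = df["total_seizure_length_s"].to_numpy(dtype=float) / 3600.0
    inter_h = df["recording_length_h"].to_numpy(dtype=float) - ictal_h
    out["ictal_h_mean"] = float(np.mean(ictal_h))
    out["ictal_h_sd"] = float(np.std(ictal_h, ddof=1)) if n_cases > 1 else 0.0
    out["interictal_h_mean"] = float(np.mean(inter_h))
    out["interictal_h_sd"] = float(np.std(inter_h, ddof=1)) if n_cases > 1 else 0.0
    return out
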