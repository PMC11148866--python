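"""Event-level seizure detection on continuous recordings.

A trained classifier is slid over the recording (4-s windows, 1-s step) to
produce an ictal probability trace.  The trace is smoothed with a
Savitzky-Golay filter (window 10, polynomial order 3), thresholded at ``Th``
(strict), and maximal supra-threshold runs of at least ``L`` steps become
candidate events spanning [first window start, last window start + 4 s).
Events closer than 10 s are merged transitively.  Detected events are scored
against annotated seizures by interval overlap: an annotated seizure with at
least one overlapping event is correct (latency = earliest overlapping
detection onset minus annotated onset, possibly negative), one with none is
missed, and a detection overlapping no annotation is a false alarm.

The Savitzky-Golay window of 10 is even, which scipy's implementation does
not accept, so the local least-squares fit is implemented directly: each
point is fitted over offsets [-5, +4] (5 left, 4 right) and edge points over
the available truncated window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MonoseizeError
from .io import Recording, SeizureAnnotation

__all__ = [
    "ProbabilityTrace", "DetectionParams", "EventSet", "MatchResult",
    "EventMetrics", "sliding_probabilities", "savgol_smooth",
    "extract_events", "match_events", "event_metrics", "tune_postprocessing",
]


@dataclass(frozen=True)
class ProbabilityTrace:
    """Per-step ictal probability over a continuous recording."""

    times: np.ndarray            # window start seconds, constant step
    probs: np.ndarray            # in [0, 1]
    step_s: float = 1.0
    window_s: float = 4.0
    source_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "probs", probs)
        if len(times) != len(probs):
            raise MonoseizeError("times and probs must have equal length")
        if len(probs) and (probs.min() < -1e-9 or probs.max() > 1 + 1e-9):
            raise MonoseizeError("probabilities must lie in [0, 1]")
        if len(times) > 1:
            d = np.diff(times)
            if d.min() <= 0 or not np.allclose(d, d[0]):
                raise MonoseizeError("times must increase with a constant step")

    def __len__(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class DetectionParams:
    """Post-processing parameters: threshold Th, run length L, merging and
    smoothing settings."""

    th: float = 0.5
    run_length: int = 5
    merge_gap_s: float = 10.0
    sg_window: int = 10
    sg_order: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "th", float(self.th))
        object.__setattr__(self, "run_length", int(self.run_length))
        if not 0 < self.th < 1:
            raise MonoseizeError("threshold must lie in (0, 1)")
        if self.run_length < 1:
            raise MonoseizeError("run length must be >= 1")
        if self.sg_order >= self.sg_window:
            raise MonoseizeError("sg_order must be < sg_window")


@dataclass(frozen=True)
class EventSet:
    """Sorted, non-overlapping detected events [onset, offset)."""

    intervals: tuple[tuple[float, float], ...]
    source_id: str = ""

    def __init__(self, intervals: Sequence[Sequence[float]] = (),
                 source_id: str = "") -> None:
        ivals = sorted((float(a), float(b)) for a, b in intervals)
        for a, b in ivals:
            if a >= b:
                raise MonoseizeError(f"event onset {a} must precede offset {b}")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise MonoseizeError("events must not overlap")
        object.__setattr__(self, "intervals", tuple(ivals))
        object.__setattr__(self, "source_id", source_id)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class MatchResult:
    """Counts from matching detected events against annotated seizures."""

    correct: int
    missed: int
    false_alarms: int
    latencies_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.latencies_s) != self.correct:
            raise MonoseizeError("one latency per correctly detected seizure")


@dataclass(frozen=True)
class EventMetrics:
    """Event-level scores: sensitivity (%), false alarms per hour, and mean
    signed onset latency (s)."""

    sensitivity: float
    far_per_h: float
    mean_latency_s: float
    recording_hours: float
    correct: int = 0
    missed: int = 0
    false_alarms: int = 0


def sliding_probabilities(
    model,
    rec: Recording,
    window_s: float = 4.0,
    step_s: float = 1.0,
) -> ProbabilityTrace:
    """Classify sliding windows over a continuous recording.

    Windows start at 0, step_s, 2*step_s, ... while a full window fits;
    for an integer duration the trace has floor(duration) - 3 steps.
    """
    from .cnn import predict_proba  # local import to avoid cycle

    w = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if rec.n_samples < w:
        raise MonoseizeError("recording shorter than one window")
    starts = np.arange(0, rec.n_samples - w + 1, step)
    view = np.lib.stride_tricks.sliding_window_view(rec.signal, w, axis=1)
    windows = view[:, starts, :].transpose(1, 0, 2).astype(np.float32)
    probs = predict_proba(model, windows)
    return ProbabilityTrace(
        times=starts / rec.fs,
        probs=np.clip(probs, 0.0, 1.0),
        step_s=step_s,
        window_s=window_s,
        source_id=rec.source_id,
    )


def _savgol_weights(offsets: np.ndarray, order: int) -> np.ndarray:
    """Least-squares weights evaluating the local polynomial fit at 0."""
    design = np.vander(offsets.astype(float), order + 1, increasing=True)
    # value at offset 0 of the fitted polynomial = e0^T (X^T X)^-1 X^T y
    pinv = np.linalg.pinv(design)
    return pinv[0]


def savgol_smooth(
    trace: ProbabilityTrace, params: DetectionParams = DetectionParams()
) -> ProbabilityTrace:
    """Savitzky-Golay smoothing supporting the even window length 10.

    Interior points use offsets -(w//2) .. w - w//2 - 1 (5 left, 4 right for
    w=10); edges fit over the truncated available window.  Output clipped to
    [0, 1].
    """
    n = len(trace)
    w, order = params.sg_window, params.sg_order
    if n < w:
        raise MonoseizeError(f"trace length {n} shorter than window {w}")
    left = w // 2
    right = w - left - 1
    y = trace.probs
    out = np.empty(n)
    interior_w = _savgol_weights(np.arange(-left, right + 1), order)
    for i in range(n):
        lo, hi = max(0, i - left), min(n - 1, i + right)
        if lo == i - left and hi == i + right:
            out[i] = interior_w @ y[lo:hi + 1]
        else:
            offs = np.arange(lo, hi + 1) - i
            out[i] = _savgol_weights(offs, order) @ y[lo:hi + 1]
    return ProbabilityTrace(
        times=trace.times,
        probs=np.clip(out, 0.0, 1.0),
        step_s=trace.step_s,
        window_s=trace.window_s,
        source_id=trace.source_id,
    )


def extract_events(
    trace: ProbabilityTrace, params: DetectionParams
) -> EventSet:
    """Threshold + run-length + merge post-processing.

    Maximal runs of steps with probability strictly above ``Th`` and length
    >= ``L`` become events [first start, last start + window_s); events whose
    gap is < merge_gap_s are merged transitively.
    """
    above = trace.probs > params.th
    events: list[tuple[float, float]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= params.run_length:
                events.append(
                    (float(trace.times[i]), float(trace.times[j]) + trace.window_s)
                )
            i = j + 1
        else:
            i += 1
    merged: list[list[float]] = []
    for a, b in events:
        if merged and a - merged[-1][1] < params.merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return EventSet(intervals=merged, source_id=trace.source_id)


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_events(detected: EventSet, annotated: SeizureAnnotation) -> MatchResult:
    """Overlap-based matching of detections against annotated seizures."""
    if detected.source_id and annotated.source_id and \
            detected.source_id != annotated.source_id:
        raise MonoseizeError(
            f"source mismatch: {detected.source_id!r} vs {annotated.source_id!r}"
        )
    correct, latencies = 0, []
    for seiz in annotated.intervals:
        hits = [d for d in detected.intervals if _overlaps(d, seiz)]
        if hits:
            correct += 1
            latencies.append(min(d[0] for d in hits) - seiz[0])
    missed = len(annotated.intervals) - correct
    false_alarms = sum(
        1 for d in detected.intervals
        if not any(_overlaps(d, s) for s in annotated.intervals)
    )
    return MatchResult(
        correct=correct,
        missed=missed,
        false_alarms=false_alarms,
        latencies_s=tuple(latencies),
    )


def event_metrics(match: MatchResult, recording_hours: float) -> EventMetrics:
    """Sensitivity (%), FAR per hour, and mean signed latency."""
    if recording_hours <= 0:
        raise MonoseizeError("recording_hours must be positive")
    n_annot = match.correct + match.missed
    sensitivity = 100.0 if n_annot == 0 else 100.0 * match.correct / n_annot
    far = match.false_alarms / recording_hours
    latency = float(np.mean(match.latencies_s)) if match.latencies_s else float("nan")
    return EventMetrics(
        sensitivity=sensitivity,
        far_per_h=far,
        mean_latency_s=latency,
        recording_hours=recording_hours,
        correct=match.correct,
        missed=match.missed,
        false_alarms=match.false_alarms,
    )


def tune_postprocessing(
    traces: Sequence[ProbabilityTrace],
    annotations: Sequence[SeizureAnnotation],
    th_grid: Sequence[float] = tuple(np.round(np.arange(0.2, 0.91, 0.1), 2)),
    run_length_grid: Sequence[int] = tuple(range(5, 11)),
    merge_gap_s: float = 10.0,
    sg_window: int = 10,
    sg_order: int = 3,
) -> DetectionParams:
    """Pick (Th, L) on training traces: maximise event sensitivity, then
    minimise FAR, then prefer larger L, then larger Th (deterministic)."""
    if not len(th_grid) or not len(run_length_grid):
        raise MonoseizeError("empty tuning grid")
    pairs = [(t, a) for t, a in zip(traces, annotations)]
    if not any(len(a) for _, a in pairs):
        raise MonoseizeError("tuning needs at least one annotated seizure")
    total_hours = sum(
        (len(t) - 1) * t.step_s + t.window_s for t, _ in pairs
    ) / 3600.0
    smoothed = [
        (savgol_smooth(t, DetectionParams(sg_window=sg_window, sg_order=sg_order)), a)
        for t, a in pairs
    ]
    best = None
    for th, run_len in itertools.product(th_grid, run_length_grid):
        params = DetectionParams(
            th=th, run_length=run_len, merge_gap_s=merge_gap_s,
            sg_window=sg_window, sg_order=sg_order,
        )
        correct = annotated = fas = 0
        for tr, ann in smoothed:
            m = match_events(extract_events(tr, params), ann)
            correct += m.correct
            annotated += m.correct + m.missed
            fas += m.false_alarms
        sens = correct / annotated if annotated else 0.0
        far = fas / total_hours if total_hours else 0.0
        key = (sens, -far, run_len, th)
        if best is None or key > best[0]:
            best = (key, params)
    return best[1]
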