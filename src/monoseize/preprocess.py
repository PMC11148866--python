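"""Band-pass filtering, windowing/labelling, and class-balanced batching.

The detector consumes 4-s windows of 1-30 Hz band-passed EEG.  Windows fully
inside an annotated seizure interval are ictal, windows fully outside every
interval are interictal; windows straddling a boundary carry neither pure
class and are excluded (their count is kept for bookkeeping).  Ictal windows
are vastly outnumbered by interictal ones, so training draws class-balanced
batches with minority oversampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .errors import MonoseizeError
from .io import Recording, SeizureAnnotation

__all__ = [
    "FilterSpec",
    "SegmentSet",
    "BatchPlan",
    "bandpass",
    "segment_and_label",
    "balanced_batches",
    "BalancedBatchStream",
]

ICTAL, INTERICTAL = 1, 0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; defaults to the 1-30 Hz seizure band."""

    low_hz: float = 1.0
    high_hz: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise MonoseizeError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise MonoseizeError("filter order must be >= 1")


@dataclass
class SegmentSet:
    """Fixed-length labelled windows cut from one or more recordings."""

    windows: np.ndarray          # (M, N, W) float32
    labels: np.ndarray           # (M,) int, 1 = ictal
    window_starts: np.ndarray    # (M,) seconds from file start
    source_ids: np.ndarray       # (M,) str
    fs: float
    n_straddling: int = 0

    def __post_init__(self) -> None:
        m = len(self.windows)
        if not (len(self.labels) == len(self.window_starts) == len(self.source_ids) == m):
            raise MonoseizeError("inconsistent segment arrays")
        if m and not set(np.unique(self.labels)) <= {ICTAL, INTERICTAL}:
            raise MonoseizeError("labels must be ictal(1)/interictal(0)")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_samples(self) -> int:
        return self.windows.shape[2] if len(self.windows) else 0

    @property
    def n_ictal(self) -> int:
        return int(np.sum(self.labels == ICTAL))

    @property
    def n_interictal(self) -> int:
        return int(np.sum(self.labels == INTERICTAL))

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            windows=self.windows[idx],
            labels=self.labels[idx],
            window_starts=self.window_starts[idx],
            source_ids=self.source_ids[idx],
            fs=self.fs,
        )

    @staticmethod
    def concatenate(parts: list["SegmentSet"]) -> "SegmentSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise MonoseizeError("nothing to concatenate")
        fs = parts[0].fs
        if any(p.fs != fs for p in parts):
            raise MonoseizeError("mixed sampling rates")
        return SegmentSet(
            windows=np.concatenate([p.windows for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            window_starts=np.concatenate([p.window_starts for p in parts]),
            source_ids=np.concatenate([p.source_ids for p in parts]),
            fs=fs,
            n_straddling=sum(p.n_straddling for p in parts),
        )


@dataclass(frozen=True)
class BatchPlan:
    """How balanced batches are drawn: even batch size, seeded, fixed
    number of batches per epoch."""

    batch_size: int = 32
    seed: int = 0
    epoch_batches: int = 50

    def __post_init__(self) -> None:
        if self.batch_size < 2 or self.batch_size % 2:
            raise MonoseizeError("batch_size must be even and >= 2")
        if self.epoch_batches < 1:
            raise MonoseizeError("epoch_batches must be >= 1")


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Butterworth band-pass each channel (zero-phase by default)."""
    if spec.high_hz >= rec.fs / 2:
        raise MonoseizeError(
            f"band edge {spec.high_hz} Hz needs fs > {2 * spec.high_hz} Hz"
        )
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
        fs=rec.fs, output="sos",
    )
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    else:
        filtered = sps.sosfilt(sos, rec.signal, axis=1)
    return Recording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        signal=filtered,
        start_offset=rec.start_offset,
        source_id=rec.source_id,
    )


def segment_and_label(
    rec: Recording,
    ann: SeizureAnnotation,
    window_s: float = 4.0,
    step_samples: int = 64,
) -> SegmentSet:
    """Cut windows at starts 0, step, 2*step, ... and label them.

    A window is ictal iff it lies entirely inside one annotated interval and
    interictal iff it lies entirely outside all intervals; straddling windows
    are dropped and counted in ``n_straddling``.  Interval bounds map to
    sample indices via floor(t * fs) with half-open semantics.
    """
    w = int(round(window_s * rec.fs))
    t = rec.n_samples
    if t < w:
        raise MonoseizeError(f"recording ({t} samples) shorter than window ({w})")
    if step_samples < 1:
        raise MonoseizeError("step_samples must be >= 1")
    starts = np.arange(0, t - w + 1, step_samples)
    onset_idx = np.array([int(np.floor(a * rec.fs)) for a, _ in ann.intervals])
    offset_idx = np.array([int(np.floor(b * rec.fs)) for _, b in ann.intervals])

    if len(onset_idx):
        s = starts[:, None]
        inside = (s >= onset_idx[None, :]) & (s + w <= offset_idx[None, :])
        overlap = (s < offset_idx[None, :]) & (s + w > onset_idx[None, :])
        ictal = inside.any(axis=1)
        touches = overlap.any(axis=1)
        straddle = touches & ~ictal
    else:
        ictal = np.zeros(len(starts), dtype=bool)
        straddle = np.zeros(len(starts), dtype=bool)
    keep = ~straddle
    kept_starts = starts[keep]

    # gather windows without materialising the straddlers
    view = np.lib.stride_tricks.sliding_window_view(rec.signal, w, axis=1)
    windows = view[:, kept_starts, :].transpose(1, 0, 2).astype(np.float32)
    return SegmentSet(
        windows=windows,
        labels=ictal[keep].astype(np.int64),
        window_starts=kept_starts / rec.fs,
        source_ids=np.full(len(kept_starts), rec.source_id, dtype=object),
        fs=rec.fs,
        n_straddling=int(straddle.sum()),
    )


class BalancedBatchStream:
    """Deterministic stream of class-balanced batches.

    Each batch holds exactly ``batch_size/2`` ictal and ``batch_size/2``
    interictal windows.  Within an epoch the majority class is consumed
    without replacement (reshuffled when exhausted); the minority class is
    resampled with replacement.  Epoch ``e`` under seed ``s`` is a pure
    function of ``(s, e)``.
    """

    def __init__(self, segs: SegmentSet, plan: BatchPlan) -> None:
        if segs.n_ictal == 0 or segs.n_interictal == 0:
            raise MonoseizeError("balanced batching needs both classes")
        self.segs = segs
        self.plan = plan
        self._ictal_idx = np.flatnonzero(segs.labels == ICTAL)
        self._inter_idx = np.flatnonzero(segs.labels == INTERICTAL)

    def _epoch_indices(self, epoch: int) -> list[np.ndarray]:
        rng = np.random.default_rng((self.plan.seed, epoch))
        half = self.plan.batch_size // 2
        if len(self._ictal_idx) <= len(self._inter_idx):
            minority, majority = self._ictal_idx, self._inter_idx
        else:
            minority, majority = self._inter_idx, self._ictal_idx
        pool = {"perm": rng.permutation(majority), "pos": 0}
        batches = []
        for _ in range(self.plan.epoch_batches):
            minor = rng.choice(minority, size=half, replace=True)
            major: list[int] = []
            while len(major) < half:
                if pool["pos"] >= len(pool["perm"]):
                    pool["perm"] = rng.permutation(majority)
                    pool["pos"] = 0
                room = min(half - len(major), len(pool["perm"]) - pool["pos"])
                major.extend(pool["perm"][pool["pos"]:pool["pos"] + room])
                pool["pos"] += room
            batch = np.concatenate([minor, np.array(major, dtype=minor.dtype)])
            batches.append(rng.permutation(batch))
        return batches

    def epoch(self, epoch: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for idx in self._epoch_indices(epoch):
            yield self.segs.windows[idx], self.segs.labels[idx]


def balanced_batches(
    segs: SegmentSet, plan: BatchPlan, epoch: int = 0
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """One epoch of balanced batches (see :class:`BalancedBatchStream`)."""
    return BalancedBatchStream(segs, plan).epoch(epoch)
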