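"""Recordings, seizure annotations and bipolar montage handling.

Scalp EEG arrives either referentially (one signal per 10-20 electrode) or
already as longitudinal bipolar derivations such as ``Fp1-F3``.  This module
reads/writes 16-bit EDF, derives bipolar montages as simple electrode
differences, selects the 18-, 4- and single-channel configurations used by
wearable-oriented seizure detectors, and round-trips seizure annotations
through a small JSON dialect (with a read-only parser for CHB-MIT style
``-summary.txt`` files).

Conventions: signals are microvolts; times are seconds from file start;
intervals are half-open ``[onset, offset)``; sample index = floor(t * fs).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    ChannelSelectionError,
    EdfFormatError,
    MontageError,
    SamplingRateError,
)

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "MontageSpec",
    "ChannelSubsetPolicy",
    "STANDARD_18_DERIVATIONS",
    "WEARABLE_4_CHANNELS",
    "read_recording",
    "write_recording",
    "apply_montage",
    "ensure_montaged",
    "select_channels",
    "read_annotations",
    "write_annotations",
]

#: The 18 longitudinal-bipolar derivations of the full double-banana montage,
#: in the conventional printed order.
STANDARD_18_DERIVATIONS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("Fp2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

#: Wearable-candidate channels: two forehead, two behind-the-ear, fixed order.
WEARABLE_4_CHANNELS: tuple[str, ...] = ("Fp1-F3", "Fp2-F4", "P7-O1", "P8-O2")


def _norm_label(label: str) -> str:
    return label.strip().casefold()


@dataclass
class Recording:
    """A multichannel signal block in microvolts.

    Attributes
    ----------
    channel_labels : ordered channel names (electrodes or ``A-B`` derivations)
    fs : sampling rate in Hz
    signal : float array of shape (n_channels, n_samples), microvolts
    start_offset : seconds between the session origin and this file's start
    source_id : identity of the originating file
    """

    channel_labels: list[str]
    fs: float
    signal: np.ndarray
    start_offset: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        n, t = self.signal.shape
        if n != len(self.channel_labels) or n < 1:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n} signal rows"
            )
        if t < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def _label_index(self) -> dict[str, int]:
        # first occurrence wins: CHB-MIT headers repeat labels ("T8-P8-0/-1")
        index: dict[str, int] = {}
        for i, lab in enumerate(self.channel_labels):
            index.setdefault(_norm_label(lab), i)
            # expose "T8-P8-0" additionally as "T8-P8"
            m = re.fullmatch(r"(.+?)-\d", lab.strip())
            if m:
                index.setdefault(_norm_label(m.group(1)), i)
        return index

    def channel(self, label: str) -> np.ndarray:
        idx = self._label_index()
        key = _norm_label(label)
        if key not in idx:
            raise ChannelSelectionError(f"channel {label!r} not in recording")
        return self.signal[idx[key]]


@dataclass(frozen=True)
class SeizureAnnotation:
    """Ordered, non-overlapping seizure intervals ``[onset, offset)`` in seconds."""

    intervals: tuple[tuple[float, float], ...]
    source_id: str = ""

    def __init__(
        self,
        intervals: Iterable[Sequence[float]] = (),
        source_id: str = "",
    ) -> None:
        ivals = sorted((float(a), float(b)) for a, b in intervals)
        for a, b in ivals:
            if not (np.isfinite(a) and np.isfinite(b)):
                raise AnnotationError("non-finite interval bound")
            if a < 0:
                raise AnnotationError(f"negative onset {a}")
            if a >= b:
                raise AnnotationError(f"onset {a} must precede offset {b}")
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise AnnotationError(
                    f"intervals [{a0},{b0}) and [{a1},{b1}) overlap"
                )
        object.__setattr__(self, "intervals", tuple(ivals))
        object.__setattr__(self, "source_id", source_id)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_seizure_s(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def validate_against(self, rec: Recording) -> None:
        """Check every interval lies within the recording extent."""
        for a, b in self.intervals:
            if b > rec.duration_s + 1e-9:
                raise AnnotationError(
                    f"interval [{a},{b}) exceeds recording length "
                    f"{rec.duration_s:.3f}s"
                )


@dataclass(frozen=True)
class MontageSpec:
    """An ordered list of bipolar derivations (anode, cathode)."""

    derivations: tuple[tuple[str, str], ...] = STANDARD_18_DERIVATIONS

    def __post_init__(self) -> None:
        seen = set()
        for name in self.display_names:
            key = _norm_label(name)
            if key in seen:
                raise MontageError(f"duplicate derivation {name!r}")
            seen.add(key)

    @property
    def display_names(self) -> tuple[str, ...]:
        return tuple(f"{a}-{c}" for a, c in self.derivations)

    @classmethod
    def standard_18(cls) -> "MontageSpec":
        return cls(STANDARD_18_DERIVATIONS)


@dataclass(frozen=True)
class ChannelSubsetPolicy:
    """Which channels feed the detector: full montage, four wearable
    candidates, or a single neurologist-designated wearable channel."""

    mode: str  # {"full18", "wearable4", "single"}
    single_channel: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("full18", "wearable4", "single"):
            raise ChannelSelectionError(f"unknown policy mode {self.mode!r}")
        if self.mode == "single":
            if self.single_channel is None:
                raise ChannelSelectionError("single mode requires a channel")
            wanted = _norm_label(self.single_channel)
            if wanted not in {_norm_label(c) for c in WEARABLE_4_CHANNELS}:
                raise ChannelSelectionError(
                    f"{self.single_channel!r} is not one of the four "
                    f"wearable candidates {WEARABLE_4_CHANNELS}"
                )
        elif self.single_channel is not None:
            raise ChannelSelectionError(
                "single_channel only meaningful with mode='single'"
            )


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, expected_fs: float | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Raises :class:`EdfFormatError` for missing/truncated files and
    :class:`SamplingRateError` when ``expected_fs`` is given and differs
    from the file's rate, or channels disagree on rate.
    """
    path = Path(path)
    if not path.exists():
        raise EdfFormatError(f"no such file: {path}")
    if path.stat().st_size < 256:
        raise EdfFormatError(f"truncated or empty EDF header: {path}")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted errors on malformed files
        raise EdfFormatError(f"cannot parse EDF {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise SamplingRateError(
            f"{path} sampled at {fs} Hz, expected {expected_fs} Hz"
        )
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        channel_labels=list(raw.ch_names),
        fs=fs,
        signal=data,
        source_id=path.stem,
    )


def _edf_ascii(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be a positive integer and the duration an
    integral number of seconds (both hold for the 256 Hz recordings this
    package targets); the signal is quantized onto the per-channel
    physical range, i.e. amplitude error is at most half a quantization
    step of that range.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise EdfFormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per channel
    if rec.n_samples % spr != 0:
        raise EdfFormatError("EDF writer requires whole seconds of data")
    n_records = rec.n_samples // spr
    nchan = rec.n_channels

    phys_max = np.maximum(np.abs(rec.signal).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.round((rec.signal - phys_min[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),            # patient id
        _edf_ascii(f"Startdate X X X X {rec.source_id or 'rec'}", 80),
        _edf_ascii("01.01.00", 8),
        _edf_ascii("00.00.00", 8),
        _edf_ascii(256 * (nchan + 1), 8),
        _edf_ascii("", 44),
        _edf_ascii(n_records, 8),
        _edf_ascii(1, 8),                      # record duration, seconds
        _edf_ascii(nchan, 4),
    ])
    fields: list[bytes] = []
    for width, values in [
        (16, rec.channel_labels),
        (80, ["EEG"] * nchan),
        (8, ["uV"] * nchan),
        (8, [f"{v:g}" for v in phys_min]),
        (8, [f"{v:g}" for v in phys_max]),
        (8, [dig_min] * nchan),
        (8, [dig_max] * nchan),
        (80, [""] * nchan),
        (8, [spr] * nchan),
        (32, [""] * nchan),
    ]:
        fields.extend(_edf_ascii(v, width) for v in values)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        # records: for each second, each channel's spr samples contiguously
        blocks = digital.reshape(nchan, n_records, spr)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())


# ---------------------------------------------------------------------------
# Montage and channel selection
# ---------------------------------------------------------------------------

def apply_montage(rec: Recording, montage: MontageSpec | None = None) -> Recording:
    """Derive bipolar channels ``anode - cathode`` from a referential recording.

    Output channel i is ``rec[anode_i] - rec[cathode_i]`` with display name
    ``"anode-cathode"``, in the montage's order.
    """
    montage = montage or MontageSpec.standard_18()
    index = rec._label_index()
    missing = [
        lab
        for pair in montage.derivations
        for lab in pair
        if _norm_label(lab) not in index
    ]
    if missing:
        raise MontageError(f"electrodes missing from recording: {sorted(set(missing))}")
    rows = [
        rec.signal[index[_norm_label(a)]] - rec.signal[index[_norm_label(c)]]
        for a, c in montage.derivations
    ]
    return Recording(
        channel_labels=list(montage.display_names),
        fs=rec.fs,
        signal=np.vstack(rows),
        start_offset=rec.start_offset,
        source_id=rec.source_id,
    )


def ensure_montaged(rec: Recording, montage: MontageSpec | None = None) -> Recording:
    """Return ``rec`` in bipolar form: already-bipolar inputs (all display
    names present) are re-ordered/selected, referential inputs are derived."""
    montage = montage or MontageSpec.standard_18()
    index = rec._label_index()
    names = montage.display_names
    if all(_norm_label(n) in index for n in names):
        rows = [rec.signal[index[_norm_label(n)]] for n in names]
        return Recording(
            channel_labels=list(names),
            fs=rec.fs,
            signal=np.vstack(rows),
            start_offset=rec.start_offset,
            source_id=rec.source_id,
        )
    return apply_montage(rec, montage)


def select_channels(rec: Recording, policy: ChannelSubsetPolicy) -> Recording:
    """Project a montaged recording onto the policy's channel subset."""
    if policy.mode == "full18":
        wanted = list(MontageSpec.standard_18().display_names)
    elif policy.mode == "wearable4":
        wanted = list(WEARABLE_4_CHANNELS)
    else:
        wanted = [policy.single_channel]  # validated by the policy
    index = rec._label_index()
    missing = [n for n in wanted if _norm_label(n) not in index]
    if missing:
        raise ChannelSelectionError(f"channels missing from recording: {missing}")
    rows = [rec.signal[index[_norm_label(n)]] for n in wanted]
    return Recording(
        channel_labels=wanted,
        fs=rec.fs,
        signal=np.vstack(rows),
        start_offset=rec.start_offset,
        source_id=rec.source_id,
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    dialect: str = "json",
    source_id: str | None = None,
) -> SeizureAnnotation:
    """Read seizure annotations.

    ``dialect="json"`` reads the package's own format
    ``{"source_id": str, "intervals": [[onset_s, offset_s], ...]}``.
    ``dialect="chbmit_summary"`` parses a CHB-MIT style ``-summary.txt``;
    ``source_id`` selects the file block (required when several are present).
    """
    path = Path(path)
    if dialect == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return SeizureAnnotation(
            intervals=payload.get("intervals", []),
            source_id=payload.get("source_id", source_id or path.stem),
        )
    if dialect == "chbmit_summary":
        return _parse_chbmit_summary(path, source_id)
    raise AnnotationError(f"unknown annotation dialect {dialect!r}")


def _parse_chbmit_summary(path: Path, source_id: str | None) -> SeizureAnnotation:
    text = Path(path).read_text()
    blocks: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    starts: list[float] = []
    ends: list[float] = []
    for line in text.splitlines():
        m = re.match(r"File Name:\s*(\S+)", line)
        if m:
            if current is not None:
                blocks[current] = list(zip(starts, ends))
            current = Path(m.group(1)).stem
            starts, ends = [], []
            continue
        m = re.match(r"Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)", line)
        if m:
            starts.append(float(m.group(1)))
            continue
        m = re.match(r"Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)", line)
        if m:
            ends.append(float(m.group(1)))
    if current is not None:
        blocks[current] = list(zip(starts, ends))
    if not blocks:
        raise AnnotationError(f"no file blocks found in summary {path}")
    if source_id is None:
        if len(blocks) > 1:
            raise AnnotationError(
                "summary describes several files; pass source_id to pick one"
            )
        source_id = next(iter(blocks))
    key = source_id if source_id in blocks else Path(source_id).stem
    if key not in blocks:
        raise AnnotationError(f"{source_id!r} not found in summary {path}")
    return SeizureAnnotation(intervals=blocks[key], source_id=key)


def write_annotations(ann: SeizureAnnotation, path: str | Path) -> None:
    """Write annotations in the JSON dialect (lossless round-trip)."""
    payload = {
        "source_id": ann.source_id,
        "intervals": [[a, b] for a, b in ann.intervals],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
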