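"""EEG segment I/O, band-pass preprocessing, and ictal/interictal windowing.

Two input dialects are supported:

* Bonn-style ASCII: one sample per line, single channel, nominally
  173.61 Hz and 4,097 samples per segment (23.6 s).
* EDF recordings (continuous, uniform per-channel rate) with a sidecar
  annotation CSV ``recording,start_s,end_s`` giving seizure events in
  seconds from recording start.

Windowing follows the usual clinical bookkeeping: ictal samples come
from a 2-s sliding window with 50% overlap inside each annotated
seizure, interictal epochs are non-overlapping 2-s cuts taken at least
4 h away from every seizure. Window intervals are half-open
``[start, start + win_s)`` with 0-based sample indexing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from ._edf import peek_edf_header

__all__ = [
    "LABELS",
    "EegSegment",
    "FilterSpec",
    "SeizureAnnotation",
    "read_bonn_segment",
    "write_bonn_segment",
    "read_edf_recording",
    "read_annotation_csv",
    "write_annotation_csv",
    "bandpass_filter",
    "extract_ictal_windows",
    "extract_interictal_epochs",
]

#: Allowed segment class labels.
LABELS = ("ictal", "interictal", "healthy", "unlabeled")


@dataclass
class EegSegment:
    """One fixed-length EEG window: channels x timepoints, microvolts."""

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    label: str = "unlabeled"
    origin: str = ""

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.shape[1] < 2:
            raise ValueError("segment needs at least 2 timepoints")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match sample rows")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    The magnitude response of the order-``n`` prototype is
    ``|H(jw)|^2 = 1 / (1 + (w/w_c)^(2n))`` at each cutoff; with
    ``zero_phase`` the filter is applied forward and backward, squaring
    the magnitude response and cancelling phase distortion.
    """

    low_hz: float = 0.5
    high_hz: float = 60.0
    order: int = 5
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def validate_against(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist rate {fs / 2} Hz"
            )


@dataclass
class SeizureAnnotation:
    """Seizure events as (start_s, end_s) from recording start, sorted."""

    events: list[tuple[float, float]]
    recording_length_s: float

    def __post_init__(self):
        evs = [(float(a), float(b)) for a, b in self.events]
        evs.sort()
        for a, b in evs:
            if not (0 <= a < b <= self.recording_length_s):
                raise ValueError(f"event ({a}, {b}) outside [0, {self.recording_length_s}]")
        for (a0, b0), (a1, b1) in zip(evs, evs[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping events ({a0},{b0}) and ({a1},{b1})")
        self.events = evs


def read_bonn_segment(path, fs: float = 173.61) -> EegSegment:
    """Read a Bonn-style ASCII segment: one numeric sample per line."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise ValueError(f"{path}: non-numeric sample at line {lineno}: {s!r}") from None
    if not values:
        raise ValueError(f"{path}: empty segment file")
    return EegSegment(
        samples=np.asarray(values)[None, :],
        fs=fs,
        channel_names=["ch0"],
        label="unlabeled",
        origin=str(path),
    )


def write_bonn_segment(path, samples_1d) -> None:
    """Write a single-channel segment in Bonn ASCII (one sample per line)."""
    x = np.asarray(samples_1d, dtype=float).ravel()
    with open(path, "w") as fh:
        for v in x:
            fh.write(f"{v:.6f}\n")


def read_edf_recording(path, channels: list[str] | None = None) -> EegSegment:
    """Read a continuous EDF recording into a multi-channel segment (µV).

    Only plain continuous EDF with a single per-channel sampling rate is
    supported; mixed-rate files and EDF+D discontinuous files are
    rejected rather than silently resampled.
    """
    import mne

    hdr = peek_edf_header(path)
    spr = hdr["samples_per_record"]
    # EDF annotation channels carry their own rate; ignore them in the check
    data_spr = [s for lbl, s in zip(hdr["labels"], spr) if "EDF Annotations" not in lbl]
    if len(set(data_spr)) > 1:
        raise ValueError(
            f"{path}: unequal per-channel sampling rates {sorted(set(data_spr))}; "
            "only uniform-rate continuous EDF is supported"
        )

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in available]
        if missing:
            raise ValueError(
                f"{path}: channel(s) {missing} not found; available: {available}"
            )
        raw = raw.pick(channels)
        names = list(channels)
    else:
        names = available
    data = raw.get_data() * 1e6  # mne returns volts for uV-calibrated channels
    return EegSegment(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        label="unlabeled",
        origin=str(path),
    )


def read_annotation_csv(path, recording: str | None = None,
                        recording_length_s: float | None = None) -> SeizureAnnotation:
    """Read a ``recording,start_s,end_s`` sidecar CSV.

    If ``recording`` is given, rows are filtered to that recording name.
    ``recording_length_s`` must be supplied (the CSV does not carry it);
    it defaults to the largest end time if omitted.
    """
    df = pd.read_csv(path)
    required = {"recording", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    if recording is not None:
        df = df[df["recording"] == recording]
    events = list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
    if recording_length_s is None:
        recording_length_s = max((e for _, e in events), default=0.0)
    return SeizureAnnotation(events=events, recording_length_s=recording_length_s)


def write_annotation_csv(path, ann: SeizureAnnotation, recording: str) -> None:
    df = pd.DataFrame(
        [(recording, a, b) for a, b in ann.events],
        columns=["recording", "start_s", "end_s"],
    )
    df.to_csv(path, index=False)


def bandpass_filter(seg: EegSegment, spec: FilterSpec = FilterSpec()) -> EegSegment:
    """Apply the Butterworth band-pass channel-wise; shape/fs/label preserved."""
    spec.validate_against(seg.fs)
    sos = _sig.butter(spec.order, [spec.low_hz, spec.high_hz],
                      btype="bandpass", fs=seg.fs, output="sos")
    if spec.zero_phase:
        out = _sig.sosfiltfilt(sos, seg.samples, axis=1)
    else:
        out = _sig.sosfilt(sos, seg.samples, axis=1)
    return replace(seg, samples=np.ascontiguousarray(out))


def _slice_segment(rec: EegSegment, t0: float, win_s: float, label: str) -> EegSegment:
    i0 = int(round(t0 * rec.fs))
    n = int(round(win_s * rec.fs))
    return EegSegment(
        samples=rec.samples[:, i0:i0 + n].copy(),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        label=label,
        origin=f"{rec.origin}@{t0:g}s",
    )


def extract_ictal_windows(rec: EegSegment, ann: SeizureAnnotation,
                          win_s: float = 2.0, step_s: float = 1.0) -> list[EegSegment]:
    """Sliding ictal windows inside each seizure event (default 2 s, 1-s step).

    Seizure durations are treated as whole seconds: fractional event ends
    are floored, so an event of integer duration L yields
    ``floor((L - win_s)/step_s) + 1`` windows and never crosses its own
    boundary.
    """
    n_win = win_s * rec.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("win_s * fs must be an integer number of samples")
    out: list[EegSegment] = []
    for a, b in ann.events:
        dur = math.floor(b - a)
        if dur < win_s:
            warnings.warn(f"seizure event ({a}, {b}) shorter than {win_s} s window; skipped")
            continue
        k = int(math.floor((dur - win_s) / step_s)) + 1
        for i in range(k):
            out.append(_slice_segment(rec, a + i * step_s, win_s, "ictal"))
    return out


def interictal_regions(ann: SeizureAnnotation, gap_s: float) -> list[tuple[float, float]]:
    """Intervals at least ``gap_s`` from every seizure boundary, clipped to the recording."""
    blocked = [(max(0.0, a - gap_s), min(ann.recording_length_s, b + gap_s))
               for a, b in ann.events]
    regions = []
    cursor = 0.0
    for a, b in blocked:
        if a > cursor:
            regions.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < ann.recording_length_s:
        regions.append((cursor, ann.recording_length_s))
    return regions


def extract_interictal_epochs(rec: EegSegment, ann: SeizureAnnotation,
                              win_s: float = 2.0, gap_s: float = 14400.0) -> list[EegSegment]:
    """Non-overlapping interictal epochs taken >= ``gap_s`` from every seizure."""
    n_win = win_s * rec.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("win_s * fs must be an integer number of samples")
    out: list[EegSegment] = []
    for a, b in interictal_regions(ann, gap_s):
        k = int(math.floor((b - a) / win_s))
        for i in range(k):
            out.append(_slice_segment(rec, a + i * win_s, win_s, "interictal"))
    if not out:
        warnings.warn(f"no interictal region at least {gap_s} s away from every seizure")
    return out
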