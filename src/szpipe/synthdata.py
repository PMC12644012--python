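"""Deterministic generator of EEG-like two-class signals and fixtures.

The generator emulates the contrast that drives seizure detectors:

* interictal activity — low-amplitude broadband noise with a 0.5–30 Hz
  emphasis (white or pink source), RMS ``amp_interictal`` µV;
* ictal activity — the same background plus a superimposed discharge:
  a ~3 Hz spike-wave rhythm (fundamental + two harmonics + one sharp
  spike per cycle) mixed with a broadband high-frequency component and
  a beta-band (~18-24 Hz) recruiting rhythm, mirroring the increased
  wideband activity and low-voltage fast rhythms of seizure EEG. The
  discharge RMS is ``sqrt(amp_ictal^2 - amp_interictal^2)`` so the
  total RMS is ``amp_ictal`` and the two classes coincide as
  ``amp_ictal -> amp_interictal`` — class separability is a dial, not
  a constant.

Generation is a pure function of :class:`SynthConfig`: every segment
draws from a counter-based sub-seed ``(seed, class, index)``, so
datasets are reproducible and order-independent. The module also writes
Bonn-style ASCII segments, EDF recordings and annotation CSVs so the
I/O layer can be exercised without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from ._edf import write_edf
from .signal_io import EegSegment, SeizureAnnotation, write_annotation_csv

__all__ = [
    "SynthConfig",
    "gen_interictal_signal",
    "gen_ictal_signal",
    "gen_dataset",
    "gen_annotated_recording",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic two-class EEG corpus.

    Defaults mirror the imbalanced single-channel setting used
    throughout the test-bench: 2-s windows at 256 Hz, roughly 60:1
    interictal:ictal, a 3 Hz spike-wave rhythm, and a 6x amplitude
    contrast (10 vs 60 µV RMS).
    """

    fs: float = 256.0
    win_s: float = 2.0
    n_interictal: int = 1000
    n_ictal: int = 17
    n_channels: int = 1
    ictal_freq_hz: float = 3.0
    amp_interictal: float = 10.0
    amp_ictal: float = 60.0
    noise_model: str = "white"
    seed: int = 0

    def __post_init__(self):
        if self.n_interictal < 0 or self.n_ictal < 0:
            raise ValueError("counts must be non-negative")
        if self.amp_ictal <= self.amp_interictal:
            raise ValueError("amp_ictal must exceed amp_interictal")
        n = self.fs * self.win_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * win_s must be an integer sample count")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")

    @property
    def imbalance_ratio(self) -> float:
        """Emulated interictal:ictal imbalance (e.g. ~59:1 at the defaults)."""
        return self.n_interictal / max(self.n_ictal, 1)


def _noise(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Band-limited (0.5-30 Hz) unit-RMS background noise, one channel."""
    x = rng.standard_normal(n + 2 * int(cfg.fs))  # pad a second each side for the filter
    if cfg.noise_model == "pink":
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(len(x), 1 / cfg.fs)
        spec[1:] /= np.sqrt(f[1:])
        x = np.fft.irfft(spec, n=len(x))
    sos = _sig.butter(4, [0.5, min(30.0, 0.45 * cfg.fs)], btype="bandpass",
                      fs=cfg.fs, output="sos")
    x = _sig.sosfiltfilt(sos, x)[int(cfg.fs):int(cfg.fs) + n]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _background(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.amp_interictal == 0:
        return np.zeros(n)
    return cfg.amp_interictal * _noise(cfg, rng, n)


#: amplitude fraction of broadband noise inside the non-beta part of the discharge
_BROADBAND_FRAC = 0.45
#: amplitude fraction of the beta recruiting rhythm in the discharge
_BETA_FRAC = 0.3


def _spike_wave(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS ictal discharge: spike-wave + broadband + beta rhythm.

    Three stereotyped ingredients of seizure EEG: the ``ictal_freq_hz``
    spike-wave rhythm (fundamental + two harmonics + one sharp ~20 ms
    transient per cycle), wide-band (0.5 Hz to 0.45*fs) noise carrying
    the increased high-frequency content of ictal activity, and a
    low-voltage fast "recruiting" oscillation drawn from 18-24 Hz.
    """
    t = np.arange(n) / cfg.fs
    f0 = cfg.ictal_freq_hz
    phase = rng.uniform(0, 2 * np.pi)
    w = (1.5 * np.sin(2 * np.pi * f0 * t + phase)
         + 0.5 * np.sin(2 * np.pi * 2 * f0 * t + 2 * phase)
         + 0.25 * np.sin(2 * np.pi * 3 * f0 * t + 3 * phase))
    # one sharp transient per cycle (Gaussian bump, ~20 ms wide)
    cycle = 1.0 / f0
    width = 0.02
    t0 = rng.uniform(0, cycle)
    centers = np.arange(t0, t[-1] + cycle, cycle)
    spikes = np.zeros(n)
    for c in centers:
        spikes += np.exp(-0.5 * ((t - c) / width) ** 2)
    w = w + 1.5 * spikes
    w /= np.sqrt(np.mean(w ** 2))
    pad = int(cfg.fs)
    b = rng.standard_normal(n + 2 * pad)
    sos = _sig.butter(4, [0.5, 0.45 * cfg.fs], btype="bandpass", fs=cfg.fs,
                      output="sos")
    b = _sig.sosfiltfilt(sos, b)[pad:pad + n]
    b /= np.sqrt(np.mean(b ** 2))
    f_beta = rng.uniform(18.0, 24.0)
    beta = np.sin(2 * np.pi * f_beta * t + rng.uniform(0, 2 * np.pi))
    beta /= np.sqrt(np.mean(beta ** 2))
    s = np.sqrt(1 - _BETA_FRAC ** 2)
    mix = (s * np.sqrt(1 - _BROADBAND_FRAC ** 2) * w
           + s * _BROADBAND_FRAC * b
           + _BETA_FRAC * beta)
    return mix / np.sqrt(np.mean(mix ** 2))


def gen_interictal_signal(cfg: SynthConfig, rng: np.random.Generator) -> EegSegment:
    """One interictal window: band-limited noise at RMS ~ amp_interictal."""
    n = int(round(cfg.fs * cfg.win_s))
    data = np.vstack([_background(cfg, rng, n) for _ in range(cfg.n_channels)])
    return EegSegment(samples=data, fs=cfg.fs, label="interictal", origin="synth:interictal")


def gen_ictal_signal(cfg: SynthConfig, rng: np.random.Generator) -> EegSegment:
    """One ictal window: background + spike-wave rhythm, total RMS ~ amp_ictal."""
    n = int(round(cfg.fs * cfg.win_s))
    rhythm_rms = np.sqrt(max(cfg.amp_ictal ** 2 - cfg.amp_interictal ** 2, 0.0))
    chans = []
    for _ in range(cfg.n_channels):
        chans.append(_background(cfg, rng, n) + rhythm_rms * _spike_wave(cfg, rng, n))
    return EegSegment(samples=np.vstack(chans), fs=cfg.fs, label="ictal",
                      origin="synth:ictal")


def _sub_rng(cfg: SynthConfig, klass: int, index: int) -> np.random.Generator:
    # counter-based sub-seeding: order-independent per-segment streams
    return np.random.default_rng([int(cfg.seed), klass, index])


def gen_dataset(cfg: SynthConfig) -> list[EegSegment]:
    """Seeded, shuffled dataset with the exact requested class counts."""
    if cfg.n_interictal == 0 and cfg.n_ictal == 0:
        raise ValueError("at least one class count must be positive")
    segs = [gen_interictal_signal(cfg, _sub_rng(cfg, 0, i))
            for i in range(cfg.n_interictal)]
    segs += [gen_ictal_signal(cfg, _sub_rng(cfg, 1, i)) for i in range(cfg.n_ictal)]
    shuffle_rng = np.random.default_rng([int(cfg.seed), 2, 0])
    order = shuffle_rng.permutation(len(segs))
    return [segs[i] for i in order]


def gen_annotated_recording(cfg: SynthConfig, n_seizures: int,
                            durations_s: list[int], total_s: float,
                            edf_path=None, csv_path=None,
                            recording_name: str = "synthetic"):
    """Continuous recording with seizure intervals carrying the ictal waveform.

    Seizures are spread out with equal inter-event gaps. Returns
    ``(EegSegment, SeizureAnnotation)``; when ``edf_path``/``csv_path``
    are given the recording and its sidecar annotation CSV are written
    to disk (EDF needs an integer sampling rate).
    """
    if len(durations_s) != n_seizures:
        raise ValueError("durations_s length must equal n_seizures")
    durations = [int(d) for d in durations_s]
    total_busy = sum(durations)
    gap = (total_s - total_busy) / (n_seizures + 1) if n_seizures else total_s
    if n_seizures and gap < 1.0:
        raise ValueError(
            f"cannot pack {n_seizures} seizures totalling {total_busy} s into {total_s} s"
        )
    n_total = int(round(total_s * cfg.fs))
    rng = _sub_rng(cfg, 3, 0)
    data = np.vstack([_background(cfg, rng, n_total) for _ in range(cfg.n_channels)])

    events = []
    cursor = gap
    rhythm_rms = np.sqrt(max(cfg.amp_ictal ** 2 - cfg.amp_interictal ** 2, 0.0))
    for j, dur in enumerate(durations):
        start = float(np.floor(cursor))
        end = start + dur
        i0, i1 = int(round(start * cfg.fs)), int(round(end * cfg.fs))
        for c in range(cfg.n_channels):
            data[c, i0:i1] += rhythm_rms * _spike_wave(cfg, _sub_rng(cfg, 4, j), i1 - i0)
        events.append((start, end))
        cursor = end + gap
    rec = EegSegment(samples=data, fs=cfg.fs, label="unlabeled",
                     origin=recording_name)
    ann = SeizureAnnotation(events=events, recording_length_s=total_s)
    if edf_path is not None:
        write_edf(edf_path, data, int(cfg.fs), rec.channel_names)
    if csv_path is not None:
        write_annotation_csv(csv_path, ann, recording_name)
    return rec, ann
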