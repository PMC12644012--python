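"""Five-level db4 DWT sub-band decomposition and the per-band feature set.

Each preprocessed segment channel is decomposed into six coefficient
sequences (A5, D5, D4, D3, D2, D1) whose nominal frequency bands halve
dyadically: D_k spans (fs/2^(k+1), fs/2^k] and A5 spans (0, fs/2^6].
From every sub-band four scalars are extracted:

* MAV  — mean absolute value, (1/N) sum |x_i|
* STD  — population standard deviation (divisor N)
* PSD  — total band power, the Parseval-consistent periodogram sum,
         equal to mean(x^2)
* FuEn — fuzzy entropy of the coefficient sequence (Chen-style:
         mean-centred m-templates, Chebyshev distance, exponential
         membership exp(-(d/r)^grad))

Features are computed on the coefficient sequences directly rather
than on band-reconstructed signals; this is the cheaper convention and
preserves the class-separation structure the classifier consumes.
A single-channel segment therefore yields 6 bands x 4 features = 24
columns; a 23-channel segment yields 552.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import pywt
from scipy import signal as _sig

from .signal_io import EegSegment

__all__ = [
    "BAND_ORDER",
    "FEATURE_ORDER",
    "SubbandDecomposition",
    "FuzzyEnSpec",
    "ColumnDesc",
    "FeatureTable",
    "MinMaxMap",
    "dwt_decompose",
    "reconstruct",
    "mav",
    "population_std",
    "band_power_psd",
    "fuzzy_entropy",
    "build_feature_table",
    "fit_normalizer",
    "apply_normalizer",
]

#: Band order used everywhere (low to high frequency).
BAND_ORDER = ("A5", "D5", "D4", "D3", "D2", "D1")
#: Feature order within each band.
FEATURE_ORDER = ("MAV", "STD", "PSD", "FuEn")

PROVENANCE = ("original", "centroid", "synthetic")


@dataclass
class SubbandDecomposition:
    """Six DWT coefficient sequences with dyadic band edges in Hz."""

    bands: dict[str, np.ndarray]
    band_edges_hz: dict[str, tuple[float, float]]
    wavelet_name: str
    levels: int
    n_samples: int  # original signal length, needed for exact reconstruction


class FuzzyEnSpec(NamedTuple):
    """Fuzzy-entropy parameters: embedding dim, tolerance (fraction of SD), exponent."""

    m: int = 2
    r: float = 0.2
    grad: float = 2.0


def dwt_decompose(seg_channel, fs: float, wavelet: str = "db4",
                  levels: int = 5) -> SubbandDecomposition:
    """Multi-level DWT of a 1-D sequence into A{levels} + D{levels}..D1."""
    x = np.asarray(seg_channel, dtype=float).ravel()
    w = pywt.Wavelet(wavelet)
    min_len = (w.dec_len - 1) * 2 ** levels
    if pywt.dwt_max_level(len(x), w) < levels:
        raise ValueError(
            f"input of length {len(x)} too short for {levels}-level {wavelet} "
            f"decomposition; need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(x, w, level=levels)
    names = [f"A{levels}"] + [f"D{k}" for k in range(levels, 0, -1)]
    bands = dict(zip(names, coeffs))
    edges = {f"A{levels}": (0.0, fs / 2 ** (levels + 1))}
    for k in range(levels, 0, -1):
        edges[f"D{k}"] = (fs / 2 ** (k + 1), fs / 2 ** k)
    return SubbandDecomposition(
        bands=bands, band_edges_hz=edges, wavelet_name=wavelet,
        levels=levels, n_samples=len(x),
    )


def reconstruct(dec: SubbandDecomposition) -> np.ndarray:
    """Inverse DWT from all coefficient sequences (perfect reconstruction)."""
    names = [f"A{dec.levels}"] + [f"D{k}" for k in range(dec.levels, 0, -1)]
    coeffs = [dec.bands[n] for n in names]
    x = pywt.waverec(coeffs, dec.wavelet_name)
    return x[: dec.n_samples]


def mav(x) -> float:
    """Mean absolute value, (1/N) sum |x_i|."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("mav of empty sequence")
    return float(np.mean(np.abs(x)))


def population_std(x) -> float:
    """Population standard deviation: sqrt((1/N) sum (x_i - mean)^2), divisor N."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("population_std of empty sequence")
    return float(np.std(x, ddof=0))


def band_power_psd(x, fs: float = 1.0) -> float:
    """Total power via one-sided periodogram summation (= mean of squared samples).

    With a boxcar window, no detrending and 'spectrum' scaling the
    periodogram bins satisfy Parseval's identity, so their sum equals
    ``mean(x**2)`` to machine precision.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("band_power_psd needs at least 2 samples")
    _, pxx = _sig.periodogram(x, fs=fs, window="boxcar", detrend=False,
                              scaling="spectrum")
    return float(pxx.sum())


def fuzzy_entropy(x, spec: FuzzyEnSpec = FuzzyEnSpec()) -> float:
    """Fuzzy entropy: ln(phi_m) - ln(phi_{m+1}).

    ``phi_d`` is the mean pairwise similarity (self-matches excluded) of
    mean-centred d-length templates under the exponential membership
    ``exp(-(d_cheb / r_abs)**grad)`` with ``r_abs = r * population SD``.
    A constant input short-circuits to 0 (all distances vanish).
    """
    x = np.asarray(x, dtype=float).ravel()
    m, r, grad = spec
    if m < 1 or r <= 0 or grad <= 0:
        raise ValueError("FuzzyEnSpec requires m >= 1, r > 0, grad > 0")
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need length > m + 1 = {m + 1}, got {n}")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r_abs = r * sd

    def phi(dim: int) -> float:
        n_t = n - m  # same template count for both dimensions
        t = np.lib.stride_tricks.sliding_window_view(x, dim)[:n_t]
        t = t - t.mean(axis=1, keepdims=True)
        d = np.max(np.abs(t[:, None, :] - t[None, :, :]), axis=2)
        sim = np.exp(-((d / r_abs) ** grad))
        total = sim.sum() - np.trace(sim)
        return total / (n_t * (n_t - 1))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


_FEATURE_FUNCS = {
    "MAV": lambda c, fs, fz: mav(c),
    "STD": lambda c, fs, fz: population_std(c),
    "PSD": lambda c, fs, fz: band_power_psd(c, fs),
    "FuEn": lambda c, fs, fz: fuzzy_entropy(c, fz),
}


class ColumnDesc(NamedTuple):
    channel: str
    band: str
    feature: str

    def __str__(self) -> str:
        return f"{self.channel}|{self.band}|{self.feature}"


@dataclass
class FeatureTable:
    """N x F feature matrix with column descriptors, labels and provenance."""

    values: np.ndarray
    columns: list[ColumnDesc]
    labels: np.ndarray
    provenance: np.ndarray
    norm_state: str = "raw"
    role: str = "unsplit"  # 'unsplit' | 'train' | 'test'

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        self.provenance = np.asarray(self.provenance)
        n, f = self.values.shape
        if len(self.columns) != f:
            raise ValueError("column descriptor count does not match matrix width")
        if len(set(self.columns)) != f:
            raise ValueError("duplicate column descriptors")
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("labels/provenance length does not match row count")
        if self.norm_state not in ("raw", "unit_interval"):
            raise ValueError("norm_state must be 'raw' or 'unit_interval'")
        bad = set(self.provenance) - set(PROVENANCE)
        if bad:
            raise ValueError(f"unknown provenance values {bad}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))

    def subset(self, rows, role: str | None = None) -> "FeatureTable":
        rows = np.asarray(rows)
        return FeatureTable(
            values=self.values[rows].copy(),
            columns=list(self.columns),
            labels=self.labels[rows].copy(),
            provenance=self.provenance[rows].copy(),
            norm_state=self.norm_state,
            role=role if role is not None else self.role,
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        """CSV with 'channel|band|feature' headers + JSON sidecar for metadata."""
        df = pd.DataFrame(self.values, columns=[str(c) for c in self.columns])
        df.to_csv(path, index=False)
        side = {
            "labels": self.labels.tolist(),
            "provenance": self.provenance.tolist(),
            "norm_state": self.norm_state,
            "role": self.role,
        }
        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(side, fh)

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "FeatureTable":
        df = pd.read_csv(path)
        cols = [ColumnDesc(*c.split("|")) for c in df.columns]
        if sidecar_path is None:
            sidecar_path = str(path) + ".json"
        with open(sidecar_path) as fh:
            side = json.load(fh)
        return cls(
            values=df.to_numpy(dtype=float),
            columns=cols,
            labels=np.asarray(side["labels"]),
            provenance=np.asarray(side["provenance"]),
            norm_state=side["norm_state"],
            role=side.get("role", "unsplit"),
        )


def build_feature_table(segments: list[EegSegment],
                        fuzzy_spec: FuzzyEnSpec = FuzzyEnSpec(),
                        wavelet: str = "db4", levels: int = 5) -> FeatureTable:
    """Assemble the N x (channels * 24) raw feature table, row order = input order."""
    if not segments:
        raise ValueError("no segments")
    fs = segments[0].fs
    nch = segments[0].n_channels
    names = segments[0].channel_names
    for s in segments:
        if s.n_channels != nch:
            raise ValueError("segments have heterogeneous channel counts")
        if abs(s.fs - fs) > 1e-9:
            raise ValueError("segments have heterogeneous sampling rates")

    columns = [ColumnDesc(ch, band, feat)
               for ch in names for band in BAND_ORDER for feat in FEATURE_ORDER]
    rows = np.empty((len(segments), len(columns)))
    for i, seg in enumerate(segments):
        j = 0
        for c in range(nch):
            dec = dwt_decompose(seg.samples[c], fs, wavelet=wavelet, levels=levels)
            for band in BAND_ORDER:
                coeff = dec.bands[band]
                for feat in FEATURE_ORDER:
                    rows[i, j] = _FEATURE_FUNCS[feat](coeff, fs, fuzzy_spec)
                    j += 1
    labels = np.asarray([s.label for s in segments])
    provenance = np.asarray(["original"] * len(segments))
    return FeatureTable(values=rows, columns=columns, labels=labels,
                        provenance=provenance, norm_state="raw")


@dataclass
class MinMaxMap:
    """Per-column (min, max) fitted on training rows only."""

    columns: list[ColumnDesc]
    mins: np.ndarray
    maxs: np.ndarray


def fit_normalizer(train: FeatureTable) -> MinMaxMap:
    """Fit per-column min/max on the (training) rows of ``train``."""
    mins = train.values.min(axis=0)
    maxs = train.values.max(axis=0)
    n_const = int(np.sum(maxs - mins == 0))
    if n_const:
        warnings.warn(f"{n_const} constant feature column(s); they will map to 0")
    return MinMaxMap(columns=list(train.columns), mins=mins, maxs=maxs)


def apply_normalizer(table: FeatureTable, mm: MinMaxMap) -> FeatureTable:
    """Map to [0, 1] on the fitted range; out-of-range values are NOT clipped."""
    if list(table.columns) != list(mm.columns):
        raise ValueError("normalizer columns do not match table columns")
    span = mm.maxs - mm.mins
    scale = np.where(span > 0, 1.0 / np.where(span > 0, span, 1.0), 0.0)
    vals = (table.values - mm.mins) * scale
    return FeatureTable(values=vals, columns=list(table.columns),
                        labels=table.labels.copy(), provenance=table.provenance.copy(),
                        norm_state="unit_interval", role=table.role)
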