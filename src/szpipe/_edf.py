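"""Minimal EDF (European Data Format) writer and header peek.

Supports only what the package needs: continuous recordings, one
uniform integer sampling rate across channels, 1-second data records,
16-bit samples, physical unit microvolts. Reading full EDF files is
delegated to :mod:`mne`; this module exists because the synthetic-data
generator must *write* EDF fixtures, and so that unequal per-channel
rates can be rejected before mne silently resamples them.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["write_edf", "peek_edf_header"]

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(buf: io.BytesIO, value, width: int) -> None:
    s = str(value)[:width].ljust(width)
    buf.write(s.encode("ascii"))


def write_edf(path, data_uv: np.ndarray, fs: int, channel_names) -> None:
    """Write ``data_uv`` (channels x timepoints, microvolts) as EDF.

    ``fs`` must be a positive integer and the number of timepoints a
    multiple of ``fs`` (whole 1-second records).
    """
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2:
        raise ValueError("data must be 2-D (channels x timepoints)")
    fs_i = int(fs)
    if fs_i != fs or fs_i <= 0:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    nch, nt = data_uv.shape
    if len(channel_names) != nch:
        raise ValueError("channel_names length does not match data")
    n_rec, rem = divmod(nt, fs_i)
    if rem or n_rec == 0:
        raise ValueError("timepoints must be a positive multiple of fs (1-s records)")

    pmin = data_uv.min(axis=1)
    pmax = data_uv.max(axis=1)
    pmax = np.where(pmax - pmin < 1e-9, pmin + 1.0, pmax)
    # EDF stores physical min/max as 8-char ASCII; quantize against the
    # values actually written so the round trip is consistent.
    pmin_s = [f"{v:.4f}"[:8] for v in pmin]
    pmax_s = [f"{v:.4f}"[:8] for v in pmax]
    pmin_q = np.array([float(s) for s in pmin_s])
    pmax_q = np.array([float(s) for s in pmax_s])
    gain = (pmax_q - pmin_q) / (_DIG_MAX - _DIG_MIN)

    hdr = io.BytesIO()
    _field(hdr, "0", 8)                            # version
    _field(hdr, "X X X X", 80)                     # patient id (anonymous)
    _field(hdr, "Startdate 01-JAN-2000 X X X", 80)  # recording id
    _field(hdr, "01.01.00", 8)                     # start date
    _field(hdr, "00.00.00", 8)                     # start time
    _field(hdr, 256 + 256 * nch, 8)                # header bytes
    _field(hdr, "", 44)                            # reserved (plain EDF)
    _field(hdr, n_rec, 8)
    _field(hdr, "1", 8)                            # record duration, seconds
    _field(hdr, nch, 4)
    for nm in channel_names:
        _field(hdr, nm, 16)
    for _ in range(nch):
        _field(hdr, "AgAgCl electrode", 80)
    for _ in range(nch):
        _field(hdr, "uV", 8)
    for s in pmin_s:
        _field(hdr, s, 8)
    for s in pmax_s:
        _field(hdr, s, 8)
    for _ in range(nch):
        _field(hdr, _DIG_MIN, 8)
    for _ in range(nch):
        _field(hdr, _DIG_MAX, 8)
    for _ in range(nch):
        _field(hdr, "", 80)
    for _ in range(nch):
        _field(hdr, fs_i, 8)                       # samples per record
    for _ in range(nch):
        _field(hdr, "", 32)

    dig = np.round((data_uv - pmin_q[:, None]) / gain[:, None]) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            sl = slice(r * fs_i, (r + 1) * fs_i)
            for c in range(nch):
                fh.write(dig[c, sl].tobytes())


def peek_edf_header(path) -> dict:
    """Read the fixed-size EDF header fields needed for dialect checks.

    Returns a dict with ``n_channels``, ``n_records``, ``record_duration_s``,
    ``labels`` and ``samples_per_record`` (per channel).
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_rec = int(fixed[236:244].decode("ascii").strip())
        dur = float(fixed[244:252].decode("ascii").strip())
        nch = int(fixed[252:256].decode("ascii").strip())
        var = fh.read(256 * nch)
        if len(var) < 256 * nch:
            raise ValueError(f"{path}: truncated EDF signal header")
    labels = [var[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(nch)]
    # samples-per-record block sits after labels(16) transducer(80) unit(8)
    # physmin(8) physmax(8) digmin(8) digmax(8) prefilter(80) = offset 216*nch
    off = 216 * nch
    spr = [int(var[off + 8 * i:off + 8 * (i + 1)].decode("ascii").strip()) for i in range(nch)]
    return {
        "n_channels": nch,
        "n_records": n_rec,
        "record_duration_s": dur,
        "labels": labels,
        "samples_per_record": spr,
    }
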