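"""Minimal EDF (European Data Format) writer.

Only what the cohort exporter needs: one data record, 16-bit samples,
microvolt physical dimension. Reading EDF goes through :mod:`mne`; this
writer exists because no pre-installed package exports EDF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DIGITAL_MIN = -32768
DIGITAL_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in ("%g", "%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str] | tuple[str, ...],
) -> None:
    """Write ``data`` (channels x samples, microvolts) as a single-record EDF file.

    Each channel is linearly mapped onto the full 16-bit digital range using
    its own physical min/max, so the round-trip error is bounded by one
    digital quantization step per channel.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    duration = n_samp / fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax <= pmin
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b""
    header += _field("0", 8)                      # version
    header += _field("X X X X", 80)               # patient id
    header += _field("Startdate X X X X", 80)     # recording id
    header += _field("01.01.00", 8)               # start date
    header += _field("00.00.00", 8)               # start time
    header += _field(str(256 * (n_ch + 1)), 8)    # header bytes
    header += _field("", 44)                      # reserved
    header += _field("1", 8)                      # number of data records
    header += _num(duration, 8)                   # record duration (s)
    header += _field(str(n_ch), 4)                # number of signals

    for vals in (
        [_field(name, 16) for name in channel_names],
        [_field("", 80)] * n_ch,                            # transducer
        [_field("uV", 8)] * n_ch,                           # physical dimension
        [_num(pmin[i], 8) for i in range(n_ch)],
        [_num(pmax[i], 8) for i in range(n_ch)],
        [_field(str(DIGITAL_MIN), 8)] * n_ch,
        [_field(str(DIGITAL_MAX), 8)] * n_ch,
        [_field("", 80)] * n_ch,                            # prefiltering
        [_field(str(n_samp), 8)] * n_ch,                    # samples per record
        [_field("", 32)] * n_ch,
    ):
        header += b"".join(vals)

    # physical->digital linear map, rounded to nearest integer
    scale = (DIGITAL_MAX - DIGITAL_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + DIGITAL_MIN)
    digital = np.clip(digital, DIGITAL_MIN, DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for i in range(n_ch):
            fh.write(digital[i].tobytes())


def parse_physical_range(path: str | Path, n_ch: int) -> tuple[np.ndarray, np.ndarray]:
    """Read back the per-channel physical min/max (used to bound round-trip error)."""
    with open(path, "rb") as fh:
        fh.seek(256 + n_ch * (16 + 80 + 8))
        pmin = np.array([float(fh.read(8)) for _ in range(n_ch)])
        pmax = np.array([float(fh.read(8)) for _ in range(n_ch)])
    return pmin, pmax


def quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel physical size of one digital step for ``data`` as written."""
    lo = data.min(axis=1)
    hi = data.max(axis=1)
    hi = np.where(hi <= lo, lo + 1.0, hi)
    return (hi - lo) / (DIGITAL_MAX - DIGITAL_MIN)
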