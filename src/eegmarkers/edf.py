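"""Minimal EDF reader/writer for microvolt-calibrated polygraphic recordings.

Implements the plain European Data Format: a 256-byte fixed header, 256
bytes per signal, then 16-bit little-endian data records. One-second data
records are used, so the sampling rate must be an integer. Recordings whose
length is not a whole number of seconds are zero-padded to the next record
boundary on write (the padded length is what a reader returns).

Physical calibration defaults to +/-800 uV, giving a quantization step of
1600/65535 ~ 0.024 uV -- ample headroom for blink transients while staying
well inside the 16-bit range.
"""

from __future__ import annotations

import datetime as _dt
import math
import os

import numpy as np

from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767
DEFAULT_PHYSICAL_RANGE = 800.0


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | os.PathLike,
              physical_range: float = DEFAULT_PHYSICAL_RANGE) -> None:
    """Write a Recording as plain EDF with 1 s data records."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    n_records = max(1, math.ceil(rec.n_samples / fs))
    total = n_records * fs

    data = np.zeros((n_sig, total))
    data[:, : rec.n_samples] = rec.data
    # physical -> digital, clipped to the declared range
    pmin, pmax = -physical_range, physical_range
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    dig = np.rint((np.clip(data, pmin, pmax) - pmin) * scale + _DIG_MIN)
    dig = dig.astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(str(rec.meta.get("subject_id", "X")), 80),
        _field(str(rec.meta.get("visit", "")), 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_sig)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),          # record duration, seconds
        _field(str(n_sig), 4),
    ])
    per = b"".join([
        b"".join(_field(lab, 16) for lab in rec.labels),
        b"".join(_field("", 80) for _ in rec.labels),      # transducer
        b"".join(_field("uV", 8) for _ in rec.labels),
        b"".join(_field(f"{pmin:g}", 8) for _ in rec.labels),
        b"".join(_field(f"{pmax:g}", 8) for _ in rec.labels),
        b"".join(_field(str(_DIG_MIN), 8) for _ in rec.labels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in rec.labels),
        b"".join(_field("", 80) for _ in rec.labels),      # prefiltering
        b"".join(_field(str(fs), 8) for _ in rec.labels),
        b"".join(_field("", 32) for _ in rec.labels),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per)
        # record-interleaved: all samples of signal 0, then signal 1, ...
        for r in range(n_records):
            chunk = dig[:, r * fs: (r + 1) * fs]
            fh.write(chunk.tobytes())


def read_edf(path: str | os.PathLike) -> Recording:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        subject = head[8:88].decode("ascii").strip()
        visit = head[88:168].decode("ascii").strip()
        n_records = int(head[236:244].decode("ascii").strip())
        record_dur = float(head[244:252].decode("ascii").strip())
        n_sig = int(head[252:256].decode("ascii").strip())

        sig_head = fh.read(256 * n_sig)

        def block(offset: int, width: int) -> list[str]:
            start = offset * n_sig
            raw = sig_head[start: start + width * n_sig]
            return [raw[i * width: (i + 1) * width].decode("ascii").strip()
                    for i in range(n_sig)]

        labels = block(0, 16)
        phys_min = [float(v) for v in block(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in block(16 + 80 + 8 + 8, 8)]
        dig_min = [int(v) for v in block(16 + 80 + 8 + 8 + 8, 8)]
        dig_max = [int(v) for v in block(16 + 80 + 8 + 8 + 8 + 8, 8)]
        n_samp = [int(v) for v in block(16 + 80 + 8 * 5 + 80, 8)]

        if len(set(n_samp)) != 1:
            raise ValueError("mixed per-signal sampling rates not supported")
        spr = n_samp[0]
        fs = spr / record_dur

        raw = np.frombuffer(fh.read(2 * spr * n_sig * n_records), dtype="<i2")
    if raw.size != spr * n_sig * n_records:
        raise ValueError("truncated EDF data section")
    raw = raw.reshape(n_records, n_sig, spr)
    data = np.concatenate([raw[r] for r in range(n_records)], axis=1)
    data = data.astype(float)
    for i in range(n_sig):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (data[i] - dig_min[i]) * gain + phys_min[i]
    return Recording(data=data, fs=fs, labels=labels,
                     meta={"subject_id": subject, "visit": visit})
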