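"""Minimal EDF (European Data Format) writer and reader.

Implements the 16-bit EDF container directly: fixed 256-byte header, one
256-byte signal-header block per channel, then 1-second data records of
little-endian int16 samples scaled channel-wise between the declared physical
and digital ranges.  This covers what the pipeline needs -- writing synthetic
recordings to disk and reading them (or externally recorded EDF files) back.
The last record is zero-padded when the signal length is not a whole number
of records; callers that know the true length can trim.

The reader is deliberately independent of MNE so the two can cross-validate
each other in tests.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

_HDR = 256
_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


@dataclass
class EdfSignal:
    label: str
    physical_dim: str = "uV"


def write_edf(path, data: np.ndarray, sfreq: float, channels,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write channels x samples (physical units) to an EDF file.

    The sampling rate must be a whole number of samples per 1-second record.
    Physical ranges are per-channel symmetric around zero, sized to the data.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = sfreq
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("sample rate must be an integer for 1 s records")
    spr = int(round(spr))
    n_rec = int(np.ceil(n_samp / spr))

    phys_max = np.abs(data).max(axis=1)
    phys_max = np.where(phys_max > 0, phys_max * 1.0001, 1.0)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(_HDR * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(str(ch)[:16], 16) for ch in channels),
        b"".join(_field("AgAgCl electrode", 80) for _ in channels),
        b"".join(_field("uV", 8) for _ in channels),
        b"".join(_field(f"{-pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_field(f"{pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_field(str(-_DIG_MAX), 8) for _ in channels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in channels),
        b"".join(_field("", 80) for _ in channels),
        b"".join(_field(str(spr), 8) for _ in channels),
        b"".join(_field("", 32) for _ in channels),
    ])

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    # declared phys range is what we actually scale with, so round-trips are
    # exact to the 16-bit quantization step
    declared = np.array([float(f"{pm:.6g}"[:8]) for pm in phys_max])
    gains = _DIG_MAX / declared
    digital = np.clip(np.rint(padded * gains[:, None]),
                      -_DIG_MAX, _DIG_MAX).astype("<i2")
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())


def read_edf(path, n_samples: int | None = None
             ) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples, sfreq, labels)."""
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if head[:8].strip() != b"0":
            raise ValueError("not an EDF file (bad version field)")
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(_HDR * n_ch)

        def col(offset: int, width: int):
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width].decode(
                "ascii").strip() for i in range(n_ch)]

        labels = col(0, 16)
        phys_min = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = np.array([int(v) for v in
                        col(16 + 80 + 8 + 32 + 80, 8)])
        if len(set(spr)) != 1:
            raise ValueError("per-channel sampling rates unsupported")
        spr = int(spr[0])
        raw = np.frombuffer(fh.read(n_rec * n_ch * spr * 2), dtype="<i2")

    records = raw.reshape(n_rec, n_ch, spr).transpose(1, 0, 2)
    digital = records.reshape(n_ch, n_rec * spr).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    if n_samples is not None:
        data = data[:, :n_samples]
    return data, spr / rec_dur, labels
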