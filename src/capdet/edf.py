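"""EDF (European Data Format) signal I/O.

Reading goes through MNE, which handles per-channel sampling rates, unit
scaling and the format's many dialects.  Writing is done by a small
self-contained EDF encoder (16-bit, one-second data records) sufficient
for exporting synthetic recordings that standard readers accept.
"""

from __future__ import annotations

import datetime as _dt
import struct
from pathlib import Path

import numpy as np

from .preprocess import TimeSeries

__all__ = ["read_edf_channels", "write_edf"]


def read_edf_channels(path: str | Path, channels: list[str]) -> dict[str, TimeSeries]:
    """Extract named channels from an EDF file as :class:`TimeSeries`.

    Raises ``KeyError`` naming the first requested channel absent from the
    file.  Values are returned in the file's physical units.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    out: dict[str, TimeSeries] = {}
    for ch in channels:
        if ch not in raw.ch_names:
            raise KeyError(
                f"channel {ch!r} not in EDF file (available: {raw.ch_names})"
            )
        try:
            data = raw.get_data(picks=[ch], units="uV")[0]
        except ValueError:  # channel without a convertible unit
            data = raw.get_data(picks=[ch])[0]
        out[ch] = TimeSeries(samples=data, fs=float(raw.info["sfreq"]), label=ch)
    return out


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, channels: dict[str, TimeSeries]) -> None:
    """Write channels to an EDF file (int16, 1 s data records).

    All channels must share one sampling rate, which must be an integer.
    The last record is zero-padded to a whole second.
    """
    names = list(channels)
    fs = channels[names[0]].fs
    if any(channels[n].fs != fs for n in names):
        raise ValueError("all channels must share one sampling rate")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_samples = max(len(channels[n].samples) for n in names)
    n_records = int(np.ceil(n_samples / spr))

    digital_min, digital_max = -32768, 32767
    phys = {}
    digitized = {}
    for n in names:
        x = np.zeros(n_records * spr)
        x[: len(channels[n].samples)] = channels[n].samples
        amp = float(np.max(np.abs(x)))
        pmax = amp if amp > 0 else 1.0
        pmin = -pmax
        scale = (digital_max - digital_min) / (pmax - pmin)
        d = np.round((x - pmin) * scale + digital_min).astype("<i2")
        phys[n] = (pmin, pmax)
        digitized[n] = d

    ns = len(names)
    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _pad_field("0", 8),
            _pad_field("X X X X", 80),
            _pad_field("Startdate 01-JAN-2000 X X X", 80),
            _pad_field(now.strftime("%d.%m.%y"), 8),
            _pad_field(now.strftime("%H.%M.%S"), 8),
            _pad_field(str(256 * (ns + 1)), 8),
            _pad_field("", 44),
            _pad_field(str(n_records), 8),
            _pad_field("1", 8),
            _pad_field(str(ns), 4),
        ]
    )
    sig_fields = [
        ("label", 16, lambda n: n),
        ("transducer", 80, lambda n: ""),
        ("dim", 8, lambda n: "uV"),
        ("pmin", 8, lambda n: f"{phys[n][0]:.6g}"[:8]),
        ("pmax", 8, lambda n: f"{phys[n][1]:.6g}"[:8]),
        ("dmin", 8, lambda n: str(digital_min)),
        ("dmax", 8, lambda n: str(digital_max)),
        ("prefilter", 80, lambda n: ""),
        ("spr", 8, lambda n: str(spr)),
        ("reserved", 32, lambda n: ""),
    ]
    sig_header = b"".join(
        b"".join(_pad_field(fn(n), width) for n in names)
        for _, width, fn in sig_fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec in range(n_records):
            for n in names:
                block = digitized[n][rec * spr : (rec + 1) * spr]
                fh.write(block.tobytes())
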