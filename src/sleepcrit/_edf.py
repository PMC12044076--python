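"""Minimal EDF (European Data Format) writer.

Writes uniform-rate multichannel signals as 16-bit EDF with one-second
data records, which is all the pipeline needs to serialize synthetic
recordings.  Reading is delegated to :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_names: list[str],
              physical_unit: str = "uV", patient_id: str = "X",
              recording_id: str = "X") -> None:
    """Write ``data`` (channels x samples, physical units) as 16-bit EDF.

    The sampling rate must be a positive integer (samples are packed in
    1-second records); trailing samples that do not fill a whole record
    are dropped.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_ch, n_samp = data.shape
    if n_ch != len(channel_names):
        raise ValueError("channel_names length must match data")
    n_rec = n_samp // fs_i
    if n_rec < 1:
        raise ValueError("need at least one second of data")
    data = data[:, : n_rec * fs_i]

    # per-channel physical range, padded so constant channels stay valid
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.maximum(pmax - pmin, 1e-6)
    pmin = pmin - 0.001 * span
    pmax = pmax + 0.001 * span
    dmin, dmax = -32768, 32767

    start = datetime(2000, 1, 1)
    header = b""
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field(start.strftime("%d.%m.%y"), 8)
    header += _field(start.strftime("%H.%M.%S"), 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(n_ch), 4)

    header += b"".join(_field(name, 16) for name in channel_names)
    header += b"".join(_field("", 80) for _ in channel_names)   # transducer
    header += b"".join(_field(physical_unit, 8) for _ in channel_names)
    header += b"".join(_field(f"{v:.10g}"[:8], 8) for v in pmin)
    header += b"".join(_field(f"{v:.10g}"[:8], 8) for v in pmax)
    header += b"".join(_field(str(dmin), 8) for _ in channel_names)
    header += b"".join(_field(str(dmax), 8) for _ in channel_names)
    header += b"".join(_field("", 80) for _ in channel_names)   # prefiltering
    header += b"".join(_field(str(fs_i), 8) for _ in channel_names)
    header += b"".join(_field("", 32) for _ in channel_names)   # reserved

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.rint((data - pmin[:, None]) * gain[:, None] + dmin),
        dmin, dmax,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each channel's fs_i samples contiguously
        rec_view = digital.reshape(n_ch, n_rec, fs_i)
        np.ascontiguousarray(rec_view.transpose(1, 0, 2)).tofile(fh)
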