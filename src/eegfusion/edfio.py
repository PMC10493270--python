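"""Minimal EDF (European Data Format) writer/reader.

Supports the subset needed here: continuous recordings, one-second data
records, identical integer sampling rate on every signal, 16-bit samples.
Values round-trip to within the 16-bit quantization of the physical range.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

_HDR = 256  # bytes, fixed part and per-signal field block size


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data: np.ndarray, fs: float, channel_names,
              patient_id: str = "X", recording_id: str = "synthetic",
              start: _dt.datetime | None = None) -> None:
    """Write ``data`` (channels x samples, physical units) as a 16-bit EDF file.

    ``fs`` must be a positive integer (one-second data records are used);
    trailing samples beyond the last full second are dropped.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_chan = data.shape[0]
    if len(channel_names) != n_chan:
        raise ValueError("channel_names length must match channel count")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be a positive integer for EDF export")
    fs = int(round(fs))
    n_records = data.shape[1] // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = data[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0001
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(_HDR * (1 + n_chan)), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))           # record duration, seconds
        fh.write(_field(str(n_chan), 4))
        for name in channel_names:
            fh.write(_field(name, 16))
        for _ in range(n_chan):
            fh.write(_field("synthetic", 80))   # transducer
        for _ in range(n_chan):
            fh.write(_field("uV", 8))
        for v in phys_min:
            fh.write(_field(f"{v:.6g}", 8))
        for v in phys_max:
            fh.write(_field(f"{v:.6g}", 8))
        for _ in range(n_chan):
            fh.write(_field(str(dig_min), 8))
        for _ in range(n_chan):
            fh.write(_field(str(dig_max), 8))
        for _ in range(n_chan):
            fh.write(_field("", 80))            # prefiltering
        for _ in range(n_chan):
            fh.write(_field(str(fs), 8))        # samples per record
        for _ in range(n_chan):
            fh.write(_field("", 32))            # reserved
        # data records: for each second, each signal's samples in sequence
        blocks = digital.reshape(n_chan, n_records, fs)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path):
    """Read an EDF file written in the supported subset.

    Returns ``(data, fs, channel_names, meta)`` with ``data`` in physical units.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def fixed(off, width):
        return raw[off:off + width].decode("ascii", "replace").strip()

    patient_id = fixed(8, 80)
    recording_id = fixed(88, 80)
    n_records = int(fixed(236, 8))
    record_dur = float(fixed(244, 8))
    n_chan = int(fixed(252, 4))

    # per-signal field blocks follow the 256-byte fixed header in order:
    # label(16) transducer(80) dim(8) phys_min(8) phys_max(8) dig_min(8)
    # dig_max(8) prefilter(80) samples_per_record(8) reserved(32)
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = np.cumsum([0] + widths[:-1])
    base = _HDR

    def read_block(which, width, conv=str):
        off = base + int(offsets[which]) * n_chan
        return [conv(raw[off + i * width: off + (i + 1) * width]
                     .decode("ascii", "replace").strip()) for i in range(n_chan)]

    labels = read_block(0, 16)
    phys_min = np.array(read_block(3, 8, float))
    phys_max = np.array(read_block(4, 8, float))
    dig_min = np.array(read_block(5, 8, float))
    dig_max = np.array(read_block(6, 8, float))
    spr = read_block(8, 8, int)
    if len(set(spr)) != 1:
        raise ValueError("heterogeneous per-signal sampling rates are not supported")
    fs = spr[0] / record_dur

    data_off = _HDR * (1 + n_chan)
    digital = np.frombuffer(raw, dtype="<i2", offset=data_off,
                            count=n_records * n_chan * spr[0])
    digital = digital.reshape(n_records, n_chan, spr[0]).transpose(1, 0, 2)
    digital = digital.reshape(n_chan, n_records * spr[0]).astype(np.float64)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    meta = {"patient_id": patient_id, "recording_id": recording_id}
    return data, fs, labels, meta
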