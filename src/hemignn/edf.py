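"""Minimal 16-bit European Data Format (EDF) reader/writer.

Supports the plain continuous-recording subset of EDF used for resting-state
EEG exports: one fixed-rate signal group, 1-second data records, int16
samples with per-signal linear physical scaling.  Annotations (EDF+),
discontinuous records and per-signal sampling rates are out of scope.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_edf", "write_edf"]

_HDR = 256  # bytes in the fixed header; +256 per signal


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(
    path,
    data: np.ndarray,
    channel_names: list[str],
    sampling_rate: float,
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write a channels x samples array (microvolts) as 16-bit EDF.

    The recording is chunked into 1-second data records, so the sample count
    must be an integer multiple of the sampling rate and the rate itself an
    integer.
    """
    data = np.asarray(data, dtype=np.float64)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length does not match data rows")
    fs = int(round(sampling_rate))
    if fs != sampling_rate or fs <= 0:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    if n_samp % fs:
        raise ValueError("sample count must be a whole number of seconds")
    n_rec = n_samp // fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HDR * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(name, 16) for name in channel_names),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax),
            b"".join(_field(str(dmin), 8) for _ in range(n_ch)),
            b"".join(_field(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    # records: for each second, all channels' fs samples in sequence
    records = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(np.ascontiguousarray(records).tobytes())


def read_edf(path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (channels x samples float64, labels, fs)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise IOError(f"{path}: not an EDF file (truncated header)")

    def ascii_at(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    n_rec = int(ascii_at(236, 8))
    rec_dur = float(ascii_at(244, 8))
    n_ch = int(ascii_at(252, 4))
    off = _HDR

    def sig_fields(width: int) -> list[str]:
        nonlocal off
        out = [ascii_at(off + i * width, width) for i in range(n_ch)]
        off += width * n_ch
        return out

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # physical dimension
    pmin = np.array([float(v) for v in sig_fields(8)])
    pmax = np.array([float(v) for v in sig_fields(8)])
    dmin = np.array([float(v) for v in sig_fields(8)])
    dmax = np.array([float(v) for v in sig_fields(8)])
    sig_fields(80)  # prefiltering
    spr = [int(v) for v in sig_fields(8)]  # samples per record
    sig_fields(32)

    if len(set(spr)) != 1:
        raise IOError(f"{path}: per-signal sampling rates are not supported")
    ns = spr[0]
    fs = ns / rec_dur
    payload = np.frombuffer(raw, dtype="<i2", offset=_HDR * (1 + n_ch))
    if n_rec < 0:  # unknown record count: infer from size
        n_rec = payload.size // (n_ch * ns)
    payload = payload[: n_rec * n_ch * ns].reshape(n_rec, n_ch, ns)
    digital = payload.transpose(1, 0, 2).reshape(n_ch, n_rec * ns).astype(np.float64)
    scale = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return physical, labels, fs
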