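"""Recording I/O, automatable preprocessing, and fixed-length windowing.

Recordings enter either as 16-bit EDF or as delimited numeric text with a
channel-name header row, are reordered to montage order, band-pass and notch
filtered (zero phase), optionally re-referenced to the common average, cut to
the centered analysis segment, and finally split into non-overlapping
fixed-length windows -- the model's unit of classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import edf as _edf
from .montage import Montage, MontageError, normalize_channel, standard_1020_montage

__all__ = [
    "EEGRecording",
    "WindowSample",
    "DataError",
    "read_recording",
    "write_recording",
    "bandpass_notch",
    "average_reference",
    "extract_middle_segment",
    "make_windows",
    "read_manifest",
    "load_cohort",
]

GROUPS = ("MDD", "HC")
CONDITIONS = ("EC", "EO")


class DataError(ValueError):
    """The recording does not satisfy a data precondition."""


@dataclass
class EEGRecording:
    """One subject/condition recording in microvolts, montage-ordered."""

    subject_id: str
    group: str  # MDD | HC
    condition: str  # EC | EO
    data: np.ndarray  # channels x samples
    sampling_rate: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_channels:
            raise DataError(
                f"data must be ({self.montage.n_channels}, n_samples); got {self.data.shape}"
            )
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if not np.isfinite(self.data).all():
            raise DataError("recording contains non-finite values")
        if self.group not in GROUPS:
            raise DataError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise DataError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


@dataclass(frozen=True)
class WindowSample:
    """One channels x T window with its labels."""

    x: np.ndarray
    subject_id: str
    group: str
    condition: str
    window_index: int

    @property
    def label(self) -> int:
        """MDD is the positive class (1)."""
        return 1 if self.group == "MDD" else 0


def _reorder(data: np.ndarray, labels: list[str], montage: Montage) -> np.ndarray:
    by_name = {normalize_channel(l): i for i, l in enumerate(labels)}
    rows = []
    for name in montage.channel_names:
        if name not in by_name:
            raise MontageError(f"channel {name!r} missing from file")
        rows.append(by_name[name])
    return data[rows]


def read_recording(
    path,
    fmt: str | None = None,
    *,
    subject_id: str = "",
    group: str = "HC",
    condition: str = "EC",
    montage: Montage | None = None,
    sampling_rate: float | None = None,
) -> EEGRecording:
    """Load a recording from EDF or delimited text, montage-ordered.

    Delimited text carries one header row of channel labels and one sample
    per line (any whitespace/comma delimiter); its sampling rate must be
    supplied (defaults to the montage rate).  Channel columns may appear in
    any order and any alias spelling.
    """
    path = Path(path)
    montage = montage or standard_1020_montage()
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        data, labels, fs = _edf.read_edf(path)
    elif fmt == "delimited":
        df = pd.read_csv(path, sep=None, engine="python")
        labels = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=np.float64).T
        fs = sampling_rate or montage.sampling_rate
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'delimited'")
    data = _reorder(data, labels, montage)
    return EEGRecording(
        subject_id=subject_id or path.stem,
        group=group,
        condition=condition,
        data=data,
        sampling_rate=float(fs),
        montage=montage,
    )


def write_recording(rec: EEGRecording, path, fmt: str = "delimited") -> None:
    """Write a recording as EDF or delimited text (header = channel names)."""
    path = Path(path)
    if fmt == "edf":
        _edf.write_edf(
            path,
            rec.data,
            list(rec.montage.channel_names),
            rec.sampling_rate,
            patient_id=rec.subject_id,
            recording_id=f"{rec.group}/{rec.condition}",
        )
    elif fmt == "delimited":
        pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_names)).to_csv(
            path, index=False, float_format="%.6f"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def bandpass_notch(
    rec: EEGRecording,
    low: float = 0.5,
    high: float = 70.0,
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase band-pass (Butterworth) plus power-line notch filtering.

    Both stages run forward-backward (``filtfilt``) so the output is
    phase-neutral and has the input's length.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) for fs={rec.sampling_rate}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError(f"notch frequency {notch} outside (0, {nyq})")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.sampling_rate)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(rec, data=out)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Common-average re-reference (optional stand-in for an infinity reference)."""
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def extract_middle_segment(rec: EEGRecording, duration: float = 180.0) -> EEGRecording:
    """Return the centered contiguous segment of exactly ``duration`` seconds."""
    n_need = int(round(duration * rec.sampling_rate))
    n_have = rec.data.shape[1]
    if n_have < n_need:
        raise DataError(
            f"recording {rec.subject_id}/{rec.condition} is {rec.duration:.1f} s, "
            f"shorter than the requested {duration:.1f} s segment"
        )
    start = (n_have - n_need) // 2
    return replace(rec, data=rec.data[:, start : start + n_need])


def make_windows(
    rec: EEGRecording, window_seconds: float = 2.0, overlap: float = 0.0
) -> list[WindowSample]:
    """Cut fixed-length sliding windows; a trailing partial window is dropped."""
    t = window_seconds * rec.sampling_rate
    if abs(t - round(t)) > 1e-9:
        raise ValueError("window_seconds x sampling_rate must be an integer")
    t = int(round(t))
    step = t - int(round(overlap * rec.sampling_rate))
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    n = rec.data.shape[1]
    out = []
    idx = 0
    for start in range(0, n - t + 1, step):
        out.append(
            WindowSample(
                x=rec.data[:, start : start + t].copy(),
                subject_id=rec.subject_id,
                group=rec.group,
                condition=rec.condition,
                window_index=idx,
            )
        )
        idx += 1
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (subject_id, group, condition, path).

    Relative recording paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "condition", "path"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest missing columns: {sorted(missing)}")
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in df["path"]
    ]
    return df


def load_cohort(
    manifest: pd.DataFrame | str | Path,
    montage: Montage | None = None,
    sampling_rate: float | None = None,
) -> list[EEGRecording]:
    """Load every recording listed in a manifest, montage-ordered."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    montage = montage or standard_1020_montage()
    return [
        read_recording(
            row.path,
            subject_id=str(row.subject_id),
            group=row.group,
            condition=row.condition,
            montage=montage,
            sampling_rate=sampling_rate,
        )
        for row in manifest.itertuples()
    ]
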