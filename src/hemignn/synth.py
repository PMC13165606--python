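"""Synthetic resting-state EEG cohorts with a planted hemispheric asymmetry.

Each channel is 1/f^beta background noise (partially shared across channels
through a small set of common sources, so functional-connectivity graphs are
nontrivial) plus an alpha-band oscillation with random phase.  For the MDD
class the alpha amplitude is scaled by ``asymmetry_effect**(-1/4)`` on
left-hemisphere electrodes and ``asymmetry_effect**(+1/4)`` on right-hemisphere
electrodes, so the planted right/left alpha *power* ratio equals
``asymmetry_effect``; midline electrodes and the HC class are untouched.
The lateralized alpha signal emulates the hemispheric-asymmetry abnormalities
reported for depression and is the only class-discriminative feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EEGRecording, write_recording
from .montage import Montage, build_partition, standard_1020_montage

__all__ = ["SynthSpec", "generate_recording", "generate_cohort"]


@dataclass(frozen=True)
class SynthSpec:
    """Stated world of the synthetic cohort.

    ``asymmetry_effect`` is the right/left alpha power ratio planted in the
    MDD class (1.0 = no signal, classes identical in distribution);
    ``snr`` is the oscillation-to-noise amplitude (RMS) ratio.
    """

    n_pairs: int = 6
    duration: float = 200.0  # s; long enough to exercise 180 s mid-segment extraction
    sampling_rate: float = 256.0
    noise_exponent: float = 1.0  # 1/f^beta slope
    alpha_band: tuple[float, float] = (8.0, 12.0)
    asymmetry_effect: float = 4.0
    snr: float = 1.0
    noise_rms: float = 10.0  # microvolts
    n_shared_sources: int = 4
    shared_mix: float = 0.5  # amplitude fraction of noise common across channels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.duration < 2.0:
            raise ValueError("duration must be >= 2 s")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 < self.alpha_band[0] < self.alpha_band[1] < self.sampling_rate / 2):
            raise ValueError("alpha_band must lie inside (0, Nyquist)")
        if self.asymmetry_effect < 1.0:
            raise ValueError("asymmetry_effect must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not (0.0 <= self.shared_mix < 1.0):
            raise ValueError("shared_mix must be in [0, 1)")


def _pink_noise(rng: np.random.Generator, n: int, beta: float, size: int) -> np.ndarray:
    """``size`` rows of spectrally shaped (1/f^beta) unit-RMS Gaussian noise."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    shape = np.empty_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def _hemisphere_scales(montage: Montage, effect: float) -> np.ndarray:
    """Per-channel alpha amplitude scale planting a right/left power ratio."""
    part = build_partition(montage, "two_region")
    shared = part.shared_channels
    scale = np.ones(montage.n_channels)
    for ch in part.regions["left"]:
        if ch not in shared:
            scale[montage.index(ch)] = effect ** (-1 / 4)
    for ch in part.regions["right"]:
        if ch not in shared:
            scale[montage.index(ch)] = effect ** (1 / 4)
    return scale


def generate_recording(
    spec: SynthSpec,
    subject_id: str,
    group: str,
    condition: str,
    rng: np.random.Generator,
    montage: Montage | None = None,
) -> EEGRecording:
    """Generate one subject/condition recording under the stated world."""
    montage = montage or standard_1020_montage(spec.sampling_rate)
    c = montage.n_channels
    n = int(round(spec.duration * spec.sampling_rate))

    own = _pink_noise(rng, n, spec.noise_exponent, c)
    shared = _pink_noise(rng, n, spec.noise_exponent, spec.n_shared_sources)
    mix = rng.standard_normal((c, spec.n_shared_sources))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    rho = spec.shared_mix
    noise = spec.noise_rms * (np.sqrt(1 - rho**2) * own + rho * (mix @ shared))

    lo, hi = spec.alpha_band
    f0 = rng.uniform(lo + (hi - lo) / 4, hi - (hi - lo) / 4)  # subject-specific alpha peak
    phases = rng.uniform(0, 2 * np.pi, size=(c, 1))
    t = np.arange(n) / spec.sampling_rate
    amp = spec.snr * spec.noise_rms * np.sqrt(2.0)  # oscillation RMS = snr * noise RMS
    alpha = amp * np.sin(2 * np.pi * f0 * t[None, :] + phases)
    if group == "MDD":
        alpha = alpha * _hemisphere_scales(montage, spec.asymmetry_effect)[:, None]

    return EEGRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        data=noise + alpha,
        sampling_rate=spec.sampling_rate,
        montage=montage,
    )


def generate_cohort(
    spec: SynthSpec,
    out_dir: str | Path | None = None,
    fmt: str = "delimited",
) -> tuple[pd.DataFrame, list[EEGRecording]]:
    """Generate a balanced cohort: n_pairs MDD + n_pairs HC, one EC and one EO each.

    Returns the manifest (subject_id, group, condition, path) and the
    recordings.  With ``out_dir`` set, recordings are written to disk in the
    requested format and the manifest CSV is saved alongside them; otherwise
    the cohort stays in memory and the path column is empty.
    """
    montage = standard_1020_montage(spec.sampling_rate)
    root = np.random.SeedSequence(spec.seed)
    subjects = [("MDD", f"MDD{i + 1:02d}") for i in range(spec.n_pairs)]
    subjects += [("HC", f"HC{i + 1:02d}") for i in range(spec.n_pairs)]
    streams = root.spawn(len(subjects) * 2)

    rows, recordings = [], []
    k = 0
    for group, sid in subjects:
        for condition in ("EC", "EO"):
            rng = np.random.default_rng(streams[k])
            k += 1
            rec = generate_recording(spec, sid, group, condition, rng, montage)
            recordings.append(rec)
            path = ""
            if out_dir is not None:
                ext = "edf" if fmt == "edf" else "csv"
                path = f"{sid}_{condition}.{ext}"
                Path(out_dir).mkdir(parents=True, exist_ok=True)
                write_recording(rec, Path(out_dir) / path, fmt=fmt)
            rows.append(
                {"subject_id": sid, "group": group, "condition": condition, "path": path}
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, recordings
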