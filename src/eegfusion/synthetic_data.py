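"""Synthetic awake resting-state EEG cohorts with class-distinct spectra.

Stands in for clinical recordings so the full pipeline is testable.  The
three default classes carry spectral signatures loosely modeled on clinical
descriptions — a posterior-dominant ~10 Hz rhythm for controls, diffuse
high-amplitude 2-4 Hz slowing for the "viral" class, and delta activity
with superimposed beta bursts for the "nmdar" class — superimposed on pink
(1/f) background noise.  The quantitative parameters are stand-ins with no
claim of physiological fidelity (no head model, no artifacts).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .edfio import write_edf
from .montage import MONTAGE_18
from .preprocess import EEGRecording

#: Canonical class labels, in the fixed integer-encoding order.
CLASS_NAMES: tuple[str, str, str] = ("control", "nmdar", "viral")

#: Oscillation rate (Hz) of the burst envelope used when a component's
#: duty cycle is < 1 (delta-rate bursting, as in a delta-brush-like pattern).
BURST_RATE_HZ = 2.5


@dataclass(frozen=True)
class Component:
    """One narrowband oscillatory component of a class signature."""

    center_freq: float      # Hz
    bandwidth: float        # Hz
    amplitude: float        # uV-scale std of the component
    burst_duty_cycle: float = 1.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.burst_duty_cycle <= 1.0:
            raise ValueError("burst_duty_cycle must lie in [0, 1]")
        if self.amplitude > 0 and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0 for a nonzero component")


@dataclass(frozen=True)
class ClassSpec:
    """Spectral signature of one class."""

    label: str
    components: tuple[Component, ...]
    noise_amplitude: float
    spatial_profile: Mapping[str, float]

    def __post_init__(self):
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        for name, gain in self.spatial_profile.items():
            if not 0.0 <= gain <= 1.0:
                raise ValueError(f"spatial gain for {name} must lie in [0, 1]")

    def validate_montage(self, montage: Sequence[str]) -> None:
        missing = [ch for ch in montage if ch not in self.spatial_profile]
        if missing:
            raise ValueError(f"spatial_profile missing montage channels: {missing}")


@dataclass(frozen=True)
class CohortSpec:
    n_subjects_per_class: int
    duration_s: float = 60.0
    fs: float = 200.0
    seed: int = 0
    montage: tuple[str, ...] = MONTAGE_18

    def __post_init__(self):
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60 so at least one segment exists")
        if self.fs <= 140:
            raise ValueError("fs must exceed 140 Hz (2 x 70 Hz filter edge)")
        missing = [ch for ch in MONTAGE_18 if ch not in self.montage]
        if missing:
            raise ValueError(f"montage missing required channels: {missing}")


def _profile(base: float, overrides: Mapping[str, float]) -> dict[str, float]:
    prof = {ch: base for ch in MONTAGE_18}
    prof.update(overrides)
    prof["A1"] = min(prof["A1"], 0.1)
    prof["A2"] = min(prof["A2"], 0.1)
    return prof


def default_class_specs(separation: float = 1.0) -> tuple[ClassSpec, ClassSpec, ClassSpec]:
    """Default three-class signatures.

    ``separation`` in [0, 1] scales every class-specific component amplitude;
    at 0 all classes degenerate to identical pink noise, so classification
    accuracy should fall to chance as it shrinks.
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    s = separation
    posterior = _profile(0.3, {"O1": 1.0, "O2": 1.0, "P3": 0.8, "P4": 0.8,
                               "T5": 0.6, "T6": 0.6})
    diffuse = _profile(1.0, {})
    anterior = _profile(0.8, {"Fp1": 1.0, "Fp2": 1.0, "F3": 1.0, "F4": 1.0,
                              "F7": 1.0, "F8": 1.0})
    control = ClassSpec(
        label="control",
        components=(Component(10.0, 2.0, 5.0 * s),),
        noise_amplitude=2.0,
        spatial_profile=posterior,
    )
    nmdar = ClassSpec(
        label="nmdar",
        components=(Component(2.5, 1.5, 6.0 * s),
                    Component(25.0, 6.0, 3.0 * s, burst_duty_cycle=0.5)),
        noise_amplitude=2.0,
        spatial_profile=anterior,
    )
    viral = ClassSpec(
        label="viral",
        components=(Component(3.0, 2.0, 8.0 * s),),
        noise_amplitude=2.0,
        spatial_profile=diffuse,
    )
    return control, nmdar, viral


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-std 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    k = np.arange(len(spec), dtype=np.float64)
    k[0] = 1.0
    spec /= np.sqrt(k)
    spec[0] = 0.0
    pink = np.fft.irfft(spec, n=n)
    std = pink.std()
    return pink / std if std > 0 else pink


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                f0: float, bw: float) -> np.ndarray:
    """Unit-std noise band-limited to [f0 - bw/2, f0 + bw/2]."""
    lo = max(f0 - bw / 2.0, 0.05)
    hi = min(f0 + bw / 2.0, 0.99 * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    std = y.std()
    return y / std if std > 0 else y


def _burst_envelope(rng: np.random.Generator, n: int, fs: float, duty: float) -> np.ndarray:
    """On/off envelope active a ``duty`` fraction of time at the burst rate."""
    if duty >= 1.0:
        return np.ones(n)
    if duty <= 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    osc = np.sin(2.0 * np.pi * BURST_RATE_HZ * t + phase)
    gate = (osc > np.cos(np.pi * duty)).astype(np.float64)
    width = max(int(round(0.05 * fs)), 3)
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    return np.convolve(gate, kernel, mode="same")


def generate_recording(spec: ClassSpec, duration_s: float, fs: float,
                       montage: Sequence[str], subject_id: str,
                       seed: int) -> EEGRecording:
    """Simulate one subject's multichannel recording; deterministic in ``seed``.

    Component waveforms are shared across channels (scaled by the spatial
    profile) while background noise is channel-independent.  A per-subject
    gain (+-20%) and center-frequency jitter (+-0.5 Hz) keep subjects from
    being trivially identical.
    """
    if fs <= 140:
        raise ValueError("fs must exceed 140 Hz (2 x 70 Hz filter edge)")
    unknown = [ch for ch in montage if ch not in MONTAGE_18]
    if unknown:
        raise ValueError(f"unknown montage channels: {unknown}")
    spec.validate_montage(montage)

    rng = np.random.default_rng(seed)
    gain = rng.uniform(0.8, 1.2)
    jitter = rng.uniform(-0.5, 0.5)
    n = int(round(duration_s * fs))
    data = np.zeros((len(montage), n))
    profile = np.array([spec.spatial_profile[ch] for ch in montage])

    for comp in spec.components:
        if comp.amplitude == 0:
            continue
        f0 = max(comp.center_freq + jitter, 0.5)
        wave = _narrowband(rng, n, fs, f0, comp.bandwidth)
        wave *= _burst_envelope(rng, n, fs, comp.burst_duty_cycle)
        data += np.outer(profile, comp.amplitude * gain * wave)

    if spec.noise_amplitude > 0:
        for ci in range(len(montage)):
            data[ci] += spec.noise_amplitude * gain * _pink_noise(rng, n)

    return EEGRecording(data=data, fs=fs, channel_names=tuple(montage),
                        subject_id=subject_id, label=spec.label)


def generate_cohort(cohort: CohortSpec,
                    class_specs: Sequence[ClassSpec] | None = None) -> list[EEGRecording]:
    """Generate ``3 * n_subjects_per_class`` recordings with unique subject IDs."""
    if cohort.n_subjects_per_class < 1:
        raise ValueError("n_subjects_per_class must be >= 1")
    specs = tuple(class_specs) if class_specs is not None else default_class_specs()
    if len(specs) != 3:
        raise ValueError("exactly three class specs are required")
    seeds = np.random.SeedSequence(cohort.seed).generate_state(
        3 * cohort.n_subjects_per_class, dtype=np.uint32)
    recordings = []
    i = 0
    for spec in specs:
        for j in range(cohort.n_subjects_per_class):
            sid = f"{spec.label}-{j:03d}"
            recordings.append(generate_recording(
                spec, cohort.duration_s, cohort.fs, cohort.montage,
                subject_id=sid, seed=int(seeds[i])))
            i += 1
    return recordings


def write_cohort(recordings: Sequence[EEGRecording], outdir) -> Path:
    """Write one EDF per recording plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path"])
        for rec in recordings:
            fname = f"{rec.subject_id}.edf"
            write_edf(outdir / fname, rec.data, rec.fs, rec.channel_names,
                      patient_id=rec.subject_id, recording_id=rec.label)
            writer.writerow([rec.subject_id, rec.label, fname])
    return manifest


def load_cohort(manifest_path) -> list[EEGRecording]:
    """Load recordings listed in a cohort manifest (paths relative to it)."""
    from .edfio import read_edf
    from .montage import canonical_name

    manifest_path = Path(manifest_path)
    recordings = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            path = manifest_path.parent / row["path"]
            data, fs, labels, _ = read_edf(path)
            names = tuple(canonical_name(x) for x in labels)
            recordings.append(EEGRecording(data=data, fs=fs, channel_names=names,
                                           subject_id=row["subject_id"],
                                           label=row["label"]))
    return recordings
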