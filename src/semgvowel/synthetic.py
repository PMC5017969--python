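"""Synthetic labeled sEMG with the statistical structure the pipeline assumes.

The muscle-activity surrogate is resonantly filtered Gaussian noise (the
standard stochastic interference model of motor-unit action-potential
trains) under an attack--sustain--decay amplitude envelope.  Mains hum,
DC offset, slow drift and measurement noise are injected afterwards so
the preprocessing stage has real work to do.

All randomness flows through counter-derived ``numpy`` Generator
substreams, making trial generation order-independent and the whole
dataset a pure function of :class:`GeneratorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import Trial

_BAND = (0.15, 450.0)  # physiological band the classes must live inside


@dataclass
class VowelClassSpec:
    """Spectral/temporal recipe for one vowel class."""

    class_id: int
    spectral_peaks: list[tuple[float, float, float]]  # (center Hz, bw Hz, gain)
    envelope_duration: float = 1.0  # seconds
    attack_frac: float = 0.2
    decay_frac: float = 0.2
    amplitude_mv: float = 0.8

    def __post_init__(self) -> None:
        if self.envelope_duration <= 0.064:
            raise ValueError("envelope_duration must exceed 0.064 s")
        for center, bw, gain in self.spectral_peaks:
            if not (_BAND[0] < center < _BAND[1]):
                raise ValueError(f"peak center {center} Hz outside {_BAND}")
            if bw <= 0 or gain <= 0:
                raise ValueError("peak bandwidth and gain must be positive")

    def spectral_centroid(self) -> float:
        """Gain-weighted mean peak center, in Hz."""
        w = np.array([g for _, _, g in self.spectral_peaks])
        c = np.array([c for c, _, _ in self.spectral_peaks])
        return float(np.sum(w * c) / np.sum(w))


@dataclass
class GeneratorConfig:
    fs: float = 1000.0
    n_classes: int = 11
    trials_per_class: int = 10
    n_subjects: int = 8
    subject_gain_sd: float = 0.1
    dc_offset_mv: float = 0.5
    mains_amp_mv: float = 0.3
    drift_amp_mv: float = 0.4
    drift_freq_hz: float = 0.05
    noise_sd_mv: float = 0.02
    seed: int = 0
    spread: float = 1.0  # separability dial: scales inter-class peak spacing

    def __post_init__(self) -> None:
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def make_class_specs(
    n_classes: int,
    rng_seed: int,
    spread: float = 1.0,
    fs: float = 1000.0,
) -> list[VowelClassSpec]:
    """Deterministic, mutually distinct spectral-peak layouts for each class.

    Primary peak centers are spread over 20--350 Hz; ``spread`` < 1 shrinks
    the layout toward its midpoint (the separability dial), 0 collapsing
    every class onto the same spectrum.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng([rng_seed, 0xC1A55])
    lo, hi = 20.0, 350.0
    base = np.linspace(lo, hi, n_classes)
    jitter = rng.uniform(-0.25, 0.25, size=n_classes) * (hi - lo) / n_classes
    centers = base + jitter
    bws = rng.uniform(25.0, 45.0, size=n_classes)
    amps = rng.uniform(0.6, 1.0, size=n_classes)

    def shrink(v: np.ndarray) -> np.ndarray:
        # spread < 1 pulls every class toward the common mean; 0 collapses
        # all classes onto one identical spec
        return v.mean() + (v - v.mean()) * spread

    centers = np.clip(shrink(centers), 5.0, 440.0)
    bws = shrink(bws)
    amps = shrink(amps)
    specs = []
    for i, c in enumerate(centers):
        bw = float(bws[i])
        # weak secondary resonance above the primary, kept inside the band
        c2 = min(c * 1.8 + 15.0, 430.0)
        amp = float(amps[i])
        specs.append(
            VowelClassSpec(
                class_id=i + 1,
                spectral_peaks=[
                    (float(c), bw, 1.0),
                    (float(c2), bw * 1.5, 0.35),
                ],
                envelope_duration=1.0,
                amplitude_mv=amp,
            )
        )
    return specs


def _envelope(n: int, attack_frac: float, decay_frac: float) -> np.ndarray:
    """Raised-cosine attack, unit sustain, raised-cosine decay."""
    na = max(int(round(n * attack_frac)), 1)
    nd = max(int(round(n * decay_frac)), 1)
    env = np.ones(n)
    env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    env[n - nd:] = 0.5 * (1 + np.cos(np.pi * np.arange(nd) / nd))
    return env


def generate_trial(
    spec: VowelClassSpec,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "s1",
) -> Trial:
    """Clean (artifact-free) class-shaped burst at the spec's amplitude."""
    n = int(round(spec.envelope_duration * cfg.fs))
    white = rng.standard_normal(n)
    shaped = np.zeros(n)
    nyq = cfg.fs / 2
    for center, bw, gain in spec.spectral_peaks:
        lo = max(center - bw / 2, 0.5) / nyq
        hi = min(center + bw / 2, nyq * 0.99) / nyq
        sos = sps.butter(2, [lo, hi], btype="band", output="sos")
        shaped += gain * sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0 and spec.amplitude_mv != 0:
        shaped = shaped / rms * spec.amplitude_mv
    else:
        shaped = np.zeros(n)
    shaped *= _envelope(n, spec.attack_frac, spec.decay_frac)
    return Trial(shaped, fs=cfg.fs, class_id=spec.class_id, subject_id=subject_id)


def corrupt_with_artifacts(
    trial: Trial,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> Trial:
    """Add DC offset, 50 Hz mains (random phase), slow drift and white noise."""
    n = len(trial)
    t = np.arange(n) / trial.fs
    out = trial.samples.copy()
    out += cfg.dc_offset_mv
    if cfg.mains_amp_mv != 0:
        out += cfg.mains_amp_mv * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.drift_amp_mv != 0:
        out += cfg.drift_amp_mv * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if cfg.noise_sd_mv != 0:
        out += cfg.noise_sd_mv * rng.standard_normal(n)
    return Trial(out, fs=trial.fs, class_id=trial.class_id,
                 subject_id=trial.subject_id)


@dataclass
class DatasetMeta:
    """Per-trial metadata aligned with the trial list."""

    records: list[dict] = field(default_factory=list)


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[Trial], DatasetMeta]:
    """Balanced, artifact-corrupted dataset: subjects x classes x trials.

    Per-trial RNG substreams are keyed on (seed, subject, class, trial), so
    any one trial can be regenerated in isolation.
    """
    specs = make_class_specs(cfg.n_classes, cfg.seed, spread=cfg.spread,
                             fs=cfg.fs)
    trials: list[Trial] = []
    meta = DatasetMeta()
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:02d}"
        gain_rng = np.random.default_rng([cfg.seed, 0x5AB, s])
        gain = float(1.0 + cfg.subject_gain_sd * gain_rng.standard_normal())
        gain = max(gain, 0.05)
        for spec in specs:
            for r in range(cfg.trials_per_class):
                rng = np.random.default_rng(
                    [cfg.seed, s, spec.class_id, r]
                )
                clean = generate_trial(spec, cfg, rng, subject_id=subject_id)
                clean.samples *= gain
                trial = corrupt_with_artifacts(clean, cfg, rng)
                trials.append(trial)
                meta.records.append(
                    {
                        "subject_id": subject_id,
                        "class_id": spec.class_id,
                        "repeat": r,
                        "n_samples": len(trial),
                    }
                )
    return trials, meta
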