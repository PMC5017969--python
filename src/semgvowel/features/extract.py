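"""Assembly of the full 57-value feature vector from a preprocessed trial."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..signal_io import Trial
from .entropy_domain import ENTROPY_FEATURE_NAMES, entropy_domain_features
from .frequency_domain import (
    FREQUENCY_FEATURE_NAMES,
    SEF_FRACTIONS,
    frequency_domain_features,
)
from .time_domain import TIME_FEATURE_NAMES, time_domain_features
from .wavelet import WAVELET_FEATURE_NAMES, dwt_decompose, wavelet_features

#: Canonical order: time (9) | entropy (13) | frequency (9) | wavelet (26).
FEATURE_NAMES: tuple[str, ...] = (
    TIME_FEATURE_NAMES
    + ENTROPY_FEATURE_NAMES
    + FREQUENCY_FEATURE_NAMES
    + WAVELET_FEATURE_NAMES
)

FAMILY_SIZES: dict[str, int] = {
    "time": len(TIME_FEATURE_NAMES),
    "entropy": len(ENTROPY_FEATURE_NAMES),
    "frequency": len(FREQUENCY_FEATURE_NAMES),
    "wavelet": len(WAVELET_FEATURE_NAMES),
}


@dataclass
class FeatureParams:
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    higuchi_kmax: int = 8
    apen_m: int = 2
    sampen_m: int = 2
    apen_r_factor: float = 0.2
    sampen_r_factor: float = 0.2
    hist_bins: int = 100
    flux_frame: int = 256
    flux_overlap: float = 0.5
    wavelet_name: str = "sym4"
    wavelet_level: int = 3
    sef_fractions: tuple[float, ...] = SEF_FRACTIONS

    def __post_init__(self) -> None:
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")
        if not 0 <= self.flux_overlap < 1:
            raise ValueError("flux_overlap must be in [0, 1)")
        for f in (self.renyi_alpha, self.tsallis_q, self.apen_r_factor,
                  self.sampen_r_factor):
            if f <= 0:
                raise ValueError("feature parameters must be positive")


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError(
                f"{self.values.size} values for {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values)
                   if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return self.values.size


def extract_features(trial: Trial,
                     params: FeatureParams | None = None) -> FeatureVector:
    """Compute all 57 features of a preprocessed trial in canonical order."""
    params = params or FeatureParams()
    x = trial.samples
    feats: dict[str, float] = {}
    try:
        feats.update(time_domain_features(x))
    except Exception as exc:
        raise RuntimeError(f"time-domain features failed: {exc}") from exc
    try:
        feats.update(
            entropy_domain_features(
                x,
                renyi_alpha=params.renyi_alpha,
                tsallis_q=params.tsallis_q,
                higuchi_kmax=params.higuchi_kmax,
                apen_m=params.apen_m,
                sampen_m=params.sampen_m,
                apen_r_factor=params.apen_r_factor,
                sampen_r_factor=params.sampen_r_factor,
                hist_bins=params.hist_bins,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"entropy-domain features failed: {exc}") from exc
    try:
        feats.update(
            frequency_domain_features(
                x,
                trial.fs,
                flux_frame=params.flux_frame,
                flux_overlap=params.flux_overlap,
                sef_fractions=params.sef_fractions,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"frequency-domain features failed: {exc}") from exc
    try:
        dec = dwt_decompose(x, wavelet_name=params.wavelet_name,
                            level=params.wavelet_level)
        feats.update(wavelet_features(dec, hist_bins=params.hist_bins))
    except Exception as exc:
        raise RuntimeError(f"wavelet features failed: {exc}") from exc
    values = np.array([feats[name] for name in FEATURE_NAMES])
    return FeatureVector(values=values)
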