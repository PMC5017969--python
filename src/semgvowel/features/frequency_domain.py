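"""Nine FFT-based spectral descriptors."""

from __future__ import annotations

import numpy as np
from scipy.signal import get_window, periodogram

FREQUENCY_FEATURE_NAMES: tuple[str, ...] = (
    "spectral_flatness",
    "spectral_flux",
    "spectral_entropy",
    "sef80",
    "sep80",
    "sef90",
    "sep90",
    "sef95",
    "sep95",
)

SEF_FRACTIONS: tuple[float, ...] = (0.80, 0.90, 0.95)


def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (mean removed), satisfying Parseval:
    sum(psd) * df ~= var(x)."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for a power spectrum")
    freqs, psd = periodogram(x, fs=fs, detrend="constant")
    return freqs, psd


def spectral_edge(
    freqs: np.ndarray, psd: np.ndarray, fraction: float
) -> tuple[float, float]:
    """(SEF, SEP): lowest frequency whose cumulative power reaches
    ``fraction`` of the total, and the cumulative power there (absolute
    units).  Zero total power -> (0, 0) guard."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    cum = np.cumsum(psd)
    total = cum[-1]
    if total <= 0:
        return 0.0, 0.0
    idx = int(np.searchsorted(cum, fraction * total))
    idx = min(idx, len(freqs) - 1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return float(freqs[idx]), float(cum[idx] * df)


def spectral_flatness(psd: np.ndarray) -> float:
    """Geometric / arithmetic mean of the PSD; 1 for white, ~0 for a tone.

    Bins are floored at 1e-12 of the mean power: deep-cancellation bins are
    pure rounding noise and would otherwise make the geometric mean
    irreproducible.
    """
    p = np.asarray(psd, dtype=float)
    if p.size == 0 or p.max() <= 0:
        return 0.0
    p = np.maximum(p, 1e-12 * p.mean())
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def spectral_entropy(psd: np.ndarray) -> float:
    """Shannon entropy of the PSD-as-probability, normalized to [0, 1]."""
    p = np.asarray(psd, dtype=float)
    total = p.sum()
    if total <= 0 or p.size < 2:
        return 0.0
    p = p / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)) / np.log2(psd.size))


def spectral_flux(
    x: np.ndarray, frame: int = 256, overlap: float = 0.5
) -> float:
    """Mean squared change of the L1-normalized magnitude spectrum across
    successive Hann-windowed frames."""
    x = np.asarray(x, dtype=float)
    hop = max(int(frame * (1 - overlap)), 1)
    if x.size < frame + hop:
        raise ValueError(
            f"trial of {x.size} samples too short for two {frame}-sample "
            "flux frames"
        )
    win = get_window("hann", frame)
    mags = []
    for start in range(0, x.size - frame + 1, hop):
        spec = np.abs(np.fft.rfft(x[start:start + frame] * win))
        norm = spec.sum()
        mags.append(spec / norm if norm > 0 else spec)
    mags = np.array(mags)
    diffs = np.diff(mags, axis=0)
    return float(np.mean(np.sum(diffs**2, axis=1)))


def frequency_domain_features(
    x: np.ndarray,
    fs: float,
    flux_frame: int = 256,
    flux_overlap: float = 0.5,
    sef_fractions: tuple[float, ...] = SEF_FRACTIONS,
) -> dict[str, float]:
    freqs, psd = power_spectrum(x, fs)
    out = {
        "spectral_flatness": spectral_flatness(psd),
        "spectral_flux": spectral_flux(x, frame=flux_frame,
                                       overlap=flux_overlap),
        "spectral_entropy": spectral_entropy(psd),
    }
    for frac in sef_fractions:
        sef, sep = spectral_edge(freqs, psd, frac)
        pct = int(round(frac * 100))
        out[f"sef{pct}"] = sef
        out[f"sep{pct}"] = sep
    return out
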