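"""Symlet-4 discrete wavelet transform and the 26 sub-band features.

The orthonormal sym4 analysis pair is hard-coded (8 taps, 4 vanishing
moments); decomposition uses symmetric edge-replication padding and
critical downsampling, exactly as the classic pyramid algorithm
prescribes.  Level 3 yields four coefficient vectors: approximation ca3
and details cd3, cd2, cd1 (finest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy_domain import shannon_entropy

# Orthonormal Symlet-4 scaling (low-pass) analysis filter.
SYM4_DEC_LO = np.array(
    [
        -0.07576571478927333,
        -0.02963552764599851,
        0.49761866763201545,
        0.8037387518059161,
        0.29785779560527736,
        -0.09921954357684722,
        -0.012603967262037833,
        0.0322231006040427,
    ]
)
# Quadrature-mirror high-pass: g[k] = (-1)^k h[L-1-k].
SYM4_DEC_HI = SYM4_DEC_LO[::-1] * np.power(-1.0, np.arange(SYM4_DEC_LO.size))

WAVELET_BAND_NAMES: tuple[str, ...] = ("ca3", "cd3", "cd2", "cd1")
_BAND_STATS: tuple[str, ...] = (
    "entropy", "variance", "std", "median", "mean", "maxmin_ratio"
)

WAVELET_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band}_{stat}" for band in WAVELET_BAND_NAMES for stat in _BAND_STATS
) + ("energy_approx_pct", "energy_detail_pct")

_MAXMIN_EPS = 1e-12


@dataclass
class DWTDecomposition:
    """Three-level decomposition: approximation plus details cd3, cd2, cd1."""

    approx: np.ndarray
    details: list[np.ndarray]  # [cd3, cd2, cd1]
    energies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.energies:
            self.energies = {"ca3": float(np.sum(self.approx**2))}
            for name, d in zip(("cd3", "cd2", "cd1"), self.details):
                self.energies[name] = float(np.sum(d**2))

    @property
    def bands(self) -> dict[str, np.ndarray]:
        return {
            "ca3": self.approx,
            "cd3": self.details[0],
            "cd2": self.details[1],
            "cd1": self.details[2],
        }

    def total_energy(self) -> float:
        return float(sum(self.energies.values()))


def _dwt_single(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level with symmetric (edge-replicating) padding."""
    pad = SYM4_DEC_LO.size - 1
    left = x[:pad][::-1]
    right = x[-pad:][::-1]
    xp = np.concatenate([left, x, right])
    lo = np.convolve(xp, SYM4_DEC_LO, mode="valid")[1::2]
    hi = np.convolve(xp, SYM4_DEC_HI, mode="valid")[1::2]
    return lo, hi


def dwt_decompose(
    x: np.ndarray, wavelet_name: str = "sym4", level: int = 3
) -> DWTDecomposition:
    """Symlet-4 pyramid decomposition to the requested level (default 3)."""
    if wavelet_name != "sym4":
        raise ValueError("only the sym4 wavelet is provided")
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError(
            f"need at least 64 samples for a {level}-level decomposition"
        )
    approx = x
    details: list[np.ndarray] = []
    for _ in range(level):
        approx, detail = _dwt_single(approx)
        details.append(detail)  # d1 first
    details.reverse()  # [cd3, cd2, cd1]
    return DWTDecomposition(approx=approx, details=details)


def _band_stats(c: np.ndarray, hist_bins: int) -> dict[str, float]:
    a = np.abs(c)
    return {
        "entropy": shannon_entropy(c, bins=hist_bins),
        "variance": float(np.var(c)),
        "std": float(np.std(c)),
        "median": float(np.median(c)),
        "mean": float(np.mean(c)),
        "maxmin_ratio": float(a.max() / max(a.min(), _MAXMIN_EPS)),
    }


def wavelet_features(
    dec: DWTDecomposition, hist_bins: int = 100
) -> dict[str, float]:
    """Six statistics per band (24) plus the approximation/detail energy
    percentages EA and ED; EA + ED = 100 exactly."""
    total = dec.total_energy()
    if total <= 0:
        raise ValueError("zero-energy decomposition: energy shares undefined")
    out: dict[str, float] = {}
    for band_name, coeffs in dec.bands.items():
        for stat, value in _band_stats(coeffs, hist_bins).items():
            out[f"{band_name}_{stat}"] = value
    ea = 100.0 * dec.energies["ca3"] / total
    out["energy_approx_pct"] = ea
    out["energy_detail_pct"] = 100.0 - ea
    return out
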