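"""Thirteen complexity / entropy descriptors of a sample vector.

Amplitude-distribution entropies (Shannon, Renyi, Tsallis) are computed on
a fixed-bin histogram of the trial, in bits.  Regularity statistics
(ApEn/SampEn) use Chebyshev template matching with tolerance proportional
to the signal's standard deviation, so they are amplitude-scale invariant.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

ENTROPY_FEATURE_NAMES: tuple[str, ...] = (
    "hjorth_mobility",
    "hjorth_complexity",
    "lower_envelope_mean",
    "upper_envelope_mean",
    "mean_abs_diff",
    "higuchi_fd",
    "lz_complexity",
    "renyi_entropy",
    "shannon_entropy",
    "tsallis_entropy",
    "hurst_exponent",
    "approximate_entropy",
    "sample_entropy",
)


def hjorth_mobility(x: np.ndarray) -> float:
    """sqrt(var(diff x) / var(x)); 0 for a constant signal."""
    v = np.var(x)
    if v == 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def hjorth_complexity(x: np.ndarray) -> float:
    """mobility(diff x) / mobility(x); 0 when undefined."""
    m = hjorth_mobility(x)
    if m == 0:
        return 0.0
    return hjorth_mobility(np.diff(x)) / m


def _envelope_mean(x: np.ndarray, upper: bool) -> float:
    comparator = np.greater if upper else np.less
    idx = argrelextrema(x, comparator, order=1)[0]
    if idx.size < 2:
        return float(x.max() if upper else x.min())
    # anchor at the endpoints so the spline spans the whole trial
    knots = np.concatenate([[0], idx, [x.size - 1]])
    knots = np.unique(knots)
    spline = CubicSpline(knots, x[knots])
    return float(np.mean(spline(np.arange(x.size))))


def envelope_means(x: np.ndarray) -> tuple[float, float]:
    """(lower, upper) envelope means via cubic splines through local extrema."""
    return _envelope_mean(x, upper=False), _envelope_mean(x, upper=True)


def mean_abs_diff(x: np.ndarray) -> float:
    """Mean absolute successive difference, mean(|x[i+1] - x[i]|)."""
    return float(np.mean(np.abs(np.diff(x))))


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi's fractal dimension (1 = smooth curve, 2 = space-filling)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    lks = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            seg = x[m::k]
            if seg.size < 2:
                continue
            nmax = seg.size - 1
            norm = (n - 1) / (nmax * k)
            lengths.append(np.sum(np.abs(np.diff(seg))) * norm / k)
        lks[k - 1] = np.mean(lengths)
    valid = lks > 0
    if valid.sum() < 2:
        return 1.0
    k_arr = np.arange(1, kmax + 1)[valid]
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lks[valid]), 1)[0]
    return float(slope)


def lz_complexity(x: np.ndarray) -> float:
    """Lempel-Ziv (LZ76) complexity of the median-thresholded binary
    sequence, normalized by n / log2(n)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    i, c, k = 0, 1, 1
    # LZ76 parsing: count the number of distinct phrases
    while i + k < n:
        if s[i:i + k] in s[:i + k - 1]:
            k += 1
        else:
            c += 1
            i += k
            k = 1
    if n < 2:
        return 0.0
    return float(c * np.log2(n) / n)


def _hist_probs(x: np.ndarray, bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0].astype(float)
    return p / p.sum()


def shannon_entropy(x: np.ndarray, bins: int = 100) -> float:
    """Histogram Shannon entropy, bits."""
    p = _hist_probs(x, bins)
    return float(-np.sum(p * np.log2(p)))


def renyi_entropy(x: np.ndarray, alpha: float = 2.0, bins: int = 100) -> float:
    """Histogram Renyi entropy of order alpha (default 2), bits."""
    if alpha == 1.0:
        return shannon_entropy(x, bins)
    p = _hist_probs(x, bins)
    return float(np.log2(np.sum(p**alpha)) / (1.0 - alpha))


def tsallis_entropy(x: np.ndarray, q: float = 2.0, bins: int = 100) -> float:
    """Histogram Tsallis entropy of order q (default 2)."""
    if q == 1.0:
        return shannon_entropy(x, bins) * np.log(2.0)  # nats limit
    p = _hist_probs(x, bins)
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def hurst_exponent(x: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst exponent.

    Log-regression of mean R/S over dyadic window sizes 8..n/2; white noise
    sits near 0.5, persistent signals above.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sizes = []
    w = 8
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    if len(sizes) < 2 or np.ptp(x) == 0:
        return 0.5
    log_rs = []
    log_w = []
    for w in sizes:
        m = n // w
        segs = x[: m * w].reshape(m, w)
        means = segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs - means, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = segs.std(axis=1)
        ok = s > 0
        if not np.any(ok):
            continue
        rs = np.mean(r[ok] / s[ok])
        if rs > 0:
            log_rs.append(np.log(rs))
            log_w.append(np.log(w))
    if len(log_rs) < 2:
        return 0.5
    return float(np.polyfit(log_w, log_rs, 1)[0])


def _count_matches(x: np.ndarray, m: int, r: float,
                   exclude_self: bool) -> np.ndarray:
    """Per-template counts of Chebyshev-close templates of length m."""
    n = x.size
    nt = n - m + 1
    close = np.ones((nt, nt), dtype=bool)
    for d in range(m):
        xi = x[d:d + nt]
        close &= np.abs(xi[:, None] - xi[None, :]) <= r
    counts = close.sum(axis=1).astype(float)
    if exclude_self:
        counts -= 1.0
    return counts


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r_factor: float = 0.2) -> float:
    """ApEn(m, r = r_factor * sd).  Constant signals return 0 by guard."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or x.size < m + 2:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        counts = _count_matches(x, mm, r, exclude_self=False)
        return float(np.mean(np.log(counts / counts.size)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r = r_factor * sd), self-matches excluded.

    Degenerate cases (constant signal, or no template matches) return 0.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or x.size < m + 2:
        return 0.0
    r = r_factor * sd
    n = x.size
    nt = n - m  # same template count for both lengths (standard convention)

    def total(mm: int) -> float:
        close = np.ones((nt, nt), dtype=bool)
        for d in range(mm):
            xi = x[d:d + nt]
            close &= np.abs(xi[:, None] - xi[None, :]) <= r
        return float(close.sum() - nt)  # drop self-matches

    b_total = total(m)
    a_total = total(m + 1)
    if b_total == 0 or a_total == 0:
        return 0.0
    return float(-np.log(a_total / b_total))


def entropy_domain_features(
    x: np.ndarray,
    renyi_alpha: float = 2.0,
    tsallis_q: float = 2.0,
    higuchi_kmax: int = 8,
    apen_m: int = 2,
    sampen_m: int = 2,
    apen_r_factor: float = 0.2,
    sampen_r_factor: float = 0.2,
    hist_bins: int = 100,
) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for entropy features")
    lower, upper = envelope_means(x)
    return {
        "hjorth_mobility": hjorth_mobility(x),
        "hjorth_complexity": hjorth_complexity(x),
        "lower_envelope_mean": lower,
        "upper_envelope_mean": upper,
        "mean_abs_diff": mean_abs_diff(x),
        "higuchi_fd": higuchi_fd(x, kmax=higuchi_kmax),
        "lz_complexity": lz_complexity(x),
        "renyi_entropy": renyi_entropy(x, alpha=renyi_alpha, bins=hist_bins),
        "shannon_entropy": shannon_entropy(x, bins=hist_bins),
        "tsallis_entropy": tsallis_entropy(x, q=tsallis_q, bins=hist_bins),
        "hurst_exponent": hurst_exponent(x),
        "approximate_entropy": approximate_entropy(
            x, m=apen_m, r_factor=apen_r_factor
        ),
        "sample_entropy": sample_entropy(
            x, m=sampen_m, r_factor=sampen_r_factor
        ),
    }
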