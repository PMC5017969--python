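"""Nine time-domain amplitude statistics."""

from __future__ import annotations

import numpy as np

TIME_FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "maximum",
    "std",
    "minimum",
    "variance",
    "cov",
    "skewness",
    "kurtosis",
    "rms",
)


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """Population moments of the sample vector.

    Guards: a constant signal (sd = 0) yields CoV = skewness = kurtosis = 0;
    CoV is also 0 when the mean is exactly zero.  Kurtosis is excess
    (Gaussian -> 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for time-domain features")
    mean = float(x.mean())
    var = float(x.var())  # population (ddof=0)
    sd = float(np.sqrt(var))
    if sd > 0:
        zs = (x - mean) / sd  # standardize first to dodge underflow
        skew = float(np.mean(zs**3))
        kurt = float(np.mean(zs**4)) - 3.0
        cov = sd / mean if mean != 0 else 0.0
    else:
        skew = kurt = cov = 0.0
    return {
        "mean": mean,
        "maximum": float(x.max()),
        "std": sd,
        "minimum": float(x.min()),
        "variance": var,
        "cov": cov,
        "skewness": skew,
        "kurtosis": kurt,
        "rms": float(np.sqrt(np.mean(x**2))),
    }
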