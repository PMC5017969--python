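"""Greedy mRMR feature ranking on discretized features.

Mutual information is estimated on a 3-state z-threshold discretization
(cuts at mean +/- sd of each feature), in bits.  Relevance of a set is the
mean feature--class MI; redundancy is the 1/|S|^2-normalized sum of all
pairwise feature--feature MIs (self terms included); the greedy criterion
for the next feature is I(x; c) - mean over selected of I(x; x_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DiscretizationScheme:
    method: str = "z-threshold"
    n_bins: int = 3  # only used by the equal-frequency alternative

    def __post_init__(self) -> None:
        if self.method not in ("z-threshold", "equal-frequency"):
            raise ValueError(f"unknown discretization method {self.method!r}")


@dataclass
class SelectionStep:
    feature: int
    relevance: float  # D of the growing set
    redundancy: float  # R of the growing set
    score: float  # phi = D - R


@dataclass
class SelectionResult:
    ranked_indices: list[int]
    per_step: list[SelectionStep]
    k: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ranked_indices)) != len(self.ranked_indices):
            raise ValueError("ranked indices must be unique")
        if len(self.ranked_indices) != self.k:
            raise ValueError("ranking length must equal k")


def discretize(values: np.ndarray,
               scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Map a continuous vector to small-integer states.

    z-threshold: cuts at mean - sd and mean + sd give states {0, 1, 2}.
    A constant vector maps to the single middle state.
    """
    scheme = scheme or DiscretizationScheme()
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to discretize")
    if scheme.method == "z-threshold":
        mu, sd = v.mean(), v.std()
        out = np.ones(v.size, dtype=np.int64)
        out[v < mu - sd] = 0
        out[v > mu + sd] = 2
        return out
    # equal-frequency k-bin
    qs = np.quantile(v, np.linspace(0, 1, scheme.n_bins + 1)[1:-1])
    return np.searchsorted(qs, v, side="right").astype(np.int64)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in discrete mutual information, in bits; symmetric and >= 0."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    # canonicalize the argument order so I(a,b) == I(b,a) bit-exactly
    if (ai.max(), ai.tobytes()) > (bi.max(), bi.tobytes()):
        ai, bi = bi, ai
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb)
    joint = joint / a.size
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def relevance(S: list[int], c: np.ndarray, F: np.ndarray) -> float:
    """D = mean over the set of I(feature; class)."""
    if not S:
        raise ValueError("relevance of an empty set is undefined")
    return float(np.mean([mutual_information(F[:, i], c) for i in S]))


def redundancy(S: list[int], F: np.ndarray) -> float:
    """R = (1/|S|^2) * sum over all ordered pairs of I(x_i; x_j),
    self terms included (|S| = 1 gives the feature's self-entropy)."""
    if not S:
        raise ValueError("redundancy of an empty set is undefined")
    total = 0.0
    for i in S:
        for j in S:
            total += mutual_information(F[:, i], F[:, j])
    return total / len(S) ** 2


def mrmr_rank(
    F: np.ndarray,
    c: np.ndarray,
    k: int = 12,
    scheme: DiscretizationScheme | None = None,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Greedy incremental mRMR ranking of ``k`` features.

    The first pick maximizes I(x; c); each later pick maximizes
    I(x; c) - (1/|S|) sum_{j in S} I(x; x_j).  Ties break to the lower
    feature index, making the ranking deterministic.
    """
    F = np.asarray(F, dtype=float)
    c = np.asarray(c)
    n, p = F.shape
    if k > p:
        raise ValueError(f"cannot select k={k} from {p} features")
    if n < 10:
        raise ValueError("need at least 10 samples for MI estimation")
    scheme = scheme or DiscretizationScheme()
    D = np.column_stack([discretize(F[:, j], scheme) for j in range(p)])

    rel = np.array([mutual_information(D[:, j], c) for j in range(p)])
    pair_mi = np.zeros((p, p))  # filled lazily, row per selected feature
    selected: list[int] = []
    steps: list[SelectionStep] = []
    red_sum = np.zeros(p)  # sum of MI with already-selected features

    for _ in range(k):
        if selected:
            scores = rel - red_sum / len(selected)
        else:
            scores = rel.copy()
        scores[selected] = -np.inf
        best = int(np.argmax(scores))  # argmax takes the lowest tied index
        selected.append(best)
        for j in range(p):
            pair_mi[best, j] = mutual_information(D[:, best], D[:, j])
        red_sum += pair_mi[best]
        d_val = float(rel[selected].mean())
        r_val = float(
            sum(pair_mi[i, j] for i in selected for j in selected)
            / len(selected) ** 2
        )
        steps.append(
            SelectionStep(feature=best, relevance=d_val, redundancy=r_val,
                          score=d_val - r_val)
        )
    names = (
        [feature_names[i] for i in selected] if feature_names else []
    )
    return SelectionResult(ranked_indices=selected, per_step=steps, k=k,
                           feature_names=names)
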