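import itertools

import numpy as np
import pytest

from semgvowel.feature_selection import (
    DiscretizationScheme,
    discretize,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)


def brute_force_mrmr(F, c, k):
    """Independent oracle: re-evaluate the greedy incremental criterion by
    direct enumeration, using its own entropy arithmetic."""

    def disc(v):
        mu, sd = v.mean(), v.std()
        out = np.ones(len(v), dtype=int)
        out[v < mu - sd] = 0
        out[v > mu + sd] = 2
        return out

    def mi(a, b):
        n = len(a)
        total = 0.0
        for va in set(a):
            for vb in set(b):
                pab = np.mean((a == va) & (b == vb))
                if pab > 0:
                    pa = np.mean(a == va)
                    pb = np.mean(b == vb)
                    total += pab * np.log2(pab / (pa * pb))
        return total

    D = [disc(F[:, j]) for j in range(F.shape[1])]
    c = np.asarray(c)
    selected = []
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in range(F.shape[1]):
            if j in selected:
                continue
            score = mi(D[j], c)
            if selected:
                score -= np.mean([mi(D[j], D[s]) for s in selected])
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


class TestDiscretize:
    def test_normal_occupancy(self, rng):
        x = rng.standard_normal(20000)
        states = discretize(x)
        frac = np.bincount(states, minlength=3) / x.size
        assert frac[0] == pytest.approx(0.16, abs=0.05)
        assert frac[1] == pytest.approx(0.68, abs=0.05)
        assert frac[2] == pytest.approx(0.16, abs=0.05)

    def test_constant_single_state(self):
        states = discretize(np.full(50, 2.5))
        assert set(states) == {1}

    def test_affine_rescale_invariant(self, rng):
        x = rng.standard_normal(500)
        a = discretize(x)
        b = discretize(3.0 * x + 10.0)
        np.testing.assert_array_equal(a, b)

    def test_equal_frequency_alternative(self, rng):
        x = rng.standard_normal(3000)
        states = discretize(x, DiscretizationScheme("equal-frequency", 3))
        frac = np.bincount(states, minlength=3) / x.size
        assert np.all(np.abs(frac - 1 / 3) < 0.02)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0]))


class TestMutualInformation:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=5000)
        b = rng.integers(0, 3, size=5000)
        assert mutual_information(a, b) <= 0.05

    def test_self_information_is_entropy(self):
        a = np.tile([0, 1, 2], 300)
        assert mutual_information(a, a) == pytest.approx(np.log2(3), abs=1e-9)

    def test_symmetry_exact(self, rng):
        a = rng.integers(0, 3, size=400)
        b = rng.integers(0, 4, size=400)
        assert mutual_information(a, b) == mutual_information(b, a)

    def test_nonnegative(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, size=100)
            b = rng.integers(0, 3, size=100)
            assert mutual_information(a, b) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(5), np.zeros(6))


class TestRelevanceRedundancy:
    def test_copy_of_class_gives_entropy(self):
        c = np.tile([1, 2, 3], 100)
        F = c[:, None].astype(float)
        d = relevance([0], c, np.column_stack([discretize(F[:, 0])]))
        assert d == pytest.approx(np.log2(3), abs=0.2)

    def test_noise_relevance_near_zero(self, rng):
        c = rng.integers(1, 4, size=3000)
        noise = discretize(rng.standard_normal(3000))
        assert relevance([0], c, noise[:, None]) <= 0.01

    def test_mean_bounded_by_max(self, rng):
        c = rng.integers(1, 4, size=500)
        F = np.column_stack(
            [discretize(rng.standard_normal(500)) for _ in range(4)]
        )
        individual = [relevance([j], c, F) for j in range(4)]
        assert relevance([0, 1, 2, 3], c, F) <= max(individual) + 1e-12

    def test_duplicate_redundancy_is_entropy(self):
        f = np.tile([0, 1, 2], 100)
        F = np.column_stack([f, f])
        h = mutual_information(f, f)
        assert redundancy([0, 1], F) == pytest.approx(h, abs=1e-12)

    def test_singleton_redundancy_is_self_entropy(self):
        f = np.tile([0, 1, 1, 2], 50)
        assert redundancy([0], f[:, None]) == pytest.approx(
            mutual_information(f, f), abs=1e-12
        )

    def test_empty_set_rejected(self, rng):
        F = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            relevance([], np.ones(20), F)
        with pytest.raises(ValueError):
            redundancy([], F)


class TestMRMRRank:
    def test_class_copy_ranked_first(self, rng):
        c = rng.integers(1, 4, size=300)
        F = np.column_stack([c.astype(float), rng.standard_normal(300)])
        res = mrmr_rank(F, c, k=2)
        assert res.ranked_indices[0] == 0

    def test_duplicate_penalized_below_weak_feature(self):
        rng = np.random.default_rng(42)
        n = 2000
        c = rng.integers(1, 4, size=n)
        # noisy informative feature: its exact duplicate pays full
        # self-redundancy H(f1) while adding no new class information
        f1 = np.where(rng.random(n) < 0.8, c, rng.integers(1, 4, size=n))
        f1 = f1 + 0.01 * rng.standard_normal(n)
        f2 = f1.copy()
        # weakly informative, conditionally independent of f1 given c
        f3 = np.where(rng.random(n) < 0.3, c, rng.integers(1, 4, size=n))
        f3 = f3 + 0.01 * rng.standard_normal(n)
        res = mrmr_rank(np.column_stack([f1, f2, f3]), c, k=3)
        order = res.ranked_indices
        assert order[0] == 0
        assert order.index(2) < order.index(1)

    def test_oracle_equivalence_20_tables(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 80, 6
            c = rng.integers(1, 4, size=n)
            F = rng.standard_normal((n, p))
            # plant class signal in a random half of the features
            for j in rng.choice(p, size=3, replace=False):
                F[:, j] += 0.8 * c
            got = mrmr_rank(F, c, k=p).ranked_indices
            want = brute_force_mrmr(F, c, k=p)
            assert got == want, f"seed {seed}"

    def test_k_too_large_rejected(self, rng):
        F = rng.standard_normal((50, 3))
        with pytest.raises(ValueError):
            mrmr_rank(F, rng.integers(1, 3, size=50), k=4)

    def test_deterministic(self, rng):
        F = rng.standard_normal((100, 8))
        c = rng.integers(1, 5, size=100)
        a = mrmr_rank(F, c, k=5).ranked_indices
        b = mrmr_rank(F, c, k=5).ranked_indices
        assert a == b

    def test_monotone_rescale_invariant(self, rng):
        F = rng.standard_normal((200, 6))
        c = rng.integers(1, 4, size=200)
        a = mrmr_rank(F, c, k=4).ranked_indices
        G = F * np.array([2.0, 0.5, 10.0, 1.0, 3.0, 7.0]) + 5.0
        b = mrmr_rank(G, c, k=4).ranked_indices
        assert a == b

    def test_per_step_scores_finite_and_recorded(self, rng):
        F = rng.standard_normal((100, 6))
        c = rng.integers(1, 4, size=100)
        res = mrmr_rank(F, c, k=4)
        assert len(res.per_step) == 4
        for step in res.per_step:
            assert np.isfinite(step.relevance)
            assert np.isfinite(step.redundancy)
            assert step.score == pytest.approx(
                step.relevance - step.redundancy
            )

    def test_informative_recovery_benchmark(self):
        # 12 features, 4 informative 3-state features with flip-noise 0.1,
        # n=500: top-4 recovers >= 3 informative in every seed
        for seed in range(20):
            rng = np.random.default_rng(seed + 1000)
            n = 500
            c = rng.integers(1, 4, size=n)
            cols = []
            informative = [0, 3, 7, 11]
            for j in range(12):
                if j in informative:
                    f = c.copy()
                    flip = rng.random(n) < 0.1
                    f[flip] = rng.integers(1, 4, size=flip.sum())
                else:
                    f = rng.integers(1, 4, size=n)
                cols.append(f + 0.01 * rng.standard_normal(n))
            res = mrmr_rank(np.column_stack(cols), c, k=4)
            hits = len(set(res.ranked_indices) & set(informative))
            assert hits >= 3, f"seed {seed}: {res.ranked_indices}"
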