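import numpy as np
import pytest

from semgvowel.classifier import (
    NetworkConfig,
    NetworkModel,
    TrainConfig,
    TrainingError,
    forward,
    hidden_size,
    init_network,
    load_model,
    loss_and_grad,
    one_hot,
    predict,
    save_model,
    split_data,
    train_scg,
    _pack,
)


class TestHiddenSize:
    def test_twelve_gives_25(self):
        assert hidden_size(12) == 25

    def test_lower_bound(self):
        assert hidden_size(2) == 5

    def test_57_gives_115(self):
        assert hidden_size(57) == 115

    def test_below_bound_rejected(self):
        with pytest.raises(ValueError):
            hidden_size(1)


class TestInitNetwork:
    def test_seed_reproducible(self):
        a = init_network(NetworkConfig(12, seed=3))
        b = init_network(NetworkConfig(12, seed=3))
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.b2, b.b2)

    def test_shapes(self):
        m = init_network(NetworkConfig(n_inputs=12, n_outputs=11))
        assert m.w1.shape == (25, 12)
        assert m.b1.shape == (25,)
        assert m.w2.shape == (11, 25)
        assert m.b2.shape == (11,)

    def test_zero_weights_zero_output(self, rng):
        m = init_network(NetworkConfig(4, n_outputs=3))
        m.w1[:] = 0; m.b1[:] = 0; m.w2[:] = 0; m.b2[:] = 0
        out = forward(m, rng.standard_normal((5, 4)))
        np.testing.assert_array_equal(out, np.zeros((5, 3)))

    def test_default_hidden_follows_rule(self):
        assert NetworkConfig(n_inputs=7).n_hidden == 15


class TestForward:
    def test_hand_computed_2_2_1(self):
        cfg = NetworkConfig(n_inputs=2, n_hidden=2, n_outputs=2)
        m = init_network(cfg)
        m.w1 = np.array([[0.5, -0.25], [1.0, 2.0]])
        m.b1 = np.array([0.1, -0.2])
        m.w2 = np.array([[1.5, -1.0], [0.5, 0.5]])
        m.b2 = np.array([0.05, 0.0])
        x = np.array([0.3, -0.7])
        h = np.tanh(m.w1 @ x + m.b1)
        want = np.tanh(m.w2 @ h + m.b2)
        got = forward(m, x)[0]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_outputs_in_open_interval(self, rng):
        m = init_network(NetworkConfig(5, n_outputs=4))
        out = forward(m, rng.standard_normal((20, 5)) * 100)
        assert np.all(np.abs(out) < 1.0)

    def test_dimension_mismatch_rejected(self, rng):
        m = init_network(NetworkConfig(5, n_outputs=4))
        with pytest.raises(ValueError):
            forward(m, rng.standard_normal((3, 7)))


class TestGradient:
    def test_analytic_matches_finite_differences(self, rng):
        # the core SCG correctness check
        cfg = NetworkConfig(n_inputs=4, n_hidden=6, n_outputs=3, seed=1)
        m = init_network(cfg)
        X = rng.standard_normal((12, 4))
        T = one_hot(rng.integers(1, 4, size=12), 3)
        w0 = _pack(m)
        _, g = loss_and_grad(m, w0, X, T)
        eps = 1e-6
        num = np.empty_like(w0)
        for i in range(w0.size):
            wp = w0.copy(); wp[i] += eps
            wm = w0.copy(); wm[i] -= eps
            fp, _ = loss_and_grad(m, wp, X, T, want_grad=False)
            fm, _ = loss_and_grad(m, wm, X, T, want_grad=False)
            num[i] = (fp - fm) / (2 * eps)
        rel = np.linalg.norm(g - num) / max(np.linalg.norm(g + num), 1e-12)
        assert rel < 1e-6


class TestSplitData:
    def test_sizes_100(self):
        y = np.repeat(np.arange(1, 11), 10)
        tr, va, te = split_data(np.zeros((100, 2)), y, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_cover(self, rng):
        y = rng.integers(1, 5, size=83)
        tr, va, te = split_data(np.zeros((83, 2)), y, seed=1,
                                stratified=False)
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx) == list(range(83))

    def test_same_seed_same_split(self, rng):
        y = rng.integers(1, 5, size=60)
        a = split_data(np.zeros((60, 2)), y, seed=9)
        b = split_data(np.zeros((60, 2)), y, seed=9)
        for x1, x2 in zip(a, b):
            np.testing.assert_array_equal(x1, x2)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.zeros((10, 1)), np.ones(10), (0.5, 0.2, 0.2))

    def test_stratified_preserves_classes(self):
        y = np.repeat([1, 2, 3, 4], 25)
        tr, va, te = split_data(np.zeros((100, 1)), y, seed=3)
        for part in (tr, va, te):
            assert set(y[part]) == {1, 2, 3, 4}


def _xor_data(n_rep=25, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.tile(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]),
                (n_rep, 1))
    y = np.tile(np.array([1, 2, 2, 1]), n_rep)
    X = X + noise * rng.standard_normal(X.shape)
    return X, y


class TestTrainSCG:
    def test_xor_solved_most_seeds(self):
        solved = 0
        for seed in range(20):
            X, y = _xor_data(n_rep=25, noise=0.05, seed=seed)
            cfg = NetworkConfig(n_inputs=2, n_hidden=5, n_outputs=2,
                                seed=seed)
            m = init_network(cfg)
            tc = TrainConfig(max_epochs=500, patience=50, seed=seed)
            train_scg(m, X, y, tc)
            pred, _ = predict(m, X)
            if np.mean(pred == y) == 1.0:
                solved += 1
        assert solved >= 18

    def test_separated_gaussians(self, rng):
        n_per = 60
        centers = rng.standard_normal((2, 12)) * 6
        X = np.vstack([
            centers[0] + rng.standard_normal((n_per, 12)),
            centers[1] + rng.standard_normal((n_per, 12)),
        ])
        y = np.repeat([1, 2], n_per)
        m = init_network(NetworkConfig(12, n_outputs=2, seed=0))
        train_scg(m, X, y, TrainConfig(max_epochs=300, seed=0))
        _, va, te = split_data(X, y, seed=0)
        pred, _ = predict(m, X[te])
        assert np.mean(pred == y[te]) >= 0.95

    def test_training_loss_decreases(self, rng):
        X, y = _xor_data(n_rep=25, noise=0.05, seed=1)
        m = init_network(NetworkConfig(2, n_hidden=5, n_outputs=2, seed=1))
        train_scg(m, X, y, TrainConfig(max_epochs=200, seed=1))
        hist = m.history
        assert hist[min(m.stopped_epoch, len(hist)) - 1]["train_loss"] \
            <= hist[0]["train_loss"]

    def test_early_stopping_returns_best_epoch(self, rng):
        X = rng.standard_normal((200, 4))
        y = rng.integers(1, 4, size=200)  # unlearnable -> overfits fast
        m = init_network(NetworkConfig(4, n_outputs=3, seed=2))
        train_scg(m, X, y, TrainConfig(max_epochs=300, patience=6, seed=2))
        val = [h["val_loss"] for h in m.history]
        best = m.stopped_epoch
        assert all(val[best - 1] <= v + 1e-12 for v in val[best:])

    def test_label_permutation_chance_level(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 5))
            y = rng.integers(1, 4, size=150)
            m = init_network(NetworkConfig(5, n_outputs=3, seed=seed))
            train_scg(m, X, y, TrainConfig(max_epochs=60, seed=seed))
            _, va, te = split_data(X, y, seed=seed)
            pred, _ = predict(m, X[te])
            accs.append(np.mean(pred == y[te]))
        chance = 1 / 3
        sd = np.sqrt(chance * (1 - chance) / (0.15 * 150))
        assert abs(np.mean(accs) - chance) < 3 * sd

    def test_missing_class_in_training_rejected(self, rng):
        # a singleton class ends up outside the non-stratified training
        # split for some seed; the guard must then refuse to train
        X = rng.standard_normal((40, 3))
        y = np.array([1] * 39 + [2])
        raised = False
        for seed in range(20):
            m = init_network(NetworkConfig(3, n_outputs=2, seed=seed))
            try:
                train_scg(m, X, y,
                          TrainConfig(seed=seed, max_epochs=5,
                                      stratified=False))
            except (TrainingError, ValueError):
                raised = True
                break
        assert raised


class TestPredict:
    def _trained(self):
        X, y = _xor_data(seed=3, noise=0.05)
        m = init_network(NetworkConfig(2, n_hidden=5, n_outputs=2, seed=3))
        return train_scg(m, X, y, TrainConfig(max_epochs=200, seed=3)), X

    def test_argmax_rule(self):
        m, X = self._trained()
        pred, scores = predict(m, X)
        np.testing.assert_array_equal(pred, np.argmax(scores, axis=1) + 1)

    def test_untrained_rejected(self, rng):
        m = init_network(NetworkConfig(3, n_outputs=2))
        with pytest.raises(TrainingError):
            predict(m, rng.standard_normal((2, 3)))

    def test_tie_breaks_low_index(self):
        labels = np.argmax(np.array([[0.5, 0.5, 0.1]]), axis=1) + 1
        assert labels[0] == 1


class TestModelIO:
    def test_round_trip(self, tmp_path):
        X, y = _xor_data(seed=4, noise=0.05)
        m = init_network(NetworkConfig(2, n_hidden=5, n_outputs=2, seed=4))
        train_scg(m, X, y, TrainConfig(max_epochs=100, seed=4))
        p = tmp_path / "model.json"
        save_model(m, str(p))
        m2 = load_model(str(p))
        pred1, s1 = predict(m, X)
        pred2, s2 = predict(m2, X)
        np.testing.assert_array_equal(pred1, pred2)
        np.testing.assert_allclose(s1, s2, atol=1e-12)


def test_one_hot_contract():
    T = one_hot(np.array([1, 3, 2]), 3)
    np.testing.assert_array_equal(
        T, [[1, 0, 0], [0, 0, 1], [0, 1, 0]]
    )
    with pytest.raises(ValueError):
        one_hot(np.array([0, 1]), 3)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(split=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError):
        TrainConfig(patience=0)
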