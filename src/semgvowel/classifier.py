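"""One-hidden-layer tanh network sized by the 2*n_inputs + 1 rule, trained
with scaled conjugate gradient (Moller 1993) and validation-based early
stopping.

The loss is cross-entropy of the tanh outputs mapped affinely to (0, 1)
against {0, 1} one-hot targets; with y = tanh(z) and p = (y + 1)/2 the
per-output gradient wrt z collapses to 2 (p - t), which makes the
finite-difference gradient check sharp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

_EPS = 1e-12


class TrainingError(RuntimeError):
    pass


def hidden_size(n_inputs: int) -> int:
    """Hidden-layer width 2*n_inputs + 1 (mapping-network sizing rule;
    requires n_inputs >= 2)."""
    if n_inputs < 2:
        raise ValueError("sizing rule requires at least 2 inputs")
    return 2 * n_inputs + 1


@dataclass
class NetworkConfig:
    n_inputs: int
    n_hidden: int | None = None
    n_outputs: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 2:
            raise ValueError("n_inputs must be >= 2")
        if self.n_outputs < 2:
            raise ValueError("n_outputs must be >= 2")
        if self.n_hidden is None:
            self.n_hidden = hidden_size(self.n_inputs)


@dataclass
class TrainConfig:
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 1000
    patience: int = 6
    sigma: float = 5e-5
    lambda_init: float = 5e-7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class NetworkModel:
    config: NetworkConfig
    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)
    history: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    trained: bool = False
    x_mean: np.ndarray | None = None  # training-split z-score statistics
    x_std: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size


def init_network(cfg: NetworkConfig) -> NetworkModel:
    """Nguyen-Widrow-style scaled uniform initialization, seed-reproducible."""
    rng = np.random.default_rng(cfg.seed)
    nh = cfg.n_hidden
    w1 = rng.uniform(-1, 1, size=(nh, cfg.n_inputs))
    beta = 0.7 * nh ** (1.0 / cfg.n_inputs)
    norms = np.linalg.norm(w1, axis=1, keepdims=True)
    w1 = beta * w1 / np.maximum(norms, _EPS)
    b1 = rng.uniform(-beta, beta, size=nh)
    lim = 1.0 / np.sqrt(nh)
    w2 = rng.uniform(-lim, lim, size=(cfg.n_outputs, nh))
    b2 = rng.uniform(-lim, lim, size=cfg.n_outputs)
    return NetworkModel(config=cfg, w1=w1, b1=b1, w2=w2, b2=b2)


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """y = tanh(W2 tanh(W1 x + b1) + b2); rows are samples."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.config.n_inputs:
        raise ValueError(
            f"input dimension {x.shape[1]} != n_inputs {model.config.n_inputs}"
        )
    h = np.tanh(x @ model.w1.T + model.b1)
    return np.tanh(h @ model.w2.T + model.b2)


def _pack(model: NetworkModel) -> np.ndarray:
    return np.concatenate(
        [model.w1.ravel(), model.b1, model.w2.ravel(), model.b2]
    )


def _unpack(model: NetworkModel, w: np.ndarray) -> None:
    ni, nh, no = (model.config.n_inputs, model.config.n_hidden,
                  model.config.n_outputs)
    i = 0
    model.w1 = w[i:i + nh * ni].reshape(nh, ni); i += nh * ni
    model.b1 = w[i:i + nh]; i += nh
    model.w2 = w[i:i + no * nh].reshape(no, nh); i += no * nh
    model.b2 = w[i:i + no]


def loss_and_grad(
    model: NetworkModel,
    w: np.ndarray,
    X: np.ndarray,
    T: np.ndarray,
    want_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Mean cross-entropy over samples and outputs, and its gradient."""
    _unpack(model, w)
    n = X.shape[0]
    a1 = X @ model.w1.T + model.b1
    h = np.tanh(a1)
    a2 = h @ model.w2.T + model.b2
    y = np.tanh(a2)
    p = np.clip((y + 1.0) / 2.0, _EPS, 1.0 - _EPS)
    loss = float(
        -np.mean(T * np.log(p) + (1.0 - T) * np.log(1.0 - p))
    )
    if not want_grad:
        return loss, None
    m = T.size  # n * n_outputs, the mean's denominator
    # d loss / d a2 = 2 (p - t) / m   (exact when p is unclipped)
    delta2 = 2.0 * (p - T) / m
    gw2 = delta2.T @ h
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ model.w2) * (1.0 - h**2)
    gw1 = delta1.T @ X
    gb1 = delta1.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])
    return loss, grad


def split_data(
    X: np.ndarray,
    y: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test index cover (stratified by
    class unless disabled)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(y)
    idx = np.arange(n)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    empty = np.array([], dtype=int)
    if n_test > 0:
        strat = y if stratified else None
        rest, test = train_test_split(
            idx, test_size=n_test, random_state=seed, stratify=strat
        )
    else:
        rest, test = idx, empty
    if n_val > 0:
        strat_rest = y[rest] if stratified else None
        train, val = train_test_split(
            rest, test_size=n_val, random_state=seed + 1, stratify=strat_rest
        )
    else:
        train, val = rest, empty
    return np.sort(train), np.sort(val), np.sort(test)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    """{0,1} targets; labels are 1-based class ids."""
    y = np.asarray(y, dtype=int)
    if y.min() < 1 or y.max() > n_classes:
        raise ValueError("labels must be 1-based class ids within range")
    T = np.zeros((y.size, n_classes))
    T[np.arange(y.size), y - 1] = 1.0
    return T


def scg_minimize(
    model: NetworkModel,
    X: np.ndarray,
    T: np.ndarray,
    max_iters: int,
    sigma0: float = 5e-5,
    lambda_init: float = 5e-7,
    callback=None,
) -> np.ndarray:
    """Moller's scaled conjugate gradient on the packed weight vector.

    ``callback(k, w)`` may return True to stop early (early stopping).
    """
    w = _pack(model)
    n_par = w.size
    lam = lambda_init
    lam_bar = 0.0
    f, g = loss_and_grad(model, w, X, T)
    r = -g
    p = r.copy()
    success = True
    delta = 0.0
    s = np.zeros_like(w)
    for k in range(1, max_iters + 1):
        p_norm2 = float(p @ p)
        if p_norm2 < _EPS:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_plus = loss_and_grad(model, w + sigma * p, X, T)
            s = (g_plus - g) / sigma
            delta = float(p @ s)
        # scale to make the Hessian estimate positive definite
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, _ = loss_and_grad(model, w + alpha * p, X, T,
                                 want_grad=False)
        Delta = 2.0 * delta * (f - f_new) / mu**2
        if Delta >= 0:
            w = w + alpha * p
            f, g_new = loss_and_grad(model, w, X, T)
            lam_bar = 0.0
            success = True
            r_new = -g_new
            if k % n_par == 0:
                p = r_new.copy()  # restart along steepest descent
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            g = g_new
            if Delta >= 0.75:
                lam = max(lam * 0.25, 1e-20)
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam += delta * (1.0 - Delta) / p_norm2
            lam = min(lam, 1e20)
        if callback is not None and callback(k, w):
            break
    _unpack(model, w)
    return w


def train_scg(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    tc: TrainConfig | None = None,
) -> NetworkModel:
    """Train with SCG and early stopping on a random 70/15/15 split.

    Inputs are z-scored with training-split statistics (stored on the
    model); weights from the best-validation epoch are returned.
    """
    tc = tc or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_classes = model.config.n_outputs
    tr, va, te = split_data(X, y, tc.split, seed=tc.seed,
                            stratified=tc.stratified)
    if len(np.unique(y[tr])) < len(np.unique(y)):
        raise TrainingError(
            "a class is missing from the training split; "
            "use stratified splitting or more data"
        )
    mean = X[tr].mean(axis=0)
    std = X[tr].std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    model.x_mean, model.x_std = mean, std
    T = one_hot(y, n_classes)

    sets = {"train": tr, "val": va, "test": te}
    best = {"loss": np.inf, "w": _pack(model).copy(), "epoch": 0}
    bad_streak = 0
    history: list[dict] = []

    def callback(k: int, w: np.ndarray) -> bool:
        nonlocal bad_streak
        entry = {"epoch": k}
        for name, idx in sets.items():
            if idx.size:
                l, _ = loss_and_grad(model, w, Z[idx], T[idx],
                                     want_grad=False)
            else:
                l = np.nan
            entry[f"{name}_loss"] = l
        history.append(entry)
        v = entry["val_loss"]
        if np.isnan(v) or v < best["loss"] - 1e-12:
            if not np.isnan(v):
                best.update(loss=v, w=w.copy(), epoch=k)
            bad_streak = 0
        else:
            bad_streak += 1
        return bad_streak >= tc.patience

    scg_minimize(
        model, Z[tr], T[tr], max_iters=tc.max_epochs,
        sigma0=tc.sigma, lambda_init=tc.lambda_init, callback=callback,
    )
    _unpack(model, best["w"])
    model.history = history
    model.stopped_epoch = best["epoch"]
    model.trained = True
    return model


def predict(model: NetworkModel,
            X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores): argmax over output scores, 1-based labels; ties
    break to the lowest class index."""
    if not model.trained:
        raise TrainingError("model has not been trained")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.x_mean is not None:
        X = (X - model.x_mean) / model.x_std
    scores = forward(model, X)
    labels = np.argmax(scores, axis=1) + 1
    return labels, scores


def save_model(model: NetworkModel, path: str) -> None:
    payload = {
        "config": {
            "n_inputs": model.config.n_inputs,
            "n_hidden": model.config.n_hidden,
            "n_outputs": model.config.n_outputs,
            "seed": model.config.seed,
        },
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "x_mean": None if model.x_mean is None else model.x_mean.tolist(),
        "x_std": None if model.x_std is None else model.x_std.tolist(),
        "feature_names": model.feature_names,
        "stopped_epoch": model.stopped_epoch,
        "trained": model.trained,
        "history": model.history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str) -> NetworkModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = NetworkConfig(**payload["config"])
    model = NetworkModel(
        config=cfg,
        w1=np.array(payload["w1"]),
        b1=np.array(payload["b1"]),
        w2=np.array(payload["w2"]),
        b2=np.array(payload["b2"]),
        history=payload.get("history", []),
        stopped_epoch=payload.get("stopped_epoch", 0),
        trained=payload.get("trained", False),
        feature_names=payload.get("feature_names", []),
    )
    if payload.get("x_mean") is not None:
        model.x_mean = np.array(payload["x_mean"])
        model.x_std = np.array(payload["x_std"])
    return model
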