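"""Cross-validated multiclass evaluation: confusion matrix, per-class
accuracy, one-vs-rest ROC and stratified k-fold CV.

The 70/15/15 split lives INSIDE each training fold (it drives early
stopping); the outer stratified 10-fold supplies the reported accuracy.
Feature scaling and mRMR selection are refit per fold, and every fold
logs the indices used to fit them so leakage can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .classifier import (
    NetworkConfig,
    TrainConfig,
    hidden_size,
    init_network,
    predict,
    train_scg,
)
from .feature_selection import DiscretizationScheme, mrmr_rank


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.class_names:
            self.class_names = [str(i + 1) for i in range(len(self.counts))]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ROCCurve:
    class_id: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    defined: bool = True


@dataclass
class CVResult:
    fold_accuracies: list[float]
    pooled_confusion: ConfusionMatrix
    mean_accuracy: float
    sd_accuracy: float
    per_class_accuracy: np.ndarray
    fold_assignments: np.ndarray
    seed: int
    selections: list[list[int]] = field(default_factory=list)
    fit_index_log: list[np.ndarray] = field(default_factory=list)
    roc: list[ROCCurve] = field(default_factory=list)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    """counts[i][j] = #{true class i+1 predicted as class j+1}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 1 or v.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts=counts)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """100 * diagonal / row sum, NaN-flagged for empty classes."""
    row = cm.counts.sum(axis=1).astype(float)
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = 100.0 * diag / row
    acc[row == 0] = np.nan
    return acc


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def roc_one_vs_rest(
    scores: np.ndarray, y_true: np.ndarray, n_classes: int | None = None
) -> list[ROCCurve]:
    """Per-class ROC treating class c as positive, all others negative."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_classes = n_classes or scores.shape[1]
    curves = []
    for c in range(1, n_classes + 1):
        pos = (y_true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == pos.size:
            curves.append(
                ROCCurve(c, np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                         np.array([np.inf, -np.inf]), auc=np.nan,
                         defined=False)
            )
            continue
        fpr, tpr, thr = _roc_curve(pos, scores[:, c - 1])
        curves.append(ROCCurve(c, fpr, tpr, thr, auc=float(_auc(fpr, tpr))))
    return curves


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray | None = None,
    k_folds: int = 10,
    seed: int = 0,
    n_select: int = 12,
    n_classes: int = 11,
    scheme: DiscretizationScheme | None = None,
    train_config: TrainConfig | None = None,
    cv_mode: str = "trial",
    fixed_selection: list[int] | None = None,
) -> CVResult:
    """Outer stratified k-fold CV with per-fold mRMR and network training.

    ``cv_mode='subject'`` switches to leave-subjects-out grouping.
    ``fixed_selection`` bypasses per-fold mRMR with a frozen feature list.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=n_classes + 1)[1:]
    if cv_mode == "trial" and counts.min() < k_folds:
        raise ValueError(
            f"stratified {k_folds}-fold CV needs >= {k_folds} trials per "
            f"class; worst class has {counts.min()}"
        )
    if cv_mode == "subject":
        if subjects is None:
            raise ValueError("subject-wise CV requires subject ids")
        splitter = GroupKFold(n_splits=k_folds)
        folds = splitter.split(X, y, groups=subjects)
    else:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True,
                                   random_state=seed)
        folds = splitter.split(X, y)

    base_tc = train_config or TrainConfig()
    fold_assignments = np.full(len(y), -1, dtype=int)
    fold_acc: list[float] = []
    selections: list[list[int]] = []
    fit_log: list[np.ndarray] = []
    all_true = np.empty(len(y), dtype=int)
    all_pred = np.empty(len(y), dtype=int)
    all_scores = np.zeros((len(y), n_classes))

    for f, (tr, te) in enumerate(folds):
        fold_assignments[te] = f
        fit_log.append(np.sort(tr))
        if fixed_selection is not None:
            sel = list(fixed_selection)
        else:
            sel = mrmr_rank(X[tr], y[tr], k=n_select,
                            scheme=scheme).ranked_indices
        selections.append(sel)
        cfg = NetworkConfig(n_inputs=len(sel),
                            n_hidden=hidden_size(len(sel)),
                            n_outputs=n_classes, seed=seed + f)
        tc = TrainConfig(split=base_tc.split, max_epochs=base_tc.max_epochs,
                         patience=base_tc.patience, sigma=base_tc.sigma,
                         lambda_init=base_tc.lambda_init, seed=seed + f,
                         stratified=base_tc.stratified)
        model = init_network(cfg)
        train_scg(model, X[np.ix_(tr, sel)], y[tr], tc)
        pred, scores = predict(model, X[np.ix_(te, sel)])
        all_true[te] = y[te]
        all_pred[te] = pred
        all_scores[te] = scores
        fold_acc.append(float(np.mean(pred == y[te]) * 100.0))

    pooled = confusion_matrix(all_true, all_pred, n_classes)
    return CVResult(
        fold_accuracies=fold_acc,
        pooled_confusion=pooled,
        mean_accuracy=float(np.mean(fold_acc)),
        sd_accuracy=float(np.std(fold_acc)),
        per_class_accuracy=per_class_accuracy(pooled),
        fold_assignments=fold_assignments,
        seed=seed,
        selections=selections,
        fit_index_log=fit_log,
        roc=roc_one_vs_rest(all_scores, all_true, n_classes),
    )
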