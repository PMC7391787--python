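"""RBF-kernel SVM training, grid search, and evaluation machinery.

Classifiers predict labels in {+1, -1}.  Evaluation covers the jackknife
(leave-one-out) test, stratified k-fold cross-validation, and the standard
binary metrics: sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/N, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(FN+TN)(TP+FN)(TN+FP)).

Compositional features already lie in [0, 1], so no additional scaling is
applied before the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoders import FeatureMatrix

#: Default coarse grid for (C, gamma): C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3.
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMConfig:
    """Radial-basis SVM hyperparameters (C regularization, gamma kernel width)."""

    C: float
    gamma: float
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError(f"C and gamma must be positive, got C={self.C}, gamma={self.gamma}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {"Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC,
                "flags": list(self.flags)}


def _check_labels(y: np.ndarray) -> None:
    bad = set(np.unique(y)) - {+1, -1}
    if bad:
        raise ValueError(f"labels must be +1/-1, got extra values {sorted(bad)}")


def train(fm: FeatureMatrix, config: SVMConfig) -> SVC:
    """Fit an RBF SVM on the whole matrix; both classes must be present."""
    if fm.n_samples == 0 or fm.n_features == 0:
        raise ValueError("empty feature matrix")
    _check_labels(fm.labels)
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("both classes must be present to train")
    model = SVC(kernel="rbf", C=config.C, gamma=config.gamma,
                class_weight=config.class_weight)
    model.fit(fm.X, fm.labels)
    return model


def predict_labels(model: SVC, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"dimension mismatch: model expects {model.n_features_in_} features, got {X.shape[1]}"
        )
    return model.predict(X).astype(int)


def confusion(pred, truth) -> ConfusionCounts:
    """Tabulate TP/FP/FN/TN for +/-1 predictions against +/-1 truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    _check_labels(pred)
    _check_labels(truth)
    return ConfusionCounts(
        TP=int(np.sum((pred == +1) & (truth == +1))),
        FP=int(np.sum((pred == +1) & (truth == -1))),
        FN=int(np.sum((pred == -1) & (truth == +1))),
        TN=int(np.sum((pred == -1) & (truth == -1))),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn/Sp/Acc/MCC from confusion counts, with flagged degenerate conventions.

    Sn (Sp) is reported as 0 and flagged when there are no positives
    (negatives); MCC is reported as 0 and flagged when any denominator
    factor vanishes.
    """
    TP, FP, FN, TN = counts.TP, counts.FP, counts.FN, counts.TN
    flags: list[str] = []
    if TP + FN > 0:
        sn = TP / (TP + FN)
    else:
        sn, flags = 0.0, flags + ["Sn undefined (no positives); reported as 0"]
    if TN + FP > 0:
        sp = TN / (TN + FP)
    else:
        sp, flags = 0.0, flags + ["Sp undefined (no negatives); reported as 0"]
    total = counts.total
    acc = (TP + TN) / total if total else 0.0
    denom = (TP + FP) * (FN + TN) * (TP + FN) * (TN + FP)
    if denom > 0:
        mcc = (TN * TP - FP * FN) / math.sqrt(denom)
    else:
        mcc = 0.0
        flags.append("MCC denominator zero; reported as 0")
    return MetricsReport(Sn=sn, Sp=sp, Acc=acc, MCC=mcc, flags=tuple(flags))


def kfold_accuracy(fm: FeatureMatrix, config: SVMConfig, folds: int = 5, seed: int = 0) -> float:
    """Mean accuracy over stratified k-fold cross-validation (seeded shuffle)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _check_labels(fm.labels)
    smallest = min(int(np.sum(fm.labels == c)) for c in (+1, -1))
    if folds > smallest:
        raise ValueError(f"folds={folds} exceeds smallest class size {smallest}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(fm.X, fm.labels):
        model = train(fm.subset_rows(tr), config)
        pred = predict_labels(model, fm.X[te])
        accs.append(float(np.mean(pred == fm.labels[te])))
    return float(np.mean(accs))


def grid_search(
    fm: FeatureMatrix,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    class_weight: str | None = None,
) -> SVMConfig:
    """Exhaustive (C, gamma) search maximizing cross-validated accuracy.

    Ties break deterministically to the smallest C, then the smallest gamma
    (grids are scanned in ascending order and only strict improvements are
    kept).
    """
    c_grid = sorted(float(c) for c in c_grid)
    gamma_grid = sorted(float(g) for g in gamma_grid)
    if not c_grid or not gamma_grid:
        raise ValueError("empty hyperparameter grid")
    best: SVMConfig | None = None
    best_acc = -1.0
    for C in c_grid:
        for gamma in gamma_grid:
            cfg = SVMConfig(C=C, gamma=gamma, class_weight=class_weight)
            acc = kfold_accuracy(fm, cfg, folds=folds, seed=seed)
            if acc > best_acc:
                best, best_acc = cfg, acc
    assert best is not None
    return best


def jackknife(fm: FeatureMatrix, config: SVMConfig) -> tuple[ConfusionCounts, MetricsReport]:
    """Leave-one-out test: each sample predicted by a model trained on the rest."""
    n = fm.n_samples
    _check_labels(fm.labels)
    for cls in (+1, -1):
        if int(np.sum(fm.labels == cls)) < 2:
            raise ValueError(f"class {cls:+d} needs >= 2 samples for jackknife")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        model = train(fm.subset_rows(rest), config)
        preds[i] = predict_labels(model, fm.X[i])[0]
    counts = confusion(preds, fm.labels)
    return counts, metrics(counts)
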