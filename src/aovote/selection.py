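"""ANOVA F-value feature ranking and incremental feature selection (IFS).

For each feature, the one-way two-group F statistic is the ratio of
between-class to within-class mean squares; for two classes it equals the
square of the pooled-variance two-sample t statistic.  IFS then adds features
from the top of the ranking one at a time, evaluates a classifier at each
subset size, and keeps the smallest subset attaining the peak accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .encoders import FeatureMatrix

#: Evaluator contract: FeatureMatrix -> accuracy in [0, 1].
Evaluator = Callable[[FeatureMatrix], float]


@dataclass
class FScoreRanking:
    """Features sorted by descending ANOVA F (ties broken by name)."""

    feature_names: list[str]
    f_values: np.ndarray

    def __post_init__(self) -> None:
        self.f_values = np.asarray(self.f_values, dtype=float)
        if len(self.feature_names) != self.f_values.shape[0]:
            raise ValueError("names/values length mismatch")

    def top(self, k: int) -> list[str]:
        return self.feature_names[:k]


@dataclass
class IFSResult:
    """Accuracy-vs-feature-count curve and its peak."""

    curve: list[tuple[int, float]]
    optimal_k: int
    optimal_features: list[str]
    optimal_accuracy: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.curve, columns=["k", "accuracy"]).to_csv(path, sep="\t", index=False)


def anova_f_values(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-column two-group ANOVA F, with degenerate-variance conventions.

    F = MSB / MSW with K = 2 groups; MSB = sum_c n_c (m_c - m)^2 / (K - 1),
    MSW = within-group sum of squares / (N - K).  A feature with zero
    within-group variance but distinct group means gets +inf (perfectly
    separating); an everywhere-constant feature gets 0.
    """
    labels = np.asarray(labels)
    pos = X[labels == +1]
    neg = X[labels == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples per class for ANOVA F")
    n1, n2 = len(pos), len(neg)
    N = n1 + n2
    m1 = pos.mean(axis=0)
    m2 = neg.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / N
    msb = (n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2) / (2 - 1)
    ssw = ((pos - m1) ** 2).sum(axis=0) + ((neg - m2) ** 2).sum(axis=0)
    msw = ssw / (N - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[(msw == 0) & (msb > 0)] = np.inf
    f[(msw == 0) & (msb == 0)] = 0.0
    # numerical fuzz can make msb tiny-negative-free but msw ~ 0
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    return f


def anova_f_scores(fm: FeatureMatrix) -> FScoreRanking:
    """Rank all features of ``fm`` by descending F (name-lexicographic ties)."""
    f = anova_f_values(fm.X, fm.labels)
    order = sorted(range(fm.n_features), key=lambda j: (-f[j], fm.feature_names[j]))
    return FScoreRanking(
        feature_names=[fm.feature_names[j] for j in order],
        f_values=f[order],
    )


def ifs_select(
    fm: FeatureMatrix,
    ranking: FScoreRanking,
    evaluator: Evaluator,
    max_k: int | None = None,
) -> IFSResult:
    """Incremental feature selection along ``ranking``.

    Evaluates the top-k feature subsets for k = 1..D (or up to ``max_k``,
    which truncates the search to the highest-ranked features) and returns
    the full curve plus the smallest k attaining the maximum accuracy.
    """
    missing = set(ranking.feature_names) - set(fm.feature_names)
    if missing:
        raise ValueError(f"ranking contains unknown features: {sorted(missing)[:5]}")
    D = len(ranking.feature_names)
    k_max = D if max_k is None else min(max_k, D)
    curve: list[tuple[int, float]] = []
    best_k, best_acc = 1, -1.0
    for k in range(1, k_max + 1):
        sub = fm.select_features(ranking.top(k))
        try:
            acc = float(evaluator(sub))
        except Exception as exc:
            raise RuntimeError(f"IFS evaluator failed at k={k}: {exc}") from exc
        if not 0.0 <= acc <= 1.0:
            raise RuntimeError(f"IFS evaluator returned accuracy {acc} at k={k}")
        curve.append((k, acc))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return IFSResult(
        curve=curve,
        optimal_k=best_k,
        optimal_features=ranking.top(best_k),
        optimal_accuracy=best_acc,
    )


def plot_ifs_curves(results: dict[str, IFSResult], path: str | Path) -> None:
    """Render IFS curves (one per model) with peak annotations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, res in results.items():
        ks, accs = zip(*res.curve)
        ax.plot(ks, accs, label=f"{name} (k*={res.optimal_k}, acc={res.optimal_accuracy:.3f})")
    ax.set_xlabel("number of features")
    ax.set_ylabel("accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
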