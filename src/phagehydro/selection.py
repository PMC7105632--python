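"""ANOVA F-scoring and incremental feature selection (IFS).

Each feature is scored by the one-way ANOVA F-value — the ratio of the
between-class mean square to the within-class mean square for the two
label groups; a large F marks a feature whose class means separate well
relative to its within-class spread.  IFS then evaluates a classifier by
cross-validation on growing prefixes of the F-ranked feature list and
returns the accuracy-vs-size curve with the smallest prefix achieving the
maximal accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ClassifierSpec, cv_accuracy
from .exceptions import ConfigError, PhageHydroError
from .features import FeatureMatrix

__all__ = ["FeatureRanking", "IFSResult", "anova_f", "incremental_feature_selection"]


@dataclass
class FeatureRanking:
    """Features ordered by descending F-value (ties by original column index)."""

    feature_names: list[str]
    f_values: np.ndarray

    def __post_init__(self) -> None:
        self.f_values = np.asarray(self.f_values, dtype=float)
        if len(self.feature_names) != len(self.f_values):
            raise PhageHydroError("ranking names and F-values differ in length")

    def top(self, k: int) -> list[str]:
        return self.feature_names[:k]


@dataclass
class IFSResult:
    """Accuracy-vs-subset-size curve and its optimum (smallest size at max)."""

    subset_sizes: list[int]
    accuracies: list[float]
    optimal_size: int
    optimal_accuracy: float
    selected_features: list[str]
    ranking: FeatureRanking


def anova_f(matrix: FeatureMatrix) -> FeatureRanking:
    """Per-feature one-way ANOVA F over the two label groups.

    Conventions: a feature constant across all samples gets F = 0; a
    feature with zero within-class variance but distinct class means is a
    perfect separator and gets F = +inf, sorting before every finite F.
    """
    if matrix.labels is None:
        raise PhageHydroError("ANOVA scoring requires a labelled matrix")
    y = matrix.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise PhageHydroError("ANOVA requires both classes present")
    if len(classes) > 2:
        raise PhageHydroError("labels must be binary")
    X = matrix.values
    if np.isnan(X).any():
        raise PhageHydroError("feature matrix contains missing values")
    g0, g1 = X[y == classes[0]], X[y == classes[1]]
    n0, n1 = len(g0), len(g1)
    if n0 < 2 or n1 < 2:
        raise PhageHydroError("ANOVA requires at least two samples per class")
    n = n0 + n1
    m0, m1 = g0.mean(axis=0), g1.mean(axis=0)
    grand = X.mean(axis=0)
    ss_between = n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2  # df = 1
    ss_within = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    ms_within = ss_within / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / ms_within
    f = np.where(ms_within == 0, np.where(ss_between > 0, np.inf, 0.0), f)
    f = np.where(ss_between == 0, 0.0, f)  # identical group means -> 0 even if noisy
    order = np.argsort(-f, kind="stable")  # stable: ties keep column order
    return FeatureRanking([matrix.names[i] for i in order], f[order])


def incremental_feature_selection(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    cv="loo",
    size_grid=None,
    stride: int = 1,
) -> IFSResult:
    """Evaluate CV accuracy on growing prefixes of the F-ranked features.

    ``size_grid`` defaults to every size 1..D in steps of ``stride`` (D is
    always included).  The optimum is the smallest evaluated size reaching
    the maximal accuracy.
    """
    if matrix.labels is None:
        raise PhageHydroError("IFS requires a labelled matrix")
    d = matrix.n_features
    if size_grid is None:
        if stride < 1:
            raise ConfigError(f"stride must be >= 1, got {stride}")
        size_grid = list(range(1, d + 1, stride))
        if size_grid[-1] != d:
            size_grid.append(d)
    sizes = sorted(set(int(k) for k in size_grid))
    if not sizes:
        raise ConfigError("IFS size grid is empty")
    if sizes[0] < 1 or sizes[-1] > d:
        raise ConfigError(f"IFS sizes must lie in 1..{d}, got {sizes[0]}..{sizes[-1]}")
    ranking = anova_f(matrix)
    col = {name: i for i, name in enumerate(matrix.names)}
    ranked_cols = np.array([col[name] for name in ranking.feature_names])
    accuracies = []
    for k in sizes:
        Xk = matrix.values[:, ranked_cols[:k]]
        accuracies.append(cv_accuracy(Xk, matrix.labels, spec, cv))
    best = int(np.argmax(accuracies))  # argmax returns first max -> smallest size
    return IFSResult(
        subset_sizes=sizes,
        accuracies=accuracies,
        optimal_size=sizes[best],
        optimal_accuracy=accuracies[best],
        selected_features=ranking.top(sizes[best]),
        ranking=ranking,
    )
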