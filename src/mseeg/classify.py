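"""Per-scale classification under 10-fold cross-validation.

Four classifiers are evaluated on the entropy feature matrices: linear
discriminant analysis (LDA), logistic regression (LR), a support vector
machine with radial-basis-function kernel (RBF-SVM, kernel scale 6.2), and
k-nearest neighbours (KNN, k = 10, Euclidean distance).  Performance is
summarised by accuracy, sensitivity, specificity and F1-score, averaged
over folds, with the MDD group as the positive class.

The RBF kernel follows the "kernel scale" convention
``K(u, v) = exp(-||u - v||^2 / s^2)``; libraries parameterised by gamma use
``gamma = 1 / s^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .entropy import EntropyConfig
from .features import FeatureMatrix, extract_feature_curves

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "MetricsTable",
    "DEFAULT_CLASSIFIERS",
    "POSITIVE_CLASS",
    "metrics_from_counts",
    "crossvalidate",
    "scale_scan",
    "make_estimator",
]

POSITIVE_CLASS = "MDD"
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration of the evaluation grid."""

    kind: str                       # LDA | LR | RBF-SVM | KNN
    svm_kernel_scale: float = 6.2
    knn_k: int = 10
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("LDA", "LR", "RBF-SVM", "KNN"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


DEFAULT_CLASSIFIERS = (
    ClassifierSpec("LDA"),
    ClassifierSpec("LR"),
    ClassifierSpec("RBF-SVM"),
    ClassifierSpec("KNN"),
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (positive class = MDD)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F1 from confusion counts.

    Accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).  A metric whose denominator is zero
    is returned as NaN (flagged missing), never raised.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


class NearestTieKNN(BaseEstimator, ClassifierMixin):
    """KNN majority vote; a tied vote falls to the single nearest neighbour."""

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._nn = NearestNeighbors(n_neighbors=min(self.k, len(X))).fit(X)
        self._y = np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        votes = self._y[idx]                       # n_query x k, nearest first
        out = np.empty(len(votes), dtype=self._y.dtype)
        for i, row in enumerate(votes):
            counts = {c: int((row == c).sum()) for c in self.classes_}
            best = max(counts.values())
            winners = [c for c, n in counts.items() if n == best]
            out[i] = winners[0] if len(winners) == 1 else row[0]
        return out


def make_estimator(spec: ClassifierSpec):
    """The scikit-learn estimator realising ``spec`` (without scaling)."""
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis()
    if spec.kind == "LR":
        # plain maximum likelihood up to a negligible ridge (C = 1e6),
        # which also keeps the solver fast on separable folds
        return LogisticRegression(C=1e6, max_iter=2000)
    if spec.kind == "RBF-SVM":
        return SVC(kernel="rbf", gamma=1.0 / spec.svm_kernel_scale**2)
    return NearestTieKNN(k=spec.knn_k)


@dataclass
class MetricsTable:
    """Fold-averaged metrics per (classifier, temporal scale).

    Wraps a tidy DataFrame with columns ``classifier``, ``tau`` and the
    four metric names.  ``grid(metric)`` pivots to the classifier x scale
    layout; ``classifier_average()`` is the discrete metric-vs-scale
    function f(tau) averaged over classifiers; ``scale_average()`` is the
    per-classifier mean over scales.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["classifier", "tau", *METRIC_NAMES]))

    def add_row(self, classifier: str, tau: int,
                metrics: dict[str, float]) -> None:
        row = pd.DataFrame([{"classifier": classifier, "tau": tau,
                             **metrics}])
        self.df = row if self.df.empty else \
            pd.concat([self.df, row], ignore_index=True)

    def grid(self, metric: str = "accuracy") -> pd.DataFrame:
        return self.df.pivot(index="classifier", columns="tau",
                             values=metric)

    def classifier_average(self) -> pd.DataFrame:
        return self.df.groupby("tau")[list(METRIC_NAMES)].mean()

    def scale_average(self) -> pd.DataFrame:
        return self.df.groupby("classifier")[list(METRIC_NAMES)].mean()


def _fold_splitter(k: int, seed: int | None, grouped: bool):
    if grouped:
        return StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def crossvalidate(fm: FeatureMatrix, spec: ClassifierSpec, k: int = 10,
                  seed: int | None = 0,
                  subject_grouped: bool = False) -> dict[str, float]:
    """Stratified k-fold cross-validation of one classifier on one matrix.

    Epochs are partitioned at random into ``k`` stratified folds (seeded,
    so bit-reproducible); standardisation statistics are fitted on the
    training folds only.  Metrics are computed per fold from its confusion
    counts and averaged (NaN-aware) over folds.

    ``subject_grouped=True`` keeps all epochs of a subject in the same
    fold.  The default epoch-level partition lets epochs of one subject
    appear in both training and test folds, which inflates performance on
    real cohorts — a caveat to keep in mind when interpreting absolute
    numbers.
    """
    y = np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in fm.y])
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"need >= {k} samples per class for {k}-fold CV, got {counts}"
        )
    splitter = _fold_splitter(k, seed, subject_grouped)
    groups = fm.subject_ids if subject_grouped else None
    fold_metrics: list[dict[str, float]] = []
    for train, test in splitter.split(fm.X, y, groups=groups):
        Xtr, Xte = fm.X[train], fm.X[test]
        if spec.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        est = make_estimator(spec).fit(Xtr, y[train])
        pred = np.asarray(est.predict(Xte))
        yt = y[test]
        cc = ConfusionCounts(
            tp=int(((pred == 1) & (yt == 1)).sum()),
            fp=int(((pred == 1) & (yt == 0)).sum()),
            fn=int(((pred == 0) & (yt == 1)).sum()),
            tn=int(((pred == 0) & (yt == 0)).sum()),
        )
        fold_metrics.append(metrics_from_counts(cc))
    return {name: float(np.nanmean([fm_[name] for fm_ in fold_metrics]))
            for name in METRIC_NAMES}


def scale_scan(epochs, cfg: EntropyConfig = EntropyConfig(),
               specs=DEFAULT_CLASSIFIERS, seed: int = 0, k: int = 10,
               subject_grouped: bool = False,
               feature_matrices: dict[int, FeatureMatrix] | None = None,
               ) -> MetricsTable:
    """The full classifier x scale evaluation grid.

    Extracts the per-scale feature matrices once (unless pre-computed ones
    are passed) and cross-validates every classifier at every scale
    tau = 1..cfg.tau_max.  All classifiers share the same fold partition at
    a given scale; the partition seed is derived from ``seed`` and tau.
    """
    if feature_matrices is None:
        feature_matrices = extract_feature_curves(epochs, cfg)
    table = MetricsTable()
    for tau in sorted(feature_matrices):
        fm = feature_matrices[tau]
        fold_seed = (seed * 1000003 + tau) % (2**31)
        for spec in specs:
            table.add_row(spec.kind, tau,
                          crossvalidate(fm, spec, k=k, seed=fold_seed,
                                        subject_grouped=subject_grouped))
    return table
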