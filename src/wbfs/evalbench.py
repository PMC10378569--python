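"""Cross-validation benchmarking of criterion + classifier pairs.

The protocol: stratified 10-fold partition; per fold the training portion
is discretized, the ranking criterion is run on it, the top-K features are
kept, a classifier is trained on those features, and held-out accuracy is
recorded.  Two methods are then compared per dataset by a paired t-test on
matched fold accuracies, yielding a Win/Tie/Loss verdict at a chosen
significance level (0.1 in the reference protocol, with K = 15 features
and a 5-neighbor KNN).

Discretization may be fitted on the full table before splitting
(``fit_bins_on="full"``, replicating protocols that discretize datasets up
front) or on each training fold only (``"train"``, the leakage-safe
default).  The same switch exists for where the ranking runs
(``select_on``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import CategoricalNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datatable import FeatureTable
from .discretize import DiscreteTable, apply_binning, fit_equal_width
from .selectors import CriterionSpec, select

__all__ = [
    "CVReport",
    "ComparisonReport",
    "ClassifierAdapter",
    "make_classifier",
    "evaluate",
    "accuracy_curve",
    "dataset_ratio",
    "compare_wtl",
]

PROTOCOL_K = 15          # features kept in the reference protocol
PROTOCOL_KNN_K = 5       # KNN neighbor count
PROTOCOL_ALPHA = 0.1     # W/T/L significance level
PROTOCOL_FOLDS = 10


@dataclass
class CVReport:
    """Per-fold accuracies of one (criterion, classifier, K) run."""

    method: str
    classifier: str
    K: int
    accuracies: list[float]
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "classifier": self.classifier,
                "K": self.K,
                "accuracies": self.accuracies,
                "mean": self.mean,
                "sd": self.sd,
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass
class ComparisonReport:
    """Win/Tie/Loss verdict from the reference method's perspective."""

    decision: str  # "Win" | "Tie" | "Loss"
    p_value: float  # nan when the t statistic is undefined
    alpha: float


class ClassifierAdapter:
    """Thin train/predict wrapper; ``wants_discrete`` picks the representation."""

    def __init__(self, name: str, estimator, wants_discrete: bool = False):
        self.name = name
        self.estimator = estimator
        self.wants_discrete = wants_discrete

    def train(self, features: np.ndarray, labels: np.ndarray) -> None:
        self.estimator.fit(features, labels)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.predict(features)


class _MajorityVote:
    """Predicts the most frequent training label; noise-floor baseline."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.label_)


def make_classifier(name: str, bins: int = 5) -> ClassifierAdapter:
    """Reference adapters: knn (k=5), nbc (naive Bayes on codes), svm, majority."""
    if name == "knn":
        return ClassifierAdapter(
            "knn", KNeighborsClassifier(n_neighbors=PROTOCOL_KNN_K)
        )
    if name == "nbc":
        return ClassifierAdapter(
            "nbc", CategoricalNB(min_categories=bins), wants_discrete=True
        )
    if name == "svm":
        return ClassifierAdapter("svm", SVC())
    if name == "majority":
        return ClassifierAdapter("majority", _MajorityVote())
    raise ValueError(f"unknown classifier {name!r}; valid: knn, nbc, svm, majority")


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    seen: dict = {}
    return np.array([seen.setdefault(l, len(seen)) for l in labels], dtype=np.int64)


def _fold_traces(
    data: FeatureTable,
    criterion: CriterionSpec,
    K: int,
    folds: int,
    bins: int,
    seed: int,
    fit_bins_on: str,
    select_on: str,
):
    """Shared fold loop: yields (train_idx, test_idx, trace, disc_train, disc_test)."""
    if fit_bins_on not in ("full", "train") or select_on not in ("full", "train"):
        raise ValueError("fit_bins_on and select_on must be 'full' or 'train'")
    y = _encode_labels(data.class_labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    full_model = fit_equal_width(data, bins) if fit_bins_on == "full" else None
    full_disc = apply_binning(data, full_model) if full_model is not None else None

    out = []
    for train_idx, test_idx in skf.split(data.values, y):
        train = FeatureTable(
            data.values[train_idx], data.feature_names, data.class_labels[train_idx]
        )
        test = FeatureTable(
            data.values[test_idx], data.feature_names, data.class_labels[test_idx]
        )
        model = full_model if full_model is not None else fit_equal_width(train, bins)
        disc_train = apply_binning(train, model)
        disc_test = apply_binning(test, model)
        if select_on == "full":
            sel_data = DiscreteTable(
                full_disc.codes if full_disc is not None
                else apply_binning(data, model).codes,
                list(data.feature_names),
                y,
            )
        else:
            sel_data = disc_train
        trace = select(sel_data, criterion, K)
        out.append((train_idx, test_idx, trace, disc_train, disc_test, train, test))
    return out


def evaluate(
    data: FeatureTable,
    criterion: CriterionSpec,
    classifier: ClassifierAdapter,
    K: int = PROTOCOL_K,
    folds: int = PROTOCOL_FOLDS,
    bins: int = 5,
    seed: int = 0,
    fit_bins_on: str = "train",
    select_on: str = "train",
    repeats: int = 1,
) -> CVReport:
    """Stratified K-fold accuracy of one criterion + classifier pair.

    Selection always runs on discrete codes; the classifier sees discrete
    codes or the original values according to its adapter.  ``repeats``
    re-partitions and re-runs the whole procedure with derived seeds,
    concatenating fold accuracies (the repeated-CV reading of the
    protocol).  A fixed seed yields an identical report.
    """
    if K > data.n_features:
        raise ValueError(f"K={K} exceeds feature count {data.n_features}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    accs: list[float] = []
    fold_runs = []
    for r in range(repeats):
        fold_runs.extend(
            _fold_traces(
                data, criterion, K, folds, bins, seed + r, fit_bins_on, select_on
            )
        )
    for (_, _, trace, disc_train, disc_test, train, test) in fold_runs:
        cols = [data.feature_names.index(f) for f in trace.selected[:K]]
        if classifier.wants_discrete:
            Xtr, Xte = disc_train.codes[:, cols], disc_test.codes[:, cols]
            ytr, yte = disc_train.class_codes, disc_test.class_codes
        else:
            Xtr, Xte = train.values[:, cols], test.values[:, cols]
            ytr, yte = train.class_labels.astype(str), test.class_labels.astype(str)
        try:
            classifier.train(Xtr, ytr)
            pred = classifier.predict(Xte)
        except Exception as exc:  # pragma: no cover - propagate with context
            raise RuntimeError(
                f"classifier {classifier.name!r} failed on fold: {exc}"
            ) from exc
        accs.append(float(np.mean(pred == yte)))
    return CVReport(criterion.name, classifier.name, K, accs, seed)


def accuracy_curve(
    data: FeatureTable,
    criterion: CriterionSpec,
    classifiers: list[ClassifierAdapter],
    k_max: int,
    folds: int = PROTOCOL_FOLDS,
    bins: int = 5,
    seed: int = 0,
    fit_bins_on: str = "train",
    select_on: str = "train",
) -> list[float]:
    """Mean accuracy (averaged over classifiers) for k = 1..k_max.

    Each fold is ranked once to depth ``k_max`` and truncated per k, so the
    fold partition and ranking are shared across the whole sweep.
    """
    if k_max > data.n_features:
        raise ValueError(f"k_max={k_max} exceeds feature count")
    traces = _fold_traces(
        data, criterion, k_max, folds, bins, seed, fit_bins_on, select_on
    )
    curve = []
    for k in range(1, k_max + 1):
        accs = []
        for clf in classifiers:
            fold_accs = []
            for (_, _, trace, disc_train, disc_test, train, test) in traces:
                cols = [data.feature_names.index(f) for f in trace.selected[:k]]
                if clf.wants_discrete:
                    Xtr, Xte = disc_train.codes[:, cols], disc_test.codes[:, cols]
                    ytr, yte = disc_train.class_codes, disc_test.class_codes
                else:
                    Xtr, Xte = train.values[:, cols], test.values[:, cols]
                    ytr, yte = train.class_labels.astype(str), test.class_labels.astype(str)
                clf.train(Xtr, ytr)
                fold_accs.append(float(np.mean(clf.predict(Xte) == yte)))
            accs.append(float(np.mean(fold_accs)))
        curve.append(float(np.mean(accs)))
    return curve


def dataset_ratio(N: int, median_arity: float, c: int) -> int:
    """Classification-difficulty ratio N / (m·c), rounded half away from zero.

    ``m`` is the median feature arity and ``c`` the class count; a smaller
    ratio indicates a harder selection problem.
    """
    if N <= 0 or median_arity <= 0 or c <= 0:
        raise ValueError("all inputs must be positive")
    x = N / (median_arity * c)
    return int(math.floor(x + 0.5))


def compare_wtl(
    reference: CVReport,
    baseline: CVReport,
    alpha: float = PROTOCOL_ALPHA,
    paired: bool = True,
) -> ComparisonReport:
    """Win/Tie/Loss verdict for ``reference`` vs ``baseline``.

    Paired two-sided t-test on matched fold accuracies (folds must come
    from the same partition).  Win iff the reference mean is higher and
    p < alpha; Loss iff lower and p < alpha; Tie otherwise, including the
    zero-variance case where the t statistic is undefined.
    """
    a = np.asarray(reference.accuracies, dtype=float)
    b = np.asarray(baseline.accuracies, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched accuracy vector lengths")
    diff = a - b
    if np.allclose(diff, 0.0):
        return ComparisonReport("Tie", float("nan"), alpha)
    if paired:
        if np.ptp(diff) == 0.0:
            p = 0.0  # constant nonzero difference: infinitely strong evidence
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    if not math.isnan(p) and p < alpha:
        decision = "Win" if a.mean() > b.mean() else "Loss"
    else:
        decision = "Tie"
    return ComparisonReport(decision, p, alpha)
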