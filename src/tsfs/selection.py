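"""Stage 3: cumulative sequential forward feature selection.

Features are scanned in ranking order in fixed-size cumulative blocks
(the paper-scale default appends 50 features per step): prefix t holds
the top ``t * step`` ranked features.  Each prefix is scored by
stratified k-fold mean accuracy with a chosen classifier, and the
selected set is the prefix with the highest accuracy (ties broken in
favour of fewer features).  The resulting accuracy-versus-prefix curve
typically rises out of an underfit (bias) region, peaks, and decays as
noise features accumulate (variance) — the selected set sits at the
peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "CLASSIFIERS",
    "make_classifier",
    "SelectionConfig",
    "SelectionResult",
    "cumulative_sets",
    "sffs_select",
    "SequentialPrefixSelector",
    "accuracy_curve_report",
    "common_features",
]

CLASSIFIERS = ("lr", "svm", "ld", "rf", "dt")


def make_classifier(name: str, seed: int = 0) -> BaseEstimator:
    """Seeded default classifier by short name.

    lr: L2 logistic regression (C=1); svm: linear-kernel SVC (C=1);
    ld: linear discriminant; rf: 100-tree random forest; dt: unpruned
    decision tree.
    """
    if name == "lr":
        return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "ld":
        return LinearDiscriminantAnalysis()
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass(frozen=True)
class SelectionConfig:
    """Settings of the cumulative forward scan."""

    step: int = 50
    max_features: int | None = None
    classifier: str = "lr"
    cv_folds: int = 10
    threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be positive")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Accuracy curve over cumulative prefixes and the argmax feature set."""

    steps: list[int]
    accuracies: list[float]
    best_step: int
    selected_indices: np.ndarray
    classifier: str

    @property
    def best_accuracy(self) -> float:
        return self.accuracies[self.best_step]

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)


def cumulative_sets(
    order: Sequence[int], step: int, max_features: int | None = None
) -> list[np.ndarray]:
    """Nested prefixes of the ranking: prefix t has min(t*step, max) indices."""
    order = np.asarray(order)
    if order.size == 0:
        raise ValueError("empty ranking")
    if step < 1:
        raise ValueError("step must be >= 1")
    limit = order.size if max_features is None else min(max_features, order.size)
    sizes = list(range(step, limit + 1, step))
    if not sizes or sizes[-1] != limit:
        sizes.append(limit)
    return [order[:s].copy() for s in sizes]


def _prefix_accuracy(CONN, labels, prefix, clf, cv_folds, seed) -> float:
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clone(clf), CONN[:, prefix], labels, cv=cv, scoring="accuracy")
    return float(scores.mean())


def sffs_select(
    CONN,
    labels,
    order: Sequence[int],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Scan cumulative ranked prefixes; return the accuracy-maximising one.

    Every prefix's stratified k-fold mean accuracy is recorded; the
    returned set is the argmax with the smaller prefix winning ties.  If
    ``config.threshold`` is set, the scan stops early at the first prefix
    whose accuracy reaches it.
    """
    config = config or SelectionConfig()
    CONN = np.asarray(CONN, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need both classes present, got {classes}")
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"need at least cv_folds={config.cv_folds} subjects per class "
            f"(smallest class has {counts.min()})"
        )
    clf = make_classifier(config.classifier, seed=config.seed)
    prefixes = cumulative_sets(order, config.step, config.max_features)
    steps: list[int] = []
    accuracies: list[float] = []
    for prefix in prefixes:
        acc = _prefix_accuracy(CONN, labels, prefix, clf, config.cv_folds, config.seed)
        steps.append(len(prefix))
        accuracies.append(acc)
        if config.threshold is not None and acc >= config.threshold:
            break
    best = int(np.argmax(accuracies))  # argmax returns the first maximum: fewer features
    return SelectionResult(
        steps=steps,
        accuracies=accuracies,
        best_step=best,
        selected_indices=prefixes[best],
        classifier=config.classifier,
    )


class SequentialPrefixSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the cumulative forward scan.

    ``fit(X, y)`` requires a precomputed feature ranking (``order``); use
    :class:`tsfs.student.DistillationRanker` to obtain one.  After
    fitting, ``get_support()``/``transform`` expose the selected subset
    and ``result_`` the full accuracy curve.
    """

    def __init__(
        self,
        order=None,
        step: int = 50,
        max_features: int | None = None,
        classifier: str = "lr",
        cv_folds: int = 10,
        threshold: float | None = None,
        seed: int = 0,
    ):
        self.order = order
        self.step = step
        self.max_features = max_features
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.order is None:
            raise ValueError(
                "SequentialPrefixSelector requires a feature ranking; "
                "fit a DistillationRanker first and pass order=ranker.order_"
            )
        config = SelectionConfig(
            step=self.step,
            max_features=self.max_features,
            classifier=self.classifier,
            cv_folds=self.cv_folds,
            threshold=self.threshold,
            seed=self.seed,
        )
        self.n_features_in_ = X.shape[1]
        self.result_ = sffs_select(X, y, self.order, config)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "result_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.selected_indices] = True
        return mask


def accuracy_curve_report(results: Sequence[SelectionResult]) -> pd.DataFrame:
    """One row per classifier: best cumulative step and selected-set size."""
    if len(results) == 0:
        raise ValueError("no selection results")
    rows = [
        {
            "classifier": r.classifier,
            "max_cumulative_feature_step": r.best_step + 1,
            "features_count": r.n_selected,
            "best_accuracy": r.best_accuracy,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def common_features(results: Sequence[SelectionResult]) -> np.ndarray:
    """Sorted intersection of the selected index sets of several results."""
    if len(results) < 2:
        raise ValueError("need at least two selection results to intersect")
    sets = [set(np.asarray(r.selected_indices).tolist()) for r in results]
    common = reduce(set.intersection, sets)
    if not common:
        warnings.warn("no features are common to all selections", UserWarning)
    return np.array(sorted(common), dtype=int)
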