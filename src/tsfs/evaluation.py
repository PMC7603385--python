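"""Cross-validated accuracy / sensitivity / specificity reporting.

Two evaluation scopes mirror how multi-site connectivity studies report
results: the combined cohort under stratified 10-fold cross-validation,
and each acquisition site separately under 5-fold cross-validation with
the feature set fixed (features are selected once on the combined data;
per-site evaluation probes their robustness, not per-site reselection).

The positive class is the patient label 1, so sensitivity = TP/(TP+FN)
is the patient detection rate and specificity = TN/(TN+FP) the control
detection rate.  Metrics whose denominator is empty are reported as NaN
rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .selection import make_classifier

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "kfold_evaluate",
    "site_wise_evaluate",
    "reports_to_frame",
]


@dataclass
class MetricsReport:
    """Aggregate and per-fold classification metrics for one scope."""

    classifier: str
    scope: str  # 'combined' or 'site:<id>'
    folds: int
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: list[tuple[float, float, float]] = field(default_factory=list)


def confusion_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with class 1 positive.

    An undefined ratio (no positives or no negatives in ``y_true``) is
    returned as ``nan``.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if not (set(np.unique(y_true)) <= {0, 1} and set(np.unique(y_pred)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    specificity = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return accuracy, sensitivity, specificity


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.nanmean(arr)) if not np.all(np.isnan(arr)) else math.nan


def kfold_evaluate(
    X,
    labels,
    classifier: str = "lr",
    k: int = 10,
    seed: int = 0,
    scope: str = "combined",
) -> MetricsReport:
    """Stratified k-fold metrics; aggregate = unweighted mean over folds."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need both classes, got {classes}")
    if counts.min() < k:
        raise ValueError(
            f"k={k} folds need at least k subjects per class (have {counts.min()})"
        )
    clf = make_classifier(classifier, seed=seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in cv.split(X, labels):
        model = clone(clf).fit(X[train_idx], labels[train_idx])
        pred = model.predict(X[test_idx])
        per_fold.append(confusion_metrics(labels[test_idx], pred))
    return MetricsReport(
        classifier=classifier,
        scope=scope,
        folds=k,
        accuracy=_nanmean([m[0] for m in per_fold]),
        sensitivity=_nanmean([m[1] for m in per_fold]),
        specificity=_nanmean([m[2] for m in per_fold]),
        per_fold=per_fold,
    )


def site_wise_evaluate(
    X,
    labels,
    sites,
    selected: Sequence[int] | None = None,
    classifier: str = "lr",
    k: int = 5,
    seed: int = 0,
    min_per_class: int | None = None,
) -> list[MetricsReport]:
    """Per-site k-fold metrics with a fixed (combined-data) feature set.

    Sites with fewer than ``min_per_class`` subjects in either class
    (default: the fold count) are skipped with a logged reason.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int)
    sites = np.asarray(sites)
    if sites.shape[0] != X.shape[0]:
        raise ValueError("sites and X disagree on the number of subjects")
    if selected is not None:
        X = X[:, np.asarray(selected, dtype=int)]
    need = k if min_per_class is None else min_per_class
    reports = []
    for site in pd.unique(sites):
        mask = sites == site
        y_site = labels[mask]
        counts = np.bincount(y_site, minlength=2)
        if counts.min() < need:
            logger.warning(
                "skipping site %s: class counts %s below %d per class",
                site,
                counts.tolist(),
                need,
            )
            continue
        reports.append(
            kfold_evaluate(
                X[mask], y_site, classifier=classifier, k=k, seed=seed,
                scope=f"site:{site}",
            )
        )
    return reports


def reports_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Tabular report: one row per (scope, classifier) with the three metrics."""
    rows = [
        {
            "scope": r.scope,
            "classifier": r.classifier,
            "folds": r.folds,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
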