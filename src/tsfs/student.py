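"""Stage 2: student distillation and the diag(W·Wt) feature ranking.

The student is a one-hidden-layer network (relu hidden, linear output)
trained with mean squared error to reproduce the teacher's standardized
codes from the same connectivity inputs.  Because every feature enters
the student only through its row of the input-to-hidden weight matrix W
(n_features x n_hidden), the squared Euclidean norm of that row —
``diag(W @ W.T)`` computed without forming the n x n product — measures
how much the feature contributes to reconstructing the codes.  Sorting
these scores in descending order ranks the features by discriminative
relevance.

A row-wise group-L2 penalty on W (optionally plain L1) pushes the rows
of irrelevant features toward zero, which is what makes the row norm an
importance score rather than noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._nn import MLP
from .teacher import (
    CodeMatrix,
    TeacherNetwork,
    TeacherSpec,
    extract_codes,
    standardize_codes,
)

__all__ = [
    "StudentSpec",
    "ImportanceRanking",
    "StudentNetwork",
    "DistillationRanker",
    "train_student",
    "score_features",
    "rank_features",
    "rank_pipeline",
]


@dataclass(frozen=True)
class StudentSpec:
    """Architecture and optimisation settings of the student network."""

    hidden_size: int = 100
    regularizer: str = "group_row_l2"  # 'l1', 'group_row_l2' or 'none'
    strength: float = 2e-2
    activation: str = "relu"
    optimizer: str = "adadelta"
    learning_rate: float = 0.01
    loss: str = "mse"
    epochs: int = 500
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.strength < 0:
            raise ValueError("regularizer strength must be non-negative")
        if self.regularizer not in ("l1", "group_row_l2", "none"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass
class ImportanceRanking:
    """Per-feature scores s_i = sum_j W_ij^2 and the descending sort order."""

    scores: np.ndarray
    order: np.ndarray
    W_shape: tuple[int, int]

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


class StudentNetwork(TransformerMixin, BaseEstimator):
    """One-hidden-layer code-reproduction network (the distillation student).

    ``fit(X, codes)`` trains input(n) -> hidden(h, relu) -> output(d,
    linear) with MSE against the standardized teacher codes; the fitted
    attribute ``input_weights_`` is the n x h first-layer weight matrix
    driving the feature scores.
    """

    def __init__(
        self,
        hidden_size: int = 100,
        regularizer: str = "group_row_l2",
        strength: float = 2e-2,
        activation: str = "relu",
        learning_rate: float = 0.01,
        epochs: int = 500,
        batch_size: int = 16,
        seed: int = 0,
    ):
        self.hidden_size = hidden_size
        self.regularizer = regularizer
        self.strength = strength
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, codes):
        spec = StudentSpec(
            hidden_size=self.hidden_size,
            regularizer=self.regularizer,
            strength=self.strength,
            activation=self.activation,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        X = check_array(X, dtype=float)
        if isinstance(codes, CodeMatrix):
            if not codes.standardized:
                warnings.warn(
                    "codes are not standardized; standardizing before distillation",
                    UserWarning,
                )
                codes = standardize_codes(codes)
            Y = codes.values
        else:
            Y = check_array(np.asarray(codes, dtype=float))
            if not (
                np.allclose(Y.mean(axis=0), 0.0, atol=1e-6)
                and np.allclose(Y.std(axis=0), 1.0, atol=1e-6)
            ):
                warnings.warn(
                    "codes are not standardized; standardizing before distillation",
                    UserWarning,
                )
                Y = standardize_codes(Y).values
        if Y.shape[0] != X.shape[0]:
            raise ValueError(
                f"shape mismatch: {X.shape[0]} subjects vs {Y.shape[0]} code rows"
            )
        self.n_features_in_ = X.shape[1]
        net = MLP(
            [X.shape[1], spec.hidden_size, Y.shape[1]],
            [spec.activation, "linear"],
            seed=spec.seed,
        )
        reg_kwargs = {}
        if spec.regularizer == "l1":
            reg_kwargs["l1_first_layer"] = spec.strength
        elif spec.regularizer == "group_row_l2":
            reg_kwargs["group_l2_first_layer"] = spec.strength
        self.loss_history_ = net.fit(
            X,
            Y,
            loss="mse",
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            **reg_kwargs,
        )
        self.net_ = net
        self.input_weights_ = net.weights[0]
        self.spec_ = spec
        return self

    def transform(self, X):
        """Predicted codes for each row of ``X``."""
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        return self.net_.forward(X)


def train_student(CONN, codes, spec: StudentSpec | None = None):
    """Train a student; returns ``(W, loss_history)`` with W of shape n x h."""
    spec = spec or StudentSpec()
    est = StudentNetwork(
        hidden_size=spec.hidden_size,
        regularizer=spec.regularizer,
        strength=spec.strength,
        activation=spec.activation,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=spec.seed,
    ).fit(CONN, codes)
    return est.input_weights_, est.loss_history_


def score_features(W: np.ndarray) -> np.ndarray:
    """Per-feature importance s_i = sum_j W_ij^2 (= diag(W @ W.T)).

    Computed row-wise, never forming the n x n product.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite entries in W")
    return np.einsum("ij,ij->i", W, W)


def rank_features(scores: np.ndarray, descending: bool = True) -> ImportanceRanking:
    """Sort features by score; ties broken by the lower feature index.

    Higher score means the feature's weight row carries more of the code
    reconstruction, i.e. more discriminative relevance; descending order
    is the default (a flag inverts it).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be 1-D")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    key = -scores if descending else scores
    order = np.argsort(key, kind="stable")  # stable => lower index wins ties
    return ImportanceRanking(scores=scores, order=order, W_shape=(scores.shape[0], 0))


class DistillationRanker(BaseEstimator):
    """Full two-stage ranking: teacher codes, student distillation, scores.

    ``fit(X, y)`` runs teacher training, code extraction and
    standardization, student training, and feature scoring in one seeded
    pass; fitted attributes expose ``scores_`` (diag(W W^T)), ``order_``
    (descending feature ranking) and the underlying estimators.
    """

    def __init__(
        self,
        teacher: TeacherNetwork | None = None,
        student: StudentNetwork | None = None,
        descending: bool = True,
    ):
        self.teacher = teacher
        self.student = student
        self.descending = descending

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        teacher = clone_or_default(self.teacher, TeacherNetwork)
        student = clone_or_default(self.student, StudentNetwork)
        teacher.fit(X, y)
        codes = standardize_codes(extract_codes(teacher, X))
        student.fit(X, codes)
        self.teacher_ = teacher
        self.student_ = student
        self.W_ = student.input_weights_
        self.scores_ = score_features(self.W_)
        ranking = rank_features(self.scores_, descending=self.descending)
        ranking.W_shape = self.W_.shape
        self.ranking_ = ranking
        self.order_ = ranking.order
        return self


def clone_or_default(est, cls):
    from sklearn.base import clone

    return cls() if est is None else clone(est)


def rank_pipeline(
    CONN,
    labels,
    teacher_spec: TeacherSpec | None = None,
    student_spec: StudentSpec | None = None,
) -> ImportanceRanking:
    """Run the whole ranking pipeline from explicit stage specs."""
    from .teacher import default_teacher_spec

    CONN = np.asarray(CONN, dtype=float)
    tspec = teacher_spec or default_teacher_spec(CONN.shape[1])
    sspec = student_spec or StudentSpec()
    teacher = TeacherNetwork(
        layer_sizes=tspec.layer_sizes,
        code_layer_size=tspec.code_layer_size,
        activation=tspec.activation,
        dropout_schedule=tspec.dropout_schedule,
        learning_rate=tspec.learning_rate,
        epochs=tspec.epochs,
        batch_size=tspec.batch_size,
        seed=tspec.seed,
    )
    student = StudentNetwork(
        hidden_size=sspec.hidden_size,
        regularizer=sspec.regularizer,
        strength=sspec.strength,
        activation=sspec.activation,
        learning_rate=sspec.learning_rate,
        epochs=sspec.epochs,
        batch_size=sspec.batch_size,
        seed=sspec.seed,
    )
    ranker = DistillationRanker(teacher=teacher, student=student).fit(CONN, labels)
    return ranker.ranking_
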