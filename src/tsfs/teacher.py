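"""Stage 1: the teacher network and its low-dimensional codes.

The teacher is a deep funnel-shaped classifier (17 layers counting the
input and the 2-unit output) trained on the connectivity feature vectors
with binary cross-entropy.  Once trained, the network is truncated at
its small "code" layer (5 units by default) and every subject is mapped
to that latent space; the standardized codes are the distillation target
for the student network.

The funnel is built by geometric interpolation from the input width down
to the code width, which realises a gradual reduction of units without
requiring a hand-picked size per layer.  Dropout decays linearly from
0.3 after the first hidden layer to 0 before the code layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._nn import MLP

__all__ = [
    "TeacherSpec",
    "CodeMatrix",
    "default_teacher_spec",
    "TeacherNetwork",
    "train_teacher",
    "extract_codes",
    "standardize_codes",
]

N_LAYERS = 17  # input + 15 hidden (code layer included) + 2-unit output


@dataclass(frozen=True)
class TeacherSpec:
    """Architecture and optimisation settings of the teacher network."""

    layer_sizes: tuple[int, ...]
    code_layer_size: int = 5
    activation: str = "tanh"
    dropout_schedule: tuple[float, ...] = ()
    optimizer: str = "adadelta"
    learning_rate: float = 0.001
    loss: str = "binary_cross_entropy"
    epochs: int = 500
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if sizes[-1] != 2:
            raise ValueError("last layer must have 2 units (binary head)")
        if sizes.count(self.code_layer_size) != 1:
            raise ValueError(
                f"code layer size {self.code_layer_size} must appear exactly once "
                f"in {sizes}"
            )
        code_idx = sizes.index(self.code_layer_size)
        funnel = sizes[: code_idx + 1]
        if any(a < b for a, b in zip(funnel[:-1], funnel[1:])):
            raise ValueError("layer sizes must be non-increasing down to the code layer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")

    @property
    def code_layer_index(self) -> int:
        return self.layer_sizes.index(self.code_layer_size)


@dataclass
class CodeMatrix:
    """m x d latent codes; optionally column-standardized (z-scored)."""

    values: np.ndarray
    standardized: bool
    means: np.ndarray | None = None
    sds: np.ndarray | None = None


def default_teacher_spec(
    n: int,
    code_layer_size: int = 5,
    *,
    epochs: int = 500,
    learning_rate: float = 0.001,
    batch_size: int = 16,
    seed: int = 0,
    max_dropout: float = 0.3,
) -> TeacherSpec:
    """Default 17-layer funnel from ``n`` input features to the binary head.

    Sizes interpolate geometrically from ``n`` down to the code width over
    16 layers (rounded, with pre-code layers floored at ``code + 1`` so the
    code width occurs exactly once), followed by the 2-unit output.
    """
    if n < 2:
        raise ValueError("need at least 2 input features")
    if code_layer_size < 1:
        raise ValueError("code layer must have at least one unit")
    if n <= code_layer_size:
        raise ValueError(
            f"feature count {n} must exceed the code layer size {code_layer_size}"
        )
    sizes = np.geomspace(n, code_layer_size, N_LAYERS - 1)
    sizes = np.rint(sizes).astype(int)
    # enforce the funnel: non-increasing, code width only at the code layer
    for i in range(1, len(sizes)):
        sizes[i] = min(sizes[i], sizes[i - 1])
    sizes[:-1] = np.maximum(sizes[:-1], code_layer_size + 1)
    sizes[-1] = code_layer_size
    sizes[0] = n
    layer_sizes = tuple(int(s) for s in sizes) + (2,)
    n_hidden_pre_code = len(layer_sizes) - 3  # hidden layers before the code layer
    dropout = tuple(np.linspace(max_dropout, 0.0, n_hidden_pre_code)) + (0.0,)
    return TeacherSpec(
        layer_sizes=layer_sizes,
        code_layer_size=code_layer_size,
        dropout_schedule=dropout,
        epochs=epochs,
        learning_rate=learning_rate,
        batch_size=batch_size,
        seed=seed,
    )


class TeacherNetwork(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Deep funnel classifier whose mid-network layer yields subject codes.

    Scikit-learn estimator: ``fit(X, y)`` trains the network with Adadelta
    and binary cross-entropy, ``predict``/``predict_proba`` give class
    decisions, and ``transform(X)`` returns the (raw, unstandardized)
    activations of the code layer.

    Parameters mirror :class:`TeacherSpec`; when ``layer_sizes`` is None
    the default geometric funnel for the data's feature count is used.
    """

    def __init__(
        self,
        layer_sizes=None,
        code_layer_size: int = 5,
        activation: str = "tanh",
        dropout_schedule=None,
        learning_rate: float = 0.001,
        epochs: int = 500,
        batch_size: int = 16,
        seed: int = 0,
        code_post_activation: bool = True,
    ):
        self.layer_sizes = layer_sizes
        self.code_layer_size = code_layer_size
        self.activation = activation
        self.dropout_schedule = dropout_schedule
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.code_post_activation = code_post_activation

    # ------------------------------------------------------------------ #
    def _build_spec(self, n: int) -> TeacherSpec:
        if self.layer_sizes is None:
            spec = default_teacher_spec(
                n,
                self.code_layer_size,
                epochs=self.epochs,
                learning_rate=self.learning_rate,
                batch_size=self.batch_size,
                seed=self.seed,
            )
        else:
            sizes = tuple(int(s) for s in self.layer_sizes)
            dropout = (
                tuple(self.dropout_schedule)
                if self.dropout_schedule is not None
                else (0.0,) * (len(sizes) - 2)
            )
            spec = TeacherSpec(
                layer_sizes=sizes,
                code_layer_size=self.code_layer_size,
                activation=self.activation,
                dropout_schedule=dropout,
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                batch_size=self.batch_size,
                seed=self.seed,
            )
        if spec.layer_sizes[0] != n:
            raise ValueError(
                f"input layer has {spec.layer_sizes[0]} units but data has {n} features"
            )
        return spec

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"teacher is a binary classifier; got classes {self.classes_}"
            )
        y01 = (y == self.classes_[1]).astype(int)
        self.n_features_in_ = X.shape[1]
        self.spec_ = self._build_spec(self.n_features_in_)
        n_w = len(self.spec_.layer_sizes) - 1
        activations = [self.spec_.activation] * (n_w - 1) + ["linear"]
        net = MLP(
            self.spec_.layer_sizes,
            activations,
            dropout=self.spec_.dropout_schedule,
            seed=self.spec_.seed,
        )
        self.loss_history_ = net.fit(
            X,
            y01,
            loss="softmax_ce",
            epochs=self.spec_.epochs,
            batch_size=self.spec_.batch_size,
            learning_rate=self.spec_.learning_rate,
        )
        self.net_ = net
        self.code_layer_index_ = self.spec_.code_layer_index
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        return self.net_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def transform(self, X):
        """Raw code-layer activations for each row of ``X``."""
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        outputs, pre = self.net_.forward(X, return_all=True)
        idx = self.code_layer_index_
        return (outputs[idx] if self.code_post_activation else pre[idx]).copy()


# ---------------------------------------------------------------------- #
# functional wrappers


def train_teacher(CONN, labels, spec: TeacherSpec) -> TeacherNetwork:
    """Train a :class:`TeacherNetwork` from an explicit :class:`TeacherSpec`."""
    est = TeacherNetwork(
        layer_sizes=spec.layer_sizes,
        code_layer_size=spec.code_layer_size,
        activation=spec.activation,
        dropout_schedule=spec.dropout_schedule,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        seed=spec.seed,
    )
    return est.fit(CONN, labels)


def extract_codes(model: TeacherNetwork, CONN) -> CodeMatrix:
    """Map every subject through the trained teacher up to the code layer."""
    return CodeMatrix(values=model.transform(CONN), standardized=False)


def standardize_codes(codes: CodeMatrix | np.ndarray) -> CodeMatrix:
    """Column z-score (population sd, i.e. divide by n) of the code matrix.

    The fitted means/sds are kept on the returned :class:`CodeMatrix` so
    the same transform can be reapplied to held-out subjects.
    """
    values = codes.values if isinstance(codes, CodeMatrix) else np.asarray(codes, float)
    if values.ndim != 2:
        raise ValueError("codes must be a 2-D matrix")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize (sd undefined)")
    means = values.mean(axis=0)
    sds = values.std(axis=0)  # population sd by convention
    # round-off tolerant: a constant column's sd is ~eps * |mean|, not 0
    tiny = 1e-12 * np.maximum(1.0, np.abs(means))
    if np.any(sds <= tiny):
        bad = np.flatnonzero(sds <= tiny).tolist()
        raise ValueError(f"zero-variance code column(s): {bad}")
    return CodeMatrix(
        values=(values - means) / sds, standardized=True, means=means, sds=sds
    )
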