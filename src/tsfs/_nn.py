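"""Minimal seeded feed-forward network core used by the teacher and student.

Plain-numpy multilayer perceptron with:

* Glorot-uniform initialisation, zero biases;
* tanh / relu / linear activations per layer;
* inverted dropout on hidden activations;
* Adadelta updates (accumulated squared gradients and squared updates,
  decay rho, epsilon inside both square roots, scaled by a learning rate);
* softmax cross-entropy (classification) or mean squared error
  (reproduction) losses;
* optional L1 or row-wise group-L2 penalty on the first weight matrix.

Everything — initial weights, batch shuffling, dropout masks — is driven
by one ``numpy.random.Generator``, so training is reproducible from a
single integer seed on a fixed BLAS configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP"]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0.0).astype(a.dtype)),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class _AdadeltaState:
    acc_grad: list
    acc_update: list


class MLP:
    """Feed-forward network trained with mini-batch Adadelta.

    Parameters
    ----------
    layer_sizes : sequence of int
        Unit counts from the input layer to the output layer inclusive.
    activations : sequence of str
        One of 'tanh', 'relu', 'linear' per non-input layer.  For the
        'softmax_ce' loss the final entry is ignored (logits + softmax).
    dropout : sequence of float
        Drop probability applied to the activation of each non-input,
        non-output layer (length ``len(layer_sizes) - 2``); 0 disables.
    """

    def __init__(
        self,
        layer_sizes,
        activations,
        *,
        dropout=None,
        seed: int = 0,
    ):
        self.layer_sizes = [int(s) for s in layer_sizes]
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        n_w = len(self.layer_sizes) - 1
        self.activations = list(activations)
        if len(self.activations) != n_w:
            raise ValueError(f"need {n_w} activations, got {len(self.activations)}")
        for name in self.activations:
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")
        if dropout is None:
            dropout = [0.0] * (n_w - 1)
        self.dropout = [float(p) for p in dropout]
        if len(self.dropout) != n_w - 1:
            raise ValueError(f"need {n_w - 1} dropout rates, got {len(self.dropout)}")
        if any(not 0.0 <= p < 1.0 for p in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(self.rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # ------------------------------------------------------------------ #
    def forward(self, X: np.ndarray, return_all: bool = False):
        """Deterministic (no-dropout) forward pass.

        With ``return_all`` the post-activation output of every layer is
        returned, input included, enabling code extraction mid-network.
        """
        a = np.asarray(X, dtype=float)
        outputs = [a]
        pre = [a]
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = _ACTIVATIONS[self.activations[l]][0](z)
            pre.append(z)
            outputs.append(a)
        if return_all:
            return outputs, pre
        return a

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax over the final layer's pre-activations."""
        _, pre = self.forward(X, return_all=True)
        return _softmax(pre[-1])

    # ------------------------------------------------------------------ #
    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        *,
        loss: str,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        rho: float = 0.95,
        eps: float = 1e-6,
        l1_first_layer: float = 0.0,
        group_l2_first_layer: float = 0.0,
    ) -> list[float]:
        """Train in place; returns the mean training loss per epoch.

        ``loss`` is 'softmax_ce' (Y = integer labels) or 'mse' (Y = real
        targets).  Penalties act on ``weights[0]`` only — the student's
        feature rows.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if loss not in ("softmax_ce", "mse"):
            raise ValueError(f"unknown loss {loss!r}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in the input")
        m = X.shape[0]
        if loss == "softmax_ce":
            y_int = Y.astype(int)
            n_classes = self.layer_sizes[-1]
            onehot = np.eye(n_classes)[y_int]
        else:
            Y = Y.astype(float)
            if Y.ndim == 1:
                Y = Y[:, None]

        state = _AdadeltaState(
            acc_grad=[np.zeros_like(W) for W in self.weights]
            + [np.zeros_like(b) for b in self.biases],
            acc_update=[np.zeros_like(W) for W in self.weights]
            + [np.zeros_like(b) for b in self.biases],
        )
        n_w = len(self.weights)
        history: list[float] = []
        for _ in range(int(epochs)):
            order = self.rng.permutation(m)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, m, int(batch_size)):
                idx = order[start : start + int(batch_size)]
                xb = X[idx]
                tb = onehot[idx] if loss == "softmax_ce" else Y[idx]
                batch_loss, grads_w, grads_b = self._backprop(xb, tb, loss)
                if l1_first_layer > 0.0:
                    grads_w[0] = grads_w[0] + l1_first_layer * np.sign(self.weights[0])
                if group_l2_first_layer > 0.0:
                    W0 = self.weights[0]
                    norms = np.linalg.norm(W0, axis=1, keepdims=True)
                    grads_w[0] = grads_w[0] + group_l2_first_layer * np.where(
                        norms > 0, W0 / np.maximum(norms, 1e-12), 0.0
                    )
                params = self.weights + self.biases
                grads = grads_w + grads_b
                for i in range(len(params)):
                    g = grads[i]
                    state.acc_grad[i] = rho * state.acc_grad[i] + (1 - rho) * g * g
                    update = (
                        np.sqrt(state.acc_update[i] + eps)
                        / np.sqrt(state.acc_grad[i] + eps)
                        * g
                    )
                    state.acc_update[i] = (
                        rho * state.acc_update[i] + (1 - rho) * update * update
                    )
                    params[i] -= learning_rate * update
                epoch_loss += batch_loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
        return history

    # ------------------------------------------------------------------ #
    def _backprop(self, xb: np.ndarray, tb: np.ndarray, loss: str):
        """One forward/backward pass with dropout; returns loss and grads."""
        n_w = len(self.weights)
        B = xb.shape[0]
        a = xb
        inputs = [a]  # dropped-out input to each layer
        raw = []  # post-activation, pre-dropout, per layer
        masks: list[np.ndarray | None] = []
        for l in range(n_w):
            z = a @ self.weights[l] + self.biases[l]
            if loss == "softmax_ce" and l == n_w - 1:
                a = z  # logits; softmax folded into the loss gradient
            else:
                a = _ACTIVATIONS[self.activations[l]][0](z)
            raw.append(a)
            if l < n_w - 1 and self.dropout[l] > 0.0:
                p = self.dropout[l]
                mask = (self.rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            inputs.append(a)

        if loss == "softmax_ce":
            probs = _softmax(raw[-1])
            batch_loss = float(
                -np.mean(np.log(np.sum(probs * tb, axis=1) + 1e-12))
            )
            delta = (probs - tb) / B
        else:
            diff = raw[-1] - tb
            batch_loss = float(np.mean(diff * diff))
            delta = 2.0 * diff / diff.size

        grads_w = [np.zeros_like(W) for W in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        for l in range(n_w - 1, -1, -1):
            grads_w[l] = inputs[l].T @ delta
            grads_b[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.weights[l].T
                if masks[l - 1] is not None:
                    delta = delta * masks[l - 1]
                # derivative w.r.t. the pre-dropout activation
                delta = delta * _ACTIVATIONS[self.activations[l - 1]][1](raw[l - 1])
        return batch_loss, grads_w, grads_b
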