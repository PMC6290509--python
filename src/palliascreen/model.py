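"""Fully-connected probabilistic mortality classifier.

A configurable multilayer perceptron with a sigmoid output trained on log
loss: SeLU (default), ReLU or tanh hidden activations, Adam optimization,
mini-batches of 128, and *snapshot selection* — every ``snapshot_interval``
mini-batch iterations the weights are scored by Average Precision on the
validation set, and the best-scoring snapshot is retroactively kept as the
final model (earliest iteration wins ties).  ``hidden_layers=0`` degenerates
to a logistic-regression baseline trained by the same protocol.  No
explicit regularization is applied.

Implemented directly on numpy/scipy so sparse design matrices stream
through the input layer without densification.  Determinism: given the
seed, single-threaded execution reproduces the weight trajectory and the
validation-AP history exactly on the same machine.
"""

from __future__ import annotations

import io
import json
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import average_precision

SELU_ALPHA = 1.6732632423543772848170429916717
SELU_SCALE = 1.0507009873554804934193349852946


def _selu(z):
    return SELU_SCALE * np.where(z > 0, z, SELU_ALPHA * np.expm1(z))


def _selu_grad(z):
    return SELU_SCALE * np.where(z > 0, 1.0, SELU_ALPHA * np.exp(z))


_ACTIVATIONS = {
    "selu": (_selu, _selu_grad),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _logloss(z, y):
    # numerically stable mean BCE on logits
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


class MLPMortalityClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward net with validation-AP snapshot selection.

    Parameters mirror the training protocol: ``hidden_layers`` x
    ``hidden_width`` SeLU layers (0 layers = logistic regression), Adam at
    ``learning_rate``, mini-batch ``batch_size``, snapshots every
    ``snapshot_interval`` iterations up to ``max_iterations``.

    Fitted attributes: ``coefs_``/``intercepts_`` (selected snapshot),
    ``validation_ap_history_`` (list of ``(iteration, ap)``),
    ``selected_snapshot_index_``, ``loss_history_``, ``n_features_in_``,
    ``classes_``.
    """

    def __init__(self, hidden_layers: int = 2, hidden_width: int = 64,
                 activation: str = "selu", learning_rate: float = 1e-3,
                 batch_size: int = 128, snapshot_interval: int = 250,
                 max_iterations: int = 2000, seed: int = 0):
        self.hidden_layers = hidden_layers
        self.hidden_width = hidden_width
        self.activation = activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.snapshot_interval = snapshot_interval
        self.max_iterations = max_iterations
        self.seed = seed

    # ------------------------------------------------------------------ core
    def _validate_config(self, n_features: int) -> None:
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")
        if self.hidden_layers > 0 and self.hidden_width <= 0:
            raise ValueError("hidden_width must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if min(self.batch_size, self.snapshot_interval, self.max_iterations) <= 0:
            raise ValueError("batch_size, snapshot_interval and max_iterations "
                             "must be positive")
        if n_features <= 0:
            raise ValueError("empty feature space")

    def _init_weights(self, n_features: int, rng) -> tuple[list, list]:
        dims = ([n_features] + [self.hidden_width] * self.hidden_layers + [1])
        gain = {"selu": 1.0, "relu": 2.0, "tanh": 1.0}[self.activation]
        Ws, bs = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            std = np.sqrt(gain / fan_in)
            Ws.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
            bs.append(np.zeros(fan_out))
        return Ws, bs

    def _forward(self, X, Ws, bs, keep: bool = False):
        act, _ = _ACTIVATIONS[self.activation]
        zs, hs = [], []
        h = X
        for layer, (W, b) in enumerate(zip(Ws, bs)):
            z = (h @ W) + b
            z = np.asarray(z)
            if layer < len(Ws) - 1:
                if keep:
                    zs.append(z)
                    hs.append(h)
                h = act(z)
            else:
                if keep:
                    hs.append(h)
        logits = z[:, 0]
        return (logits, zs, hs) if keep else logits

    def _backward(self, X, y, Ws, bs):
        _, grad = _ACTIVATIONS[self.activation]
        logits, zs, hs = self._forward(X, Ws, bs, keep=True)
        n = X.shape[0]
        delta = ((_sigmoid(logits) - y) / n)[:, None]
        gWs = [None] * len(Ws)
        gbs = [None] * len(bs)
        for layer in range(len(Ws) - 1, -1, -1):
            h = hs[layer]
            gWs[layer] = np.asarray(h.T @ delta)
            gbs[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ Ws[layer].T) * grad(zs[layer - 1])
        loss = _logloss(logits, y)
        return loss, gWs, gbs

    # ----------------------------------------------------------------- sklearn
    def fit(self, X, y, X_val=None, y_val=None) -> "MLPMortalityClassifier":
        """Train on (X, y), selecting the snapshot with the best validation AP.

        When no validation set is supplied the training set itself is used
        for snapshot scoring (adequate for smoke tests only).
        """
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("empty training matrix")
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        if X_val is None:
            X_val, y_val = X, y
        else:
            X_val = sp.csr_matrix(X_val) if sp.issparse(X_val) else np.asarray(
                X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
            if X_val.shape[1] != X.shape[1]:
                raise ValueError("train/validation feature dimension mismatch")
        if y_val.sum() == 0:
            raise ValueError("validation set needs at least one positive for "
                             "AP snapshot selection")
        self._validate_config(X.shape[1])

        rng = np.random.default_rng(self.seed)
        Ws, bs = self._init_weights(X.shape[1], rng)
        mWs = [np.zeros_like(W) for W in Ws]
        vWs = [np.zeros_like(W) for W in Ws]
        mbs = [np.zeros_like(b) for b in bs]
        vbs = [np.zeros_like(b) for b in bs]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate

        n = X.shape[0]
        order = np.empty(0, dtype=int)
        pos = 0
        history: list[tuple[int, float]] = []
        losses: list[float] = []
        best = (-np.inf, None, None, None)

        def snapshot(iteration: int):
            nonlocal best
            scores = _sigmoid(self._forward(X_val, Ws, bs))
            ap = average_precision(scores, y_val.astype(int))
            history.append((iteration, ap))
            if ap > best[0]:
                best = (ap, [W.copy() for W in Ws], [b.copy() for b in bs],
                        len(history) - 1)

        for it in range(1, self.max_iterations + 1):
            if pos + self.batch_size > len(order):
                order = rng.permutation(n)
                pos = 0
            idx = order[pos:pos + min(self.batch_size, n)]
            pos += self.batch_size
            loss, gWs, gbs = self._backward(X[idx], y[idx], Ws, bs)
            losses.append(loss)
            for lst, g_lst, m_lst, v_lst in ((Ws, gWs, mWs, vWs),
                                             (bs, gbs, mbs, vbs)):
                for j in range(len(lst)):
                    m_lst[j] = b1 * m_lst[j] + (1 - b1) * g_lst[j]
                    v_lst[j] = b2 * v_lst[j] + (1 - b2) * g_lst[j] ** 2
                    mhat = m_lst[j] / (1 - b1 ** it)
                    vhat = v_lst[j] / (1 - b2 ** it)
                    lst[j] = lst[j] - lr * mhat / (np.sqrt(vhat) + eps)
            if it % self.snapshot_interval == 0 or it == self.max_iterations:
                snapshot(it)

        self.coefs_ = best[1]
        self.intercepts_ = best[2]
        self.selected_snapshot_index_ = best[3]
        self.validation_ap_history_ = history
        self.loss_history_ = losses
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "coefs_"):
            raise RuntimeError("model is not fitted")
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, "
                             f"got {X.shape[1]}")
        return self._forward(X, self.coefs_, self.intercepts_)

    def predict_proba(self, X) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ------------------------------------------------------------------ wrappers

def train(train_matrix, validation_matrix, **params) -> MLPMortalityClassifier:
    """Train a classifier from two :class:`FeatureMatrix` objects."""
    model = MLPMortalityClassifier(**params)
    return model.fit(train_matrix.X, train_matrix.labels,
                     validation_matrix.X, validation_matrix.labels)


def predict_probability(model: MLPMortalityClassifier, X) -> np.ndarray:
    """Death probabilities as a flat vector (row order preserved)."""
    return model.predict_proba(X)[:, 1]


def save_model(model: MLPMortalityClassifier, path) -> None:
    """Serialize a fitted model; predictions round-trip bit-for-bit."""
    payload = {f"W{i}": W for i, W in enumerate(model.coefs_)}
    payload.update({f"b{i}": b for i, b in enumerate(model.intercepts_)})
    meta = {
        "params": model.get_params(),
        "n_layers": len(model.coefs_),
        "n_features_in": int(model.n_features_in_),
        "selected_snapshot_index": int(model.selected_snapshot_index_),
        "validation_ap_history": model.validation_ap_history_,
    }
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path) -> MLPMortalityClassifier:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            coefs = [data[f"W{i}"] for i in range(meta["n_layers"])]
            intercepts = [data[f"b{i}"] for i in range(meta["n_layers"])]
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise IOError(f"cannot load model from {path}: {exc}") from exc
    model = MLPMortalityClassifier(**meta["params"])
    model.coefs_ = coefs
    model.intercepts_ = intercepts
    model.n_features_in_ = meta["n_features_in"]
    model.selected_snapshot_index_ = meta["selected_snapshot_index"]
    model.validation_ap_history_ = [tuple(h) for h in meta["validation_ap_history"]]
    model.classes_ = np.array([0, 1])
    return model
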