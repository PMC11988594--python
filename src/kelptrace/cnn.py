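"""A small 1-D convolutional network for origin classification.

Architecture (reference configuration, 107 input features, 3 classes):

    input (107 x 1)
    -> conv1d(kernel 3, 4 filters, valid) -> ReLU -> maxpool(3, stride 3)
    -> conv1d(kernel 3, 8 filters, valid) -> ReLU -> maxpool(3, stride 3)
    -> flatten (88)
    -> dense(32) -> ReLU
    -> dense(n_classes) -> softmax

Pooling windows do not overlap and trailing remainders are dropped, which is
what yields the 107 -> 105 -> 35 -> 33 -> 11 length chain and the 88-element
flattened vector.  The trainable parameter count at this configuration is
(3*1+1)*4 + (3*4+1)*8 + (88+1)*32 + (32+1)*3 = 3067 (~3.1 K), and one
forward pass costs 16083 FLOPs (~16.1 K) under the convention documented in
:func:`count_flops`.

Training minimizes categorical cross-entropy with mini-batch Adam
(beta1=0.9, beta2=0.999, eps=1e-7) and seeded shuffling; weights are
initialized Glorot-uniform with zero biases.  Everything is plain numpy:
the forward pass uses strided windows + einsum, gradients are hand-derived
backpropagation (validated in the test suite against a naive-loop forward
oracle and central finite differences).
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["Cnn1DClassifier", "flatten_length", "count_params",
           "count_flops", "save_model", "load_model"]

_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-7


def flatten_length(input_len: int, conv_filters=(4, 8), kernel_len: int = 3,
                   pool_len: int = 3) -> int:
    """Length of the flattened vector after the conv/pool stack.

    Raises ValueError when the geometry degenerates (a layer output would be
    empty).
    """
    L = int(input_len)
    for f in conv_filters:
        L = L - kernel_len + 1
        if L <= 0:
            raise ValueError(
                f"input_len {input_len} too short for kernel {kernel_len}"
            )
        L = L // pool_len
        if L <= 0:
            raise ValueError(
                f"input_len {input_len} collapses to an empty pooled layer"
            )
    return L * conv_filters[-1]


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv1d(x, W):
    # x: (n, L, C_in), W: (k, C_in, C_out) -> (n, L-k+1, C_out)
    win = sliding_window_view(x, W.shape[0], axis=1)  # (n, L_out, C_in, k)
    return np.einsum("nlck,kcf->nlf", win, W, optimize=True)


def _maxpool(x, p):
    # x: (n, L, C) -> (n, L//p, C), argmax indices for backprop
    n, L, C = x.shape
    m = L // p
    xt = x[:, : m * p].reshape(n, m, p, C)
    idx = xt.argmax(axis=2)
    out = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, idx


class Cnn1DClassifier(ClassifierMixin, BaseEstimator):
    """1-D CNN classifier for chemometric feature vectors.

    Parameters
    ----------
    conv_filters : tuple of int, default (4, 8)
        Channel widths of the convolutional layers.
    kernel_len, pool_len : int, default 3
        Convolution kernel length (valid padding) and non-overlapping
        max-pool window (stride equals the window).
    dense_units : int, default 32
        Width of the hidden dense layer.
    learning_rate, epochs, batch_size
        Adam step size and training schedule.
    random_state : int or None
        Seeds both weight initialization and epoch shuffling.

    Attributes
    ----------
    weights_ : dict of str -> ndarray
        Layer-named weight and bias tensors.
    classes_ : ndarray
        Sorted class labels seen in fit.
    history_ : pandas.DataFrame
        Per-epoch training cross-entropy (nats) and accuracy.
    """

    def __init__(self, conv_filters=(4, 8), kernel_len=3, pool_len=3,
                 dense_units=32, learning_rate=1e-3, epochs=100,
                 batch_size=16, random_state=None):
        self.conv_filters = conv_filters
        self.kernel_len = kernel_len
        self.pool_len = pool_len
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # construction

    def initialize(self, input_len: int, n_classes: int = 3,
                   rng: np.random.Generator | None = None):
        """Build seeded Glorot-uniform weights without training.

        Useful for forward-pass tests and as the starting point of fit.
        """
        flat = flatten_length(input_len, self.conv_filters, self.kernel_len,
                              self.pool_len)
        rng = rng or np.random.default_rng(self.random_state)

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        k = self.kernel_len
        w: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(self.conv_filters, start=1):
            w[f"conv{i}_W"] = glorot((k, c_in, c_out), k * c_in, k * c_out)
            w[f"conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        w["dense1_W"] = glorot((flat, self.dense_units), flat,
                               self.dense_units)
        w["dense1_b"] = np.zeros(self.dense_units)
        w["dense2_W"] = glorot((self.dense_units, n_classes),
                               self.dense_units, n_classes)
        w["dense2_b"] = np.zeros(n_classes)
        self.weights_ = w
        self.n_features_in_ = input_len
        if not hasattr(self, "classes_"):
            self.classes_ = np.arange(n_classes)
        return self

    # ------------------------------------------------------------------ #
    # forward / backward

    def _forward(self, X, cache: bool = False):
        w = self.weights_
        a = X[:, :, None]  # (n, L, 1)
        caches = []
        for i in range(1, len(self.conv_filters) + 1):
            z = _conv1d(a, w[f"conv{i}_W"]) + w[f"conv{i}_b"]
            r = _relu(z)
            pooled, idx = _maxpool(r, self.pool_len)
            caches.append((a, z, r.shape, idx))
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        z1 = flat @ w["dense1_W"] + w["dense1_b"]
        a1 = _relu(z1)
        z2 = a1 @ w["dense2_W"] + w["dense2_b"]
        proba = _softmax(z2)
        if cache:
            return proba, (caches, a.shape, flat, z1, a1)
        return proba

    def _backward(self, X, Y, proba, cache):
        """Gradients of mean cross-entropy w.r.t. every weight tensor."""
        w = self.weights_
        caches, pooled_shape, flat, z1, a1 = cache
        n = X.shape[0]
        grads: dict[str, np.ndarray] = {}

        dz2 = (proba - Y) / n  # softmax + CE
        grads["dense2_W"] = a1.T @ dz2
        grads["dense2_b"] = dz2.sum(axis=0)
        da1 = dz2 @ w["dense2_W"].T
        dz1 = da1 * (z1 > 0)
        grads["dense1_W"] = flat.T @ dz1
        grads["dense1_b"] = dz1.sum(axis=0)
        dpooled = (dz1 @ w["dense1_W"].T).reshape(pooled_shape)

        for i in range(len(self.conv_filters), 0, -1):
            a_in, z, r_shape, idx = caches[i - 1]
            p = self.pool_len
            nb, m, C = dpooled.shape
            # un-pool: route gradient to the argmax positions
            dr = np.zeros((nb, m, p, C))
            np.put_along_axis(dr, idx[:, :, None, :], dpooled[:, :, None, :],
                              axis=2)
            dr_full = np.zeros(r_shape)
            dr_full[:, : m * p] = dr.reshape(nb, m * p, C)
            dz = dr_full * (z > 0)
            win = sliding_window_view(a_in, self.kernel_len, axis=1)
            grads[f"conv{i}_W"] = np.einsum("nlck,nlf->kcf", win, dz,
                                            optimize=True)
            grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
            if i > 1:
                # full correlation with the kernel flipped along its length
                W = w[f"conv{i}_W"]
                k = self.kernel_len
                dz_pad = np.pad(dz, ((0, 0), (k - 1, k - 1), (0, 0)))
                winp = sliding_window_view(dz_pad, k, axis=1)  # (n,L,C_out,k)
                dpooled = np.einsum("nlfk,kcf->nlc", winp, W[::-1],
                                    optimize=True)
        return grads

    def loss_and_gradients(self, X, y_onehot):
        """Mean categorical cross-entropy and its weight gradients.

        Exposed so gradient correctness can be checked against finite
        differences.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y_onehot, dtype=float)
        proba, cache = self._forward(X, cache=True)
        eps = 1e-12
        loss = float(-(Y * np.log(proba + eps)).sum(axis=1).mean())
        grads = self._backward(X, Y, proba, cache)
        return loss, grads

    # ------------------------------------------------------------------ #
    # sklearn API

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        n_classes = len(self.classes_)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[v] for v in y])
        Y = np.eye(n_classes)[yi]
        n, d = X.shape

        rng = np.random.default_rng(self.random_state)
        self.initialize(d, n_classes, rng=rng)
        w = self.weights_
        m = {k: np.zeros_like(v) for k, v in w.items()}
        v = {k: np.zeros_like(val) for k, val in w.items()}
        t = 0
        records = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                proba, cache = self._forward(X[batch], cache=True)
                grads = self._backward(X[batch], Y[batch], proba, cache)
                t += 1
                for key in w:
                    g = grads[key]
                    m[key] = _ADAM_BETA1 * m[key] + (1 - _ADAM_BETA1) * g
                    v[key] = _ADAM_BETA2 * v[key] + (1 - _ADAM_BETA2) * g * g
                    mhat = m[key] / (1 - _ADAM_BETA1 ** t)
                    vhat = v[key] / (1 - _ADAM_BETA2 ** t)
                    w[key] -= self.learning_rate * mhat / (
                        np.sqrt(vhat) + _ADAM_EPS)
            proba = self._forward(X)
            loss = float(-(Y * np.log(proba + 1e-12)).sum(axis=1).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            acc = float((proba.argmax(axis=1) == yi).mean())
            records.append({"epoch": epoch, "loss": loss, "accuracy": acc})
        self.history_ = pd.DataFrame(records)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


# ---------------------------------------------------------------------- #
# complexity accounting


def _geometry(input_len, conv_filters, kernel_len, pool_len):
    """Per-layer (conv_out_len, pool_out_len, c_in, c_out) chain."""
    chain = []
    L, c_in = input_len, 1
    for c_out in conv_filters:
        conv_out = L - kernel_len + 1
        pool_out = conv_out // pool_len
        chain.append((conv_out, pool_out, c_in, c_out))
        L, c_in = pool_out, c_out
    return chain


def count_params(model: Cnn1DClassifier) -> int:
    """Total number of trainable weights and biases."""
    check_is_fitted(model, "weights_")
    return int(sum(v.size for v in model.weights_.values()))


def count_flops(model: Cnn1DClassifier | None = None, *,
                input_len: int | None = None, conv_filters=(4, 8),
                kernel_len: int = 3, pool_len: int = 3, dense_units: int = 32,
                n_classes: int = 3) -> int:
    """Static FLOPs of one forward pass.

    Convention: 2 FLOPs per multiply-accumulate in conv
    (2*k*C_in*C_out*L_out) and dense (2*n_in*n_out) layers, plus one add per
    bias application (L_out*C_out per conv, n_out per dense), plus pool_len
    comparisons per max-pool output element; activations and the softmax are
    excluded.
    """
    if model is not None:
        check_is_fitted(model, "weights_")
        input_len = model.n_features_in_
        conv_filters = model.conv_filters
        kernel_len = model.kernel_len
        pool_len = model.pool_len
        dense_units = model.dense_units
        n_classes = len(model.classes_)
    if input_len is None:
        raise ValueError("input_len required when no model is given")
    total = 0
    for conv_out, pool_out, c_in, c_out in _geometry(
            input_len, conv_filters, kernel_len, pool_len):
        total += 2 * kernel_len * c_in * c_out * conv_out  # conv MACs
        total += conv_out * c_out  # bias adds
        total += pool_len * pool_out * c_out  # pool comparisons
    flat = flatten_length(input_len, conv_filters, kernel_len, pool_len)
    total += 2 * flat * dense_units + dense_units
    total += 2 * dense_units * n_classes + n_classes
    return int(total)


# ---------------------------------------------------------------------- #
# serialization


def save_model(model: Cnn1DClassifier, path: str | Path) -> Path:
    """Save weights plus a JSON config block into one .npz archive."""
    check_is_fitted(model, "weights_")
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    config = {
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "n_features_in": int(model.n_features_in_),
    }
    np.savez(path, **model.weights_)
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("config.json", json.dumps(config))
    return path


def load_model(path: str | Path) -> Cnn1DClassifier:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        config = json.loads(zf.read("config.json"))
    data = np.load(path)
    params = config["params"]
    params["conv_filters"] = tuple(params["conv_filters"])
    model = Cnn1DClassifier(**params)
    model.weights_ = {k: data[k] for k in data.files
                      if not k.endswith(".json")}
    model.classes_ = np.asarray(config["classes"])
    model.n_features_in_ = config["n_features_in"]
    return model
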