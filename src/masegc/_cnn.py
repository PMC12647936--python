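"""A small seeded 1-D convolutional classifier for fused latent vectors.

The latent vector is treated as a length-``d`` single-channel sequence:
two convolution blocks (kernel 3, same padding; 16 then 32 filters, ReLU),
each followed by max-pooling of width 2, then dropout and a dense softmax
head. Trained with Adam on cross-entropy. Implemented in numpy with manual
backpropagation; deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np

from ._nn import Adam, glorot
from .errors import DimensionError

__all__ = ["Conv1DClassifier"]


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(n, L, C) -> (n, L, K*C) patches with zero 'same' padding."""
    n, L, C = x.shape
    pad = kernel // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    cols = np.empty((n, L, kernel * C))
    for k in range(kernel):
        cols[:, :, k * C : (k + 1) * C] = xp[:, k : k + L, :]
    return cols


def _col2im(dcols: np.ndarray, L: int, C: int, kernel: int) -> np.ndarray:
    n = dcols.shape[0]
    pad = kernel // 2
    dxp = np.zeros((n, L + 2 * pad, C))
    for k in range(kernel):
        dxp[:, k : k + L, :] += dcols[:, :, k * C : (k + 1) * C]
    return dxp[:, pad : pad + L, :]


class Conv1DClassifier:
    """Binary classifier with a ``fit`` / ``predict_proba`` contract.

    Parameters follow the package's pinned architecture: ``filters=(16, 32)``,
    ``kernel_size=3``, ``dropout=0.3``. ``epochs`` and ``learning_rate``
    govern Adam training; everything random is driven by ``seed``.
    """

    def __init__(
        self,
        kernel_size: int = 3,
        filters: tuple[int, int] = (16, 32),
        dropout: float = 0.3,
        epochs: int = 100,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        seed: int = 0,
    ):
        self.kernel_size = kernel_size
        self.filters = tuple(filters)
        self.dropout = dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.classes_ = np.array([0, 1])
        self._params: dict[str, np.ndarray] | None = None

    # -- forward -----------------------------------------------------------

    def _pool(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        n, L, C = x.shape
        if L < 2:
            return x, None
        L2 = L // 2
        trimmed = x[:, : 2 * L2, :].reshape(n, L2, 2, C)
        arg = trimmed.argmax(axis=2)
        return trimmed.max(axis=2), arg

    def _unpool(self, dy: np.ndarray, arg: np.ndarray | None, L: int) -> np.ndarray:
        if arg is None:
            return dy
        n, L2, C = dy.shape
        dx = np.zeros((n, L, C))
        grid_n, grid_l, grid_c = np.ogrid[:n, :L2, :C]
        flat = np.zeros((n, L2, 2, C))
        flat[grid_n, grid_l, arg, grid_c] = dy
        dx[:, : 2 * L2, :] = flat.reshape(n, 2 * L2, C)
        return dx

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        p = self._params
        cache: dict = {}
        x = X[:, :, None]  # (n, L, 1)
        for i in (1, 2):
            cols = _im2col(x, self.kernel_size)
            z = cols @ p[f"w{i}"] + p[f"b{i}"]
            a = np.maximum(z, 0.0)
            pooled, arg = self._pool(a)
            cache[i] = (x.shape, cols, a, arg)
            x = pooled
        flat = x.reshape(x.shape[0], -1)
        if rng is not None and self.dropout > 0:
            mask = (rng.random(flat.shape) >= self.dropout) / (1 - self.dropout)
            flat = flat * mask
            cache["drop"] = mask
        logits = flat @ p["wd"] + p["bd"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        proba = e / e.sum(axis=1, keepdims=True)
        cache["flat"] = flat
        cache["pool_shape"] = x.shape
        return proba, cache

    # -- training ----------------------------------------------------------

    def _init(self, L: int, rng: np.random.Generator) -> None:
        k = self.kernel_size
        f1, f2 = self.filters
        L1 = L // 2 if L >= 2 else L
        L2 = L1 // 2 if L1 >= 2 else L1
        self._input_len = L
        self._params = {
            "w1": glorot(rng, k * 1, f1),
            "b1": np.zeros(f1),
            "w2": glorot(rng, k * f1, f2),
            "b2": np.zeros(f2),
            "wd": glorot(rng, L2 * f2, 2),
            "bd": np.zeros(2),
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise DimensionError("X must be (n_samples, sequence_length)")
        n, L = X.shape
        rng = np.random.default_rng(self.seed)
        self._init(L, rng)
        p = self._params
        names = list(p)
        opt = Adam([p[k] for k in names], lr=self.learning_rate)
        onehot = np.eye(2)[y]
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], onehot[idx]
                proba, cache = self._forward(xb, rng)
                grads = self._backward(proba, yb, cache)
                opt.step([grads[k] for k in names])
        return self

    def _backward(self, proba, onehot, cache):
        p = self._params
        nb = proba.shape[0]
        grads = {}
        dlogits = (proba - onehot) / nb
        flat = cache["flat"]
        grads["wd"] = flat.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["wd"].T
        if "drop" in cache:
            dflat = dflat * cache["drop"]
        dx = dflat.reshape(cache["pool_shape"])
        for i in (2, 1):
            x_shape, cols, a, arg = cache[i]
            da = self._unpool(dx, arg, a.shape[1])
            dz = da * (a > 0)
            grads[f"w{i}"] = np.tensordot(cols, dz, axes=([0, 1], [0, 1]))
            grads[f"b{i}"] = dz.sum(axis=(0, 1))
            dcols = dz @ p[f"w{i}"].T
            dx = _col2im(dcols, x_shape[1], x_shape[2], self.kernel_size)
        return grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise DimensionError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self._input_len:
            raise DimensionError(f"expected (n, {self._input_len}) input, got {X.shape}")
        proba, _ = self._forward(X, rng=None)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "kernel_size": self.kernel_size,
            "filters": self.filters,
            "dropout": self.dropout,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    def set_params(self, **kwargs) -> "Conv1DClassifier":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
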