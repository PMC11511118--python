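"""Minimal seeded neural-network engine (numpy) for the MLP and 1-D CNN classifiers.

Implements exactly the pieces the shoulder-task models need: dense, ReLU,
dropout, 1-D same-padded convolution, batch normalization, max-pooling, a
softmax cross-entropy head, full-batch Adam, and loss-plateau early stopping.
Everything is driven by a single ``numpy`` Generator so that building and
training are bit-reproducible for a given seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

#: Single-precision keeps the full-batch GEMMs memory-bound ops ~2x faster;
#: all parameters, activations and gradients use this dtype.
DTYPE = np.float32

__all__ = [
    "EarlyStopping",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv1D",
    "BatchNorm1D",
    "MaxPool1D",
    "Flatten",
    "Network",
    "softmax",
]


class EarlyStopping:
    """Stop when the monitored loss fails to drop by ``min_delta`` for ``patience`` epochs.

    An epoch counts as an improvement only if its loss undercuts the best loss
    seen so far by at least ``min_delta``; after ``patience`` consecutive
    non-improving epochs :meth:`update` returns True.
    """

    def __init__(self, patience: int = 10, min_delta: float = 0.01):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.wait = 0

    def update(self, loss: float) -> bool:
        if self.best - loss >= self.min_delta:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep.astype(DTYPE) / DTYPE(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self.rate == 0.0:
            return dy
        return dy * self._mask


class Conv1D(_Layer):
    """Same-padded 1-D convolution with stride 1; input shape (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, (c_out, c_in, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in = c_in
        self.kernel = kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l

    @staticmethod
    def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
        """(batch, channels, padded_len) -> contiguous (batch*out_len, channels*kernel)."""
        win = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=2)
        b, c, length, k = win.shape
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * length, c * k)

    def forward(self, x, train):
        b, _, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        self._cols = self._im2col(xp, self.kernel)          # (b*L, c_in*k)
        self._in_len = length
        y = self._cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return y.reshape(b, length, -1).transpose(0, 2, 1)  # (b, c_out, L)

    def backward(self, dy):
        b, c_out, length = dy.shape
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * length, c_out)
        self.dW[...] = (dy_flat.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dy_flat.sum(axis=0)
        k = self.kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        dy_cols = self._im2col(dyp, k)                      # (b*(L+k-1), c_out*k)
        w_flip = np.ascontiguousarray(self.W[:, :, ::-1].transpose(0, 2, 1)).reshape(c_out * k, self.c_in)
        dxp = (dy_cols @ w_flip).reshape(b, length + k - 1, self.c_in).transpose(0, 2, 1)
        return np.ascontiguousarray(dxp[:, :, self.pad_l:self.pad_l + self._in_len])

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1D(_Layer):
    """Per-channel batch normalization over (batch, length) for conv activations."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = DTYPE(momentum)
        self.eps = DTYPE(eps)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2), dtype=DTYPE)
            var = x.var(axis=(0, 2), dtype=DTYPE)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * (DTYPE(1.0) / self._std[:, None])
        self._m = x.shape[0] * x.shape[2]
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, dy):
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[:, None]
        m = self._m
        return (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True) / m
        ) / self._std[:, None]

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class MaxPool1D(_Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        b, c, length = x.shape
        n = length // self.size
        self._in_shape = x.shape
        xr = x[:, :, : n * self.size].reshape(b, c, n, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, length = self._in_shape
        n = dy.shape[2]
        dx = np.zeros((b, c, n, self.size), dtype=dy.dtype)
        bi, ci, ni = np.ogrid[:b, :c, :n]
        dx[bi, ci, ni, self._argmax] = dy
        out = np.zeros(self._in_shape, dtype=dy.dtype)
        out[:, :, : n * self.size] = dx.reshape(b, c, n * self.size)
        return out


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape1D(_Layer):
    """(batch, d) -> (batch, 1, d) to feed a feature vector to a 1-D convolution."""

    def forward(self, x, train):
        return x[:, None, :]

    def backward(self, dy):
        return dy[:, 0, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params_grads: Sequence[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(params_grads):
            m = self.m.setdefault(i, np.zeros_like(p))
            v = self.v.setdefault(i, np.zeros_like(p))
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    """A feed-forward stack trained with mini-batch Adam on softmax cross-entropy."""

    def __init__(self, layers: Sequence[_Layer], lr: float = 1e-3,
                 rng: np.random.Generator | None = None, batch_size: int = 32):
        self.layers = list(layers)
        self.lr = lr
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.batch_size = batch_size
        self.training_log: list[float] = []
        self.fitted = False

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params_grads())

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p, _ in layer.params_grads()]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        max_epochs: int = 100,
        patience: int = 10,
        min_delta: float = 0.01,
    ) -> "Network":
        X = np.asarray(X, dtype=DTYPE)
        y = np.asarray(y, dtype=int)
        onehot = np.eye(2, dtype=DTYPE)[y]
        n = X.shape[0]
        stopper = EarlyStopping(patience=patience, min_delta=min_delta)
        self.training_log = []
        for _ in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, tb = X[idx], onehot[idx]
                prob = softmax(self._forward(xb, train=True))
                loss = float(-np.mean(np.sum(tb * np.log(prob + 1e-12), axis=1)))
                epoch_loss += loss * idx.size
                grad = (prob - tb) / idx.size
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._optimizer().step(self._all_params_grads())
            self.training_log.append(epoch_loss / n)
            if stopper.update(self.training_log[-1]):
                break
        self.fitted = True
        return self

    def _optimizer(self) -> _Adam:
        if not hasattr(self, "_adam"):
            self._adam = _Adam(self.lr)
        return self._adam

    def _all_params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [pg for layer in self.layers for pg in layer.params_grads()]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("network is not fitted")
        return softmax(self._forward(np.asarray(X, dtype=DTYPE), train=False))
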