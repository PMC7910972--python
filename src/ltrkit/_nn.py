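"""Minimal numpy layer stack with explicit backprop and Adam.

Supports exactly what the lineage classifiers need: dense, ReLU, 1-D
convolution (channels-first), max pooling, dropout, flatten; softmax
outputs trained with either mean-squared error on one-hot targets or
categorical cross-entropy.  float32 throughout; fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: str = "he"):
        super().__init__()
        if scale == "he":
            std = np.sqrt(2.0 / n_in)
        else:  # glorot, for the output layer
            std = np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv1D(Layer):
    """1-D convolution, valid padding, stride 1, channels-first (B, C, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, std, size=(c_out, c_in * kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.c_in = c_in
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        B, C, L = x.shape
        k = self.kernel
        L_out = L - k + 1
        if L_out < 1:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        # (B, C, L_out, k) view -> (B, L_out, C*k)
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, L_out, C * k)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.W.T + self.b  # (B, L_out, c_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, g):
        B, c_out, L_out = g.shape
        k = self.kernel
        gt = g.transpose(0, 2, 1)  # (B, L_out, c_out)
        self.grads[0][...] = np.einsum("blo,blk->ok", gt, self._cols, optimize=True)
        self.grads[1][...] = gt.sum(axis=(0, 1))
        gcols = gt @ self.W  # (B, L_out, C*k)
        gcols = gcols.reshape(B, L_out, self.c_in, k).transpose(0, 2, 1, 3)
        gx = np.zeros(self._in_shape, dtype=np.float32)
        for j in range(k):
            gx[:, :, j : j + L_out] += gcols[:, :, :, j]
        return gx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the last axis; trailing remainder dropped."""

    def __init__(self, window: int = 2):
        super().__init__()
        self.window = window

    def forward(self, x, train):
        B, C, L = x.shape
        w = self.window
        L_out = L // w
        if L_out < 1:
            raise ValueError(f"input length {L} shorter than pool window {w}")
        xt = x[:, :, : L_out * w].reshape(B, C, L_out, w)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, g):
        B, C, L_out = g.shape
        gx = np.zeros(self._in_shape, dtype=np.float32)
        gx_view = gx[:, :, : L_out * self.window].reshape(B, C, L_out, self.window)
        np.put_along_axis(gx_view, self._argmax[..., None], g[..., None], axis=3)
        return gx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape1D(Layer):
    """(B, d) -> (B, 1, d): present a feature vector as a 1-channel signal."""

    def forward(self, x, train):
        return x[:, None, :]

    def backward(self, g):
        return g[:, 0, :]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class Loss:
    """Softmax-output loss: value and gradient w.r.t. the logits."""

    kind: str  # "mse" (on one-hot targets) or "categorical_crossentropy"

    def __call__(self, logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
        p = softmax(logits.astype(np.float64))
        B, C = p.shape
        if self.kind == "mse":
            e = p - onehot
            loss = float((e**2).mean())
            s = (e * p).sum(axis=1, keepdims=True)
            dz = 2.0 * p * (e - s) / (B * C)
        elif self.kind == "categorical_crossentropy":
            eps = 1e-12
            loss = float(-(onehot * np.log(p + eps)).sum(axis=1).mean())
            dz = (p - onehot) / B
        else:
            raise ValueError(f"unknown loss {self.kind!r}")
        return loss, dz.astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float = 0.01, **_ignored):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Network:
    """A sequential stack ending in logits; softmax applied by the loss/predict."""

    def __init__(self, layers: list[Layer], loss: Loss):
        self.layers = layers
        self.loss = loss

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dz: np.ndarray) -> None:
        g = dz
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        chunks = [softmax(self.forward(x[i : i + batch]).astype(np.float64))
                  for i in range(0, len(x), batch)]
        return np.vstack(chunks)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))
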