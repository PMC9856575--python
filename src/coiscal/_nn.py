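"""Minimal NumPy feed-forward / convolutional network backend.

Just enough machinery for the two small convolutional classifier
architectures: same-padded 1-D/2-D convolutions, stride-2 max pooling,
dense layers, ReLU/sigmoid activations, inverted dropout, softmax
cross-entropy and Adam.  Deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Network", "Dense", "Conv1D", "Conv2D", "MaxPool1D", "MaxPool2D",
           "ReLU", "Sigmoid", "Dropout", "Flatten"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def init(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        return in_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense(Layer):
    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units

    def init(self, rng, in_shape):
        (d,) = in_shape
        self.W = _uniform(rng, (d, self.units), d)
        self.b = np.zeros(self.units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, training):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self.x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Conv1D(Layer):
    """Same-padded 1-D convolution over (batch, channels, length)."""

    def __init__(self, filters: int, kernel: int) -> None:
        super().__init__()
        self.filters, self.kernel = filters, kernel

    def init(self, rng, in_shape):
        c, length = in_shape
        fan_in = c * self.kernel
        self.W = _uniform(rng, (self.filters, c, self.kernel), fan_in)
        self.b = np.zeros(self.filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.filters, length)

    def forward(self, x, training):
        k = self.kernel
        left = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (left, k - 1 - left)))
        self.windows = sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
        return (
            np.einsum("bclk,fck->bfl", self.windows, self.W)
            + self.b[None, :, None]
        )

    def backward(self, dy):
        k = self.kernel
        left = (k - 1) // 2
        self.grads[0][...] = np.einsum("bclk,bfl->fck", self.windows, dy)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        B, C, L, _ = self.windows.shape
        dxp = np.zeros((B, C, L + k - 1))
        for j in range(k):
            dxp[:, :, j : j + L] += np.einsum("bfl,fc->bcl", dy, self.W[:, :, j])
        return dxp[:, :, left : left + L]


class Conv2D(Layer):
    """Same-padded 2-D convolution over (batch, channels, height, width)."""

    def __init__(self, filters: int, kernel: int) -> None:
        super().__init__()
        self.filters, self.kernel = filters, kernel

    def init(self, rng, in_shape):
        c, h, w = in_shape
        fan_in = c * self.kernel**2
        self.W = _uniform(rng, (self.filters, c, self.kernel, self.kernel), fan_in)
        self.b = np.zeros(self.filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        return (self.filters, h, w)

    def forward(self, x, training):
        k = self.kernel
        top = (k - 1) // 2
        xp = np.pad(
            x, ((0, 0), (0, 0), (top, k - 1 - top), (top, k - 1 - top))
        )
        self.windows = sliding_window_view(xp, (k, k), axis=(2, 3))
        return (
            np.einsum("bchwij,fcij->bfhw", self.windows, self.W)
            + self.b[None, :, None, None]
        )

    def backward(self, dy):
        k = self.kernel
        top = (k - 1) // 2
        self.grads[0][...] = np.einsum("bchwij,bfhw->fcij", self.windows, dy)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        B, C, H, W_, _, _ = self.windows.shape
        dxp = np.zeros((B, C, H + k - 1, W_ + k - 1))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W_] += np.einsum(
                    "bfhw,fc->bchw", dy, self.W[:, :, i, j]
                )
        return dxp[:, :, top : top + H, top : top + W_]


class MaxPool1D(Layer):
    """Size-2, stride-2 pooling; truncates an odd trailing sample."""

    def init(self, rng, in_shape):
        c, length = in_shape
        if length < 2:
            raise ValueError("input too short to pool")
        return (c, length // 2)

    def forward(self, x, training):
        self.in_len = x.shape[2]
        L2 = self.in_len // 2
        pairs = x[:, :, : 2 * L2].reshape(x.shape[0], x.shape[1], L2, 2)
        self.argmax = pairs.argmax(axis=3)
        return pairs.max(axis=3)

    def backward(self, dy):
        B, C, L2 = dy.shape
        dpairs = np.zeros((B, C, L2, 2))
        np.put_along_axis(dpairs, self.argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros((B, C, self.in_len))
        dx[:, :, : 2 * L2] = dpairs.reshape(B, C, 2 * L2)
        return dx


class MaxPool2D(Layer):
    """2x2, stride-2 pooling; truncates odd trailing rows/columns."""

    def init(self, rng, in_shape):
        c, h, w = in_shape
        if h < 2 or w < 2:
            raise ValueError("input too small to pool")
        return (c, h // 2, w // 2)

    def forward(self, x, training):
        self.in_shape = x.shape
        B, C, H, W_ = x.shape
        H2, W2 = H // 2, W_ // 2
        tiles = x[:, :, : 2 * H2, : 2 * W2].reshape(B, C, H2, 2, W2, 2)
        tiles = tiles.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
        self.argmax = tiles.argmax(axis=4)
        return tiles.max(axis=4)

    def backward(self, dy):
        B, C, H2, W2 = dy.shape
        dtiles = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(dtiles, self.argmax[..., None], dy[..., None], axis=4)
        dtiles = dtiles.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self.in_shape)
        dx[:, :, : 2 * H2, : 2 * W2] = dtiles.reshape(B, C, 2 * H2, 2 * W2)
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class Sigmoid(Layer):
    def forward(self, x, training):
        self.y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self.y

    def backward(self, dy):
        return dy * self.y * (1.0 - self.y)


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.p <= 0:
            self.mask = None
            return x
        keep = 1.0 - self.p
        self.mask = (self.rng.random(x.shape) < keep) / keep
        return x * self.mask

    def backward(self, dy):
        return dy if self.mask is None else dy * self.mask


class Flatten(Layer):
    def init(self, rng, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self.in_shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Sequential network trained with Adam on softmax cross-entropy."""

    def __init__(
        self,
        layers: list[Layer],
        input_shape: tuple,
        seed: int = 0,
        lr: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 32,
    ) -> None:
        self.layers = layers
        self.rng = np.random.default_rng(seed)
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        shape = input_shape
        for layer in layers:
            if isinstance(layer, Dropout):
                layer.rng = self.rng
            shape = layer.init(self.rng, shape)
        self._adam_m = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self._adam_v = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self._adam_t = 0

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def _step(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self._forward(x, training=True)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        dy = probs.copy()
        dy[np.arange(n), y] -= 1.0
        dy /= n
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self._adam_m[li][pi]
                v = self._adam_v[li][pi]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return float(loss)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Network":
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                self._step(X[batch], y[batch])
        return self

    def predict_scores(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            _softmax(self._forward(X[i : i + batch_size], training=False))
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.vstack(chunks)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lower class index
        return self.predict_scores(X).argmax(axis=1)
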