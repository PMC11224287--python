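"""Minimal seedable neural-network engine (numpy).

Implements exactly the layer zoo the splice-event classifier needs --
1D valid-padding convolution, inverted dropout, ReLU, max-pooling,
dense layers -- with reverse-mode gradients and an Adam optimizer.
All floating state is float32; every source of randomness (weight
initialisation, dropout masks) draws from an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "Dropout",
    "ReLU",
    "MaxPool1D",
    "Dense",
    "Adam",
    "sigmoid",
]

DTYPE = np.float32


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: forward caches whatever backward needs."""

    #: trainable arrays, aligned with ``grads``
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """Valid-padding, stride-1 cross-correlation over (batch, length, channels)."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        w = _glorot_uniform(rng, kernel * in_channels, kernel * filters,
                            (kernel, in_channels, filters))
        b = np.zeros(filters, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def out_length(self, length: int) -> int:
        return length - self.kernel + 1

    def forward(self, x, *, train=False, rng=None):
        w, b = self.params
        lout = x.shape[1] - self.kernel + 1
        if lout < 1:
            raise ValueError(
                f"conv kernel {self.kernel} exceeds input length {x.shape[1]}")
        out = np.zeros((x.shape[0], lout, self.filters), dtype=DTYPE)
        for k in range(self.kernel):
            out += x[:, k:k + lout, :] @ w[k]
        out += b
        self._x = x
        return out

    def backward(self, dout):
        x = self._x
        w, _ = self.params
        lout = dout.shape[1]
        dw = np.zeros_like(w)
        dx = np.zeros_like(x)
        for k in range(self.kernel):
            xs = x[:, k:k + lout, :]
            dw[k] = np.einsum("btc,btf->cf", xs, dout, optimize=True)
            dx[:, k:k + lout, :] += dout @ w[k].T
        self.grads[0][...] = dw
        self.grads[1][...] = dout.sum(axis=(0, 1))
        return dx


class Dropout(Layer):
    """Inverted dropout: scales kept units by 1/(1-rate) at train time,
    identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1): {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        self._mask = mask
        return x * mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._pos: np.ndarray | None = None

    def forward(self, x, *, train=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, DTYPE(0.0))

    def backward(self, dout):
        return dout * self._pos


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; trailing remainder is dropped
    (floor division), matching the 134 -> 67, 15 -> 7 cascade."""

    def __init__(self, size: int = 2, stride: int = 2) -> None:
        super().__init__()
        if size != stride:
            raise NotImplementedError("only size == stride pooling is supported")
        self.size = size
        self._arg: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def out_length(self, length: int) -> int:
        return length // self.size

    def forward(self, x, *, train=False, rng=None):
        b, length, c = x.shape
        lout = length // self.size
        if lout < 1:
            raise ValueError(f"pool size {self.size} exceeds input length {length}")
        xv = x[:, :lout * self.size, :].reshape(b, lout, self.size, c)
        self._arg = xv.argmax(axis=2)
        self._in_shape = x.shape
        return xv.max(axis=2)

    def backward(self, dout):
        b, lout, c = dout.shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dxv = dx[:, :lout * self.size, :].reshape(b, lout, self.size, c)
        bi, ti, ci = np.ogrid[:b, :lout, :c]
        dxv[bi, ti, self._arg, ci] = dout
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.units = units
        w = _glorot_uniform(rng, in_features, units, (in_features, units))
        b = np.zeros(units, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Adam:
    """Adam with the classic bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 learning_rate: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, epsilon: float = 1e-8,
                 decay: float = 0.0) -> None:
        self.params = params
        self.grads = grads
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.decay = decay
        self.t = 0
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        if self.decay:
            lr = lr / (1.0 + self.decay * self.t)
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.epsilon)
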