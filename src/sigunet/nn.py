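"""Minimal 1D convolutional network primitives in numpy.

Every layer implements ``forward(x)`` and ``backward(dy)`` with explicit
gradients; arrays are laid out as ``(batch, length, channels)``.  Convolutions
are length-preserving ("same" padding), transposed convolutions use kernel 2
stride 2 (exact doubling), and pooling halves the length.  This is all the
machinery a 1D U-Net needs, kept deliberately small so gradients can be
checked numerically in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: layers with parameters expose ``params`` / ``grads``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv1d(Layer):
    """Length-preserving 1D convolution with bias.

    Weight shape ``(kernel, c_in, c_out)``; odd kernel so padding is symmetric.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.w = he_uniform(rng, kernel * c_in, (kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._xp = xp
        L = x.shape[1]
        y = np.broadcast_to(self.b, (x.shape[0], L, self.c_out)).copy()
        for t in range(self.kernel):
            y += xp[:, t : t + L, :] @ self.w[t]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        L = dy.shape[1]
        pad = self.kernel // 2
        self.db[:] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for t in range(self.kernel):
            self.dw[t] = np.tensordot(xp[:, t : t + L, :], dy, axes=([0, 1], [0, 1]))
            dxp[:, t : t + L, :] += dy @ self.w[t].T
        return dxp[:, pad : pad + L, :]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ConvTranspose1d(Layer):
    """Transposed convolution, kernel 2 stride 2: doubles the length."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, 2
        self.w = he_uniform(rng, c_in, (2, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, L, _ = x.shape
        y = np.empty((B, 2 * L, self.c_out))
        for t in range(2):
            y[:, t::2, :] = x @ self.w[t] + self.b
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.db[:] = dy.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        for t in range(2):
            dyt = dy[:, t::2, :]
            self.dw[t] = np.tensordot(x, dyt, axes=([0, 1], [0, 1]))
            dx += dyt @ self.w[t].T
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2(Layer):
    """Size-2 stride-2 average pooling along the length axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return 0.5 * (x[:, ::2, :] + x[:, 1::2, :])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.empty(self._shape)
        dx[:, ::2, :] = 0.5 * dy
        dx[:, 1::2, :] = 0.5 * dy
        return dx


class MaxPool2(Layer):
    """Size-2 stride-2 max pooling; ties route the gradient to the first slot."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        a, b = x[:, ::2, :], x[:, 1::2, :]
        self._first = a >= b
        return np.where(self._first, a, b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L2, C = dy.shape
        dx = np.zeros((B, 2 * L2, C))
        dx[:, ::2, :] = dy * self._first
        dx[:, 1::2, :] = dy * ~self._first
        return dx


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax along the last axis, numerically stabilised."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
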