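"""Minimal 1D neural-network layers with reverse-mode gradients.

The segmentation network is tiny (two encoder levels over 8-point windows,
a few tens of thousands of parameters), so the layers are implemented
directly on numpy float64 arrays: each layer caches what its backward pass
needs, `backward` accumulates parameter gradients in place and returns the
gradient with respect to its input.  Everything is deterministic given the
`numpy.random.Generator` used for initialisation, which is what makes
seeded training bit-reproducible on any CPU.

Shapes follow the channels-first convention: activations are
``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "ConvTranspose1d",
    "MaxPool1d",
    "ReLU",
    "Sigmoid",
    "Adam",
]


class Layer:
    """Base class: parameterised layers override `parameters`/`gradients`."""

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Stride-1 'same' 1D convolution (odd kernel), He-initialised.

    Implemented as one batched matmul per kernel tap — for the small kernels
    used here that is faster than an im2col pass and keeps every operand
    contiguous.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        scale = np.sqrt(2.0 / (c_in * kernel_size))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel_size))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = (self.k - 1) // 2
        L = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._xp = xp
        self._L = L
        y = self.b[:, None] * np.ones((x.shape[0], 1, L))
        for j in range(self.k):
            # y[n, o, l] += sum_c w[o, c, j] * xp[n, c, l + j]
            y += np.matmul(self.w[:, :, j], xp[:, :, j : j + L])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self._L
        self.gb += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            seg = self._xp[:, :, j : j + L]
            self.gw[:, :, j] += np.tensordot(dy, seg, axes=([0, 2], [0, 2]))
            dxp[:, :, j : j + L] += np.matmul(self.w[:, :, j].T, dy)
        p = (self.k - 1) // 2
        return dxp[:, :, p : p + L] if p else dxp

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class ConvTranspose1d(Layer):
    """Learned up-sampling by 2: kernel 2, stride 2 (non-overlapping taps)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 2))
        self.w = rng.normal(0.0, scale, size=(c_in, c_out, 2))
        self.b = np.zeros(c_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, _, L = x.shape
        c_out = self.w.shape[1]
        y = np.empty((n, c_out, 2 * L))
        for j in range(2):
            # y[n, o, 2l + j] = sum_c w[c, o, j] * x[n, c, l]
            y[:, :, j::2] = np.matmul(self.w[:, :, j].T, x)
        return y + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gb += dy.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        for j in range(2):
            dyj = np.ascontiguousarray(dy[:, :, j::2])
            self.gw[:, :, j] += np.tensordot(self._x, dyj, axes=([0, 2], [0, 2]))
            dx += np.matmul(self.w[:, :, j], dyj)
        return dx

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.gw, self.gb]


class MaxPool1d(Layer):
    """Max pooling, kernel 2, stride 2; ties resolve to the first position."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        v = x.reshape(n, c, L // 2, 2)
        self._argmax = v.argmax(axis=3)
        self._in_shape = x.shape
        return v.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, Lh = dy.shape
        dx = np.zeros((n, c, Lh, 2))
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        return dx.reshape(self._in_shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable piecewise form
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
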