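"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for a compact super-resolution GAN on CPU:
2D convolution (im2col forward, transposed-convolution backward),
PReLU / LeakyReLU activations, a dense head, and Adam.  All layers
cache what backward needs, accumulate gradients with ``+=`` (call
``zero_grad`` between steps), and run in float32.

Gradients are verified against central finite differences in the test
suite; there is no batch normalization anywhere, by design.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "PReLU",
    "LeakyReLU",
    "Flatten",
    "Dense",
    "Adam",
    "sigmoid",
    "softplus",
]

DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient and Adam state."""

    __slots__ = ("data", "grad", "m", "v")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.m = np.zeros_like(self.data)
        self.v = np.zeros_like(self.data)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> column matrix (N, L, C*k*k) plus output spatial size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d:
    """3x3-style convolution, zero ('same') padding, optional stride."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            rng = rng or np.random.default_rng()
            fan_in = c_in * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.weight.data.reshape(self.c_out, -1)
        y = cols @ wmat.T + self.bias.data
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(x.shape[0], ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n, _, h, w = x_shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.c_out)
        self.weight.grad += np.einsum(
            "nlc,nlk->ck", dyf, cols, optimize=True
        ).reshape(self.weight.data.shape)
        self.bias.grad += dyf.sum(axis=(0, 1))

        # input gradient = transposed convolution: dilate dy by the stride,
        # pad by k-1-pad (plus the stride remainder on the far side), and
        # correlate with the 180-degree-rotated, channel-swapped kernel.
        s, k, p = self.stride, self.k, self.pad
        if s > 1:
            dil = np.zeros((n, self.c_out, (ho - 1) * s + 1, (wo - 1) * s + 1), dtype=DTYPE)
            dil[:, :, ::s, ::s] = dy
        else:
            dil = dy.astype(DTYPE, copy=False)
        extra_h = (h + 2 * p - k) % s
        extra_w = (w + 2 * p - k) % s
        lo = k - 1 - p
        dil = np.pad(dil, ((0, 0), (0, 0), (lo, lo + extra_h), (lo, lo + extra_w)))
        w_flip = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_b, hb, wb = _im2col(dil, k, 1, 0)
        dx = cols_b @ w_flip.reshape(self.c_in, -1).T
        return dx.reshape(n, hb, wb, self.c_in).transpose(0, 3, 1, 2)


class PReLU:
    """Parametric ReLU with a single learnable slope (SRGAN convention)."""

    def __init__(self, init: float = 0.25):
        self.alpha = Param(np.array([init]))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.alpha]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.where(x > 0, x, self.alpha.data[0] * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        neg = x <= 0
        self.alpha.grad += np.array([(dy * np.where(neg, x, 0.0)).sum()], dtype=DTYPE)
        return dy * np.where(neg, self.alpha.data[0], 1.0).astype(DTYPE)


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x > 0
        return np.where(self._cache, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._cache, dy, self.slope * dy)


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)))
        self.bias = Param(np.zeros(n_out))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x.astype(DTYPE, copy=False)
        return self._cache @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._cache
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
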