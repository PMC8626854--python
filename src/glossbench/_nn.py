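"""Minimal NumPy neural-network primitives.

Forward/backward implementations of 2-D convolution (im2col), strided and
transposed convolution, 2x2 max-pooling, dense layers, and SGD with
momentum and L2 weight decay. Sized for desk-scale experiments (tens of
pixels, thousands of images) on one CPU; arrays are NCHW float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32  # training precision: single precision is ample at desk scale


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def im2col(x: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]
    ho, wo = win.shape[2], win.shape[3]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo), ho, wo


def col2im(cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int = 1) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    out = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            out[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += cols[:, :, ki, kj]
    return out


class Conv2D:
    """Same-padded (stride 1) or strided convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, stride: int = 1, pad: int | None = None):
        self.k, self.stride = k, stride
        self.pad = (k // 2 if stride == 1 else max((k - stride) // 2, 0)) if pad is None else pad
        self.W = he_init(rng, (out_ch, in_ch, k, k), fan_in=in_ch * k * k)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = _pad(x, self.pad)
        cols, ho, wo = im2col(xp, self.k, self.stride)
        self._cache = (x.shape, xp.shape, cols)
        out = (self.W.reshape(self.W.shape[0], -1) @ cols) + self.b[None, :, None]
        n = x.shape[0]
        return out.reshape(n, self.W.shape[0], ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols = self._cache
        n, o, ho, wo = dy.shape
        dyf = dy.reshape(n, o, ho * wo)
        self.dW = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.shape) / n
        self.db = dyf.sum(axis=(0, 2)) / n
        dcols = np.matmul(self.W.reshape(o, -1).T[None], dyf)
        dxp = col2im(dcols, xp_shape, self.k, self.stride)
        p = self.pad
        return dxp[:, :, p : xp_shape[2] - p, p : xp_shape[3] - p] if p else dxp

    def params(self):
        return [("W", True), ("b", False)]


class ConvTranspose2D:
    """Stride-2 transposed convolution (resolution doubling)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("ConvTranspose2D requires an odd kernel (upsample-then-convolve)")
        self.k = k
        self.conv = Conv2D(in_ch, out_ch, k, rng, stride=1, pad=k // 2)

    @property
    def W(self):
        return self.conv.W

    @property
    def b(self):
        return self.conv.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        # zero-upsample by 2 then same-pad convolve: equivalent to a
        # stride-2 transposed convolution up to kernel indexing.
        n, c, h, w = x.shape
        up = np.zeros((n, c, 2 * h, 2 * w), dtype=x.dtype)
        up[:, :, ::2, ::2] = x
        self._up_shape = up.shape
        return self.conv.forward(up)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(dy)
        return dup[:, :, ::2, ::2]

    def params(self):
        return self.conv.params()


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2:
    """2x2 max pooling with stride 2 (ties route gradient to first max)."""

    def forward(self, x):
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "maxpool needs even spatial size"
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = win.argmax(axis=-1)
        self._onehot = np.eye(4, dtype=bool)[idx]
        self._x_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._x_shape
        dwin = dy[..., None] * self._onehot
        return dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_init(rng, (n_in, n_out), fan_in=n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        n = dy.shape[0]
        self.dW = self._x.T @ dy / n
        self.db = dy.mean(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", True), ("b", False)]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and gradient wrt logits."""
    z = logits.ravel()
    y = y.ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y).reshape(logits.shape)
    return float(loss), grad


def sgd_update(layer, lr: float, momentum: float, l2: float) -> None:
    """Momentum SGD step with L2 decay on weight matrices (not biases)."""
    for name, decay in layer.params():
        if isinstance(layer, ConvTranspose2D):
            target = layer.conv
        else:
            target = layer
        g = getattr(target, "d" + name)
        if decay and l2 > 0:
            g = g + l2 * getattr(target, name)
        v = getattr(target, "v" + name)
        v *= momentum
        v -= lr * g
        setattr(target, "v" + name, v)
        setattr(target, name, getattr(target, name) + v)
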