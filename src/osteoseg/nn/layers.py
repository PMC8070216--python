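"""Layers with explicit forward/backward passes (NHWC, float32).

Convolution is implemented by im2col + matmul; its input gradient is the
'same' convolution of the output gradient with the spatially flipped,
channel-transposed kernel, which avoids a scatter-add col2im. Max pooling is
2×2/stride-2 and records per-window argmax indices (values 0..3 over the
flattened window) so the decoder can unpool into the exact positions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2D",
    "BatchNorm2D",
    "ConvBNReLU",
    "Dense",
    "maxpool2x2",
    "maxunpool2x2",
    "gather2x2",
    "softmax",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)

    def zero_grad(self):
        self.g[...] = 0.0


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H',W',C*k*k) patches in (c,u,v) order."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,H',W',C,k,k)
    n, hh, ww = win.shape[:3]
    return win.reshape(n, hh, ww, -1)


def _conv_same(x: np.ndarray, w4: np.ndarray):
    """'same' conv of x (N,H,W,Cin) with w4 (k,k,Cin,Cout); also returns cols."""
    k = w4.shape[0]
    cols = _im2col(x, k, k // 2)
    wf = w4.transpose(2, 0, 1, 3).reshape(-1, w4.shape[3])
    return cols @ wf, cols


class Conv2D:
    """k×k 'same' convolution (k odd), He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd for 'same' convolution")
        scale = np.sqrt(2.0 / (ksize * ksize * cin))
        self.w = Param(rng.normal(0.0, scale, (ksize, ksize, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k = ksize
        self._cols = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y, cols = _conv_same(x.astype(np.float32, copy=False), self.w.v)
        self._cols = cols if training else None
        return y + self.b.v

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cout = self.w.v.shape[3]
        cin = self.w.v.shape[2]
        gyf = gy.reshape(-1, cout).astype(np.float32, copy=False)
        colsf = self._cols.reshape(-1, self._cols.shape[-1])
        gw = (colsf.T @ gyf).reshape(cin, self.k, self.k, cout).transpose(1, 2, 0, 3)
        self.w.g += gw
        self.b.g += gy.sum(axis=(0, 1, 2))
        self._cols = None
        # input gradient: conv with flipped kernel, in/out channels swapped
        wt = self.w.v[::-1, ::-1].transpose(0, 1, 3, 2)
        gx, _ = _conv_same(gy.astype(np.float32, copy=False), np.ascontiguousarray(wt))
        return gx

    def params(self):
        return [self.w, self.b]

    def stats(self):
        return []


class BatchNorm2D:
    """Batch normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            std = np.sqrt(var + self.eps)
            xhat = (x - mu) / std
            self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
            self._cache = (xhat, std)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            self._cache = None
        return (self.gamma.v * xhat + self.beta.v).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        m = gy.shape[0] * gy.shape[1] * gy.shape[2]
        self.gamma.g += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.g += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.v
        gx = (
            gxhat - gxhat.mean(axis=(0, 1, 2)) - xhat * (gxhat * xhat).mean(axis=(0, 1, 2))
        ) / std
        self._cache = None
        return gx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def stats(self):
        return [self.running_mean, self.running_var]


class ConvBNReLU:
    """The encoder/decoder building unit: conv3×3 → batch-norm → ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, ksize: int = 3):
        self.conv = Conv2D(cin, cout, rng, ksize)
        self.bn = BatchNorm2D(cout)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self.bn.forward(self.conv.forward(x, training), training)
        mask = y > 0
        self._mask = mask if training else None
        return np.where(mask, y, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.where(self._mask, gy, 0.0).astype(np.float32)
        self._mask = None
        return self.conv.backward(self.bn.backward(gy))

    def params(self):
        return self.conv.params() + self.bn.params()

    def stats(self):
        return self.bn.stats()


class Dense:
    """Fully connected layer for the classification head."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        return x @ self.w.v + self.b.v

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.w.g += self._x.T @ gy
        self.b.g += gy.sum(axis=0)
        self._x = None
        return (gy @ self.w.v.T).astype(np.float32)

    def params(self):
        return [self.w, self.b]

    def stats(self):
        return []


def _windows(x: np.ndarray):
    n, h, w, c = x.shape
    return (
        x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
    )


def maxpool2x2(x: np.ndarray):
    """2×2/stride-2 max pooling. Returns (pooled, indices in 0..3 per window)."""
    if x.shape[1] % 2 or x.shape[2] % 2:
        raise ValueError(f"spatial extents must be even, got {x.shape[1:3]}")
    x4 = _windows(x)
    idx = x4.argmax(axis=3).astype(np.uint8)
    pooled = np.take_along_axis(x4, idx[:, :, :, None, :].astype(np.intp), axis=3)[:, :, :, 0, :]
    return pooled, idx


def maxunpool2x2(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place each value at its recorded argmax position; zeros elsewhere."""
    n, h, w, c = y.shape
    out4 = np.zeros((n, h, w, 4, c), dtype=np.float32)
    np.put_along_axis(out4, idx[:, :, :, None, :].astype(np.intp), y[:, :, :, None, :], axis=3)
    return out4.reshape(n, h, w, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, c)


def gather2x2(g: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Adjoint of maxunpool2x2: read the gradient at the recorded positions."""
    g4 = _windows(g)
    return np.take_along_axis(g4, idx[:, :, :, None, :].astype(np.intp), axis=3)[:, :, :, 0, :]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
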