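"""Minimal numpy neural-network layers with explicit backward passes.

Everything runs in float32. Each layer caches what its backward pass needs
during ``forward``; composites wire their children explicitly. Convolution is
im2col + one BLAS matmul; its backward folds the column gradient back with
k*k strided adds.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)
        self.decay = decay  # weight decay applies (False for BN affine params)

    @property
    def size(self) -> int:
        return self.v.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = False):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch), decay=False) if bias else None
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, oh, ow, k, k) -> (n, oh*ow, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, oh * ow, c * k * k
        )
        wflat = self.w.v.reshape(self.out_ch, -1)
        out = cols @ wflat.T
        if self.b is not None:
            out += self.b.v[None, None, :]
        if train:
            self._cols = cols
            self._xshape = (n, c, h, w)
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, oc, oh, ow = dout.shape
        k, s, p = self.k, self.stride, self.pad
        cols = self._cols
        self._cols = None
        if self.b is not None:
            self.b.g += dout.sum(axis=(0, 2, 3))
        dflat = dout.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (n, ohw, oc)
        d2 = dflat.reshape(n * oh * ow, oc)
        c2 = cols.reshape(n * oh * ow, -1)
        self.w.g += (d2.T @ c2).reshape(self.w.v.shape)
        dcols = dflat @ self.w.v.reshape(oc, -1)  # (n, ohw, c*k*k)
        _, c, h, w = self._xshape
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(ch), decay=False)
        self.beta = Param(np.zeros(ch), decay=False)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.gamma.v[None, :, None, None]
        b = self.beta.v[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(np.float32)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.g += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.v[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # clip keeps float32 output strictly inside (0, 1):
        # expit(+-15) is ~3e-7 away from the boundary, representable in float32
        out = expit(np.clip(x, -15.0, 15.0))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class PixelShuffle(Layer):
    """Sub-pixel rearrangement: (n, c*r^2, h, w) -> (n, c, h*r, w*r)."""

    def __init__(self, r: int = 2):
        self.r = r

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        out = x.reshape(n, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(out).reshape(n, c, h * r, w * r)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, hr, wr = dout.shape
        r = self.r
        h, w = hr // r, wr // r
        d = dout.reshape(n, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(d).reshape(n, c * r * r, h, w)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, oh, ow = dout.shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, oh * 2, ow * 2).astype(np.float32)


class ConvBNAct(Layer):
    """3x3 (or kxk) convolution + batch norm + optional ReLU."""

    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=None, act=True, rng=None):
        self.conv = Conv2d(in_ch, out_ch, k, stride, pad, rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = ReLU() if act else None

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        out = self.bn.forward(self.conv.forward(x, train), train)
        return self.act.forward(out, train) if self.act else out

    def backward(self, dout):
        if self.act:
            dout = self.act.backward(dout)
        return self.conv.backward(self.bn.backward(dout))


class ResBlock(Layer):
    """Two 3x3 conv+BN with identity (or projected) shortcut and ReLU."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        self.c1 = ConvBNAct(in_ch, out_ch, 3, stride, rng=rng)
        self.c2 = ConvBNAct(out_ch, out_ch, 3, 1, act=False, rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.short: ConvBNAct | None = ConvBNAct(in_ch, out_ch, 1, stride, pad=0,
                                                     act=False, rng=rng)
        else:
            self.short = None
        self.relu = ReLU()

    def params(self):
        p = self.c1.params() + self.c2.params()
        if self.short:
            p += self.short.params()
        return p

    def forward(self, x, train):
        main = self.c2.forward(self.c1.forward(x, train), train)
        sc = self.short.forward(x, train) if self.short else x
        return self.relu.forward(main + sc, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dx = self.c1.backward(self.c2.backward(d))
        dx += self.short.backward(d) if self.short else d
        return dx
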