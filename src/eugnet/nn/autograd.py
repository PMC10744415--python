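"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for an encoder--decoder segmentation network trained
with stochastic gradient descent on a CPU: elementwise arithmetic,
reductions, 2-D convolution (stride 1, arbitrary dilation, full or
depthwise grouping), 2x2 max pooling, nearest-neighbour upsampling,
channel concatenation and a numerically stable log-softmax.  Everything is
float32 and single-threaded-deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "max_pool2d", "upsample_nearest2", "log_softmax"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other).pow(-1.0)

    def pow(self, p: float):
        out = _node(np.power(self.data, p), (self,))
        out._backward = lambda g: self._accum(g * p * np.power(self.data, p - 1.0))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        m = self.data > 0
        out = _node(self.data * m, (self,))
        out._backward = lambda g: self._accum(g * m)
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        out = _node(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    # -- reductions and shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def _im2col(xp: np.ndarray, k: int, dilation: int, out_h: int, out_w: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, out_h, out_w, k, k) view of dilated taps."""
    keff = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))
    win = win[:, :, :out_h, :out_w, ::dilation, ::dilation]
    return win


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           dilation: int = 1, depthwise: bool = False) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation).

    x: (N, Cin, H, W);  w: (Cout, Cin, k, k), or (C, 1, k, k) when
    depthwise; b: (Cout,) or None.  Output spatial size equals input size.
    """
    n, cin, h, wd = x.data.shape
    cout, _, k, _ = w.data.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, dilation, h, wd)

    if depthwise:
        out = np.einsum("nchwij,cij->nchw", cols, w.data[:, 0], optimize=True)
    else:
        mat = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * wd, cin * k * k
        )
        out = (mat @ w.data.reshape(cout, -1).T).reshape(n, h, wd, cout)
        out = out.transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    res = _node(np.ascontiguousarray(out), parents)

    def bwd(g):
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if depthwise:
            dw = np.einsum("nchw,nchwij->cij", g, cols, optimize=True)
            w._accum(dw[:, None])
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i * dilation:i * dilation + h,
                        j * dilation:j * dilation + wd] += (
                            g * w.data[:, 0, i, j][None, :, None, None])
        else:
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, cout)
            dw = (gm.T @ mat).reshape(w.data.shape)
            w._accum(dw)
            dxp = np.zeros_like(xp)
            wt = w.data  # (Cout, Cin, k, k)
            for i in range(k):
                for j in range(k):
                    contrib = (gm @ wt[:, :, i, j]).reshape(n, h, wd, cin)
                    dxp[:, :, i * dilation:i * dilation + h,
                        j * dilation:j * dilation + wd] += contrib.transpose(0, 3, 1, 2)
        if pad:
            x._accum(dxp[:, :, pad:-pad, pad:-pad])
        else:
            x._accum(dxp)

    res._backward = bwd
    return res


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial sides must be even."""
    n, c, h, w = x.data.shape
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = _node(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], (x,))

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, h, w))

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.data.shape
    out = _node(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), (x,))

    def bwd(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    out = _node(y, (x,))
    sm = np.exp(y)

    def bwd(g):
        x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out
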