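"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every operation returns a new
:class:`Tensor` holding a closure that propagates gradients to its parents.
Only the operations the segmentation stack needs are implemented (elementwise
arithmetic, matmul, reductions, shape ops, stride-1 3-D convolution, 2x max
pooling, nearest upsampling).  All arithmetic is float32.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    # float64 arrays are preserved (analysis/oracle paths); everything else,
    # including python scalars and lists, becomes float32 (the network dtype)
    if isinstance(x, np.ndarray) and x.dtype == np.float64 and x.ndim > 0:
        return x
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents: tuple, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(_as_array(grad))
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bwd(g):
            a._accumulate(g * e * np.power(a.data, e - 1.0))

        return Tensor._make(np.power(a.data, e), (a,), bwd)

    # -- transcendental -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accumulate(g * (0.5 / out_data))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def softplus(self):
        a = self
        # stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        out_data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
        sig = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * sig)

        return Tensor._make(out_data.astype(DTYPE), (a,), bwd)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        """Clip values; gradient is zero outside the active range."""
        a = self
        mask = np.ones_like(a.data, dtype=bool)
        if lo is not None:
            mask &= a.data >= lo
        if hi is not None:
            mask &= a.data <= hi

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(DTYPE))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).astype(DTYPE))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = 1
            for ax in axes:
                n *= self.data.shape[ax]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        a, b = self, other

        def bwd(g):
            if g.ndim == 1:  # vector result: promote for uniform handling
                g = g.reshape(-1, 1) if b.data.ndim == 1 else g.reshape(1, -1)
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else b.data.reshape(1, -1))
                a._accumulate(_unbroadcast(ga, a.data.shape) if ga.shape != a.data.shape else ga)
            if b.requires_grad:
                at = np.swapaxes(a.data, -1, -2) if a.data.ndim > 1 else a.data.reshape(-1, 1)
                gb = np.matmul(at, g)
                b._accumulate(_unbroadcast(gb, b.data.shape) if gb.shape != b.data.shape else gb)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bwd(g):
            a._accumulate(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            a._accumulate(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bwd)

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bwd)


# -- free functions -----------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), bwd)


def stack_mean(tensors: Iterable[Tensor]) -> Tensor:
    ts = list(tensors)
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out * (1.0 / len(ts))


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


# -- spatial ops (N, C, H, W, D layout) ---------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int | None = None) -> Tensor:
    """Stride-1 3-D convolution (cross-correlation), 'same' output size.

    x: (N, C_in, H, W, D); w: (C_out, C_in, k, k, k); padding defaults to k//2.
    """
    n, cin, h, wd, d = x.data.shape
    cout, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cin_w}")
    pad = k // 2 if padding is None else padding

    if k == 1:
        xc = x.data.reshape(n, cin, -1)  # (N, Cin, V)
        wm = w.data.reshape(cout, cin)
        y = np.matmul(wm, xc)  # (N, Cout, V)
        y = y.reshape(n, cout, h, wd, d)
        if b is not None:
            y += b.data.reshape(1, cout, 1, 1, 1)

        def bwd1(g):
            gm = g.reshape(n, cout, -1)
            if x.requires_grad:
                gx = np.matmul(wm.T, gm)
                x._accumulate(gx.reshape(n, cin, h, wd, d))
            if w.requires_grad:
                gw = np.matmul(gm, xc.transpose(0, 2, 1)).sum(axis=0)
                w._accumulate(gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(gm.sum(axis=(0, 2)))

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(y, parents, bwd1)

    # channels-last im2col: the gathered patch matrix has contiguous
    # channel runs, feeding a single GEMM per direction
    def _cols(arr_ncf: np.ndarray) -> np.ndarray:
        """(N, C, H, W, D) -> (N*H*W*D, k^3*C) patch matrix, 'same' padding."""
        c = arr_ncf.shape[1]
        acl = np.ascontiguousarray(arr_ncf.transpose(0, 2, 3, 4, 1))
        ap = np.pad(acl, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
        win = sliding_window_view(ap, (k, k, k), axis=(1, 2, 3))  # (N,H,W,D,C,k,k,k)
        cols = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n * h * wd * d, k ** 3 * c)
        return np.ascontiguousarray(cols)

    cols = _cols(x.data)
    wm = np.ascontiguousarray(w.data.transpose(0, 2, 3, 4, 1)).reshape(cout, k ** 3 * cin)
    y = cols @ wm.T
    if b is not None:
        y += b.data
    y = np.ascontiguousarray(y.reshape(n, h, wd, d, cout).transpose(0, 4, 1, 2, 3))

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(n * h * wd * d, cout)
        if w.requires_grad:
            gw = (gm.T @ cols).reshape(cout, k, k, k, cin)
            w._accumulate(np.ascontiguousarray(gw.transpose(0, 4, 1, 2, 3)))
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            # dx = 'same' correlation of g with the flipped kernel, channels swapped
            wf = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 2, 3, 4, 0)
            ).reshape(cin, k ** 3 * cout)
            gcols = _cols(g)
            gx = (gcols @ wf.T).reshape(n, h, wd, d, cin).transpose(0, 4, 1, 2, 3)
            x._accumulate(np.ascontiguousarray(gx))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bwd)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial axes must be even."""
    n, c, h, w, d = x.data.shape
    if h % 2 or w % 2 or d % 2:
        raise ValueError(f"maxpool3d needs even spatial dims, got {(h, w, d)}")
    xv = x.data.reshape(n, c, h // 2, 2, w // 2, 2, d // 2, 2)
    xv = np.ascontiguousarray(xv.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
        n, c, h // 2, w // 2, d // 2, 8
    )
    idx = xv.argmax(axis=-1)
    y = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gfull = np.zeros_like(xv)
        np.put_along_axis(gfull, idx[..., None], g[..., None], axis=-1)
        gfull = gfull.reshape(n, c, h // 2, w // 2, d // 2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        x._accumulate(np.ascontiguousarray(gfull).reshape(n, c, h, w, d))

    return Tensor._make(np.ascontiguousarray(y), (x,), bwd)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the three spatial axes by `factor`."""
    f = int(factor)
    y = np.repeat(np.repeat(np.repeat(x.data, f, axis=2), f, axis=3), f, axis=4)

    def bwd(g):
        n, c, h, w, d = x.data.shape
        gv = g.reshape(n, c, h, f, w, f, d, f)
        x._accumulate(gv.sum(axis=(3, 5, 7)))

    return Tensor._make(y, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """GAP over the spatial axes of (N, C, H, W, D) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))
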