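"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd lineage, sized for the networks in
this package: dense/conv layers, normalisation, attention and the reductions
needed by the segmentation losses.  Arrays are float64 throughout so loss
identities hold to tight tolerances.

Only the operations the package uses are implemented; each op records a
closure that scatters the upstream gradient into its parents.  Broadcasting
follows NumPy semantics, with gradients summed back over broadcast axes.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- properties -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(g)
            b._accum(g)

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accum(g / b.data)
            b._accum(-g * a.data / (b.data * b.data))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accum(g * e * np.power(a.data, e - 1.0))

        return Tensor._result(np.power(a.data, e), (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(ga)
            b._accum(gb)

        return Tensor._result(np.matmul(a.data, b.data), (a, b), backward)

    # -- elementwise ------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._result(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._result(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._result(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._result(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._result(np.abs(a.data), (a,), lambda g: a._accum(g * sign))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.shape[ax] for ax in axes)
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._result(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(old))
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._result(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def __getitem__(self, key):
        a = self

        def backward(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, key, g)
            a._accum(buf)

        return Tensor._result(a.data[key], (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


# -- spatial ops (NCHW) ----------------------------------------------------

def pad2d(x: Tensor, ph: int, pw: int) -> Tensor:
    if ph == 0 and pw == 0:
        return x
    a = x
    padded = np.pad(a.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def backward(g):
        a._accum(g[:, :, ph : g.shape[2] - ph, pw : g.shape[3] - pw])

    return Tensor._result(padded, (a,), backward)


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, dh: int, dw: int):
    """Sliding windows of a padded NCHW array -> (N,C,Ho,Wo,kh,kw) view."""
    keh, kew = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (keh, kew), axis=(2, 3))
    return win[:, :, ::sh, ::sw, ::dh, ::dw]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution, NCHW input, OIHW kernel."""
    xp = pad2d(x, padding, padding)
    kh, kw = w.shape[2], w.shape[3]
    sh = sw = stride
    dh = dw = dilation
    win = _windows(xp.data, kh, kw, sh, sw, dh, dw)
    out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (xp, w) if b is None else (xp, w, b)

    def backward(g):
        w._accum(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        Ho, Wo = g.shape[2], g.shape[3]
        gxp = np.zeros_like(xp.data)
        for i in range(kh):
            for j in range(kw):
                patch = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                gxp[
                    :,
                    :,
                    i * dh : i * dh + sh * Ho : sh,
                    j * dw : j * dw + sw * Wo : sw,
                ] += patch
        xp._accum(gxp)

    return Tensor._result(out_data, parents, backward)


def depthwise_conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0
) -> Tensor:
    """Depthwise 2-D convolution; kernel shape (C, kh, kw)."""
    xp = pad2d(x, padding, padding)
    kh, kw = w.shape[1], w.shape[2]
    sh = sw = stride
    win = _windows(xp.data, kh, kw, sh, sw, 1, 1)
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (xp, w) if b is None else (xp, w, b)

    def backward(g):
        w._accum(np.einsum("nchwij,nchw->cij", win, g, optimize=True))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        Ho, Wo = g.shape[2], g.shape[3]
        gxp = np.zeros_like(xp.data)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += (
                    g * w.data[None, :, i, j, None, None]
                )
        xp._accum(gxp)

    return Tensor._result(out_data, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling; H and W must divide by k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size ({h},{w}) not divisible by pool size {k}")
    return (
        x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
    )


def _bilinear_coeffs(src: int, dst: int):
    """Half-pixel-aligned source indices and weights for 1-D bilinear resize."""
    pos = (np.arange(dst) + 0.5) * (src / dst) - 0.5
    pos = np.clip(pos, 0.0, src - 1.0)  # replicate edges beyond the grid
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    hi = np.minimum(lo + 1, src - 1)
    return lo, hi, frac


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of an NCHW tensor (half-pixel centers)."""
    n, c, h, w = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    r0, r1, fr = _bilinear_coeffs(h, oh)
    c0, c1, fc = _bilinear_coeffs(w, ow)
    wr0, wr1 = (1 - fr)[:, None], fr[:, None]
    wc0, wc1 = (1 - fc)[None, :], fc[None, :]
    a = x
    d = a.data
    out_data = (
        d[:, :, r0[:, None], c0[None, :]] * (wr0 * wc0)
        + d[:, :, r0[:, None], c1[None, :]] * (wr0 * wc1)
        + d[:, :, r1[:, None], c0[None, :]] * (wr1 * wc0)
        + d[:, :, r1[:, None], c1[None, :]] * (wr1 * wc1)
    )

    def backward(g):
        buf = np.zeros_like(d)
        np.add.at(buf, (slice(None), slice(None), r0[:, None], c0[None, :]), g * (wr0 * wc0))
        np.add.at(buf, (slice(None), slice(None), r0[:, None], c1[None, :]), g * (wr0 * wc1))
        np.add.at(buf, (slice(None), slice(None), r1[:, None], c0[None, :]), g * (wr1 * wc0))
        np.add.at(buf, (slice(None), slice(None), r1[:, None], c1[None, :]), g * (wr1 * wc1))
        a._accum(buf)

    return Tensor._result(out_data, (a,), backward)
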