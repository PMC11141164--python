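"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations a convolutional
encoder-decoder with self-attention needs: broadcasting arithmetic,
(batched) matmul, 2-D convolution/pooling, bilinear upsampling, softmax
family, and reductions.  Tensors record their parents and a backward
closure; ``Tensor.backward`` runs a topological sweep and accumulates
gradients into leaves that have ``requires_grad`` set.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf, expit

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "f":
            self.data = self.data.astype(np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return Tensor._make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)))

    return Tensor._make(a.data * b.data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        return ((a, _unbroadcast(g / b.data, a.data.shape)),
                (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)))

    return Tensor._make(a.data / b.data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)

    def backward(g):
        return ((a, g * p * np.power(a.data, p - 1)),)

    return Tensor._make(np.power(a.data, p), (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        return ((a, g * out_data),)

    return Tensor._make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        return ((a, g / a.data),)

    return Tensor._make(np.log(a.data), (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        return ((a, g * 0.5 / out_data),)

    return Tensor._make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        return ((a, g * mask),)

    return Tensor._make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = expit(a.data)

    def backward(g):
        return ((a, g * out_data * (1.0 - out_data)),)

    return Tensor._make(out_data, (a,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _wrap(a)
    cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        return ((a, g * (cdf + a.data * pdf)),)

    return Tensor._make(a.data * cdf, (a,), backward)


# -- reductions and shaping -------------------------------------------

def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)

    def backward(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g2, a.data.shape).copy()),)

    return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def backward(g):
        return ((a, g.reshape(old)),)

    return Tensor._make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return ((a, g.transpose(inv)),)

    return Tensor._make(a.data.transpose(axes), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            outs.append((t, g[tuple(idx)]))
        return tuple(outs)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        # collapse broadcast batch dimensions
        ga = _unbroadcast(ga, a.data.shape)
        gb = _unbroadcast(gb, b.data.shape)
        return ((a, ga), (b, gb))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((a, out_data * (g - dot)),)

    return Tensor._make(out_data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        sm = np.exp(out_data)
        return ((a, g - sm * g.sum(axis=axis, keepdims=True)),)

    return Tensor._make(out_data, (a,), backward)


# -- spatial operations (NCHW) ----------------------------------------

def _window_view(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Return view (N, C, OH, OW, KH, KW) of sliding windows."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW input with OIHW weights."""
    x, weight = _wrap(x), _wrap(weight)
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh, kw = weight.data.shape[2:]
    cols = _window_view(xp, kh, kw, stride, stride)  # N,C,OH,OW,KH,KW
    out_data = np.einsum("nchwij,ocij->nohw", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        grads = []
        if x.requires_grad:
            gx_pad = np.zeros_like(xp)
            oh, ow = g.shape[2], g.shape[3]
            for i in range(kh):
                for j in range(kw):
                    # contribution of kernel tap (i, j) to input positions
                    patch = np.einsum("nohw,oc->nchw", g, weight.data[:, :, i, j], optimize=True)
                    gx_pad[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += patch
            if padding:
                gx = gx_pad[:, :, padding:gx_pad.shape[2] - padding, padding:gx_pad.shape[3] - padding]
            else:
                gx = gx_pad
            grads.append((x, gx))
        else:
            grads.append((x, None))
        gw = np.einsum("nchwij,nohw->ocij", cols, g, optimize=True)
        grads.append((weight, gw))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out_data, parents, backward)


def max_pool2d(x, kernel: int = 2, stride: Optional[int] = None, padding: int = 0) -> Tensor:
    x = _wrap(x)
    stride = stride or kernel
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    cols = _window_view(xp, kernel, kernel, stride, stride)
    n, c, oh, ow = cols.shape[:4]
    flat = cols.reshape(n, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gx_pad = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        ni, ci, ohi, owi = np.indices((n, c, oh, ow))
        rows = ohi * stride + ki
        colsx = owi * stride + kj
        np.add.at(gx_pad, (ni, ci, rows, colsx), g)
        if padding:
            gx = gx_pad[:, :, padding:gx_pad.shape[2] - padding, padding:gx_pad.shape[3] - padding]
        else:
            gx = gx_pad
        return ((x, gx),)

    return Tensor._make(out_data, (x,), backward)


_upsample_cache: dict[tuple, np.ndarray] = {}


def _upsample_matrix(n_in: int, scale: int, dtype) -> np.ndarray:
    """Dense (scale*n_in, n_in) bilinear interpolation matrix, align_corners=False."""
    key = (n_in, scale, np.dtype(dtype).str)
    if key not in _upsample_cache:
        n_out = n_in * scale
        m = np.zeros((n_out, n_in), dtype=dtype)
        for i in range(n_out):
            src = (i + 0.5) / scale - 0.5
            lo = int(np.floor(src))
            frac = src - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            m[i, lo_c] += 1.0 - frac
            m[i, hi_c] += frac
        _upsample_cache[key] = m
    return _upsample_cache[key]


def upsample_bilinear2x(x) -> Tensor:
    """Bilinear 2x spatial upsampling (align_corners=False), NCHW."""
    x = _wrap(x)
    h, w = x.data.shape[2], x.data.shape[3]
    mh = _upsample_matrix(h, 2, x.data.dtype)
    mw = _upsample_matrix(w, 2, x.data.dtype)
    out_data = np.einsum("ij,ncjk,lk->ncil", mh, x.data, mw, optimize=True)

    def backward(g):
        return ((x, np.einsum("ij,ncil,lk->ncjk", mh, g, mw, optimize=True)),)

    return Tensor._make(out_data, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return _wrap(x)
    x = _wrap(x)
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return mul(x, Tensor(mask))
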