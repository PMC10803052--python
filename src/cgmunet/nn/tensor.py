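"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result propagates gradients to
every tensor created with ``requires_grad=True``.  The primitive set is the
minimum needed for a convolutional/MLP segmentation network: broadcasted
arithmetic, 2-D matmul, shape ops, reductions, the usual activations, a 3x3
"same" convolution, 2x2 max pooling and x2 bilinear upsampling.

Gradient formulas are exercised against central finite differences in the test
suite; keep any new primitive covered there.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "conv3x3", "maxpool2x2",
           "upsample_bilinear2"]

_grad_enabled = True


class no_grad:
    """Context manager that disables graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = g.astype(parent.data.dtype, copy=False)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(
            np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._make(self.data + o.data, (self, o), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        o = self._coerce(other)
        return Tensor._make(self.data - o.data, (self, o), lambda g: (
            _unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)))

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._make(self.data * o.data, (self, o), lambda g: (
            _unbroadcast(g * o.data, self.shape), _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._make(self.data / o.data, (self, o), lambda g: (
            _unbroadcast(g / o.data, self.shape),
            _unbroadcast(-g * self.data / (o.data * o.data), o.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** p
        return Tensor._make(out, (self,), lambda g: (
            g * p * self.data ** (p - 1),))

    def matmul(self, other: "Tensor") -> "Tensor":
        o = self._coerce(other)
        if self.ndim != 2 or o.ndim != 2:
            raise ValueError("matmul expects 2-D operands; reshape first")
        return Tensor._make(self.data @ o.data, (self, o), lambda g: (
            g @ o.data.T, self.data.T @ g))

    __matmul__ = matmul

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(orig),))

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx) -> "Tensor":
        def back(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)
        return Tensor._make(self.data[idx], (self,), back)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- activations / elementwise ------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def gelu(self) -> "Tensor":
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out = x * cdf

        def back(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            return (g * (cdf + x * pdf),)

        return Tensor._make(out, (self,), back)

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        return Tensor._make(r, (self,), lambda g: (g * 0.5 / r,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * mask,))


class Parameter(Tensor):
    """A tensor registered as a learnable weight of a module."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), back)


# -- spatial primitives (NHWC layout) ---------------------------------

def _corr3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' cross-correlation of NHWC ``x`` with a (3,3,Cin,Cout) kernel."""
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, 9 * c)
    out = cols @ w.reshape(9 * c, -1)
    return out.reshape(n, h, wd, w.shape[-1])


def conv3x3(x: Tensor, w: Tensor) -> Tensor:
    """3x3 convolution, stride 1, zero padding 1, no bias.

    ``x``: (N, H, W, Cin); ``w``: (3, 3, Cin, Cout).
    """
    out = _corr3x3(x.data, w.data)

    def back(g):
        n, h, wd, cin = x.shape
        # grad wrt input: full correlation with the flipped, transposed kernel
        w_flip = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
        gx = _corr3x3(g, w_flip)
        # grad wrt weights: cols^T @ g
        xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, 9 * cin)
        gw = (cols.T @ g.reshape(n * h * wd, -1)).reshape(w.shape)
        return gx, gw

    return Tensor._make(out, (x, w), back)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on an NHWC tensor (H, W even)."""
    n, h, w, c = x.shape
    v = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    v = v.reshape(n, h // 2, w // 2, c, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def back(g):
        gv = np.zeros((n, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return (gx.reshape(n, h, w, c),)

    return Tensor._make(out, (x,), back)


_interp_cache: dict[int, np.ndarray] = {}


def _interp_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear x2 interpolation matrix (half-pixel centres, clamped)."""
    m = _interp_cache.get(n)
    if m is None:
        m = np.zeros((2 * n, n))
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            f = math.floor(src)
            t = src - f
            m[i, min(max(f, 0), n - 1)] += 1.0 - t
            m[i, min(max(f + 1, 0), n - 1)] += t
        _interp_cache[n] = m
    return m


def upsample_bilinear2(x: Tensor) -> Tensor:
    """x2 bilinear upsampling of an NHWC tensor (constant maps are preserved)."""
    n, h, w, c = x.shape
    ah = _interp_matrix(h).astype(x.dtype)
    aw = _interp_matrix(w).astype(x.dtype)
    out = np.einsum("ih,nhwc->niwc", ah, x.data, optimize=True)
    out = np.einsum("jw,niwc->nijc", aw, out, optimize=True)

    def back(g):
        gx = np.einsum("jw,nijc->niwc", aw, g, optimize=True)
        gx = np.einsum("ih,niwc->nhwc", ah, gx, optimize=True)
        return (gx,)

    return Tensor._make(out, (x,), back)
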