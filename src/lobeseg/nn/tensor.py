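"""A compact reverse-mode autodiff engine over numpy arrays.

Only the operations needed by an encoder/decoder segmentation network and
its scalar training objectives are implemented: broadcasting elementwise
arithmetic, ``log``/``exp``/scalar powers, clipping, reductions, ReLU and
sigmoid activations, same-padded odd-kernel 2-D convolution, 2x2 max
pooling and stride-2 zero-insertion upsampling (which composed with a 3x3
convolution realises a stride-2 "deconvolution").

Gradients accumulate into ``Tensor.grad`` on a call to ``backward()`` of a
scalar result; the graph is traversed once in reverse topological order.
All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "relu",
    "sigmoid",
    "zero_upsample2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        # scalar exponent only; gradient floors the base to avoid the
        # infinite derivative of x**a (a < 1) at exactly x == 0
        a = float(exponent)
        out = _node(self.data**a, (self,))

        def bwd(g):
            if self.requires_grad:
                base = np.maximum(self.data, 1e-12)
                self._accumulate(g * a * base ** (a - 1.0))

        out._backward = bwd
        return out

    # -- elementwise functions --------------------------------------------
    def log(self):
        out = _node(np.log(self.data), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None):
        out = _node(self.data.sum(axis=axis, keepdims=False), (self,))

        def bwd(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accumulate(
                        np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
                    )

        out._backward = bwd
        return out

    def mean(self):
        return self.sum() / float(self.data.size)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


# -- activations -----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0.0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic: exponentiate only non-positive arguments
    d = x.data
    e = np.exp(-np.abs(d))
    s = np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = _node(s, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


# -- structured ops --------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation).

    ``x``: (N, C, H, W); ``w``: (F, C, k, k) with odd k; ``b``: (F,).
    """
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError("conv2d supports odd kernels only")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    y = np.tensordot(cols, w.data, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,F
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bwd(g):
        if w.requires_grad:
            w._accumulate(np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3])))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            wr = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,F,k,k
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
            gcols = sliding_window_view(gp, (k, k), axis=(2, 3))
            dx = np.tensordot(gcols, wr, axes=([1, 4, 5], [1, 2, 3]))
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = _node(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], (x,))

    def bwd(g):
        if x.requires_grad:
            dv = np.zeros_like(v)
            np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
            dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(np.ascontiguousarray(dx).reshape(n, c, h, w))

    out._backward = bwd
    return out


def zero_upsample2(x: Tensor) -> Tensor:
    """Insert zeros to double both spatial dimensions (stride-2 upsampling).

    Followed by a 3x3 ``conv2d`` this is a stride-2 transposed convolution.
    """
    n, c, h, w = x.data.shape
    y = np.zeros((n, c, 2 * h, 2 * w), dtype=x.data.dtype)
    y[:, :, ::2, ::2] = x.data
    out = _node(y, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, :, ::2, ::2])

    out._backward = bwd
    return out
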