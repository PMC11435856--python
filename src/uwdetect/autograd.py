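"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the detector needs: broadcasted
elementwise arithmetic, the activations used by the blocks (SiLU, sigmoid,
ReLU, softmax), reductions, matmul, im2col-based 2-D convolution with
stride/dilation/groups, max/average pooling, nearest upsampling and the
indexing primitives required by the training losses.

Tensors are float32 by default.  Gradients are accumulated into ``.grad``
by :meth:`Tensor.backward` over a dynamically recorded tape.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "cat", "stack"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference / assignment)."""

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
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    e = np.exp(v[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------- arithmetic ops
    def __add__(self, other):
        o = _as_tensor(other)
        out = self._make(self.data + o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        o = _as_tensor(other)
        out = self._make(self.data * o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        out = self._make(self.data / o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    # --------------------------------------------------------- elementwise
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)
        out._backward = bw
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = self._make(r, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(r, 1e-12))
        out._backward = bw
        return out

    def atan(self):
        out = self._make(np.arctan(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data ** 2))
        out._backward = bw
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = self._make(s, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def silu(self):
        s = _sigmoid(self.data)
        out = self._make(self.data * s, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))
        out._backward = bw
        return out

    def relu(self):
        m = self.data > 0
        out = self._make(self.data * m, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * m)
        out._backward = bw
        return out

    def clip(self, lo, hi):
        m = (self.data > lo) & (self.data < hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * m)
        out._backward = bw
        return out

    def maximum(self, other):
        o = _as_tensor(other)
        m = self.data >= o.data
        out = self._make(np.maximum(self.data, o.data), (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (~m), o.data.shape))
        out._backward = bw
        return out

    def minimum(self, other):
        o = _as_tensor(other)
        m = self.data <= o.data
        out = self._make(np.minimum(self.data, o.data), (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (~m), o.data.shape))
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,), None)

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
        out._backward = bw
        return out

    # ---------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------- shape / index
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    def matmul(self, other):
        o = _as_tensor(other)
        out = self._make(self.data @ o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.data.shape))
        out._backward = bw
        return out

    __matmul__ = matmul


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even inside no_grad


def cat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out
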