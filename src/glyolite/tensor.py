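"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autograd engine sufficient for convolutional detection
networks: 2-D convolution (strided, padded, grouped), max-pooling, nearest
upsampling, batch-norm statistics, the usual pointwise nonlinearities, and
shape surgery (slicing, concatenation, reshape).  Everything is float32.

Gradients are accumulated into ``Tensor.grad`` (a plain ndarray) by
``Tensor.backward()`` via a topological sort of the recorded graph.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "concat", "stack_k"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / target building)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free the tape as we go; grads of non-leaf nodes are scratch
                t._backward = None
                t._prev = ()

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def bw(g):
            self._accum(-g)

        out._backward = bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = bw if out.requires_grad else None
        return out

    # ------------------------------------------------------------- pointwise
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            self._accum(g * y)

        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def bw(g):
            self._accum(g / self.data)

        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            self._accum(g * 0.5 / y)

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(y, (self,), None)

        def bw(g):
            self._accum(g * y * (1.0 - y))

        out._backward = bw if out.requires_grad else None
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(self.data * s, (self,), None)

        def bw(g):
            self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        out._backward = bw if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)

        def bw(g):
            self._accum(g * mask)

        out._backward = bw if out.requires_grad else None
        return out

    def arctan(self):
        out = Tensor._make(np.arctan(self.data), (self,), None)

        def bw(g):
            self._accum(g / (1.0 + self.data**2))

        out._backward = bw if out.requires_grad else None
        return out

    def clip(self, lo, hi):
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)

        def bw(g):
            self._accum(g * mask)

        out._backward = bw if out.requires_grad else None
        return out

    def maximum(self, other):
        other = self._lift(other)
        out = Tensor._make(np.maximum(self.data, other.data), (self, other), None)
        chose_self = self.data >= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * chose_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~chose_self, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def minimum(self, other):
        other = self._lift(other)
        out = Tensor._make(np.minimum(self.data, other.data), (self, other), None)
        chose_self = self.data <= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * chose_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~chose_self, other.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        out._backward = bw if out.requires_grad else None
        return out

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def bw(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw if out.requires_grad else None
        return out

    def pad2d(self, ph: int, pw: int, value: float = 0.0):
        """Constant-pad the trailing two (spatial) axes by ``ph`` / ``pw``."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        out = Tensor._make(
            np.pad(self.data, pads, constant_values=value), (self,), None
        )

        def bw(g):
            sl = [slice(None)] * (self.data.ndim - 2) + [
                slice(ph, g.shape[-2] - ph),
                slice(pw, g.shape[-1] - pw),
            ]
            self._accum(g[tuple(sl)])

        out._backward = bw if out.requires_grad else None
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw if out.requires_grad else None
    return out


def stack_k(tensors, axis: int) -> Tensor:
    """Stack along a new axis (used for neighbourhood unfolding)."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw if out.requires_grad else None
    return out
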