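"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation whose
inputs require gradients, a backward closure producing the vector-Jacobian
product for each parent.  ``Tensor.backward`` walks the recorded graph in
reverse topological order and accumulates gradients into ``.grad``.

The op set is deliberately small: elementwise arithmetic with numpy
broadcasting, matmul (batched, with broadcast), reductions, shape ops and the
nonlinearities the network needs.  Structured ops (convolution, FFT filtering,
the selective scan) live in sibling modules and register themselves through
:func:`make_op`.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _special

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference / profiling)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- basic introspection -------------------------------------------------
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

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
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
        self.grad = np.asarray(grad) if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return make_op(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return make_op(
            self.data - other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return make_op(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return make_op(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return make_op(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data ** exponent
        return make_op(
            out, (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out = a @ b

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return make_op(out, (self, other), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return make_op(out, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            full = out if keepdims else np.expand_dims(out, axis)
            mask = (self.data == full)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (mask * g2,)

        return make_op(out, (self,), bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        return make_op(out, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = self.data.transpose(axes)
        return make_op(out, (self,), lambda g: (g.transpose(inv),))

    def flip(self, axis: int):
        out = np.flip(self.data, axis=axis)
        return make_op(out, (self,), lambda g: (np.flip(g, axis=axis),))

    def broadcast_to(self, shape):
        out = np.broadcast_to(self.data, shape)
        return make_op(out, (self,), lambda g: (_unbroadcast(g, self.shape),))

    def __getitem__(self, idx):
        out = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return make_op(out, (self,), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return make_op(out, (self,), lambda g: (g * out,))

    def log(self):
        return make_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return make_op(out, (self,), lambda g: (g * 0.5 / out,))

    def abs(self):
        return make_op(np.abs(self.data), (self,),
                       lambda g: (g * np.sign(self.data),))

    def relu(self):
        out = np.maximum(self.data, 0)
        return make_op(out, (self,), lambda g: (g * (self.data > 0),))

    def sigmoid(self):
        out = _special.expit(self.data)
        return make_op(out, (self,), lambda g: (g * out * (1 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return make_op(out, (self,), lambda g: (g * (1 - out ** 2),))

    def erf(self):
        out = _special.erf(self.data)
        c = 2.0 / np.sqrt(np.pi)
        return make_op(out, (self,),
                       lambda g: (g * c * np.exp(-self.data ** 2),))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(data: np.ndarray, parents: Sequence[Tensor],
            backward: Callable[[np.ndarray], tuple]) -> Tensor:
    """Create the output tensor of an op, recording the graph if needed."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return make_op(out, tensors, bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return make_op(out, tensors, bwd)
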