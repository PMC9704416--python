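"""Reverse-mode autodiff core: the Tensor class and its primitive ops.

Graphs are built eagerly; ``Tensor.backward()`` runs a topological sweep.
Gradients accumulate into ``.grad`` (a plain ndarray).  Broadcasting is
supported on the pointwise ops; the convolution/warping primitives live in
:mod:`ischemap.nn.functional` and register themselves through ``Tensor._op``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_grad_enabled = True
_default_dtype = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are cast to (float32 default; float64 for
    high-precision work such as numerical gradient checking)."""
    global _default_dtype
    _default_dtype = np.dtype(dtype)


def get_default_dtype():
    return _default_dtype


@contextlib.contextmanager
def default_dtype(dtype):
    prev = _default_dtype
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


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


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_default_dtype)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Iterable["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(parents)
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- pointwise arithmetic ---------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._op(-a.data, (a,),
                          lambda g: a._accumulate(-g) if a.requires_grad else None)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._op(a.data / b.data, (a, b), bw)

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._op(a.data ** p, (a,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape
        return Tensor._op(a.data.reshape(*shape), (a,),
                          lambda g: a._accumulate(g.reshape(old)))

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._op(np.transpose(a.data, axes), (a,),
                          lambda g: a._accumulate(np.transpose(g, inv)))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

        return Tensor._op(a.data[idx], (a,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g2, a.data.shape).copy())

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))
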