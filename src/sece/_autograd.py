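"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small tape-based engine providing exactly the
operations the autoencoder and graph-attention modules need: broadcasting
arithmetic, matrix products, the activations (ReLU/ELU/sigmoid/exp), the
special functions appearing in negative-binomial likelihoods (lgamma,
log1p, logaddexp) and a masked softmax. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via topological traversal.

All arrays are kept in the dtype they were created with; float64 is used
throughout the package except where a module opts into float32 for speed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special as _sp


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    grad = np.asarray(grad)
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: Sequence[Tensor] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg.copy()

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(a.data + b.data, (a, b), lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(a.data * b.data, (a, b),
                            lambda g: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._node(a.data / b.data, (a, b),
                            lambda g: (g / b.data, -g * a.data / b.data ** 2))

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out = a.data @ b.data

        def backward(g):
            if a.data.ndim == 2 and b.data.ndim == 2:
                return g @ b.data.T, a.data.T @ g
            if a.data.ndim == 2 and b.data.ndim == 1:
                return np.outer(g, b.data), a.data.T @ g
            if a.data.ndim == 1 and b.data.ndim == 2:
                return g @ b.data.T, np.outer(a.data, g)
            # 1-D dot
            return g * b.data, g * a.data

        return Tensor._node(out, (a, b), backward)

    @property
    def T(self):
        return Tensor._node(self.data.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._node(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.data)


# -- elementwise functions (work on Tensor; numpy passes through) -------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._node(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def elu(x: Tensor) -> Tensor:
    out = np.where(x.data > 0, x.data, np.expm1(np.minimum(x.data, 0.0)))
    return Tensor._node(out, (x,),
                        lambda g: (g * np.where(x.data > 0, 1.0, out + 1.0),))


def sigmoid(x: Tensor) -> Tensor:
    out = _sp.expit(x.data)
    return Tensor._node(out, (x,), lambda g: (g * out * (1.0 - out),))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor._node(out, (x,), lambda g: (g * out,))


def log(x: Tensor) -> Tensor:
    return Tensor._node(np.log(x.data), (x,), lambda g: (g / x.data,))


def log1p(x: Tensor) -> Tensor:
    return Tensor._node(np.log1p(x.data), (x,), lambda g: (g / (1.0 + x.data),))


def lgamma(x: Tensor) -> Tensor:
    return Tensor._node(_sp.gammaln(x.data), (x,),
                        lambda g: (g * _sp.digamma(x.data),))


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = np.logaddexp(a.data, b.data)

    def backward(g):
        wa = _sp.expit(a.data - b.data)   # exp(a) / (exp(a)+exp(b))
        return g * wa, g * (1.0 - wa)

    return Tensor._node(out, (a, b), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip with pass-through gradient inside the interval."""
    mask = (x.data > lo) & (x.data < hi)
    return Tensor._node(np.clip(x.data, lo, hi), (x,), lambda g: (g * mask,))


def where(cond: np.ndarray, a, b) -> Tensor:
    """Select elementwise; ``cond`` is a constant boolean array."""
    cond = np.asarray(cond, dtype=bool)
    a, b = Tensor._lift(a), Tensor._lift(b)
    return Tensor._node(np.where(cond, a.data, b.data), (a, b),
                        lambda g: (g * cond, g * ~cond))


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax along ``axis``; tolerates -inf entries."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - inner),)

    return Tensor._node(s, (x,), backward)


def square(x: Tensor) -> Tensor:
    return Tensor._node(x.data ** 2, (x,), lambda g: (g * 2.0 * x.data,))
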