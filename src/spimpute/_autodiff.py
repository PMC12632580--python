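"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the variational model needs: broadcasting
arithmetic, 2-D matmul, the usual element-wise nonlinearities, ``gammaln``
(for negative-binomial likelihoods), reductions, fancy-index gather (for
graph neighborhoods) and a gradient-reversal op (for the adversarial
modality classifier).  Everything is float64; tapes are built eagerly and
freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["Var", "var", "constant"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Var:
    """A node in the computation graph: a value plus a local backward rule."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    # make numpy defer `ndarray <op> Var` to our reflected operators
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo: list[Var] = []
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None:
                    continue
                g = _unbroadcast(np.asarray(g), parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> "Var":
        return Var(self.value)

    def __repr__(self):
        return f"Var(shape={self.value.shape})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)


def var(value) -> Var:
    return Var(value)


def constant(value) -> Var:
    return Var(value)


def _wrap(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    return Var(a.value + b.value, (a, b), lambda g: (g, g))


def neg(a) -> Var:
    a = _wrap(a)
    return Var(-a.value, (a,), lambda g: (-g,))


def mul(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    return Var(a.value * b.value, (a, b), lambda g: (g * b.value, g * a.value))


def div(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    out = a.value / b.value
    return Var(out, (a, b), lambda g: (g / b.value, -g * out / b.value))


def matmul(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Var(
        a.value @ b.value,
        (a, b),
        lambda g: (g @ b.value.T, a.value.T @ g),
    )


def power(a, p: float) -> Var:
    a = _wrap(a)
    return Var(a.value ** p, (a,), lambda g: (g * p * a.value ** (p - 1),))


def exp(a) -> Var:
    a = _wrap(a)
    out = np.exp(a.value)
    return Var(out, (a,), lambda g: (g * out,))


def log(a) -> Var:
    a = _wrap(a)
    return Var(np.log(a.value), (a,), lambda g: (g / a.value,))


def log1p(a) -> Var:
    a = _wrap(a)
    return Var(np.log1p(a.value), (a,), lambda g: (g / (1.0 + a.value),))


def sqrt(a) -> Var:
    a = _wrap(a)
    out = np.sqrt(a.value)
    return Var(out, (a,), lambda g: (g * 0.5 / out,))


def square(a) -> Var:
    a = _wrap(a)
    return Var(a.value ** 2, (a,), lambda g: (g * 2.0 * a.value,))


def sigmoid(a) -> Var:
    a = _wrap(a)
    out = special.expit(a.value)
    return Var(out, (a,), lambda g: (g * out * (1.0 - out),))


def softplus(a) -> Var:
    """log(1 + exp(x)), computed stably."""
    a = _wrap(a)
    out = np.logaddexp(0.0, a.value)
    return Var(out, (a,), lambda g: (g * special.expit(a.value),))


def tanh(a) -> Var:
    a = _wrap(a)
    out = np.tanh(a.value)
    return Var(out, (a,), lambda g: (g * (1.0 - out ** 2),))


def relu(a) -> Var:
    a = _wrap(a)
    mask = a.value > 0
    return Var(a.value * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a, slope: float = 0.2) -> Var:
    a = _wrap(a)
    mask = np.where(a.value > 0, 1.0, slope)
    return Var(a.value * mask, (a,), lambda g: (g * mask,))


def gammaln(a) -> Var:
    a = _wrap(a)
    return Var(special.gammaln(a.value), (a,), lambda g: (g * special.digamma(a.value),))


def absolute(a) -> Var:
    a = _wrap(a)
    sign = np.sign(a.value)
    return Var(np.abs(a.value), (a,), lambda g: (g * sign,))


def maximum(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    mask = a.value >= b.value
    return Var(
        np.maximum(a.value, b.value),
        (a, b),
        lambda g: (g * mask, g * ~mask),
    )


def where(mask, a, b) -> Var:
    """Select by a *constant* boolean mask; gradient flows through each branch."""
    mask = np.asarray(mask, dtype=bool)
    a, b = _wrap(a), _wrap(b)
    return Var(
        np.where(mask, a.value, b.value),
        (a, b),
        lambda g: (g * mask, g * ~mask),
    )


def vsum(a, axis=None, keepdims=False) -> Var:
    a = _wrap(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.value.shape),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        return (np.broadcast_to(gg, a.value.shape),)

    return Var(out, (a,), backward)


def vmean(a, axis=None, keepdims=False) -> Var:
    a = _wrap(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return vsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(parts, axis=0) -> Var:
    parts = [_wrap(p) for p in parts]
    sizes = [p.value.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]
    return Var(
        np.concatenate([p.value for p in parts], axis=axis),
        tuple(parts),
        lambda g: tuple(np.split(g, splits, axis=axis)),
    )


def reshape(a, shape) -> Var:
    a = _wrap(a)
    return Var(a.value.reshape(shape), (a,), lambda g: (g.reshape(a.value.shape),))


def take(a, idx) -> Var:
    """Gather with a constant index (int array or basic slice)."""
    a = _wrap(a)

    def backward(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return (out,)

    return Var(a.value[idx], (a,), backward)


def logsumexp(a, axis=-1, keepdims=False) -> Var:
    a = _wrap(a)
    m = a.value.max(axis=axis, keepdims=True)
    shifted = exp(a - m)
    out = log(vsum(shifted, axis=axis, keepdims=True)) + m
    if not keepdims:
        out = reshape(out, np.squeeze(out.value, axis=axis).shape)
    return out


def softmax(a, axis=-1) -> Var:
    a = _wrap(a)
    m = a.value.max(axis=axis, keepdims=True)
    e = exp(a - m)
    return e / vsum(e, axis=axis, keepdims=True)


def logaddexp(a, b) -> Var:
    a, b = _wrap(a), _wrap(b)
    return maximum(a, b) + softplus(neg(absolute(a - b)))


def grad_reverse(a, scale: float = 1.0) -> Var:
    """Identity in the forward pass; multiplies the gradient by ``-scale``."""
    a = _wrap(a)
    return Var(a.value, (a,), lambda g: (-scale * g,))
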