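"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package (hypergraph convolution, learnable time encoding,
masked multi-head attention, sigmoid-gated scorer, margin-based contrastive
loss) is small and CPU-bound, so a compact tape-based engine is all that is
needed.  ``Tensor`` wraps an ``ndarray``; arithmetic builds a computation
graph and ``backward`` runs the reverse sweep over a topological order.

Only the primitives the model actually uses are implemented: broadcasting
add/sub/mul/div, matmul, power, reductions, gather of rows, concatenation,
elementwise tanh/relu/cos/exp/log/sqrt/sigmoid/clip, and composites
(softmax, layer_norm) expressed in those primitives.  Gradients through
broadcasting are reduced back to the parent shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "tanh",
    "cos",
    "exp",
    "log",
    "sqrt",
    "sigmoid",
    "clip",
    "take_rows",
    "softmax",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep seeding ``d self / d self`` with ``grad`` (default 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data + b.data, _parents=(a, b))

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.data, _parents=(a,))
        out._backward = (lambda g: a._accum(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data * b.data, _parents=(a, b))

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data / b.data, _parents=(a, b))

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        out = Tensor(a.data ** exponent, _parents=(a,))
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * exponent * a.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out = Tensor(a.data @ b.data, _parents=(a, b))

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data))
            if b.requires_grad:
                b._accum(a.data.T @ g)

        out._backward = bwd if out.requires_grad else None
        return out

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        a = self
        out = Tensor(a.data.reshape(*shape), _parents=(a,))
        if out.requires_grad:
            out._backward = lambda g: a._accum(g.reshape(a.data.shape))
        return out

    @property
    def T(self):
        a = self
        out = Tensor(a.data.T, _parents=(a,))
        if out.requires_grad:
            out._backward = lambda g: a._accum(g.T)
        return out

    def __getitem__(self, key):
        a = self
        out = Tensor(a.data[key], _parents=(a,))

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        out._backward = bwd if out.requires_grad else None
        return out


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), _parents=tuple(ts))

    def bwd(g):
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bwd if out.requires_grad else None
    return out


def _unary(a: Tensor, value: np.ndarray, dloc: np.ndarray) -> Tensor:
    out = Tensor(value, _parents=(a,))
    if out.requires_grad:
        out._backward = lambda g: a._accum(g * dloc)
    return out


def relu(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    return _unary(a, np.maximum(a.data, 0.0), (a.data > 0).astype(np.float64))


def tanh(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    v = np.tanh(a.data)
    return _unary(a, v, 1.0 - v ** 2)


def cos(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    return _unary(a, np.cos(a.data), -np.sin(a.data))


def exp(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    v = np.exp(a.data)
    return _unary(a, v, v)


def log(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    return _unary(a, np.log(a.data), 1.0 / a.data)


def sqrt(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    v = np.sqrt(a.data)
    return _unary(a, v, 0.5 / np.maximum(v, 1e-300))


def sigmoid(a: Tensor) -> Tensor:
    a = Tensor._lift(a)
    v = 1.0 / (1.0 + np.exp(-a.data))
    return _unary(a, v, v * (1.0 - v))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the input is inside the range."""
    a = Tensor._lift(a)
    inside = ((a.data >= lo) & (a.data <= hi)).astype(np.float64)
    return _unary(a, np.clip(a.data, lo, hi), inside)


def take_rows(a: Tensor, idx: Iterable[int]) -> Tensor:
    """Gather rows by index; the backward pass scatter-adds into the table."""
    idx = np.asarray(list(idx), dtype=np.intp)
    return a[idx]


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax primitive (row-max shifted for stability)."""
    a = Tensor._lift(a)
    shifted = a.data - np.max(a.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(a,))

    def bwd(g):
        a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd if out.requires_grad else None
    return out


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis, then scale and shift."""
    a, gamma, beta = Tensor._lift(a), Tensor._lift(gamma), Tensor._lift(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    centered = a.data - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(a, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if a.requires_grad:
            dxhat = g * gamma.data
            term = dxhat - dxhat.mean(axis=-1, keepdims=True) \
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
            a._accum(inv * term)

    out._backward = bwd if out.requires_grad else None
    return out
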