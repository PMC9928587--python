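"""Minimal reverse-mode automatic differentiation on numpy arrays.

Define-by-run: every operation on :class:`Tensor` records its parents and a
vector-Jacobian product closure; :meth:`Tensor.backward` walks the graph in
reverse topological order and accumulates gradients into ``.grad``.

Only the operations needed by the model are provided (dense affine maps,
elementwise transcendentals, softmax, log-gamma, column gather, reductions).
Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, vjps) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._vjps = vjps
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                g = vjp(node.grad)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operators ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data + o.data,
            (self, o),
            (
                lambda g, s=self.data.shape: _unbroadcast(g, s),
                lambda g, s=o.data.shape: _unbroadcast(g, s),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data * o.data,
            (self, o),
            (
                lambda g, b=o.data, s=self.data.shape: _unbroadcast(g * b, s),
                lambda g, a=self.data, s=o.data.shape: _unbroadcast(g * a, s),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data / o.data,
            (self, o),
            (
                lambda g, b=o.data, s=self.data.shape: _unbroadcast(g / b, s),
                lambda g, a=self.data, b=o.data, s=o.data.shape: _unbroadcast(
                    -g * a / (b * b), s
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data @ o.data,
            (self, o),
            (
                lambda g, b=o.data: g @ b.T,
                lambda g, a=self.data: a.T @ g,
            ),
        )

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p,
            (self,),
            (lambda g, a=self.data: g * p * a ** (p - 1),),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor._make(self.data.T, (self,), (lambda g: g.T,))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def vjp(g, shape=self.data.shape):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cols(self, idx) -> "Tensor":
        """Gather columns ``idx`` of a 2-D tensor."""
        idx = np.asarray(idx, dtype=int)

        def vjp(g, shape=self.data.shape):
            out = np.zeros(shape)
            np.add.at(out.T, idx, g.T)
            return out

        return Tensor._make(self.data[:, idx], (self,), (vjp,))


# -- elementwise functions --------------------------------------------------


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return Tensor._make(out_data, (x,), (lambda g, o=out_data: g * o,))


def log(x: Tensor) -> Tensor:
    return Tensor._make(np.log(x.data), (x,), (lambda g, a=x.data: g / a,))


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)
    return Tensor._make(out_data, (x,), (lambda g, o=out_data: g / (2.0 * o),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), (lambda g, m=mask: g * m,))


def softplus(x: Tensor) -> Tensor:
    # stable: log1p(exp(-|x|)) + max(x, 0)
    out_data = np.log1p(np.exp(-np.abs(x.data))) + np.maximum(x.data, 0.0)
    return Tensor._make(out_data, (x,), (lambda g, a=x.data: g * expit(a),))


def lgamma(x: Tensor) -> Tensor:
    return Tensor._make(gammaln(x.data), (x,), (lambda g, a=x.data: g * digamma(a),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def vjp(g, o=out_data):
        return o * (g - (g * o).sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (x,), (vjp,))
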