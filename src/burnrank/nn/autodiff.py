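"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent ranking models need:
elementwise arithmetic with broadcasting, matrix multiplication, the
sigmoid/tanh/relu/softplus nonlinearities, concatenation, and reductions.
Gradients are accumulated by a topological backward sweep; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # Sum leading extra axes.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward = None

    # -- helpers ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def sigmoid(self) -> "Tensor":
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g, a=self, s=out_data):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g, a=self, t=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - t * t))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + e^x), numerically stable for large |x|.
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g, a=self, s=sig):
            if a.requires_grad:
                a._accum(g * s)

        return self._make(out_data, (self,), backward)

    # -- shape ops ----------------------------------------------------------

    @staticmethod
    def concat(tensors: Iterable["Tensor"], axis: int = 1) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g, ts=tensors, offs=offsets, ax=axis):
            for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[ax] = slice(lo, hi)
                    t._accum(g[tuple(idx)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
        if out.requires_grad:
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    def sum(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.broadcast_to(g, a.data.shape))

        return self._make(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g, a=self, size=n):
            if a.requires_grad:
                a._accum(np.broadcast_to(g / size, a.data.shape))

        return self._make(self.data.mean(), (self,), backward)

    # -- backward sweep -----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
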