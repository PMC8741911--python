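"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the training engine behind the forecasting networks: a tape of
:class:`Tensor` nodes, each storing its value, its parents and a closure
that pushes the incoming gradient to those parents.  Only the operations the
network architectures need are implemented; recurrent layers register as
single fused nodes whose backward pass runs truncated-through-time in plain
NumPy (see ``_layers``), which keeps the tape short and the Python overhead
per training step small.

Everything is float64 and single-threaded, so a fixed seed gives
bit-reproducible training.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "elu", "custom_op"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A value in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _sum_to_shape(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def back(g):
                self.accumulate(g)
                other.accumulate(g)
            out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def back(g):
                self.accumulate(g * other.data)
                other.accumulate(g * self.data)
            out._backward = back
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def back(g):
                self.accumulate(g @ np.swapaxes(other.data, -1, -2))
                other.accumulate(np.swapaxes(self.data, -1, -2) @ g)
            out._backward = back
        return out

    __matmul__ = matmul

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def back(g):
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[idx] += g
            out._backward = back
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            def back(g):
                self.accumulate(g.reshape(self.data.shape))
            out._backward = back
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        if out.requires_grad:
            def back(g):
                self.accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = back
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)


def _elementwise(x: Tensor, value: np.ndarray, dlocal: np.ndarray) -> Tensor:
    out = Tensor(value, parents=(x,))
    if out.requires_grad:
        out._backward = lambda g: x.accumulate(g * dlocal)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _elementwise(x, s, s * (1.0 - s))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return _elementwise(x, t, 1.0 - t * t)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    val = np.where(x.data > 0, x.data, neg)
    dlocal = np.where(x.data > 0, 1.0, neg + alpha)
    return _elementwise(x, val, dlocal)


def custom_op(
    value: np.ndarray,
    parents: Sequence[Tensor],
    backward: Callable[[np.ndarray], None],
) -> Tensor:
    """Register a fused operation (e.g. a whole recurrent layer) on the tape."""
    out = Tensor(value, parents=tuple(parents))
    if out.requires_grad:
        out._backward = backward
    return out
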