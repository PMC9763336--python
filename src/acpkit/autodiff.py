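"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based scalar-loss engine: :class:`Tensor` wraps an ndarray, records
the operations that produced it, and :meth:`Tensor.backward` accumulates
gradients by walking the tape in reverse topological order.  Only the
primitives needed by the sequence models in this package are provided
(broadcast arithmetic, matmul, elementwise nonlinearities, reductions,
reshaping, slicing, concatenation) plus softmax/cross-entropy composites
and an Adam optimizer.

Gradient correctness is enforced in the test suite by central
finite-difference checks on every primitive and on the full models.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[], None] | None = None
        self._prev: tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort (graphs can exceed recursion limits)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * data / other.data, other.shape)
                )

        out = self._make(data, (self, other), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul operands must have ndim >= 2")
        data = self.data @ other.data

        def backward():
            if self.requires_grad:
                g = out.grad @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = self.data.swapaxes(-1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape))

        out = self._make(data, (self, other), backward)
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - data * data))

        out = self._make(data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * data * (1.0 - data))

        out = self._make(data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        data = np.maximum(self.data, 0.0)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out = self._make(data, (self,), backward)
        return out

    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * data)

        out = self._make(data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    # -- reductions & shape ops -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out = self._make(data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accum(out.grad.swapaxes(a, b))

        out = self._make(self.data.swapaxes(a, b), (self,), backward)
        return out

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out = self._make(data, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(data, tensors, backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (composite of primitives)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    xs = x - shift
    return xs - xs.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under `logits`."""
    labels = np.asarray(labels, dtype=int)
    ls = log_softmax(logits, axis=-1)
    picked = ls[np.arange(labels.shape[0]), labels]
    return -picked.mean()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
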