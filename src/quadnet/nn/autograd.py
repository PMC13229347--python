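"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (pooled per-protein vectors, hidden
sizes of a few hundred) and trains comfortably on a CPU, so the network
is built on a compact define-by-run tape: every operation creates a
:class:`Tensor` node holding its value and a closure that routes the
upstream gradient to its inputs.  Broadcasting follows numpy semantics;
gradients of broadcast operands are summed back to the operand's shape.

Only the operations the model needs are provided (element-wise
arithmetic, batched matmul, reductions, reshapes, softmax, GELU,
sigmoid, softplus, log/exp, clipping, concatenation).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat"]

_SQRT_2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag})"

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the recorded graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd(g):
            self.accumulate(_unbroadcast(g, self.data.shape))
            other.accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd(g):
            self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bwd(g):
            self.accumulate(_unbroadcast(g / other.data, self.data.shape))
            other.accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = _bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))
        out._backward = lambda g: self.accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self.accumulate(g * b)
                other.accumulate(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self.accumulate(_unbroadcast(ga, a.shape))
            other.accumulate(_unbroadcast(gb, b.shape))

        out._backward = _bwd
        return out

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self.accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self.accumulate(g.transpose(inverse))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), _prev=(self,))
        out._backward = lambda g: self.accumulate(np.swapaxes(g, a, b))
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bwd(g):
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def exp(self) -> "Tensor":
        value = np.exp(self.data)
        out = Tensor(value, _prev=(self,))
        out._backward = lambda g: self.accumulate(g * value)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.accumulate(g / self.data)
        return out

    def sigmoid(self) -> "Tensor":
        value = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(value, _prev=(self,))
        out._backward = lambda g: self.accumulate(g * value * (1.0 - value))
        return out

    def softplus(self) -> "Tensor":
        value = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(value, _prev=(self,))
        out._backward = lambda g: self.accumulate(g * sig)
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT_2))
        out = Tensor(x * cdf, _prev=(self,))

        def _bwd(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            self.accumulate(g * (cdf + x * pdf))

        out._backward = _bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        value = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(value, _prev=(self,))

        def _bwd(g):
            inner = (g * value).sum(axis=axis, keepdims=True)
            self.accumulate(value * (g - inner))

        out._backward = _bwd
        return out

    def clip(self, lo: float | None, hi: float | None) -> "Tensor":
        """Clamp values; gradient passes through the interior only."""
        value = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data)
        if lo is not None:
            inside = inside * (self.data > lo)
        if hi is not None:
            inside = inside * (self.data < hi)
        out = Tensor(value, _prev=(self,))
        out._backward = lambda g: self.accumulate(g * inside)
        return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``, splitting the gradient back."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(start, stop)
            t.accumulate(g[tuple(index)])

    out._backward = _bwd
    return out
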