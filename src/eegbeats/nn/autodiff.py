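"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the package's trainable components: dense and
1-D convolutional stacks, LSTM cells, relative-position attention and
Q-networks.  Tensors wrap float64 arrays; gradients are accumulated by a
topological backward pass.  Broadcasting is supported (gradients are
sum-reduced back to the operand's shape).  ``detach`` implements the
stop-gradient contract used by the segment-recurrent attention memory.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union["Tensor", np.ndarray, float, int]

__all__ = ["Tensor", "concat", "unfold1d", "pad_last", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so it has ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """Return a tensor sharing data but cut out of the graph (stop-gradient)."""
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other: ArrayLike, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._wrap(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(fwd(self.data, other.data), req, (self, other))
        if req:
            def _backward(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))
            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._wrap(other).__sub__(self)

    def __neg__(self):
        return self * -1.0

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return Tensor._wrap(other).__truediv__(self)

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))
        if self.requires_grad:
            def _backward(g):
                self._accum(g * p * self.data ** (p - 1))
            out._backward = _backward
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, req, (self, other))
        if req:
            def _backward(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = _backward
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        if self.requires_grad:
            def _backward(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.data.shape).copy())
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if self.requires_grad:
            def _backward(g):
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)
            out._backward = _backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = _backward
    return out


def pad_last(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad the last axis."""
    pads = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    out = Tensor(np.pad(x.data, pads), x.requires_grad, (x,))
    if x.requires_grad:
        def _backward(g):
            sl = [slice(None)] * g.ndim
            sl[-1] = slice(left, g.shape[-1] - right)
            x._accum(g[tuple(sl)])
        out._backward = _backward
    return out


def unfold1d(x: Tensor, kernel: int, stride: int = 1) -> Tensor:
    """Extract sliding windows from the last axis.

    (..., L) -> (..., kernel, L_out) with L_out = (L - kernel)//stride + 1.
    """
    L = x.shape[-1]
    L_out = (L - kernel) // stride + 1
    if L_out <= 0:
        raise ValueError(f"kernel {kernel} longer than signal {L}")
    idx = (np.arange(L_out)[None, :] * stride) + np.arange(kernel)[:, None]  # (kernel, L_out)
    out = Tensor(x.data[..., idx], x.requires_grad, (x,))
    if x.requires_grad:
        def _backward(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, (..., idx), g)
            x._accum(gx)
        out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
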