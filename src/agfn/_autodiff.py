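"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoders, the graph-attention layers and
the expected-gradients attribution need: broadcasting arithmetic, matmul,
elementwise nonlinearities, reductions, concatenation, indexing and a masked
softmax.  Gradients are accumulated by topological-order backward traversal.
float64 throughout; determinism is inherited from the caller's numpy
generators (the engine itself draws no randomness).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "sigmoid", "relu", "tanh", "exp", "log", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: RNN graphs exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        # ties split the gradient (irrelevant in practice, keeps things finite)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return Tensor._make(
            out_data if keepdims else out_data.squeeze(axis=axis), (self,), bw
        )

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


# -- elementwise nonlinearities ---------------------------------------------

def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def bw(g):
        x._accum(g * out_data)

    return Tensor._make(out_data, (x,), bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), bw)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bw(g):
        x._accum(g * (1.0 - out_data ** 2))

    return Tensor._make(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable logistic

    def bw(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along `axis`; entries where ``mask`` is False get zero weight.

    The max-shift uses detached data, so gradients are exact.
    """
    shift = x.data.max(axis=axis, keepdims=True, initial=-np.inf, where=mask)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    z = exp(x - shift)
    if mask is not None:
        z = z * mask.astype(np.float64)
    return z / z.sum(axis=axis, keepdims=True)
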