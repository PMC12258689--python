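"""Compact reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the graph attention model needs: dense
algebra (matmul, broadcasting arithmetic), pointwise nonlinearities, row
gather, and segment (scatter) sums for message passing and graph pooling.
All arrays are float64. Gradients are accumulated by a topological-order
backward pass; correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_sum", "segment_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        out._backward = backward
        return out

    # -- pointwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: (g * (1.0 - t**2),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -700.0, 700.0))
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- backward pass ----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of `x`: out[i] = x[idx[i]]."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], parents=(x,))

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    out._backward = backward
    return out


def segment_sum(x: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of `x` into `num_segments` buckets: out[s] = sum_{i: seg[i]=s} x[i]."""
    seg = np.asarray(seg, dtype=np.int64)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, seg, x.data)
    out = Tensor(data, parents=(x,))
    out._backward = lambda g: (g[seg] if len(seg) else np.zeros_like(x.data),)
    return out


def segment_softmax(logits: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of column-vector `logits` (E, 1) within each segment.

    The per-segment max shift is treated as a constant (its gradient
    contribution cancels exactly), keeping the op numerically stable.
    """
    seg = np.asarray(seg, dtype=np.int64)
    if len(seg) == 0:
        return logits * 1.0
    m = np.full((num_segments, 1), -np.inf)
    np.maximum.at(m, seg, logits.data)
    m[~np.isfinite(m)] = 0.0  # empty segments, never gathered
    z = (logits - Tensor(m[seg])).exp()
    denom = segment_sum(z, seg, num_segments)
    return z / gather(denom, seg)


class Adam:
    """Adam optimizer with a fixed step size."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
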