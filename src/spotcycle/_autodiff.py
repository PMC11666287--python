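"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the graph-attention autoencoder,
the domain discriminator and the mapping-matrix optimization: broadcasted
arithmetic, matrix products, elementwise nonlinearities, reductions, row
gather/scatter (for edge-list message passing), concatenation and a
gradient-reversal pseudo-op for adversarial training.

All arrays are float64. Graphs are built eagerly; ``Tensor.backward()``
runs a topological sweep accumulating ``.grad`` on leaves that were created
with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather",
    "scatter_sum",
    "grad_reverse",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the dimensions that broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return np.array(self.data, copy=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- op helpers
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---------------------------------------------------------------- algebra
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            def backward(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            def backward(g, a=self):
                a._accumulate(-g)
            out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            def backward(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out._parents:
            def backward(g, a=self):
                a._accumulate(g * p * a.data ** (p - 1))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out._parents:
            def backward(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad or b._parents:
                    b._accumulate(a.data.T @ g)
            out._backward = backward
        return out

    @property
    def T(self):
        out = _node(self.data.T, (self,))
        if out._parents:
            def backward(g, a=self):
                a._accumulate(g.T)
            out._backward = backward
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out._parents:
            def backward(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._backward = backward
        return out

    # ----------------------------------------------------------- nonlinearity
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        if out._parents:
            def backward(g, a=self, v=val):
                a._accumulate(g * v)
            out._backward = backward
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out._parents:
            def backward(g, a=self):
                a._accumulate(g / a.data)
            out._backward = backward
        return out

    def sigmoid(self):
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = _node(val, (self,))
        if out._parents:
            def backward(g, a=self, v=val):
                a._accumulate(g * v * (1.0 - v))
            out._backward = backward
        return out

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        val = np.where(neg, alpha * np.expm1(np.minimum(self.data, 0.0)), self.data)
        out = _node(val, (self,))
        if out._parents:
            def backward(g, a=self, v=val, m=neg):
                a._accumulate(g * np.where(m, v + alpha, 1.0))
            out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data < 0
        out = _node(np.where(mask, slope * self.data, self.data), (self,))
        if out._parents:
            def backward(g, a=self, m=mask):
                a._accumulate(g * np.where(m, slope, 1.0))
            out._backward = backward
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def backward(g, a=self):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = live
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, ts=tensors):
            pieces = np.split(g, splits, axis=axis)
            for t, piece in zip(ts, pieces):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)
        out._backward = backward
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: ``out[e] = t[idx[e]]``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = _node(t.data[idx], (t,))
    if out._parents:
        def backward(g, a=t, i=idx):
            acc = np.zeros_like(a.data)
            np.add.at(acc, i, g)
            a._accumulate(acc)
        out._backward = backward
    return out


def scatter_sum(t: Tensor, idx: np.ndarray, num: int) -> Tensor:
    """Row scatter-add: ``out[i] = sum_{e: idx[e]=i} t[e]``."""
    idx = np.asarray(idx, dtype=np.intp)
    data = np.zeros((num,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, idx, t.data)
    out = _node(data, (t,))
    if out._parents:
        def backward(g, a=t, i=idx):
            a._accumulate(g[i])
        out._backward = backward
    return out


def grad_reverse(t: Tensor, scale: float = 1.0) -> Tensor:
    """Identity forward; multiplies the gradient by ``-scale`` on the way back."""
    out = _node(t.data.copy(), (t,))
    if out._parents:
        def backward(g, a=t):
            a._accumulate(-scale * g)
        out._backward = backward
    return out


class Adam:
    """Adam with decoupled-from-nothing (classic L2) weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
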