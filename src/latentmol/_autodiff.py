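"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the package needs: elementwise
arithmetic with broadcasting, 2-D matrix products, ``sigmoid``/``tanh``
and their stable companions, reductions, slicing/concatenation for the
coupling-layer channel splits, and a same-padded 2-D convolution for the
bond-flow networks.  Gradients are accumulated by topological traversal
of the operation graph; an :class:`Adam` optimizer with global-norm
gradient clipping drives training.

All arrays are float64.  The engine is deliberately small: correctness
is checked against finite differences in the test suite rather than by
supporting a general operator algebra.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "log_sigmoid",
    "matmul",
    "sigmoid",
    "tanh",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.shape)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __getitem__(self, key):
        def bwd(g):
            if self.requires_grad:
                scatter = np.zeros_like(self.data)
                scatter[key] = g
                self.grad += scatter

        return Tensor(self.data[key], parents=(self,), backward=bwd)

    # -- reductions & shaping -------------------------------------------
    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += np.broadcast_to(g, self.shape)

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def sum_axis(self, axis):
        def bwd(g):
            if self.requires_grad:
                self.grad += np.expand_dims(g, axis)

        return Tensor(self.data.sum(axis=axis), parents=(self,), backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self.grad += np.broadcast_to(g / n, self.shape)

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product a @ b."""
    a, b = Tensor._lift(a), Tensor._lift(b)

    def bwd(g):
        if a.requires_grad:
            a.grad += g @ b.data.T
        if b.requires_grad:
            b.grad += a.data.T @ g

    return Tensor(a.data @ b.data, parents=(a, b), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)

    def bwd(g):
        if x.requires_grad:
            x.grad += g * out * (1.0 - out)

    return Tensor(out, parents=(x,), backward=bwd)


def log_sigmoid(x: Tensor) -> Tensor:
    """log(sigmoid(x)) computed as -softplus(-x) for stability."""
    x = Tensor._lift(x)
    out = -np.logaddexp(0.0, -x.data)

    def bwd(g):
        if x.requires_grad:
            # d/dx log sig(x) = 1 - sig(x)
            x.grad += g * (1.0 - np.exp(out))

    return Tensor(out, parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            x.grad += g * (1.0 - out**2)

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2-D convolution.

    x: (C_in, H, W); w: (C_out, C_in, k, k) with odd k; b: (C_out,).
    Returns (C_out, H, W).
    """
    x, w, b = Tensor._lift(x), Tensor._lift(w), Tensor._lift(b)
    c_out, c_in, k, _ = w.shape
    _, hh, ww = x.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    out = np.zeros((c_out, hh, ww))
    for di in range(k):
        for dj in range(k):
            out += np.tensordot(w.data[:, :, di, dj], xp[:, di : di + hh, dj : dj + ww], axes=(1, 0))
    out += b.data[:, None, None]

    def bwd(g):
        if b.requires_grad:
            b.grad += g.sum(axis=(1, 2))
        if w.requires_grad:
            for di in range(k):
                for dj in range(k):
                    w.grad[:, :, di, dj] += np.tensordot(
                        g, xp[:, di : di + hh, dj : dj + ww], axes=([1, 2], [1, 2])
                    )
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, di : di + hh, dj : dj + ww] += np.tensordot(
                        w.data[:, :, di, dj], g, axes=(0, 0)
                    )
            x.grad += gxp[:, p : p + hh, p : p + ww]

    return Tensor(out, parents=(x, w, b), backward=bwd)


class Adam:
    """Adaptive-moment optimizer with optional global-norm gradient clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, clip_norm=None):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        grads = [p.grad for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g**2
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
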