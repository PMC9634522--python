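"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the relation-extraction model needs:
dense matmul, batched matmul over a leading head axis, broadcasting
elementwise arithmetic, row softmax, ReLU/tanh/sigmoid, max/sum/mean
reductions, concatenation, embedding gather, sliding-window unfolding
for 1-D convolution, dropout, and a fused softmax cross-entropy loss.

Gradients accumulate into ``Tensor.grad`` (a NumPy array of the same
shape as ``Tensor.data``) when ``backward()`` is called on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        a_vec = self.data.ndim == 1
        b_vec = other.data.ndim == 1
        A = self.data[None, :] if a_vec else self.data
        B = other.data[:, None] if b_vec else other.data
        out_data = A @ B
        if a_vec:
            out_data = out_data[0]
        if b_vec:
            out_data = out_data[..., 0]
        out = Tensor(out_data, self._needs(other), (self, other))

        def bw(g):
            if a_vec and b_vec:
                G = g.reshape(1, 1)
            elif a_vec:
                G = g[None, :]
            elif b_vec:
                G = g[..., None]
            else:
                G = g
            if self.requires_grad:
                ga = G @ B.swapaxes(-1, -2)
                self._accumulate(ga[0] if a_vec else ga)
            if other.requires_grad:
                gb = A.swapaxes(-1, -2) @ G
                other._accumulate(gb[:, 0] if b_vec else gb)

        out._backward = bw
        return out

    __matmul__ = matmul

    def transpose_last(self) -> "Tensor":
        out = Tensor(self.data.swapaxes(-1, -2), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.swapaxes(-1, -2))

        out._backward = bw
        return out

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accumulate(
                        np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
                    )

        out._backward = bw
        return out

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    def max(self, axis: int) -> "Tensor":
        """Max reduction along ``axis``; ties route gradient to the first hit."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(
                    full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
                )
                self._accumulate(full)

        out._backward = bw
        return out

    # -- softmax ------------------------------------------------------------

    def softmax_rows(self) -> "Tensor":
        """Softmax over the last axis, numerically stabilised."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = bw
        return out

    def cross_entropy(self, target: int) -> "Tensor":
        """Fused log-softmax + NLL for a 1-D logit vector and integer target."""
        if self.data.ndim != 1:
            raise ValueError("cross_entropy expects a 1-D logit vector")
        z = self.data - self.data.max()
        e = np.exp(z)
        p = e / e.sum()
        loss = -np.log(max(p[target], 1e-12))
        out = Tensor(np.asarray(loss, dtype=self.data.dtype), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                d = p.copy()
                d[target] -= 1.0
                self._accumulate(g * d)

        out._backward = bw
        return out

    def cols(self, start: int, stop: int) -> "Tensor":
        """Contiguous slice along the last axis."""
        out = Tensor(self.data[..., start:stop], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[..., start:stop] = g
                self._accumulate(full)

        out._backward = bw
        return out

    def rows(self, start: int, stop: int) -> "Tensor":
        """Contiguous slice along the first axis."""
        out = Tensor(self.data[start:stop], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[start:stop] = g
                self._accumulate(full)

        out._backward = bw
        return out

    # -- gather / structure --------------------------------------------------

    def take_rows(self, indices) -> "Tensor":
        """Embedding lookup: rows ``indices`` of a 2-D table (scatter-add grad)."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bw
        return out

    def unfold_windows(self, w: int) -> "Tensor":
        """All length-``w`` row windows of a 2-D (m, d) input as (m-w+1, w*d)."""
        m, d = self.data.shape
        if m < w:
            raise ValueError(f"input of length {m} shorter than window {w}")
        n_win = m - w + 1
        data = np.empty((n_win, w * d), dtype=self.data.dtype)
        for j in range(w):
            data[:, j * d : (j + 1) * d] = self.data[j : j + n_win]
        out = Tensor(data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                for j in range(w):
                    full[j : j + n_win] += g[:, j * d : (j + 1) * d]
                self._accumulate(full)

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator, train: bool) -> "Tensor":
        """Inverted dropout; identity when ``train`` is False or rate 0."""
        if not train or rate == 0.0:
            return self
        keep = 1.0 - rate
        mask = (rng.random(self.data.shape) < keep).astype(self.data.dtype) / keep
        return self * Tensor(mask)


def concat(tensors: list, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bw
    return out


def stack_rows(tensors: list) -> Tensor:
    """Stack 1-D tensors into a 2-D matrix (axis 0)."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=0)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[i])

    out._backward = bw
    return out
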