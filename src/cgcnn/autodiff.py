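"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for this model family: broadcast-aware elementwise
arithmetic, batched matmul, shape surgery, a row-wise L2 normalization with
an exact gradient, and a fused softmax cross-entropy loss.  Every gradient
here is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tanh", "relu", "matmul", "concat", "l2_normalize",
           "softmax", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape node that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=float).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor._from_op(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor._from_op(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor._from_op(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape surgery --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        return Tensor._from_op(out_data, (self,), bwd)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return Tensor._from_op(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g):
            if self.requires_grad:
                self.grad[key] += g

        return Tensor._from_op(out_data, (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += g
            elif keepdims:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                self.grad += np.broadcast_to(
                    np.expand_dims(g, axis), self.data.shape
                )

        return Tensor._from_op(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            scale = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            scale = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / scale)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g):
        if x.requires_grad:
            x.grad += g * (1.0 - out_data ** 2)

    return Tensor._from_op(out_data, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def bwd(g):
        if x.requires_grad:
            x.grad += g * (x.data > 0)

    return Tensor._from_op(out_data, (x,), bwd)


def matmul(x, y) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    y = y if isinstance(y, Tensor) else Tensor(y)
    out_data = np.matmul(x.data, y.data)

    def bwd(g):
        xd, yd = x.data, y.data
        if x.requires_grad:
            if yd.ndim == 1:
                gx = np.multiply.outer(g, yd) if g.ndim else g * yd
            elif xd.ndim == 1:
                gy_shape = np.matmul(yd, g[..., None])[..., 0]
                gx = gy_shape.sum(axis=tuple(range(gy_shape.ndim - 1)))
            else:
                gx = np.matmul(g, np.swapaxes(yd, -1, -2))
            x.grad += _unbroadcast(gx, xd.shape)
        if y.requires_grad:
            if yd.ndim == 1:
                axes = tuple(range(g.ndim))
                gy = np.tensordot(g, xd, axes=(axes, axes))
            elif xd.ndim == 1:
                gy = xd[:, None] * g[..., None, :]
                gy = _unbroadcast(gy, yd.shape)
            else:
                gy = np.matmul(np.swapaxes(xd, -1, -2), g)
            y.grad += _unbroadcast(gy, yd.shape)

    return Tensor._from_op(out_data, (x, y), bwd)


def concat(tensors, axis=0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._from_op(out_data, tuple(tensors), bwd)


def l2_normalize(x: Tensor, axis: int = -1) -> Tensor:
    """Divide slices along ``axis`` by their L2 norm; zero slices pass through."""
    norm = np.sqrt((x.data ** 2).sum(axis=axis, keepdims=True))
    safe = np.where(norm > 0, norm, 1.0)
    out_data = x.data / safe

    def bwd(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x.grad += (g - out_data * dot) / safe

    return Tensor._from_op(out_data, (x,), bwd)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (inference path)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer ``labels``."""
    labels = np.asarray(labels, dtype=int)
    probs = softmax(logits.data, axis=-1)
    n = logits.data.shape[0]
    eps = 1e-300
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def bwd(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits.grad += g * grad / n

    return Tensor._from_op(loss, (logits,), bwd)
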