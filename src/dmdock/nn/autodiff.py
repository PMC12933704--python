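"""A compact reverse-mode automatic differentiation engine over numpy.

Design: a ``Tensor`` wraps a float64 ndarray and records the operations that
produced it on a tape of closures; ``backward()`` walks the tape in reverse
topological order.  The op set is exactly what the docking model needs
(broadcasted arithmetic, matmul/einsum, reductions, gather, layer norm,
softmax, pointwise nonlinearities) — small enough to audit, fast enough for
desk-scale training because all heavy lifting stays inside numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "einsum", "matmul", "smooth_l1"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))

        def bwd(g):
            _maybe(self, _unbroadcast(g, self.shape))
            _maybe(other, _unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        out._backward = lambda g: _maybe(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))

        def bwd(g):
            _maybe(self, _unbroadcast(g * other.data, self.shape))
            _maybe(other, _unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))

        def bwd(g):
            _maybe(self, _unbroadcast(g / other.data, self.shape))
            _maybe(other,
                   _unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = bwd
        return out

    def __pow__(self, n: float):
        out = _make(self.data ** n, (self,))
        out._backward = lambda g: _maybe(self, g * n * self.data ** (n - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        out._backward = lambda g: _maybe(self, g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _make(self.data.transpose(*axes), (self,))
        out._backward = lambda g: _maybe(self, g.transpose(*inv))
        return out

    def take0(self, idx: np.ndarray):
        """Gather along axis 0 (integer index array of any shape)."""
        idx = np.asarray(idx)
        out = _make(self.data[idx], (self,))

        def bwd(g):
            if self.requires_grad or self._parents:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx.ravel(),
                          g.reshape(-1, *self.shape[1:]))
                _maybe(self, acc)
        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _maybe(self, np.broadcast_to(g, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        out._backward = lambda g: _maybe(self, g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        out._backward = lambda g: _maybe(self, g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _make(t, (self,))
        out._backward = lambda g: _maybe(self, g * (1.0 - t * t))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        out._backward = lambda g: _maybe(self, g * e)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        out._backward = lambda g: _maybe(self, g * 0.5 / r)
        return out

    def softmax(self):
        """Softmax over the last axis."""
        x = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(x)
        s = e / e.sum(axis=-1, keepdims=True)
        out = _make(s, (self,))

        def bwd(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            _maybe(self, s * (g - dot))
        out._backward = bwd
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis (no affine; see layers.LayerNorm)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = _make(y, (self,))

        def bwd(g):
            gy = g * inv
            _maybe(self, gy - gy.mean(axis=-1, keepdims=True)
                   - y * (gy * y).mean(axis=-1, keepdims=True))
        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.grad is not None})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents
                         if p.requires_grad or p._parents)
    return out


def _maybe(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        t._accum(g)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data @ b.data, (a, b))

    def bwd(g):
        if a.requires_grad or a._parents:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _maybe(a, _unbroadcast(ga, a.shape))
        if b.requires_grad or b._parents:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _maybe(b, _unbroadcast(gb, b.shape))
    out._backward = bwd
    return out


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Every index of each operand must appear in the output or in the other
    operand (true for all contractions used by the model).
    """
    a, b = as_tensor(a), as_tensor(b)
    lhs, rhs = subscripts.split("->")
    sa, sb = lhs.split(",")
    out = _make(np.einsum(subscripts, a.data, b.data), (a, b))

    def bwd(g):
        if a.requires_grad or a._parents:
            _maybe(a, np.einsum(f"{rhs},{sb}->{sa}", g, b.data))
        if b.requires_grad or b._parents:
            _maybe(b, np.einsum(f"{rhs},{sa}->{sb}", g, a.data))
    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis),
                tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _maybe(t, piece)
    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Elementwise smooth-L1 (Huber): 0.5 e^2 / beta for |e| < beta,
    |e| - 0.5 beta otherwise."""
    pred = as_tensor(pred)
    e = pred.data - np.asarray(target, dtype=np.float64)
    ae = np.abs(e)
    quad = ae < beta
    val = np.where(quad, 0.5 * e * e / beta, ae - 0.5 * beta)
    out = _make(val, (pred,))

    def bwd(g):
        _maybe(pred, g * np.where(quad, e / beta, np.sign(e)))
    out._backward = bwd
    return out
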