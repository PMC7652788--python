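"""Reverse-mode autodiff on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records, for every producing
operation, its parent tensors and a gradient function mapping the output
gradient to each parent's gradient contribution.  ``backward()`` runs the
tape in reverse topological order.  Dtypes are preserved (float32 for
training, float64 for gradient checks).
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra > 0:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # list of (parent_tensor, grad_fn) pairs
        self._parents: list = []

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _make(data, parents) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled:
            parents = [(p, fn) for p, fn in parents if p.requires_grad]
            if parents:
                out.requires_grad = True
                out._parents = parents
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
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
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, fn in node._parents:
                pg = fn(g)
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor._make(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ],
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, n: float):
        return Tensor._make(
            self.data**n,
            [(self, lambda g: g * n * self.data ** (n - 1))],
        )

    # -- matmul ------------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D tensors only")
        return Tensor._make(
            a @ b,
            [
                (self, lambda g: g @ b.T),
                (other, lambda g: a.T @ g),
            ],
        )

    # -- unary math --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, [(self, lambda g: g * out_data)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            self.data * mask, [(self, lambda g: g * mask)]
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * sign)])

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gx = g
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.data.ndim for a in ax)
                for a in sorted(ax):
                    gx = np.expand_dims(gx, a)
            return np.broadcast_to(gx, self.data.shape).copy()

        return Tensor._make(out_data, [(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), [(self, lambda g: g.reshape(old))]
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), [(self, lambda g: g.transpose(inv))]
        )

    def __getitem__(self, key):
        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return out

        return Tensor._make(self.data[key], [(self, grad_fn)])

    # -- softmax (stable, last axis) ---------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            return p * (g - dot)

        return Tensor._make(p, [(self, grad_fn)])


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(lo), int(hi))
        sl = tuple(sl)
        parents.append((t, lambda g, sl=sl: g[sl]))
    return Tensor._make(out, parents)
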