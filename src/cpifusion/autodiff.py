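"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (desk-scale molecular graphs and
short protein structures), so a compact tape-based engine over float64
numpy arrays is the numeric backbone: every differentiable operation
builds a node holding its parents and a closure that accumulates the
chain-rule contribution into ``parent.grad``.

Conventions:

* Broadcasting follows numpy; gradients are summed back over broadcast
  axes (`_unbroadcast`).
* ``Tensor.backward()`` seeds the output gradient with ones and walks the
  tape in reverse topological order.
* Non-differentiable inputs (masks, index arrays) are passed as plain
  numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd machinery --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, p=exponent):
                a._accum(g * p * a.data ** (p - 1.0))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g)
                    b._accum(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * 0.5 / v)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v * (1.0 - v))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * (1.0 - v * v))
        return out

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def _extreme(self, axis, keepdims, fn):
        val = fn(self.data, axis=axis, keepdims=True)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, parents=(self,))
        if out.requires_grad:
            # ties share gradient equally (subgradient choice)
            hit = (self.data == val).astype(np.float64)
            hit /= hit.sum(axis=axis, keepdims=True)

            def bw(g, a=self, ax=axis, kd=keepdims, h=hit):
                if not kd:
                    g = np.expand_dims(g, ax)
                a._accum(h * g)
            out._backward = bw
        return out

    def max(self, axis, keepdims=False):
        return self._extreme(axis, keepdims, np.max)

    def min(self, axis, keepdims=False):
        return self._extreme(axis, keepdims, np.min)

    # -- shape manipulation ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes) if axes else None
            out._backward = lambda g, a=self, iv=inv: a._accum(g.transpose(iv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bw(g, a=self, i=idx):
                acc = np.zeros_like(a.data)
                np.add.at(acc, i, g)
                a._accum(acc)
            out._backward = bw
        return out

    # -- composite helpers ----------------------------------------------------------
    def softmax(self, axis=-1):
        shifted = self + (-self.data.max(axis=axis, keepdims=True))  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g, ts=tensors, off=offsets, ax=axis):
            for t, lo, hi in zip(ts, off[:-1], off[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[ax] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        def bw(g, ts=tensors, ax=axis):
            for k, t in enumerate(ts):
                if t.requires_grad:
                    t._accum(np.take(g, k, axis=ax))
        out._backward = bw
    return out
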