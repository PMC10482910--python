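"""Reverse-mode automatic differentiation over numpy arrays.

A minimal define-by-run tape: each operation returns a :class:`Tensor` that
remembers its parents and a closure computing parent gradients from the output
gradient.  Only the operations required by the axial-attention backbone and
the differentiable contact losses are implemented — elementwise arithmetic,
two-operand einsum, (log-)softmax, gather/scatter, reductions and shape ops.

Gradients accumulate in float64.  ``backward()`` may only be called on scalar
tensors (losses).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "stack", "concatenate", "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward_fn = backward_fn if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph --------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                stack_.pop()
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        rg = self.requires_grad or other.requires_grad
        return Tensor(
            self.data + other.data, rg, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, self.requires_grad, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        rg = self.requires_grad or other.requires_grad
        return Tensor(
            self.data * other.data, rg, (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = self.data ** e
        return Tensor(
            out, self.requires_grad, (self,),
            lambda g: (g * e * self.data ** (e - 1.0),),
        )

    # -- elementwise nonlinearities ------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, self.requires_grad, (self,), lambda g: (g * mask,))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, self.requires_grad, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.data), self.requires_grad, (self,),
                      lambda g: (g / self.data,))

    def sigmoid(self):
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        return Tensor(out, self.requires_grad, (self,), lambda g: (g * out * (1.0 - out),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(out, self.requires_grad, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- softmax family --------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = shifted - lse
        sm = np.exp(out)

        def bwd(g):
            return (g - sm * g.sum(axis=axis, keepdims=True),)

        return Tensor(out, self.requires_grad, (self,), bwd)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(self.data.reshape(shape), self.requires_grad, (self,),
                      lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), self.requires_grad, (self,),
                      lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor(out, self.requires_grad, (self,), bwd)

    def gather_last(self, index: np.ndarray):
        """Pick one entry along the last axis per leading position."""
        index = np.asarray(index)
        out = np.take_along_axis(self.data, index[..., None], axis=-1)[..., 0]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, index[..., None], g[..., None], axis=-1)
            return (full,)

        return Tensor(out, self.requires_grad, (self,), bwd)

    # -- contractions -----------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        # promote 1-D operands so one backward rule covers every case
        a = self.reshape(1, -1) if self.ndim == 1 else self
        b = other.reshape(-1, 1) if other.ndim == 1 else other
        rg = a.requires_grad or b.requires_grad
        out = a.data @ b.data

        def bwd(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return (ga, gb)

        res = Tensor(out, rg, (a, b), bwd)
        if self.ndim == 1 and other.ndim == 1:
            return res.reshape(())
        if self.ndim == 1:
            return res.reshape(res.shape[1:])
        if other.ndim == 1:
            return res.reshape(res.shape[:-1])
        return res

    __matmul__ = matmul


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with reverse-mode gradients.

    Every subscript of each operand must appear in the output or in the other
    operand (no internally summed indices), which covers all attention
    contractions used here.
    """
    a, b = Tensor._lift(a), Tensor._lift(b)
    lhs, out_sub = spec.split("->")
    a_sub, b_sub = lhs.split(",")
    for sub, name in ((a_sub, "first"), (b_sub, "second")):
        missing = set(sub) - set(out_sub) - set(b_sub if name == "first" else a_sub)
        if missing:
            raise ValueError(f"unsupported einsum '{spec}': {missing} summed internally")
    out = np.einsum(spec, a.data, b.data)
    rg = a.requires_grad or b.requires_grad

    def bwd(g):
        ga = np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data)
        gb = np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data)
        return (ga, gb)

    return Tensor(out, rg, (a, b), bwd)


Tensor.einsum = staticmethod(einsum)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor(out, rg, tuple(tensors), bwd)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, rg, tuple(tensors), bwd)


def embedding(weight: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup ``weight[index]`` with scatter-add gradient."""
    index = np.asarray(index)
    out = weight.data[index]

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, index, g)
        return (full,)

    return Tensor(out, weight.requires_grad, (weight,), bwd)


class Parameter(Tensor):
    """A tensor that is optimised (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
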