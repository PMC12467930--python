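"""Reverse-mode automatic differentiation over NumPy arrays.

A small tensor engine: each :class:`Tensor` wraps an ``ndarray`` and records
the operations that produced it, so a scalar loss can backpropagate exact
gradients to every parameter.  Only the operations the networks in this
package need are implemented; all of them support float32 and float64 (the
gradient-check tests run in double precision).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float64)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- graph construction -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar if `grad` omitted)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def build(t):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 100000))
        try:
            build(self)
        finally:
            sys.setrecursionlimit(old)

        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    pg = _unbroadcast(np.asarray(pg), parent.shape)
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    elif parent._backward is None:
                        parent.grad = pg if parent.grad is None else parent.grad + pg
                    else:
                        grads[id(parent)] = pg
            if t._backward is None:  # leaf reached via direct call
                t.grad = g if t.grad is None else t.grad + g
            t._backward = None
            t._parents = ()

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data + other.data, (self, other), lambda g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(a * b, (self, other), lambda g: (g * b, g * a))

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data - other.data, (self, other), lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(a / b, (self, other), lambda g: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._make(a**p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ga, gb

        return Tensor._make(a @ b, (self, other), bw)

    # -- elementwise nonlinearities -----------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        x = self.data
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def clip(self, lo, hi):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape),)

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out = self.data.max(axis=axis, keepdims=keepdims)
        full = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == full).astype(self.data.dtype)
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (mask * g,)

        return Tensor._make(out, (self,), bw)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def bw(g):
            out = np.zeros(self.shape, dtype=self.data.dtype)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), bw)

    def pad(self, pad_width):
        """Zero padding; `pad_width` as for np.pad."""
        slices = tuple(
            slice(lo, lo + s) for (lo, _hi), s in zip(pad_width, self.shape)
        )
        return Tensor._make(
            np.pad(self.data, pad_width), (self,), lambda g: (g[slices],)
        )

    def roll(self, shift, axis):
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
        return Tensor._make(
            np.roll(self.data, shift, axis), (self,), lambda g: (np.roll(g, neg, axis),)
        )

    # -- composite helpers --------------------------------------------
    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def bw(g):
        outs = []
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bw)
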