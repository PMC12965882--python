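"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tensor engine: every operation builds a node in a
directed acyclic graph; :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating vector–Jacobian products into ``.grad``.
Arrays are float64 throughout so finite-difference gradient checks are
meaningful at ~1e-6 step sizes.

Only the operations the package needs are implemented; each op stores a
closure over the forward intermediates it needs for its backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "sigmoid", "softplus",
           "maximum_const", "where_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with gradient tracking.

    Parameters
    ----------
    data:
        Array-like forward value (stored as float64).
    requires_grad:
        Whether gradients should be accumulated for this leaf.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        # topological order over the subgraph that requires grad
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None or grad.flags.writeable is False else grad
        else:
            self.grad = self.grad + grad

    # -- construction helper ----------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=tuple(p for p in parents if p.requires_grad) if req else (),
                      _backward=backward if req else None)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accum(np.outer(g, other.data) if self.data.ndim == 2
                                else g * other.data)
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accum(np.outer(self.data, g) if other.data.ndim == 2
                                 else g * self.data)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def sin(self):
        def backward(g):
            self._accum(g * np.cos(self.data))
        return Tensor._make(np.sin(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))
        return Tensor._make(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float64))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).astype(np.float64))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        # fast paths: integer-array gathers (scatter-add via bincount beats
        # np.add.at by a wide margin)
        arr_idx = isinstance(idx, np.ndarray) and idx.dtype.kind in "iu"
        fast1d = self.data.ndim == 1 and arr_idx
        fast2d = self.data.ndim == 2 and arr_idx

        def backward(g):
            if fast1d:
                self._accum(np.bincount(idx.ravel(), weights=g.ravel(),
                                        minlength=self.data.shape[0]))
            elif fast2d:
                n, c = self.data.shape
                flat = (idx.reshape(-1, 1) * c + np.arange(c)).ravel()
                full = np.bincount(flat, weights=g.reshape(-1, c).ravel(),
                                   minlength=n * c)
                self._accum(full.reshape(n, c))
            else:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width, mode="constant"):
        """Pad with zeros or edge replication; pad_width as for np.pad."""
        out_data = np.pad(self.data, pad_width, mode=mode)
        slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, self.shape))

        def backward(g):
            if mode == "constant":
                self._accum(g[slices])
            else:  # edge: fold the replicated borders back
                gg = g.copy()
                for ax, (lo, hi) in enumerate(pad_width):
                    if lo:
                        idx_dst = [slice(None)] * gg.ndim
                        idx_src = [slice(None)] * gg.ndim
                        idx_dst[ax] = slice(lo, lo + 1)
                        idx_src[ax] = slice(0, lo)
                        gg[tuple(idx_dst)] += gg[tuple(idx_src)].sum(axis=ax, keepdims=True)
                    if hi:
                        idx_dst = [slice(None)] * gg.ndim
                        idx_src = [slice(None)] * gg.ndim
                        idx_dst[ax] = slice(gg.shape[ax] - hi - 1, gg.shape[ax] - hi)
                        idx_src[ax] = slice(gg.shape[ax] - hi, None)
                        gg[tuple(idx_dst)] += gg[tuple(idx_src)].sum(axis=ax, keepdims=True)
                self._accum(gg[slices])

        return Tensor._make(out_data, (self,), backward)

    def roll(self, shift, axis):
        def backward(g):
            self._accum(np.roll(g, tuple(-s for s in np.atleast_1d(shift)), axis))
        return Tensor._make(np.roll(self.data, shift, axis), (self,), backward)

    def repeat(self, repeats: int, axis: int):
        """Repeat each element ``repeats`` times along ``axis``."""
        out_data = np.repeat(self.data, repeats, axis=axis)

        def backward(g):
            shp = list(self.shape)
            shp[axis:axis + 1] = [self.shape[axis], repeats]
            self._accum(g.reshape(shp).sum(axis=axis + 1))

        return Tensor._make(out_data, (self,), backward)

    def cumsum(self, axis: int):
        def backward(g):
            self._accum(np.flip(np.cumsum(np.flip(g, axis), axis=axis), axis))
        return Tensor._make(np.cumsum(self.data, axis=axis), (self,), backward)

    # -- stabilized pieces -------------------------------------------------

    def clip_min(self, lo: float):
        """max(x, lo); gradient flows only where x > lo."""
        mask = self.data > lo

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1+exp(x)), computed stably; derivative is sigmoid(x)."""
    x = as_tensor(x)
    out_data = np.logaddexp(0.0, x.data)

    def backward(g):
        x._accum(g / (1.0 + np.exp(-x.data)))

    return Tensor._make(out_data, (x,), backward)


def maximum_const(x: Tensor, lo) -> Tensor:
    return as_tensor(x).clip_min(float(lo))


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select a where mask else b; mask is a constant boolean array."""
    a, b = as_tensor(a), as_tensor(b)
    m = np.asarray(mask, dtype=bool)
    out_data = np.where(m, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * m, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~m, b.shape))

    return Tensor._make(out_data, (a, b), backward)
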