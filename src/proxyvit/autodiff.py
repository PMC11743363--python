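"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operator set the proxy-attention
transformer needs: broadcasting arithmetic, (batched) matmul, exp/log,
stable softmax, GELU, reductions, reshaping/concatenation, and grid
max/mean pooling. Tensors carry float64 data; gradients are accumulated
by topological-order backpropagation from a scalar loss.

Gradient correctness is established by finite-difference checks in the
test suite rather than assumed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents

            def _bw():
                backward(out.grad)

            out._backward = _bw
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF via erf."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

        def bw(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                self._accum(g * (phi + x * pdf))

        return self._make(x * phi, (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # gradient flows to the (first) argmax position per slice
        expanded = np.expand_dims(out_data, axis) if not keepdims else out_data
        mask = (self.data == expanded)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def bw(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(mask * gg)

        return self._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (rowwise max subtracted)."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return self._make(s, (self,), bw)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    # -- grid pooling ---------------------------------------------------
    def pool_grid(self, grid: tuple[int, int], target: tuple[int, int],
                  kind: str = "max"):
        """Pool tokens laid out on a 2-D grid down to a coarser grid.

        `self` has shape (..., rows*cols, d). Window boundaries are the even
        partition floor(i*r/t); windows are never empty and edge windows may
        be smaller when the target does not divide the source.
        """
        r, c = grid
        tr, tc = target
        if tr > r or tc > c:
            raise ValueError(f"target grid {target} exceeds source grid {grid}")
        if kind not in ("max", "mean"):
            raise ValueError(f"unknown pool kind {kind!r}")
        lead = self.shape[:-2]
        d = self.shape[-1]
        x = self.data.reshape(lead + (r, c, d))
        rb = [(i * r) // tr for i in range(tr + 1)]
        cb = [(j * c) // tc for j in range(tc + 1)]
        out = np.empty(lead + (tr, tc, d))
        for i in range(tr):
            for j in range(tc):
                win = x[..., rb[i]:rb[i + 1], cb[j]:cb[j + 1], :]
                flat = win.reshape(lead + (-1, d))
                if kind == "max":
                    out[..., i, j, :] = flat.max(axis=-2)
                else:
                    out[..., i, j, :] = flat.mean(axis=-2)
        out_data = out.reshape(lead + (tr * tc, d))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g.reshape(lead + (tr, tc, d))
            gx = np.zeros_like(x)
            for i in range(tr):
                for j in range(tc):
                    win = x[..., rb[i]:rb[i + 1], cb[j]:cb[j + 1], :]
                    gwin = gx[..., rb[i]:rb[i + 1], cb[j]:cb[j + 1], :]
                    go = gg[..., i, j, :]
                    if kind == "max":
                        m = win.max(axis=(-3, -2), keepdims=True)
                        mask = (win == m).astype(float)
                        mask /= mask.sum(axis=(-3, -2), keepdims=True)
                        gwin += mask * go[..., None, None, :]
                    else:
                        n = win.shape[-3] * win.shape[-2]
                        gwin += go[..., None, None, :] / n
            self._accum(gx.reshape(self.shape))

        return self._make(out_data, (self,), bw)

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
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
            if node._backward is not None:
                node._backward()


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(g)

        out._backward = _bw
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
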