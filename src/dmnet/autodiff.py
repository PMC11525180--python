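"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains recurrent threshold-linear networks by backpropagation
through time and feedforward classifiers by plain backpropagation.  This
module provides the small set of differentiable primitives those loops need:
elementwise arithmetic with broadcasting, matmul, rectification, softplus,
reductions, advanced indexing, scatter-add, stacking and 2-D convolution via
an unfold/fold pair.  Everything is float64 and eager; calling
:meth:`Tensor.backward` on a scalar walks the recorded graph once.

Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "stack", "concat"]


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            else:  # batched matmul
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = bwd
        return out

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    def maximum(self, const: float):
        """Elementwise max with a scalar constant (used for clamping tau >= dt)."""
        out = Tensor(np.maximum(self.data, const), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data >= const))
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape & index
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), _parents=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accum(np.transpose(g, inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            gg = np.zeros_like(self.data)
            np.add.at(gg, idx, g)
            self._accum(gg)

        out._backward = bwd
        return out

    def scatter_add(self, index: np.ndarray, size: int, axis: int = -1):
        """out[..., k] = sum over positions j with index[j]==k of self[..., j].

        `index` indexes the last (or given) axis; output has that axis length
        `size`.  This is the compiled gather/scatter evaluation of synaptic
        sums over an explicit connection list.
        """
        if axis != -1 and axis != self.data.ndim - 1:
            raise ValueError("scatter_add supports the last axis only")
        shp = self.data.shape[:-1] + (size,)
        data = np.zeros(shp)
        np.add.at(data, (..., index), self.data)
        out = Tensor(data, _parents=(self,))
        out._backward = lambda g: self._accum(g[..., index])
        return out

    def unfold2d(self, kh: int, kw: int):
        """im2col for 'same' convolution with zero padding and stride 1.

        self: (B, C, H, W) -> (B, C*kh*kw, H*W)
        """
        B, C, H, W = self.data.shape
        ph, pw = kh // 2, kw // 2
        padded = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(2, 3))
        # win: (B, C, H, W, kh, kw)
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, H * W)
        out = Tensor(np.ascontiguousarray(cols), _parents=(self,))

        def bwd(g):
            g6 = g.reshape(B, C, kh, kw, H, W)
            gp = np.zeros((B, C, H + 2 * ph, W + 2 * pw))
            for i in range(kh):
                for j in range(kw):
                    gp[:, :, i : i + H, j : j + W] += g6[:, :, i, j]
            self._accum(gp[:, :, ph : ph + H, pw : pw + W])

        out._backward = bwd
        return out


def stack(tensors, axis=0) -> Tensor:
    """Stack tensors of equal shape along a new axis."""
    ts = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in ts], axis=axis), _parents=tuple(ts))

    def bwd(g):
        for i, t in enumerate(ts):
            t._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def concat(tensors, axis=0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis), _parents=tuple(ts))
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


class Adam:
    """Adaptive-moment SGD (optionally the max-variant), beta1=0.9, beta2=0.999."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, amsgrad=False):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vmax = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.amsgrad:
                self.vmax[i] = np.maximum(self.vmax[i], vhat)
                vhat = self.vmax[i]
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain stochastic gradient descent without momentum."""

    def __init__(self, params, lr=1e-3):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
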