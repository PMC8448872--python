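"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the locomotion network are provided:
dense layers, stride-1 "same" 1D convolution, tanh/relu/softmax,
dropout, gradient reversal, elementwise arithmetic and reductions.
Gradients are accumulated by a topological-order backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "dense",
    "conv1d_same",
    "relu",
    "tanh",
    "softmax",
    "dropout",
    "grad_reverse",
    "mul",
    "add",
    "sub",
    "scale",
    "sum_axis",
    "mean_all",
    "log",
    "clip",
    "weighted_time_pool",
    "Adam",
]


class Tensor:
    """Node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this (typically scalar) node."""
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
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(data):
    return Tensor(data, requires_grad=False)


def parameter(data):
    return Tensor(data, requires_grad=True)


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return Tensor(a.data * c, (a,), backward)


def dense(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis: x @ w (+ b)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            xd = x.data.reshape(-1, x.data.shape[-1])
            gd = g.reshape(-1, g.shape[-1])
            w._accumulate(xd.T @ gd)
        if b is not None and b.requires_grad:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents, backward)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 1D convolution with zero "same" padding.

    x: (B, l, C_in), w: (F, C_in, C_out), b: (C_out,) -> (B, l, C_out)
    """
    F = w.data.shape[0]
    pad_l = (F - 1) // 2
    pad_r = F // 2
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    length = x.data.shape[1]
    # windows: (B, l, F, C_in)
    win = np.lib.stride_tricks.sliding_window_view(xp, F, axis=1)
    win = np.moveaxis(win, -1, 2)
    out_data = np.einsum("blfc,fco->blo", win, w.data, optimize=True) + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("blfc,blo->fco", win, g, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for f in range(F):
                gxp[:, f : f + length, :] += g @ w.data[f].T
            x._accumulate(gxp[:, pad_l : pad_l + length, :])

    return Tensor(out_data, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data**2))

    return Tensor(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - dot))

    return Tensor(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor(np.log(x.data), (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclipped entries."""
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(np.clip(x.data, lo, hi), (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate == 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def grad_reverse(x: Tensor, mu: float) -> Tensor:
    """Identity forward; backward multiplies the gradient by -mu."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")

    def backward(g):
        if x.requires_grad:
            x._accumulate(-mu * g)

    return Tensor(x.data.copy(), (x,), backward)


def sum_axis(x: Tensor, axis: int) -> Tensor:
    out_data = x.data.sum(axis=axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.expand_dims(g, axis) * np.ones_like(x.data))

    return Tensor(out_data, (x,), backward)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, float(g) / n))

    return Tensor(x.data.mean(), (x,), backward)


def weighted_time_pool(a: Tensor, h: Tensor) -> Tensor:
    """Attention pooling: sum_t a[b,t] * h[b,t,:] -> (B, C)."""
    out_data = np.einsum("bl,blc->bc", a.data, h.data, optimize=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum("bc,blc->bl", g, h.data, optimize=True))
        if h.requires_grad:
            h._accumulate(a.data[:, :, None] * g[:, None, :])

    return Tensor(out_data, (a, h), backward)


class Adam:
    """Adam optimizer over a fixed list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
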