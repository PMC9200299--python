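"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ndarray and a
closure computing vector-Jacobian products; :func:`backward` runs the tape in
reverse topological order.  Only the operations the antibody network needs are
provided (dense/conv layers, layer norm, softmax/attention, masked
cross-entropy, and a few shape utilities), each with an analytically derived
backward pass that is verified against numerical differentiation in the test
suite.

Convolutions use 'same' zero padding with odd kernels, implemented as
im2col + BLAS matmul; the input gradient is itself a convolution with the
spatially flipped, channel-transposed kernel, which keeps the backward pass on
the fast matmul path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """Node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"

    def zero_grad(self):
        self.grad = None

    def backward(self, seed=None):
        """Backpropagate from this tensor (scalar unless `seed` is given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar tensor")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(seed, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _sum_to(g, shape):
    """Reduce a broadcast gradient back to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        _accum(a, _sum_to(g, a.data.shape))
        _accum(b, _sum_to(g, b.data.shape))
    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        _accum(a, _sum_to(g * b.data, a.data.shape))
        _accum(b, _sum_to(g * a.data, b.data.shape))
    out._backward = bwd
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, parents=(a,))
    out._backward = lambda g: _accum(a, g * s)
    return out


def detach(a: Tensor) -> Tensor:
    """Constant copy of a tensor (blocks gradient flow)."""
    return Tensor(a.data)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0), parents=(a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


# ---------------------------------------------------------------------------
# linear algebra

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports equal-rank batched operands (via np.matmul)."""
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def bwd(g):
        _accum(a, _sum_to(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape))
        _accum(b, _sum_to(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape))
    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w.T (+ b); w has shape (out, in)."""
    y = matmul(x, transpose(w, (1, 0)))
    return add(y, b) if b is not None else y


# ---------------------------------------------------------------------------
# shape ops

def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: _accum(a, g.reshape(orig))
    return out


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(np.transpose(a.data, axes), parents=(a,))
    out._backward = lambda g: _accum(a, np.transpose(g, inv))
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)
    out._backward = bwd
    return out


def mean(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    n = a.data.shape[axis]
    out = Tensor(a.data.mean(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g / n, a.data.shape))
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# network-specific shape ops

def pair_concat(h: Tensor) -> Tensor:
    """(L, F) -> (L, L, 2F) with out[i, j] = concat(h[i], h[j])."""
    L, F = h.data.shape
    left = np.broadcast_to(h.data[:, None, :], (L, L, F))
    right = np.broadcast_to(h.data[None, :, :], (L, L, F))
    out = Tensor(np.concatenate([left, right], axis=-1), parents=(h,))

    def bwd(g):
        _accum(h, g[:, :, :F].sum(axis=1) + g[:, :, F:].sum(axis=0))
    out._backward = bwd
    return out


def rowcol_mean(p: Tensor) -> Tensor:
    """(L, L, C) -> (L, 2C): concat(mean over rows' partner, mean over columns)."""
    L, _, C = p.data.shape
    out = Tensor(np.concatenate([p.data.mean(axis=1), p.data.mean(axis=0)], axis=-1),
                 parents=(p,))

    def bwd(g):
        gr = np.broadcast_to(g[:, None, :C] / L, (L, L, C))
        gc = np.broadcast_to(g[None, :, C:] / L, (L, L, C))
        _accum(p, gr + gc)
    out._backward = bwd
    return out


def sym_avg(a: Tensor) -> Tensor:
    """Symmetrize an (L, L, C) map: (a + a^T) / 2 over the first two axes."""
    out = Tensor(0.5 * (a.data + np.swapaxes(a.data, 0, 1)), parents=(a,))
    out._backward = lambda g: _accum(a, 0.5 * (g + np.swapaxes(g, 0, 1)))
    return out


# ---------------------------------------------------------------------------
# convolutions ('same' zero padding, odd kernels)

def _cols1d(x, k):
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (0, 0)))
    win = sliding_window_view(xp, k, axis=0)          # (L, C, k)
    return np.ascontiguousarray(win).reshape(x.shape[0], -1)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (L, Cin), w: (Cout, Cin, k) -> (L, Cout)."""
    L, cin = x.data.shape
    cout, _, k = w.data.shape
    cols = _cols1d(x.data, k)
    y = cols @ w.data.reshape(cout, -1).T
    if b is not None:
        y = y + b.data
    out = Tensor(y, parents=(x, w) + ((b,) if b is not None else ()))

    def bwd(g):
        _accum(w, (cols.T @ g).T.reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=0))
        if x.requires_grad:
            wt = np.ascontiguousarray(w.data.transpose(1, 0, 2)[:, :, ::-1])
            _accum(x, _cols1d(g, k) @ wt.reshape(cin, -1).T)
    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (L, L, Cin), w: (Cout, Cin, k, k) -> (L, L, Cout).

    Implemented as k*k shifted matmuls (no im2col gather), which keeps both
    passes on BLAS without materializing the window tensor.
    """
    L1, L2, cin = x.data.shape
    cout, _, k, _ = w.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((pad, pad), (pad, pad), (0, 0)))
    y = np.zeros((L1, L2, cout), dtype=x.data.dtype)
    for di in range(k):
        for dj in range(k):
            y += xp[di:di + L1, dj:dj + L2] @ w.data[:, :, di, dj].T
    if b is not None:
        y += b.data
    out = Tensor(y, parents=(x, w) + ((b,) if b is not None else ()))

    def bwd(g):
        dw = np.empty_like(w.data)
        for di in range(k):
            for dj in range(k):
                dw[:, :, di, dj] = np.tensordot(
                    g, xp[di:di + L1, dj:dj + L2], axes=([0, 1], [0, 1]))
        _accum(w, dw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1)))
        if x.requires_grad:
            gp = np.pad(g, ((pad, pad), (pad, pad), (0, 0)))
            dx = np.zeros_like(x.data)
            for di in range(k):
                for dj in range(k):
                    dx += gp[di:di + L1, dj:dj + L2] @ w.data[:, :, k - 1 - di, k - 1 - dj]
            _accum(x, dx)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# normalization / softmax / losses

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def bwd(g):
        _accum(gamma, _sum_to(g * xhat, gamma.data.shape))
        _accum(beta, _sum_to(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            dx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            _accum(x, dx)
    out._backward = bwd
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each channel over all spatial axes (batch-norm at batch 1).

    x: (..., C); gamma/beta: (C,).  Statistics are computed over every axis
    but the last.
    """
    axes = tuple(range(x.data.ndim - 1))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    n = x.data.size // x.data.shape[-1]

    def bwd(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gamma.data
            dx = inv * (gh - gh.mean(axis=axes, keepdims=True)
                        - xhat * (gh * xhat).sum(axis=axes, keepdims=True) / n)
            _accum(x, dx)
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(x, y * (g - dot))
    out._backward = bwd
    return out


def masked_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over entries with label >= 0.

    logits: (N, K); labels: int array (N,), -1 marks ignored entries.
    Returns 0 (constant) if no entry is valid.
    """
    labels = np.asarray(labels).reshape(-1)
    valid = labels >= 0
    n = int(valid.sum())
    if n == 0:
        return Tensor(np.zeros((), dtype=logits.data.dtype))
    lv = logits.data[valid]
    z = lv - lv.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1)) + lv.max(axis=-1)
    picked = lv[np.arange(n), labels[valid]]
    out = Tensor(np.asarray((lse - picked).mean(), dtype=logits.data.dtype),
                 parents=(logits,))

    def bwd(g):
        if not logits.requires_grad:
            return
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        p[np.arange(n), labels[valid]] -= 1.0
        full = np.zeros_like(logits.data)
        full[valid] = p * (g / n)
        _accum(logits, full)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with bias correction and optional global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale_f = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale_f
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
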