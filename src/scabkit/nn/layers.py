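"""Layers for the antibody network: convolutional residual blocks, layer norm,
and a transformer encoder block with attention capture.

Parameters live in a lightweight ``Module`` tree; ``named_parameters`` gives
stable dotted paths used for checkpoint (de)serialization.
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor

DTYPE = np.float32


def _param(arr) -> Tensor:
    return Tensor(np.asarray(arr, dtype=DTYPE), requires_grad=True)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = _param(rng.normal(0.0, std, size=(cout, cin)))
        self.b = _param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return core.linear(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k))
        self.w = _param(rng.normal(0.0, std, size=(cout, cin, k)))
        self.b = _param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv1d(x, self.w, self.b)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = _param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = _param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return core.layer_norm(x, self.gamma, self.beta)


class InstanceNorm(Module):
    """Per-channel normalization over spatial axes (batch norm at batch 1)."""

    def __init__(self, dim: int):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return core.instance_norm(x, self.gamma, self.beta)


class _Identity(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x


def _make_norm(kind: str, dim: int) -> Module:
    if kind == "layer":
        return LayerNorm(dim)
    if kind == "instance":
        return InstanceNorm(dim)
    if kind == "none":
        return _Identity()
    raise ValueError(f"unknown norm kind: {kind!r}")


class ResBlock1d(Module):
    """Pre-activation residual block: x + conv(relu(norm(conv(relu(norm(x))))))."""

    def __init__(self, ch: int, k: int, rng: np.random.Generator, norm: str = "layer"):
        self.norm1 = _make_norm(norm, ch)
        self.conv1 = Conv1d(ch, ch, k, rng)
        self.norm2 = _make_norm(norm, ch)
        self.conv2 = Conv1d(ch, ch, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(core.relu(self.norm1(x)))
        h = self.conv2(core.relu(self.norm2(h)))
        return core.add(x, h)


class ResBlock2d(Module):
    def __init__(self, ch: int, k: int, rng: np.random.Generator, norm: str = "layer"):
        self.norm1 = _make_norm(norm, ch)
        self.conv1 = Conv2d(ch, ch, k, rng)
        self.norm2 = _make_norm(norm, ch)
        self.conv2 = Conv2d(ch, ch, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(core.relu(self.norm1(x)))
        h = self.conv2(core.relu(self.norm2(h)))
        return core.add(x, h)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if d_model % heads:
            raise ValueError("d_model must be divisible by the number of heads")
        self.heads = heads
        self.d_head = d_model // heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None  # (heads, L, L)

    def __call__(self, x: Tensor) -> Tensor:
        L, d = x.data.shape
        qkv = self.qkv(x)                                   # (L, 3d)
        qkv = core.reshape(qkv, (L, 3, self.heads, self.d_head))
        qkv = core.transpose(qkv, (1, 2, 0, 3))             # (3, H, L, dh)
        q = _take_first_axis(qkv, 0)
        k = _take_first_axis(qkv, 1)
        v = _take_first_axis(qkv, 2)
        scores = core.scale(core.matmul(q, core.transpose(k, (0, 2, 1))),
                            1.0 / np.sqrt(self.d_head))     # (H, L, L)
        attn = core.softmax(scores, axis=-1)
        self.last_attention = attn.data.copy()
        ctx = core.matmul(attn, v)                          # (H, L, dh)
        ctx = core.reshape(core.transpose(ctx, (1, 0, 2)), (L, d))
        return self.proj(ctx)


def _take_first_axis(t: Tensor, idx: int) -> Tensor:
    out = Tensor(t.data[idx], parents=(t,))

    def bwd(g):
        full = np.zeros_like(t.data)
        full[idx] = g
        core._accum(t, full)
    out._backward = bwd
    return out


class TransformerEncoderLayer(Module):
    """Post-norm transformer encoder block (self-attention + feedforward)."""

    def __init__(self, d_model: int, heads: int, ff_dim: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(core.add(x, self.attn(x)))
        h = self.ff2(core.relu(self.ff1(x)))
        return self.ln2(core.add(x, h))

    @property
    def last_attention(self):
        return self.attn.last_attention
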