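"""Neural building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "Embedding", "FeedForward", "SelfAttention", "TransformerLayer"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        seen: set[int] = set()
        for name, value in vars(self).items():
            for sub, p in _collect_named(value, f"{prefix}{name}"):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append((sub, p))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, name):
    if isinstance(value, Parameter):
        yield name, value
    elif isinstance(value, Module):
        for sub, p in value.named_parameters(prefix=name + "."):
            yield sub, p
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{name}.{i}")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        self.table = Parameter(rng.normal(0.0, scale, size=(n_rows, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table.gather_rows(idx)


class FeedForward(Module):
    """Position-wise FFN: Linear -> GELU -> Linear."""

    def __init__(self, dim: int, inner_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, inner_dim, rng)
        self.fc2 = Linear(inner_dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def split_heads(x: Tensor, n_heads: int) -> Tensor:
    """(..., L, d) -> (..., h, L, d_k)"""
    *lead, L, d = x.shape
    d_k = d // n_heads
    return x.reshape(*lead, L, n_heads, d_k).swapaxes(-2, -3)


def merge_heads(x: Tensor) -> Tensor:
    """(..., h, L, d_k) -> (..., L, h*d_k)"""
    *lead, h, L, d_k = x.shape
    return x.swapaxes(-2, -3).reshape(*lead, L, h * d_k)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
    """q: (..., h, Lq, d_k); k, v: (..., h, Lk, d_k); key_mask True = padding."""
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if key_mask is not None:
        mask = key_mask[..., None, None, :]  # broadcast over heads and queries
        mask = np.broadcast_to(mask, scores.shape)
        scores = scores.masked_fill(mask, -1e9)
    return scores.softmax(axis=-1) @ v


class SelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        d = x.shape[-1]
        qkv = self.qkv(x)
        q, k, v = qkv[..., :d], qkv[..., d : 2 * d], qkv[..., 2 * d :]
        q, k, v = (split_heads(t, self.n_heads) for t in (q, k, v))
        return self.out(merge_heads(scaled_dot_attention(q, k, v, key_mask)))


class TransformerLayer(Module):
    """Pre-norm encoder layer used by the tiny text backbone."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, 4 * dim, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), key_mask)
        return x + self.ffn(self.ln2(x))
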