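"""Gated cross-attention fusion of structured-token and text-token streams.

The structured stream is ``[cls] + categorical tokens + numeric tokens``; each
fusion block adds a pre-norm feed-forward term and a gated cross-attention
term scaled by a learnable fusion coefficient:

    X_out = X + FFN(LN(X)) + lambda * GCA(X, H_text)

GCA queries come from the normalized structured tokens, keys/values from the
normalized text tokens, and the attention output is gated elementwise by
``sigmoid(W_g [X ; pool(H_text)])`` where pool is a masked mean over text
positions. "Bidirectional" mode runs a text-query pass first whose output
serves as the key/value source of the structured-query pass; only the
structured stream feeds the classifier.
"""

from __future__ import annotations

import numpy as np

from .encoders import (
    CategoricalEmbedder,
    EncodedBatch,
    HashTokenizer,
    NumericalEmbedder,
    TextProjector,
    TinyTextBackbone,
)
from .nn import FeedForward, LayerNorm, Linear, Module, Parameter, Tensor, concat
from .nn.layers import merge_heads, scaled_dot_attention, split_heads

__all__ = ["GCALayer", "FusionBlock", "FusionModel", "masked_mean"]


def masked_mean(h: Tensor, pad_mask: np.ndarray | None) -> Tensor:
    """Mean over the sequence axis, ignoring padded positions."""
    if pad_mask is None:
        return h.mean(axis=-2)
    weights = (~np.asarray(pad_mask, dtype=bool)).astype(float)
    counts = weights.sum(axis=-1, keepdims=True)
    counts = np.maximum(counts, 1.0)
    return (h * Tensor(weights[..., None])).sum(axis=-2) * Tensor(1.0 / counts)


class GCALayer(Module):
    """Single-direction gated cross-attention."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.ln_q = LayerNorm(dim)
        self.ln_kv = LayerNorm(dim)
        self.w_q = Linear(dim, dim, rng, bias=False)
        self.w_kv = Linear(dim, 2 * dim, rng, bias=False)
        self.w_g = Linear(2 * dim, dim, rng, bias=False)

    def __call__(self, x: Tensor, h: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        d = self.dim
        q = split_heads(self.w_q(self.ln_q(x)), self.n_heads)
        kv = self.w_kv(self.ln_kv(h))
        k = split_heads(kv[..., :d], self.n_heads)
        v = split_heads(kv[..., d:], self.n_heads)
        attended = merge_heads(scaled_dot_attention(q, k, v, key_mask))

        pooled = masked_mean(h, key_mask)  # (..., d)
        Lx = x.shape[-2]
        pooled_row = pooled.reshape(*pooled.shape[:-1], 1, pooled.shape[-1])
        pooled_b = pooled_row * Tensor(np.ones((Lx, 1)))  # broadcast to every row of x
        gate = self.w_g(concat([x, pooled_b], axis=-1)).sigmoid()
        return attended * gate


class FusionBlock(Module):
    """Residual block: identity + pre-norm FFN + lambda-scaled GCA."""

    def __init__(self, dim: int, n_heads: int, ffn_mult: int, rng: np.random.Generator,
                 bidirectional: bool = True, lambda_init: float = 1.0):
        self.ln = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult * dim, rng)
        self.gca = GCALayer(dim, n_heads, rng)
        self.fusion_coef = Parameter(np.array(lambda_init))
        self.bidirectional = bidirectional
        if bidirectional:
            self.gca_text = GCALayer(dim, n_heads, rng)
            self.fusion_coef_text = Parameter(np.array(lambda_init))

    def __call__(self, x: Tensor, h_text: Tensor, text_mask: np.ndarray | None = None,
                 use_gca: bool = True) -> Tensor:
        out = x + self.ffn(self.ln(x))
        if not use_gca:
            return out
        h = h_text
        if self.bidirectional:
            h = h_text + self.fusion_coef_text * self.gca_text(h_text, x, None)
        return out + self.fusion_coef * self.gca(x, h, text_mask)


class FusionModel(Module):
    """Full classifier: encoders -> stacked fusion blocks -> affine head.

    ``forward`` returns (logits, x_cls, h_cls_text); the pooled vectors feed
    the contrastive projection head downstream.
    """

    def __init__(self, cardinalities: list[int], n_numeric: int, *, dim: int = 64,
                 n_blocks: int = 2, n_heads: int = 4, ffn_mult: int = 4,
                 d_text: int = 32, backbone_layers: int = 1, backbone_heads: int = 4,
                 vocab_size: int = 512, max_len: int = 256, bidirectional: bool = True,
                 lambda_init: float = 1.0, backbone_trainable: bool = False,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.cat_embedder = CategoricalEmbedder(cardinalities, dim, rng)
        self.num_embedder = NumericalEmbedder(n_numeric, dim, rng)
        self.cls_token = Parameter(rng.normal(0.0, 0.02, size=(1, dim)))
        self.backbone = TinyTextBackbone(
            vocab_size=vocab_size, hidden=d_text, n_layers=backbone_layers,
            n_heads=backbone_heads, max_len=max_len, seed=seed + 1,
            trainable=backbone_trainable,
        )
        self.tokenizer = HashTokenizer(vocab_size=vocab_size, max_len=max_len)
        self.projector = TextProjector(d_text, dim, rng)
        self.blocks = [
            FusionBlock(dim, n_heads, ffn_mult, rng, bidirectional=bidirectional,
                        lambda_init=lambda_init)
            for _ in range(n_blocks)
        ]
        self.classifier = Linear(dim, 2, rng)

    def encode_structured(self, batch: EncodedBatch) -> Tensor:
        cat_tok = self.cat_embedder(batch.cat_idx)  # (B, kc, d)
        num_tok = self.num_embedder(batch.num_values)  # (B, kn, d)
        B = len(batch)
        cls = self.cls_token * Tensor(np.ones((B, 1, 1)))  # (B, 1, d)
        return concat([cls, cat_tok, num_tok], axis=1)

    def encode_text(self, batch: EncodedBatch) -> Tensor:
        hidden = self.backbone(batch.text_ids, batch.text_mask)
        return self.projector(hidden)

    def forward(self, batch: EncodedBatch, use_gca: bool = True):
        x = self.encode_structured(batch)
        h_text = self.encode_text(batch)
        for block in self.blocks:
            x = block(x, h_text, batch.text_mask, use_gca=use_gca)
        x_cls = x[:, 0, :]
        h_cls_text = h_text[:, 0, :]
        logits = self.classifier(x_cls)
        return logits, x_cls, h_cls_text

    __call__ = forward
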