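"""Modality encoders.

* Categorical fields share one embedding table addressed through per-field
  offsets, so distinct (field, category) pairs can never collide; each field
  reserves index 0 for an unknown/missing slot.
* Numeric fields use a learnable per-field affine lift: ``w_j * x_j + b_j``
  broadcasting the scalar over the embedding width.
* Text goes through a tokenizer, a backbone producing per-token hidden states,
  and a projection layer ``LayerNorm(GELU(W_p h + b_p))`` aligning widths.

The shipped backbone is a small seeded transformer (``tiny-test``); the config
keeps a selector so a pretrained encoder can be slotted in where available.
"""

from __future__ import annotations

import re
import zlib

import numpy as np

from .nn import Embedding, LayerNorm, Linear, Module, Parameter, Tensor, TransformerLayer
from .schema import MISSING, FeatureSchema, PatientRecord

__all__ = [
    "field_offset",
    "CategoricalEmbedder",
    "NumericalEmbedder",
    "HashTokenizer",
    "TinyTextBackbone",
    "TextProjector",
    "StructuredTokenizer",
    "EncodedBatch",
]


def field_offset(field_index: int, cardinalities: list[int]) -> int:
    """Offset of field i into the shared table: sum of (c_j + 1) for j < i.

    The +1 reserves one unknown/missing slot per field.
    """
    if not 0 <= field_index < len(cardinalities):
        raise IndexError(f"field index {field_index} out of range")
    return int(sum(c + 1 for c in cardinalities[:field_index]))


class OutOfVocabularyError(ValueError):
    pass


class CategoricalEmbedder(Module):
    """Shared embedding table with collision-free per-field offsets."""

    def __init__(self, cardinalities: list[int], dim: int, rng: np.random.Generator):
        if any(c < 2 for c in cardinalities):
            raise ValueError("every cardinality must be >= 2")
        self.cardinalities = list(cardinalities)
        self.offsets = np.array(
            [field_offset(i, self.cardinalities) for i in range(len(cardinalities))]
        )
        self.n_rows = int(sum(c + 1 for c in cardinalities))
        self.dim = dim
        self.table = Parameter(rng.normal(0.0, 0.02, size=(self.n_rows, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        """indices: (..., k) per-field within-field indices, 0 = unknown slot."""
        indices = np.asarray(indices, dtype=int)
        limits = np.array(self.cardinalities) + 1
        if np.any(indices < 0) or np.any(indices >= limits):
            raise OutOfVocabularyError("categorical index outside [0, c_i + 1)")
        return self.table.gather_rows(indices + self.offsets)


class NumericalEmbedder(Module):
    """Per-field learnable affine lift of a standardized scalar to width d."""

    def __init__(self, n_fields: int, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_fields, dim)))
        self.bias = Parameter(np.zeros((n_fields, dim)))

    def __call__(self, values: np.ndarray) -> Tensor:
        """values: (..., n_fields) standardized scalars -> (..., n_fields, dim)."""
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("numeric embedder requires finite inputs")
        x = Tensor(values[..., None])
        return self.weight * x + self.bias


PAD_ID = 0
CLS_ID = 1
_TOKEN_RE = re.compile(r"[a-z0-9]+")


class HashTokenizer:
    """Deterministic word-level tokenizer hashing tokens into a fixed vocab.

    IDs 0 and 1 are reserved for padding and the classification position.
    Empty text maps to the bare classification token (logged by callers).
    """

    def __init__(self, vocab_size: int = 512, max_len: int = 256):
        if vocab_size < 8:
            raise ValueError("vocab too small")
        self.vocab_size = vocab_size
        self.max_len = max_len

    def token_id(self, token: str) -> int:
        return 2 + zlib.crc32(token.encode()) % (self.vocab_size - 2)

    def encode(self, text: str) -> list[int]:
        words = _TOKEN_RE.findall(text.lower())
        ids = [CLS_ID] + [self.token_id(w) for w in words]
        return ids[: self.max_len]

    def encode_batch(self, texts: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Returns (ids, pad_mask); pad_mask True marks padding positions."""
        encoded = [self.encode(t) for t in texts]
        width = max(len(e) for e in encoded)
        ids = np.full((len(texts), width), PAD_ID, dtype=int)
        mask = np.ones((len(texts), width), dtype=bool)
        for i, e in enumerate(encoded):
            ids[i, : len(e)] = e
            mask[i, : len(e)] = False
        return ids, mask


class TinyTextBackbone(Module):
    """Small seeded transformer encoder satisfying the backbone contract.

    Deterministic in evaluation mode; output row count equals input token
    count. Frozen by default (``trainable=False``) — the projection layer and
    downstream attention remain trainable either way.
    """

    def __init__(self, vocab_size: int = 512, hidden: int = 32, n_layers: int = 1,
                 n_heads: int = 4, max_len: int = 256, seed: int = 0,
                 trainable: bool = False):
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.max_len = max_len
        self.trainable = trainable
        self.tok_emb = Embedding(vocab_size, hidden, rng)
        self.pos_emb = Embedding(max_len, hidden, rng)
        self.layers = [TransformerLayer(hidden, n_heads, rng) for _ in range(n_layers)]
        self.ln_out = LayerNorm(hidden)
        if not trainable:
            for p in self.parameters():
                p.requires_grad = False

    def __call__(self, ids: np.ndarray, pad_mask: np.ndarray | None = None) -> Tensor:
        ids = np.asarray(ids, dtype=int)
        L = ids.shape[-1]
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        h = self.tok_emb(ids) + self.pos_emb(np.arange(L))
        for layer in self.layers:
            h = layer(h, pad_mask)
        return self.ln_out(h)


class TextProjector(Module):
    """Width alignment: LayerNorm(GELU(W_p h + b_p)) applied row-wise."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.proj = Linear(d_in, d_out, rng)
        self.ln = LayerNorm(d_out)

    def __call__(self, hidden: Tensor) -> Tensor:
        return self.ln(self.proj(hidden).gelu())


class EncodedBatch:
    """Model-ready batch: category indices, standardized numerics, token ids."""

    def __init__(self, cat_idx: np.ndarray, num_values: np.ndarray,
                 text_ids: np.ndarray, text_mask: np.ndarray, labels: np.ndarray):
        self.cat_idx = cat_idx
        self.num_values = num_values
        self.text_ids = text_ids
        self.text_mask = text_mask
        self.labels = labels

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "EncodedBatch":
        # re-trim text padding to the subset's longest sequence
        ids, mask = self.text_ids[idx], self.text_mask[idx]
        keep = int((~mask).sum(axis=1).max())
        return EncodedBatch(
            self.cat_idx[idx], self.num_values[idx], ids[:, :keep], mask[:, :keep],
            self.labels[idx],
        )


class StructuredTokenizer:
    """Maps imputed records to category indices + standardized numerics."""

    def __init__(self, schema: FeatureSchema):
        self.schema = schema

    def encode_categorical(self, record: PatientRecord) -> np.ndarray:
        idx = []
        for f in self.schema.categorical_fields:
            v = record.values.get(f.name, MISSING)
            if v is MISSING:
                idx.append(0)  # field's reserved unknown slot
            elif v in f.categories:
                idx.append(1 + f.categories.index(v))
            else:
                raise OutOfVocabularyError(f"field {f.name!r}: unknown category {v!r}")
        return np.array(idx, dtype=int)

    def encode_batch(self, records, standardizer, tokenizer: HashTokenizer,
                     text_units: list[str] | None = None) -> EncodedBatch:
        units = text_units if text_units is not None else list(self.schema.text_units)
        cat = np.stack([self.encode_categorical(r) for r in records])
        num = np.stack([standardizer.transform_record(r) for r in records])
        texts = [" ".join(r.text.get(u, "") for u in units) for r in records]
        ids, mask = tokenizer.encode_batch(texts)
        labels = np.array([r.label for r in records], dtype=int)
        return EncodedBatch(cat, num, ids, mask, labels)
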