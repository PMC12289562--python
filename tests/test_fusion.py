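"""Gated cross-attention and residual fusion: oracles, identities, invariants."""

import numpy as np
import pytest
from scipy.special import erf, expit

from emrfuse.encoders import EncodedBatch, HashTokenizer, StructuredTokenizer
from emrfuse.fusion import FusionBlock, FusionModel, GCALayer, masked_mean
from emrfuse.nn import Tensor
from emrfuse.schema import Standardizer

from conftest import make_record


# --------------------------- independent oracles ---------------------------

def oracle_layernorm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def oracle_gelu(x):
    return 0.5 * x * (1 + erf(x / np.sqrt(2)))


def oracle_gca(layer: GCALayer, X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Brute-force single-example GCA: explicit per-head softmax/weighted sums."""
    d, h = layer.dim, layer.n_heads
    dk = d // h
    Xn = oracle_layernorm(X, layer.ln_q.gamma.data, layer.ln_q.beta.data)
    Hn = oracle_layernorm(H, layer.ln_kv.gamma.data, layer.ln_kv.beta.data)
    Q = Xn @ layer.w_q.weight.data
    KV = Hn @ layer.w_kv.weight.data
    K, V = KV[:, :d], KV[:, d:]
    attended = np.zeros_like(Q)
    for head in range(h):
        sl = slice(head * dk, (head + 1) * dk)
        q, k, v = Q[:, sl], K[:, sl], V[:, sl]
        scores = q @ k.T / np.sqrt(dk)
        weights = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights /= weights.sum(axis=1, keepdims=True)
        attended[:, sl] = weights @ v
    pooled = H.mean(axis=0)
    gate = expit(
        np.concatenate([X, np.tile(pooled, (X.shape[0], 1))], axis=1)
        @ layer.w_g.weight.data
    )
    return attended * gate


# ------------------------------- GCA layer ---------------------------------

class TestGCA:
    @pytest.fixture
    def layer(self, rng):
        return GCALayer(dim=8, n_heads=2, rng=rng)

    def test_single_text_token_attention_is_identity_weight(self, layer, rng):
        # l = 1: every attention row is the single value vector, gated
        X = rng.normal(size=(3, 8))
        H = rng.normal(size=(1, 8))
        out = layer(Tensor(X), Tensor(H)).data
        np.testing.assert_allclose(out, oracle_gca(layer, X, H), atol=1e-6)
        # attention contributes the same V row to every query
        d = layer.dim
        Hn = oracle_layernorm(H, layer.ln_kv.gamma.data, layer.ln_kv.beta.data)
        V = (Hn @ layer.w_kv.weight.data)[:, d:]
        gate = out / np.broadcast_to(V, out.shape)
        assert np.all((gate > 0) & (gate < 1))

    def test_zero_gate_weights_give_half(self, layer, rng):
        layer.w_g.weight.data = np.zeros_like(layer.w_g.weight.data)
        X, H = rng.normal(size=(2, 8)), rng.normal(size=(3, 8))
        gated = layer(Tensor(X), Tensor(H)).data
        # sigma(0) = 0.5 everywhere -> output is exactly half the ungated attention
        ungated = oracle_gca(layer, X, H) / 0.5  # oracle gate is the constant 0.5
        np.testing.assert_allclose(gated, 0.5 * ungated, atol=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        layer = GCALayer(dim=6, n_heads=2, rng=rng)
        # small integer-ish weights for a transparent oracle
        layer.w_q.weight.data = rng.integers(-2, 3, size=(6, 6)).astype(float)
        layer.w_kv.weight.data = rng.integers(-2, 3, size=(6, 12)).astype(float)
        layer.w_g.weight.data = rng.integers(-2, 3, size=(12, 6)).astype(float)
        X = rng.normal(size=(2, 6))
        H = rng.normal(size=(3, 6))
        out = layer(Tensor(X), Tensor(H)).data
        np.testing.assert_allclose(out, oracle_gca(layer, X, H), atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        from emrfuse.nn.layers import scaled_dot_attention, split_heads

        q = split_heads(Tensor(rng.normal(size=(2, 5, 8))), 2)
        k = split_heads(Tensor(rng.normal(size=(2, 7, 8))), 2)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(4))
        rows = scores.softmax(axis=-1).data
        np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(rows >= 0)

    def test_gate_strictly_in_unit_interval(self, layer, rng):
        X = rng.normal(scale=5.0, size=(4, 8))
        H = rng.normal(scale=5.0, size=(6, 8))
        pooled = masked_mean(Tensor(H), None).data
        pre = np.concatenate([X, np.tile(pooled, (4, 1))], axis=1) @ layer.w_g.weight.data
        gate = expit(pre)
        assert np.all((gate > 0) & (gate < 1))

    def test_width_mismatch_raises(self, layer, rng):
        with pytest.raises(ValueError):
            layer(Tensor(rng.normal(size=(2, 8))), Tensor(rng.normal(size=(3, 6))))

    def test_masked_positions_ignored(self, layer, rng):
        X = rng.normal(size=(1, 2, 8))
        H = rng.normal(size=(1, 4, 8))
        mask = np.array([[False, False, True, True]])
        out_masked = layer(Tensor(X), Tensor(H), mask).data
        out_trunc = layer(Tensor(X), Tensor(H[:, :2])).data
        # identical attention over the unmasked prefix; gate differs only via pooling
        # so compare with the same pooled gate by masking the pool too
        np.testing.assert_allclose(out_masked, out_trunc, atol=1e-6)


# ------------------------------ fusion block --------------------------------

class TestFusionBlock:
    def make_block(self, rng, dim=8, bidirectional=False):
        return FusionBlock(dim, n_heads=2, ffn_mult=2, rng=rng,
                           bidirectional=bidirectional)

    def test_identity_when_lambda_and_ffn_zero(self, rng):
        block = self.make_block(rng)
        block.fusion_coef.data = np.array(0.0)
        block.ffn.fc2.weight.data *= 0.0
        block.ffn.fc2.bias.data *= 0.0
        X = rng.normal(size=(3, 8))
        out = block(Tensor(X), Tensor(rng.normal(size=(4, 8)))).data
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_lambda_zero_severs_text_path(self, rng):
        block = self.make_block(rng)
        block.fusion_coef.data = np.array(0.0)
        X = Tensor(rng.normal(size=(3, 8)))
        out1 = block(X, Tensor(rng.normal(size=(4, 8)))).data
        out2 = block(X, Tensor(rng.normal(size=(6, 8)))).data
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_three_term_sum_oracle(self, rng):
        block = self.make_block(rng)
        X = rng.normal(size=(3, 8))
        H = rng.normal(size=(4, 8))
        out = block(Tensor(X), Tensor(H)).data
        # term-by-term oracle
        ln_x = oracle_layernorm(X, block.ln.gamma.data, block.ln.beta.data)
        ffn = oracle_gelu(ln_x @ block.ffn.fc1.weight.data + block.ffn.fc1.bias.data)
        ffn = ffn @ block.ffn.fc2.weight.data + block.ffn.fc2.bias.data
        lam = float(block.fusion_coef.data)
        expected = X + ffn + lam * oracle_gca(block.gca, X, H)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_shape_preserved_through_stack(self, rng):
        blocks = [self.make_block(rng, bidirectional=True) for _ in range(3)]
        X = Tensor(rng.normal(size=(2, 5, 8)))
        H = Tensor(rng.normal(size=(2, 7, 8)))
        for b in blocks:
            X = b(X, H)
        assert X.shape == (2, 5, 8)

    def test_cross_modal_sensitivity(self, rng):
        block = self.make_block(rng)
        X = Tensor(rng.normal(size=(3, 8)))
        out1 = block(X, Tensor(rng.normal(size=(4, 8)))).data
        out2 = block(X, Tensor(rng.normal(size=(4, 8)))).data
        assert not np.allclose(out1, out2)


# ------------------------------- full model ---------------------------------

def encode_records(schema, records, model):
    std = Standardizer.fit(records, schema)
    st_tok = StructuredTokenizer(schema)
    return st_tok.encode_batch(records, std, model.tokenizer)


@pytest.fixture
def tiny_model(schema):
    return FusionModel(schema.cardinalities, len(schema.numeric_fields), dim=16,
                       n_blocks=2, n_heads=2, ffn_mult=2, d_text=16,
                       backbone_heads=2, max_len=32, seed=0)


class TestFusionModel:
    def test_structured_sequence_length(self, schema, tiny_model):
        records = [make_record(schema, rid=f"P{i}", wbc=8.0 + i) for i in range(2)]
        batch = encode_records(schema, records, tiny_model)
        x = tiny_model.encode_structured(batch)
        k_cat = len(schema.categorical_fields)
        k_num = len(schema.numeric_fields)
        assert x.shape == (2, k_cat + k_num + 1, 16)

    def test_duplicated_patients_identical_logits(self, schema, tiny_model):
        records = [make_record(schema, rid=f"P{i}") for i in range(3)]
        batch = encode_records(schema, records, tiny_model)
        logits, _, _ = tiny_model(batch)
        np.testing.assert_allclose(logits.data[0], logits.data[1], atol=1e-10)
        np.testing.assert_allclose(logits.data[0], logits.data[2], atol=1e-10)

    def test_ablated_model_ignores_text(self, schema, tiny_model):
        r1 = make_record(schema, rid="A")
        r2 = make_record(schema, rid="B")
        r2.text["ct_report"] = "completely different findings: mosaic attenuation"
        batch = encode_records(schema, [r1, r2], tiny_model)
        logits, _, _ = tiny_model(batch, use_gca=False)
        np.testing.assert_allclose(logits.data[0], logits.data[1], atol=1e-10)

    def test_full_model_sees_text(self, schema, tiny_model):
        r1 = make_record(schema, rid="A")
        r2 = make_record(schema, rid="B")
        r2.text["ct_report"] = "completely different findings: mosaic attenuation"
        batch = encode_records(schema, [r1, r2], tiny_model)
        logits, _, _ = tiny_model(batch, use_gca=True)
        assert not np.allclose(logits.data[0], logits.data[1])

    def test_extreme_inputs_finite(self, schema, tiny_model):
        records = [make_record(schema, rid=f"P{i}") for i in range(4)]
        batch = encode_records(schema, records, tiny_model)
        batch.num_values = np.array([[-10.0, 10.0, -10.0, 10.0, -10.0, 10.0, -10.0, 10.0, -10.0]] * 4)
        logits, x_cls, h_cls = tiny_model(batch)
        assert np.all(np.isfinite(logits.data))
        assert np.all(np.isfinite(x_cls.data))
        assert np.all(np.isfinite(h_cls.data))

    def test_deterministic_forward(self, schema, tiny_model):
        records = [make_record(schema, rid=f"P{i}", crp=5.0 * (i + 1)) for i in range(3)]
        batch = encode_records(schema, records, tiny_model)
        a, _, _ = tiny_model(batch)
        b, _, _ = tiny_model(batch)
        np.testing.assert_array_equal(a.data, b.data)

    def test_gradients_reach_all_encoder_parameters(self, schema, tiny_model):
        records = [make_record(schema, rid=f"P{i}", wbc=6.0 + 2 * i, label=i % 2)
                   for i in range(4)]
        batch = encode_records(schema, records, tiny_model)
        from emrfuse.objectives import ProjectionHead, contrastive_loss, cross_entropy

        head = ProjectionHead(16, 8, np.random.default_rng(1))
        logits, x_cls, h_cls = tiny_model(batch)
        loss = cross_entropy(logits, batch.labels) + 0.5 * contrastive_loss(
            head(x_cls), head(h_cls), 0.07
        )
        loss.backward()
        for target in (tiny_model.cat_embedder.table, tiny_model.num_embedder.weight,
                       tiny_model.num_embedder.bias, tiny_model.projector.proj.weight):
            assert target.grad is not None and np.any(target.grad != 0)

    def test_empty_batch_rejected(self, schema, tiny_model):
        records = [make_record(schema, rid="P0")]
        batch = encode_records(schema, records, tiny_model)
        with pytest.raises((ValueError, IndexError)):
            batch.subset(np.array([], dtype=int))
            tiny_model(batch.subset(np.array([], dtype=int)))
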