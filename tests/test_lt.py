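"""Long-term transformer: attention oracle, block wiring, classification."""

import numpy as np
import pytest

import surgest.nn as nn
from surgest.lt import (
    AttentionParams,
    LTModel,
    SelfAttention,
    TransformerBlock,
    TransformerConfig,
    classify_clip,
    scaled_dot_product_self_attention,
    train_lt,
)
from surgest.st import TrainConfig


def brute_force_attention(tokens, params):
    """Independent double-loop oracle with explicit exponentials."""
    tokens = np.asarray(tokens, dtype=np.float64)
    q = tokens @ params.wq.astype(np.float64)
    k = tokens @ params.wk.astype(np.float64)
    v = tokens @ params.wv.astype(np.float64)
    n, dk = q.shape
    out = np.zeros_like(v)
    for i in range(n):
        logits = [float(np.dot(q[i], k[j])) / np.sqrt(dk) for j in range(n)]
        exps = [np.exp(l - max(logits)) for l in logits]
        z = sum(exps)
        for j in range(n):
            out[i] += (exps[j] / z) * v[j]
    return out


def random_params(rng, d_in, d_k):
    return AttentionParams(*(rng.standard_normal((d_in, d_k)).astype(np.float32)
                             for _ in range(3)))


class TestAttention:
    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tokens = rng.standard_normal((8, 16)).astype(np.float32)
            params = random_params(rng, 16, 16)
            got = scaled_dot_product_self_attention(tokens, params)
            np.testing.assert_allclose(got, brute_force_attention(tokens, params),
                                       atol=1e-5)

    def test_single_token_attends_only_to_itself(self):
        rng = np.random.default_rng(1)
        tokens = rng.standard_normal((1, 4)).astype(np.float32)
        params = random_params(rng, 4, 4)
        out, w = scaled_dot_product_self_attention(tokens, params,
                                                   return_weights=True)
        np.testing.assert_allclose(w, [[1.0]], atol=1e-7)
        np.testing.assert_allclose(out, tokens @ params.wv, atol=1e-6)

    def test_identity_projections_orthonormal_tokens(self):
        """With identity Q/K/V and orthonormal tokens, each row's weights are
        softmax([1/sqrt(d_k), 0]) over self vs other."""
        tokens = np.eye(2, dtype=np.float32)
        eye = AttentionParams(np.eye(2), np.eye(2), np.eye(2))
        out, w = scaled_dot_product_self_attention(tokens, eye, return_weights=True)
        s = 1.0 / np.sqrt(2)
        expected_self = np.exp(s) / (np.exp(s) + 1.0)
        np.testing.assert_allclose(np.diag(w), expected_self, atol=1e-6)
        np.testing.assert_allclose(out, brute_force_attention(tokens, eye), atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tokens = rng.standard_normal((6, 8)).astype(np.float32) * 3
            _, w = scaled_dot_product_self_attention(
                tokens, random_params(rng, 8, 8), return_weights=True)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_non_finite_input_rejected(self):
        rng = np.random.default_rng(3)
        bad = np.full((2, 4), np.nan, dtype=np.float32)
        with pytest.raises(ValueError, match="finite"):
            scaled_dot_product_self_attention(bad, random_params(rng, 4, 4))

    def test_layer_gradients_match_finite_differences(self):
        from test_nn import directional_grad_check
        rng = np.random.default_rng(4)
        layer = SelfAttention(6, 6, rng)
        x = rng.standard_normal((2, 5, 6)).astype(np.float32)
        directional_grad_check(layer, x)


class TestTransformerBlock:
    def cfg(self, d=8):
        return TransformerConfig(n_classes=3, embedding_dim=16, ns=4,
                                 d_model=d, ff_width=12, mlp_hidden=8)

    def test_shape_preserved(self):
        rng = np.random.default_rng(0)
        block = TransformerBlock(self.cfg(), rng)
        for ns in (1, 4, 9):
            x = rng.standard_normal((2, ns, 8)).astype(np.float32)
            assert block.forward(x).shape == x.shape

    def test_output_tokens_are_layer_normalised(self):
        rng = np.random.default_rng(1)
        block = TransformerBlock(self.cfg(), rng)
        y = block.forward(rng.standard_normal((3, 4, 8)).astype(np.float32))
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.var(axis=-1), 1.0, atol=1e-3)

    def test_zero_weights_reduce_to_double_layernorm(self):
        rng = np.random.default_rng(2)
        block = TransformerBlock(self.cfg(), rng)
        for p in block.attn.parameters() + block.ff1.parameters() + block.ff2.parameters():
            p.value[...] = 0.0
        x = rng.standard_normal((2, 4, 8)).astype(np.float32)
        expected = block.ln2.forward(block.ln1.forward(x))
        np.testing.assert_allclose(block.forward(x), expected, atol=1e-6)

    def test_block_stack_is_permutation_equivariant(self):
        """No positional encoding: permuting tokens permutes outputs."""
        rng = np.random.default_rng(3)
        model = LTModel(TransformerConfig.tiny(3, embedding_dim=16, ns=5), seed=3)
        x = rng.standard_normal((1, 5, 16)).astype(np.float32)
        perm = np.array([3, 0, 4, 1, 2])
        out = model.transform_tokens(x)
        out_perm = model.transform_tokens(x[:, perm])
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-4)

    def test_gradients_match_finite_differences(self):
        from test_nn import directional_grad_check
        rng = np.random.default_rng(5)
        block = TransformerBlock(self.cfg(d=6), rng)
        x = rng.standard_normal((2, 3, 6)).astype(np.float32)
        directional_grad_check(block, x, rtol=5e-2)


class TestClipClassifier:
    def test_valid_distribution_and_token_contract(self):
        cfg = TransformerConfig.tiny(5, embedding_dim=16, ns=8)
        model = LTModel(cfg, seed=0)
        rng = np.random.default_rng(0)
        probs = classify_clip(rng.standard_normal((8, 16)).astype(np.float32), model)
        assert probs.shape == (5,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-5)
        with pytest.raises(ValueError, match="expected"):
            classify_clip(rng.standard_normal((7, 16)).astype(np.float32), model)

    def test_flatten_makes_classifier_order_sensitive(self):
        model = LTModel(TransformerConfig.tiny(4, embedding_dim=16, ns=6), seed=1)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 16)).astype(np.float32)
        p1 = classify_clip(x, model)
        p2 = classify_clip(x[::-1].copy(), model)
        assert not np.allclose(p1, p2)


class TestTrainLT:
    def data(self, rng, n=40, ns=4, d=8, g=3):
        y = rng.integers(0, g, n)
        x = rng.standard_normal((n, ns, d)).astype(np.float32) * 0.1
        # class-distinct mean offsets make the problem learnable
        for i in range(n):
            x[i] += y[i] * 1.0
        return x, y

    def cfg(self, **kw):
        defaults = dict(lt_epochs=20, lr_lt=1e-3, batch_size=10, seed=0)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_loss_decreases_and_beats_chance(self):
        rng = np.random.default_rng(0)
        x, y = self.data(rng)
        model = LTModel(TransformerConfig.tiny(3, embedding_dim=8, ns=4), seed=0)
        hist = train_lt(model, x, y, self.cfg())
        assert hist[-1]["loss"] < hist[0]["loss"]
        assert hist[-1]["accuracy"] > 1 / 3

    def test_zero_learning_rate_constant_history(self):
        rng = np.random.default_rng(1)
        x, y = self.data(rng, n=20)
        model = LTModel(TransformerConfig.tiny(3, embedding_dim=8, ns=4), seed=1)
        hist = train_lt(model, x, y, self.cfg(lr_lt=0.0, lt_epochs=3))
        losses = [h["loss"] for h in hist]
        assert max(losses) - min(losses) < 1e-6

    def test_fixed_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        x, y = self.data(rng, n=20)
        h1 = train_lt(LTModel(TransformerConfig.tiny(3, 8, 4), seed=2), x, y,
                      self.cfg(lt_epochs=4))
        h2 = train_lt(LTModel(TransformerConfig.tiny(3, 8, 4), seed=2), x, y,
                      self.cfg(lt_epochs=4))
        assert [h["loss"] for h in h1] == [h["loss"] for h in h2]

    def test_empty_set_rejected(self):
        model = LTModel(TransformerConfig.tiny(3, 8, 4), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_lt(model, np.zeros((0, 4, 8), dtype=np.float32),
                     np.zeros(0, dtype=int), self.cfg())


def test_embedding_sequence_file_round_trip(tmp_path):
    from surgest.lt import load_embedding_sequences, save_embedding_sequences
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 8, 16)).astype(np.float32)
    save_embedding_sequences(tmp_path / "emb.npy", x, {"trial": "t0"})
    back, meta = load_embedding_sequences(tmp_path / "emb.npy")
    np.testing.assert_array_equal(back, x)
    assert meta["trial"] == "t0" and meta["shape"] == [3, 8, 16]


def test_dk_must_equal_dmodel_for_residual():
    with pytest.raises(ValueError, match="d_k"):
        TransformerConfig(n_classes=2, d_model=8, d_k=4)
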