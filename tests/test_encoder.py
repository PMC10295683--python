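"""Mini self-attention encoder: functional oracles and stack contracts."""

import numpy as np
import pytest

from _oracles import attention_oracle, ffn_oracle
from ohcner.encoder import (
    EncoderConfig,
    MiniEncoder,
    ShapeError,
    multi_head_attention,
    pretrained_adapter,
    position_wise_ffn,
    scaled_dot_attention,
)


class TestScaledDotAttention:
    def test_single_position_weight_is_one(self, rng):
        Q = rng.normal(size=(1, 4))
        V = rng.normal(size=(1, 4))
        out, w = scaled_dot_attention(Q, Q, V, return_weights=True)
        assert np.allclose(w, [[1.0]])
        assert np.allclose(out, V)

    def test_identical_keys_share_weight(self, rng):
        K = np.tile(rng.normal(size=(1, 4)), (2, 1))
        Q = rng.normal(size=(2, 4))
        V = rng.normal(size=(2, 4))
        _, w = scaled_dot_attention(Q, K, V, return_weights=True)
        assert np.allclose(w, 0.5)

    def test_matches_per_position_oracle(self, rng):
        for _ in range(25):
            Q, K, V = (rng.normal(size=(4, 8)) for _ in range(3))
            out = scaled_dot_attention(Q, K, V)
            assert np.allclose(out, attention_oracle(Q, K, V), atol=1e-12)

    def test_rows_sum_to_one_under_mask(self, rng):
        Q, K, V = (rng.normal(size=(6, 4)) for _ in range(3))
        mask = np.array([True, True, True, True, False, False])
        _, w = scaled_dot_attention(Q, K, V, mask=mask, return_weights=True)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w[:, ~mask] == 0.0)

    def test_permuting_values_permutes_output(self, rng):
        """Linearity in V: fixed weights, permuted V rows."""
        Q = np.zeros((3, 4))  # uniform weights regardless of K
        K = rng.normal(size=(3, 4))
        V = rng.normal(size=(3, 4))
        perm = np.array([2, 0, 1])
        out1 = scaled_dot_attention(Q, K, V)
        out2 = scaled_dot_attention(Q, K[perm], V[perm])
        assert np.allclose(out1, out2)  # uniform rows: output is mean of V

    def test_all_masked_rejected(self, rng):
        Q = rng.normal(size=(2, 4))
        with pytest.raises(ShapeError, match="all-masked"):
            scaled_dot_attention(Q, Q, Q, mask=np.array([False, False]))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            scaled_dot_attention(rng.normal(size=(2, 4)),
                                 rng.normal(size=(2, 3)),
                                 rng.normal(size=(2, 4)))


class TestMultiHead:
    def test_single_head_identity_projection(self, rng):
        X = rng.normal(size=(5, 8))
        I = np.eye(8)
        out = multi_head_attention(X, I, I, I, np.eye(8), h=1)
        assert np.allclose(out, scaled_dot_attention(X, X, X))

    def test_output_shape(self, rng):
        X = rng.normal(size=(7, 8))
        W = [rng.normal(size=(8, 8)) for _ in range(4)]
        assert multi_head_attention(X, *W, h=2).shape == (7, 8)

    def test_two_heads_match_naive_loop(self, rng):
        X = rng.normal(size=(4, 8))
        Wq, Wk, Wv, Wo = (rng.normal(size=(8, 8)) for _ in range(4))
        out = multi_head_attention(X, Wq, Wk, Wv, Wo, h=2)
        Q, K, V = X @ Wq, X @ Wk, X @ Wv
        heads = []
        for i in range(2):
            sl = slice(i * 4, (i + 1) * 4)
            heads.append(attention_oracle(Q[:, sl], K[:, sl], V[:, sl]))
        assert np.allclose(out, np.concatenate(heads, axis=1) @ Wo, atol=1e-12)

    def test_indivisible_heads_rejected(self, rng):
        X = rng.normal(size=(4, 6))
        W = rng.normal(size=(6, 6))
        with pytest.raises(ShapeError, match="divisible"):
            multi_head_attention(X, W, W, W, W, h=4)


class TestFFN:
    def test_zero_first_layer_yields_bias(self, rng):
        Z = rng.normal(size=(3, 4))
        b2 = rng.normal(size=5)
        out = position_wise_ffn(Z, np.zeros((4, 6)), np.zeros(6),
                                rng.normal(size=(6, 5)), b2)
        assert np.allclose(out, np.tile(b2, (3, 1)))

    def test_negative_preactivation_contributes_nothing(self):
        Z = np.array([[1.0]])
        W1 = np.array([[-5.0, 2.0]])   # first hidden unit rectified to 0
        W2 = np.array([[10.0], [1.0]])
        out = position_wise_ffn(Z, W1, np.zeros(2), W2, np.zeros(1))
        assert np.allclose(out, [[2.0]])

    def test_matches_formula_oracle(self, rng):
        Z = rng.normal(size=(6, 8))
        W1, b1 = rng.normal(size=(8, 16)), rng.normal(size=16)
        W2, b2 = rng.normal(size=(16, 8)), rng.normal(size=8)
        assert np.allclose(position_wise_ffn(Z, W1, b1, W2, b2),
                           ffn_oracle(Z, W1, b1, W2, b2), atol=1e-12)


class TestEncoderStack:
    def make(self, layers=2, d=16, heads=2, vocab=50, seed=0):
        return MiniEncoder(EncoderConfig(vocab_size=vocab, d=d, heads=heads,
                                         layers=layers, max_len=64), seed=seed)

    def test_deterministic(self):
        enc = self.make()
        ids = [3, 7, 2, 9]
        a = enc.encode(ids).embeddings
        b = enc.encode(ids).embeddings
        assert np.array_equal(a, b)

    def test_padding_does_not_leak(self):
        enc = self.make()
        ids = [3, 7, 2, 9]
        plain = enc.encode(ids).embeddings
        padded_ids = ids + [0] * 12
        mask = np.array([True] * 4 + [False] * 12)
        padded = enc.encode(padded_ids, mask=mask).embeddings
        assert np.allclose(plain, padded[:4], atol=1e-12)

    def test_zero_layers_is_embedding_lookup(self):
        enc = self.make(layers=0)
        ids = [5, 1, 8]
        out = enc.encode(ids).embeddings
        assert np.allclose(out, enc.params["emb"].data[ids])

    def test_attention_rows_normalized(self):
        enc = self.make()
        res = enc.encode([3, 7, 2, 9, 4])
        assert len(res.attention) == 2
        for att in res.attention:
            assert att.shape == (2, 5, 5)
            assert np.allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_out_of_vocab_id_rejected(self):
        with pytest.raises(ValueError, match="out of vocabulary"):
            self.make().encode([999])


class TestAdapter:
    def test_wrapper_transparency(self):
        enc = MiniEncoder(EncoderConfig(vocab_size=30, d=16, heads=2,
                                        layers=1, max_len=32), seed=1)
        adapter = pretrained_adapter(enc, expected_dim=16)
        ids = np.array([4, 9, 2])
        assert np.allclose(adapter.forward(ids).data,
                           enc.forward(ids).data)

    def test_dimension_contract(self):
        enc = MiniEncoder(EncoderConfig(vocab_size=30, d=16, heads=2,
                                        layers=1, max_len=32))
        pretrained_adapter(enc, expected_dim=16)  # accepted
        with pytest.raises(ShapeError, match="dimension"):
            pretrained_adapter(enc, expected_dim=768)
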