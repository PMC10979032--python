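"""Sparse self-attention encoder and distillation blocks."""

import numpy as np
import pytest

from dtafusion import autodiff as ad
from dtafusion.autodiff import Tensor
from dtafusion.chem import build_drug_graph, parse_molecule
from dtafusion.encodings import (AttentionBiasSet, EdgePathTable, compute_spd,
                                 make_spatial_weights, build_bias_set)
from dtafusion.esc import (DistillBlock, ESCStack, SparseAttentionParams,
                           esc_forward, query_sparsity_scores,
                           select_top_queries, sparsepro_attention,
                           surviving_indices)


def zero_bias(n):
    return AttentionBiasSet(spatial=Tensor(np.zeros((n, n))),
                            edge=Tensor(np.zeros((n, n))))


def dense_attention_oracle(h, wq, wk, wv):
    q, k, v = h @ wq, h @ wk, h @ wv
    logits = q @ k.T / np.sqrt(h.shape[1])
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    a = e / e.sum(axis=1, keepdims=True)
    return a @ v


class TestSparsityScores:
    def test_identical_queries_score_equal(self, rng):
        q = np.tile(rng.normal(size=(1, 6)), (5, 1))
        k = rng.normal(size=(7, 6))
        s = query_sparsity_scores(q, k)
        assert np.ptp(s) < 1e-12

    def test_aligned_query_outscores_orthogonal(self):
        # keys along axes; one query aligned with a key, one orthogonal to all
        k = np.eye(4)[:2] * 5
        q = np.array([[5.0, 0, 0, 0], [0, 0, 0, 5.0]])
        s = query_sparsity_scores(q, k)
        assert s[0] > s[1]

    def test_matches_elementwise_recomputation(self, rng):
        q, k = rng.normal(size=(10, 8)), rng.normal(size=(10, 8))
        logits = q @ k.T / np.sqrt(8)
        expected = logits.max(axis=1) - logits.mean(axis=1)
        np.testing.assert_allclose(query_sparsity_scores(q, k), expected, atol=1e-12)

    def test_tie_break_prefers_lower_index(self):
        assert list(select_top_queries(np.array([1.0, 1.0, 1.0]), 2)) == [0, 1]


class TestSparseproAttention:
    def test_equals_dense_attention_when_all_selected(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 12))
            d = 8
            h = Tensor(rng.normal(size=(L, d)))
            p = SparseAttentionParams(d, top_s=L + 5, rng=rng)
            out = sparsepro_attention(h, zero_bias(L), p)
            oracle = dense_attention_oracle(h.data, p.w_q.data, p.w_k.data, p.w_v.data)
            assert np.max(np.abs(out.data - oracle)) < 1e-6

    def test_attention_rows_normalised(self, rng):
        # with identical keys and zero biases every selected output is the
        # mean value vector, which is only possible if rows sum to one
        d = 6
        h = Tensor(np.tile(rng.normal(size=(1, d)), (5, 1)))
        p = SparseAttentionParams(d, top_s=10, rng=rng)
        out = sparsepro_attention(h, zero_bias(5), p)
        v = h.data @ p.w_v.data
        np.testing.assert_allclose(out.data, np.tile(v.mean(axis=0), (5, 1)), atol=1e-10)

    def test_constant_logit_shift_leaves_output_unchanged(self, rng):
        L, d = 6, 8
        h = Tensor(rng.normal(size=(L, d)))
        p = SparseAttentionParams(d, top_s=2, rng=rng)
        out0 = sparsepro_attention(h, zero_bias(L), p)
        shifted = AttentionBiasSet(spatial=Tensor(np.full((L, L), 3.7)),
                                   edge=Tensor(np.zeros((L, L))))
        out1 = sparsepro_attention(h, shifted, p)
        np.testing.assert_allclose(out0.data, out1.data, atol=1e-10)

    def test_unselected_queries_emit_mean_value(self, rng):
        L, d = 8, 4
        h = Tensor(rng.normal(size=(L, d)))
        p = SparseAttentionParams(d, top_s=3, rng=rng)
        out = sparsepro_attention(h, zero_bias(L), p)
        sel = select_top_queries(
            query_sparsity_scores(h.data @ p.w_q.data, h.data @ p.w_k.data), 3)
        mean_v = (h.data @ p.w_v.data).mean(axis=0)
        for i in range(L):
            if i not in sel:
                np.testing.assert_allclose(out.data[i], mean_v, atol=1e-12)

    def test_nonfinite_input_rejected(self, rng):
        h = Tensor(np.full((3, 4), np.nan))
        p = SparseAttentionParams(4, top_s=3, rng=rng)
        with pytest.raises(ValueError):
            sparsepro_attention(h, zero_bias(3), p)


class TestDistill:
    def test_zero_input_zero_output(self, rng):
        blk = DistillBlock(4, rng)
        blk.bias.data[:] = 0
        out = blk(Tensor(np.zeros((6, 4))))
        np.testing.assert_array_equal(out.data, np.zeros((3, 4)))

    @pytest.mark.parametrize("L,expected", [(8, 4), (7, 4), (5, 3), (1, 1)])
    def test_node_count_halves_rounding_up(self, rng, L, expected):
        blk = DistillBlock(4, rng)
        assert blk(Tensor(rng.normal(size=(L, 4)))).data.shape == (expected, 4)

    def test_identity_kernel_reduces_to_strided_max(self, rng):
        """Centre-tap identity kernel + positive input: pooling of the input."""
        d = 2
        blk = DistillBlock(d, rng)
        blk.kernel.data[:] = 0
        blk.kernel.data[1] = np.eye(d)  # centre tap
        blk.bias.data[:] = 0
        x = np.array([[1.0, 2.0], [5.0, 1.0], [2.0, 9.0], [4.0, 4.0], [3.0, 8.0]])
        out = blk(Tensor(x))
        expected = np.array([[5.0, 2.0], [5.0, 9.0], [4.0, 8.0]])
        np.testing.assert_allclose(out.data, expected)

    def test_surviving_indices_are_pool_anchors(self):
        np.testing.assert_array_equal(surviving_indices(7), [0, 2, 4, 6])


class TestESCForward:
    def _stack_and_bias(self, smiles, seed, dim=8):
        g = build_drug_graph(parse_molecule(smiles))
        spd = compute_spd(g)
        rng = np.random.default_rng(seed)
        stack = ESCStack(dim, top_s=25, rng=rng)
        bias = build_bias_set(g, spd, make_spatial_weights(),
                              EdgePathTable.create())
        return g, bias, stack

    def test_deterministic(self):
        g, bias, stack = self._stack_and_bias("CC(=O)Oc1ccccc1C(=O)O", 1)
        a = esc_forward(g, bias, stack)
        b = esc_forward(g, bias, stack)
        np.testing.assert_array_equal(a.data, b.data)

    def test_single_atom_molecule(self):
        g, bias, stack = self._stack_and_bias("C", 2)
        out = esc_forward(g, bias, stack)
        assert out.data.shape == (8,)
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("smiles", ["C", "CCO", "c1ccccc1",
                                        "CC(=O)Oc1ccccc1C(=O)O",
                                        "OCCN1CCN(CCCN2c3ccccc3Sc3ccccc32)CC1"])
    def test_output_length_is_model_dim(self, smiles):
        g, bias, stack = self._stack_and_bias(smiles, 3, dim=8)
        assert esc_forward(g, bias, stack).data.shape == (8,)

    def test_gradients_reach_all_parameters(self):
        g, bias, stack = self._stack_and_bias("CCO", 4)
        out = esc_forward(g, bias, stack)
        ad.sum_(out).backward()
        for p in stack.parameters():
            assert p.grad is not None
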