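"""Slice attention: column-stochastic affinities and the residual gate."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msa3d import (SliceAttention, apply_attention, attention_mass,
                   attention_scores, fuse_views)
from msa3d.nn import Tensor

RNG = np.random.default_rng(0)


class TestAttentionScores:
    def test_identical_embeddings_give_uniform(self):
        emb = np.tile(RNG.standard_normal(8), (4, 1))
        a = attention_scores(emb)
        np.testing.assert_allclose(a, 0.25, atol=1e-12)

    def test_single_slice(self):
        np.testing.assert_array_equal(attention_scores(RNG.random((1, 8))),
                                      [[1.0]])

    def test_two_slice_closed_form(self):
        """Score gap of ln 3 in a column yields (0.25, 0.75)."""
        emb = np.array([[1.0, 0.0], [1.0 + np.log(3), 0.0]])
        a = attention_scores(emb)
        np.testing.assert_allclose(a[:, 0], [0.25, 0.75], atol=1e-12)

    def test_columns_sum_to_one_across_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(1, 33))
            a = attention_scores(rng.standard_normal((m, 8)) * 3)
            np.testing.assert_allclose(a.sum(axis=0), 1.0, atol=1e-6)
            assert (a > 0).all() and (a <= 1).all()

    def test_nonfinite_rejected(self):
        emb = np.ones((3, 8))
        emb[1, 2] = np.nan
        with pytest.raises(FloatingPointError):
            attention_scores(emb)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        """Permuting slices permutes A by (sigma, sigma) and outputs by sigma."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        emb = rng.standard_normal((m, 8))
        sigma = rng.permutation(m)
        a = attention_scores(emb)
        a_perm = attention_scores(emb[sigma])
        np.testing.assert_allclose(a_perm, a[np.ix_(sigma, sigma)], atol=1e-12)
        out = apply_attention(emb, a, beta=0.7)
        out_perm = apply_attention(emb[sigma], a_perm, beta=0.7)
        np.testing.assert_allclose(out_perm, out[sigma], atol=1e-12)


class TestApplyAttention:
    def test_zero_gate_is_bitwise_identity(self):
        emb = RNG.standard_normal((6, 8))
        a = attention_scores(emb)
        out = apply_attention(emb, a, beta=0.0)
        np.testing.assert_array_equal(out, emb)

    def test_single_slice_scales_by_one_plus_beta(self):
        emb = RNG.standard_normal((1, 8))
        out = apply_attention(emb, np.array([[1.0]]), beta=0.3)
        np.testing.assert_allclose(out, 1.3 * emb, atol=1e-12)

    def test_uniform_attention_adds_row_mean(self):
        emb = RNG.standard_normal((5, 8))
        a = np.full((5, 5), 1 / 5)
        out = apply_attention(emb, a, beta=1.0)
        np.testing.assert_allclose(out, emb.mean(axis=0) + emb, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_attention(RNG.random((4, 8)), np.eye(3), beta=1.0)


class TestFuseViews:
    def test_length_contract(self):
        out = fuse_views(np.zeros((3, 8)), np.zeros((4, 8)), np.zeros((3, 8)))
        assert out.shape == (80,)

    def test_zero_inputs(self):
        assert not fuse_views(np.zeros((2, 2)), np.zeros((2, 2)),
                              np.zeros((2, 2))).any()

    def test_concatenation_order(self):
        out = fuse_views([[1, 2]], [[3, 4]], [[5, 6]])
        np.testing.assert_array_equal(out, [1, 2, 3, 4, 5, 6])


class TestAttentionMass:
    def test_uniform_gives_m_over_n(self):
        a = np.full((8, 8), 1 / 8)
        assert attention_mass(a, {0, 3, 5}) == pytest.approx(3 / 8)

    def test_all_slices_give_one(self):
        a = attention_scores(RNG.standard_normal((6, 8)))
        assert attention_mass(a, set(range(6))) == pytest.approx(1.0)

    def test_repeated_column(self):
        a = np.tile([[0.7], [0.2], [0.1]], (1, 3))
        assert attention_mass(a, {0}) == pytest.approx(0.7)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            attention_mass(np.eye(3), set())


class TestSliceAttentionModule:
    def test_matches_reference_per_sample(self):
        """Batched autograd attention equals the array-level reference."""
        sam = SliceAttention()
        sam.beta.data = np.array([0.4], dtype=np.float32)
        emb = RNG.standard_normal((3, 5, 8)).astype(np.float32)
        out, attn = sam(Tensor(emb))
        for i in range(3):
            a_ref = attention_scores(emb[i])
            np.testing.assert_allclose(attn.data[i], a_ref, atol=1e-5)
            np.testing.assert_allclose(
                out.data[i], apply_attention(emb[i], a_ref, 0.4), atol=1e-5)

    def test_gate_initialised_to_zero_passthrough(self):
        sam = SliceAttention()
        emb = RNG.standard_normal((2, 4, 8)).astype(np.float32)
        out, _ = sam(Tensor(emb))
        np.testing.assert_array_equal(out.data, emb)
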