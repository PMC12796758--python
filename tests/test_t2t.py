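"""Oracle and property tests for the tokens-to-token embedding stage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nactformer._autodiff import Tensor, cross_entropy
from nactformer.t2t import (
    LocalGlobalAttention,
    MultiScaleConv,
    ScaleBank,
    SoftSplitConfig,
    TokensToTokenArm,
    TokensToTokenBlock,
    flatten_map,
    reshape_to_map,
    soft_split,
)


def naive_softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def naive_attention(x, wq, bq, wk, bk, wv, bv):
    """Direct matrix computation of softmax(QK^T/sqrt(d))V on one sequence."""
    q, k, v = x @ wq + bq, x @ wk + bk, x @ wv + bv
    scores = q @ k.T / np.sqrt(x.shape[-1])
    return naive_softmax(scores) @ v, naive_softmax(scores)


class TestReshape:
    def test_round_trip_is_identity(self, rng):
        tokens = Tensor(rng.normal(size=(2, 196, 8)))
        fmap = reshape_to_map(tokens, 14, 14)
        assert fmap.shape == (2, 8, 14, 14)
        back = flatten_map(fmap)
        assert np.array_equal(back.data, tokens.data)

    def test_mismatched_geometry_rejected(self, rng):
        with pytest.raises(ValueError, match="match"):
            reshape_to_map(Tensor(rng.normal(size=(1, 195, 8))), 14, 14)


class TestSoftSplit:
    def test_token_count_formula_14x14(self, rng):
        fmap = Tensor(rng.normal(size=(1, 4, 14, 14)))
        out = soft_split(fmap, SoftSplitConfig(3, 2, 1))
        assert out.shape == (1, 49, 36)  # 7 per axis, dimension 9·c

    def test_degenerate_overlap_equals_hard_split(self, rng):
        fmap = rng.normal(size=(1, 2, 8, 8))
        out = soft_split(Tensor(fmap), SoftSplitConfig(4, 4, 0)).data[0]
        hard = [
            fmap[0, :, i : i + 4, j : j + 4].ravel()
            for i in range(0, 8, 4)
            for j in range(0, 8, 4)
        ]
        assert np.array_equal(out, np.array(hard))

    @settings(max_examples=40, deadline=None)
    @given(
        h=st.integers(4, 12),
        w=st.integers(4, 12),
        k=st.integers(1, 5),
        s=st.integers(1, 5),
        p=st.integers(0, 2),
    )
    def test_matches_naive_extractor_bitwise(self, h, w, k, s, p):
        if not (k >= s >= 1) or k > min(h, w) + 2 * p:
            return
        rng = np.random.default_rng(h * 1000 + w * 100 + k * 10 + s + p)
        fmap = rng.normal(size=(1, 3, h, w))
        cfg = SoftSplitConfig(k, s, p)
        out = soft_split(Tensor(fmap), cfg).data[0]
        xp = np.pad(fmap, ((0, 0), (0, 0), (p, p), (p, p)))
        naive = [
            xp[0, :, i : i + k, j : j + k].ravel()
            for i in range(0, h + 2 * p - k + 1, s)
            for j in range(0, w + 2 * p - k + 1, s)
        ]
        assert out.shape[0] == cfg.token_count(h, w)
        assert np.array_equal(out, np.array(naive))

    def test_invalid_configs_rejected(self, rng):
        with pytest.raises(ValueError, match="kernel >= stride"):
            SoftSplitConfig(2, 3, 0)
        with pytest.raises(ValueError, match="padded extent"):
            soft_split(Tensor(rng.normal(size=(1, 1, 4, 4))), SoftSplitConfig(9, 1, 1))


class TestMultiScaleConv:
    def test_outputs_preserve_spatial_extent(self, rng):
        conv = MultiScaleConv(4, (3, 5, 7), rng)
        maps = conv(Tensor(rng.normal(size=(2, 4, 14, 14))))
        assert len(maps) == 3
        for m in maps:
            assert m.shape == (2, 4, 14, 14)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            MultiScaleConv(4, (3, 4), rng)


class TestAttention:
    def test_global_attention_matches_naive_matrix_computation(self, rng):
        attn = LocalGlobalAttention(6, window=3, rng=rng)
        fmap = rng.normal(size=(1, 6, 4, 4))
        out = attn.global_attention(Tensor(fmap)).data
        x = fmap[0].reshape(6, 16).T  # row-major tokens
        naive, weights = naive_attention(
            x,
            attn.q.weight.data, attn.q.bias.data,
            attn.k.weight.data, attn.k.bias.data,
            attn.v.weight.data, attn.v.bias.data,
        )
        np.testing.assert_allclose(out[0].reshape(6, 16).T, naive, atol=1e-10)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_local_matches_per_window_loop(self, rng):
        attn = LocalGlobalAttention(5, window=4, rng=rng)
        fmap = rng.normal(size=(1, 5, 8, 8))
        out = attn.local_attention(Tensor(fmap)).data[0]
        for wi in range(2):
            for wj in range(2):
                block = fmap[0][:, wi * 4 : wi * 4 + 4, wj * 4 : wj * 4 + 4]
                x = block.reshape(5, 16).T
                naive, _ = naive_attention(
                    x,
                    attn.q.weight.data, attn.q.bias.data,
                    attn.k.weight.data, attn.k.bias.data,
                    attn.v.weight.data, attn.v.bias.data,
                )
                got = out[:, wi * 4 : wi * 4 + 4, wj * 4 : wj * 4 + 4].reshape(5, 16).T
                np.testing.assert_allclose(got, naive, atol=1e-6)

    def test_window_covering_map_equals_global(self, rng):
        attn = LocalGlobalAttention(4, window=6, rng=rng)
        fmap = Tensor(rng.normal(size=(2, 4, 6, 6)))
        local = attn.local_attention(fmap).data
        global_ = attn.global_attention(fmap).data
        np.testing.assert_allclose(local, global_, atol=1e-12)

    def test_window_one_returns_value_projection(self, rng):
        attn = LocalGlobalAttention(4, window=1, rng=rng)
        fmap = Tensor(rng.normal(size=(1, 4, 3, 3)))
        out = attn.local_attention(fmap).data
        values = attn.v(flatten_map(fmap)).data
        np.testing.assert_allclose(flatten_map(Tensor(out)).data, values, atol=1e-12)

    def test_constant_map_gives_constant_global_output(self, rng):
        attn = LocalGlobalAttention(4, window=2, rng=rng)
        fmap = Tensor(np.full((1, 4, 5, 5), 1.7))
        out = attn.global_attention(fmap).data
        # uniform attention over identical values -> spatially constant
        assert np.ptp(out.reshape(4, -1), axis=1).max() < 1e-12

    def test_single_position_map_returns_value_projection(self, rng):
        attn = LocalGlobalAttention(3, window=1, rng=rng)
        fmap = Tensor(rng.normal(size=(1, 3, 1, 1)))
        out = attn.global_attention(fmap).data
        v = attn.v(flatten_map(fmap)).data
        np.testing.assert_allclose(out.ravel(), v.ravel(), atol=1e-12)

    def test_nan_input_rejected(self, rng):
        attn = LocalGlobalAttention(3, window=1, rng=rng)
        bad = np.full((1, 3, 2, 2), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            attn.global_attention(Tensor(bad))


class TestScaleBank:
    def test_local_global_weights_sum_to_one(self, rng):
        bank = ScaleBank(4, 3, rng)
        for j in range(3):
            bank.local_global_logits[j].data = rng.normal(size=2) * 5
            ab = bank.local_global_weights(j).data
            assert ab.min() >= 0
            assert abs(ab.sum() - 1.0) < 1e-7

    def test_forced_alpha_one_returns_local(self, rng):
        bank = ScaleBank(4, 1, rng)
        bank.local_global_logits[0].data = np.array([50.0, -50.0])
        a = Tensor(rng.normal(size=(1, 4, 3, 3)))
        b = Tensor(rng.normal(size=(1, 4, 3, 3)))
        np.testing.assert_allclose(bank.fuse_local_global(a, b, 0).data, a.data, atol=1e-12)

    def test_equal_logits_give_elementwise_mean(self, rng):
        bank = ScaleBank(4, 1, rng)
        a = Tensor(rng.normal(size=(1, 4, 3, 3)))
        b = Tensor(rng.normal(size=(1, 4, 3, 3)))
        np.testing.assert_allclose(
            bank.fuse_local_global(a, b, 0).data, (a.data + b.data) / 2, atol=1e-12
        )

    def test_scale_weights_nonnegative_and_normalized(self, rng):
        bank = ScaleBank(4, 3, rng)
        maps = [Tensor(rng.normal(size=(2, 4, 5, 5))) for _ in range(3)]
        w = bank.scale_weights(maps).data
        assert w.shape == (2, 3)
        assert w.min() >= 0
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-7)

    def test_one_hot_scale_weights_select_single_map(self, rng):
        bank = ScaleBank(2, 2, rng)
        maps = [Tensor(rng.normal(size=(1, 2, 3, 3))) for _ in range(2)]
        bank.scale_fc.weight.data[:] = 0
        bank.scale_fc.bias.data = np.array([100.0, -100.0])
        np.testing.assert_allclose(bank.fuse_scales(maps).data, maps[0].data, atol=1e-10)

    def test_uniform_weights_average_two_scales(self, rng):
        bank = ScaleBank(2, 2, rng)
        bank.scale_fc.weight.data[:] = 0
        bank.scale_fc.bias.data[:] = 0
        maps = [Tensor(rng.normal(size=(1, 2, 3, 3))) for _ in range(2)]
        np.testing.assert_allclose(
            bank.fuse_scales(maps).data, (maps[0].data + maps[1].data) / 2, atol=1e-12
        )

    def test_empty_scale_list_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one"):
            ScaleBank(2, 1, rng).fuse_scales([])


def _block(rng, in_dim=12, channels=8):
    return TokensToTokenBlock(
        in_dim, channels, heads=2, kernel_sizes=(3, 5), window=3,
        split=SoftSplitConfig(3, 2, 1), rng=rng,
    )


class TestBlockAndArms:
    def test_transformer_step_preserves_shape_and_rejects_nan(self, rng):
        block = _block(rng)
        tokens = Tensor(rng.normal(size=(2, 16, 8)))
        out = block.transformer_step(tokens)
        assert out.shape == (2, 16, 8)
        with pytest.raises(ValueError, match="NaN"):
            block.transformer_step(Tensor(np.full((1, 4, 8), np.nan)))

    def test_output_token_count_matches_soft_split_formula(self, rng):
        block = _block(rng)
        tokens = Tensor(rng.normal(size=(1, 36, 12)))
        out, oh, ow = block(tokens, 6, 6)
        assert (oh, ow) == (3, 3)
        assert out.shape == (1, 9, 9 * 8)

    def test_identically_initialized_arms_agree(self):
        a = _block(np.random.default_rng(7))
        b = _block(np.random.default_rng(7))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 16, 12)))
        out_a, _, _ = a(x, 4, 4)
        out_b, _, _ = b(x, 4, 4)
        np.testing.assert_array_equal(out_a.data, out_b.data)

    def test_independently_initialized_arms_differ(self):
        a = _block(np.random.default_rng(7))
        b = _block(np.random.default_rng(8))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 16, 12)))
        assert not np.allclose(a(x, 4, 4)[0].data, b(x, 4, 4)[0].data)

    def test_arm_isolation_mutating_one_leaves_other_unchanged(self, rng):
        a = _block(np.random.default_rng(7))
        b = _block(np.random.default_rng(9))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 16, 12)))
        before = b(x, 4, 4)[0].data.copy()
        for p in a.parameters():
            p.data = p.data + 1.0
        after = b(x, 4, 4)[0].data
        np.testing.assert_array_equal(before, after)

    def test_gradient_reaches_every_parameter_group(self, rng):
        block = _block(rng)
        x = Tensor(rng.normal(size=(2, 16, 12)), requires_grad=True)
        out, _, _ = block(x, 4, 4)
        (out * out).sum().backward()
        missing = [p for p in block.parameters() if p.grad is None]
        assert not missing
        # α/β and ω logits specifically
        assert all(lg.grad is not None for lg in block.bank.local_global_logits)
        assert block.bank.scale_fc.weight.grad is not None

    def test_full_arm_token_geometry(self, rng):
        arm = TokensToTokenArm(
            image_side=16, in_channels=6, block_dims=(8, 8), heads=2,
            kernel_sizes=(3,), window=3, split=SoftSplitConfig(3, 2, 1),
            first_split=SoftSplitConfig(7, 4, 2), out_dim=8, rng=rng,
        )
        out = arm(Tensor(rng.normal(size=(2, 6, 16, 16))))
        # 16 -> grid 4 -> block1 2x2 -> block2 1x1
        assert arm.final_grid == (1, 1)
        assert out.shape == (2, 1, 8)
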