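"""Shifted-window transformer backbone: tokenisation, attention, hierarchy."""

import numpy as np
import pytest

from somaswin import autograd as ag
from somaswin.autograd import Tensor
from somaswin.backbone import (
    BackboneConfig,
    PatchMerging,
    SwinBackbone,
    SwinBlock,
    WindowAttention,
    backbone_forward,
    build_attention_mask,
    cyclic_shift,
    linear_embed,
    merge_windows,
    partition_windows,
    patch_merge,
    patch_partition,
    swin_block,
    tokens_to_image,
)


class TestPatchPartition:
    def test_512_gives_128x128_tokens_of_dim_16(self):
        grid = patch_partition(np.zeros((512, 512), dtype=np.float32))
        assert grid.tokens.shape == (128, 128, 16)

    def test_constant_image_gives_identical_tokens(self):
        grid = patch_partition(np.full((16, 16), 0.7, dtype=np.float32))
        flat = grid.tokens.reshape(-1, 16)
        assert np.allclose(flat, flat[0])

    def test_round_trip_re_tiles_padded_image(self, rng):
        img = rng.random((37, 53)).astype(np.float32)
        rec = tokens_to_image(patch_partition(img), 4)
        assert rec.shape == (40, 56)
        assert np.array_equal(rec[:37, :53], img)
        assert np.all(rec[37:, :] == 0) and np.all(rec[:, 53:] == 0)

    def test_empty_image_errors(self):
        with pytest.raises(ValueError):
            patch_partition(np.zeros((0, 0)))


class TestLinearEmbed:
    def test_zero_tokens_map_to_zero(self):
        grid = patch_partition(np.zeros((16, 16), dtype=np.float32))
        out = linear_embed(grid, 8)
        assert np.allclose(out.tokens, 0.0)

    def test_output_channels_are_96_by_default(self, rng):
        grid = patch_partition(rng.random((32, 32)).astype(np.float32))
        assert linear_embed(grid).tokens.shape == (8, 8, 96)

    def test_position_sharing_commutes_with_permutation(self, rng):
        grid = patch_partition(rng.random((24, 24)).astype(np.float32))
        perm = rng.permutation(6)
        permuted = patch_partition(np.zeros((24, 24), dtype=np.float32))
        permuted.tokens = grid.tokens[perm][:, perm]
        a = linear_embed(permuted, 12, seed=3).tokens
        b = linear_embed(grid, 12, seed=3).tokens[perm][:, perm]
        assert np.allclose(a, b)


class TestCyclicShift:
    def test_zero_shift_identity(self, rng):
        t = rng.random((5, 7, 3))
        assert np.array_equal(cyclic_shift(t, (0, 0)), t)

    def test_shift_then_inverse_identity(self, rng):
        t = rng.random((6, 9, 4))
        assert np.array_equal(cyclic_shift(cyclic_shift(t, (-2, 3)), (2, -3)), t)

    def test_index_arithmetic(self):
        t = np.zeros((4, 4, 1))
        t[2, 2, 0] = 1.0
        assert cyclic_shift(t, (-2, -2))[0, 0, 0] == 1.0

    def test_excessive_shift_errors(self):
        with pytest.raises(ValueError):
            cyclic_shift(np.zeros((3, 3, 1)), (3, 0))


class TestWindowPartition:
    @pytest.mark.parametrize("shape,window,shift", [
        ((8, 8, 4), 4, (0, 0)),
        ((13, 9, 5), 4, (-2, -2)),
        ((7, 7, 2), 7, (0, 0)),
        ((10, 6, 3), 4, (-1, -3)),
    ])
    def test_partition_merge_round_trip(self, rng, shape, window, shift):
        t = rng.random(shape).astype(np.float32)
        ws = partition_windows(t, window, shift)
        assert ws.windows.shape[1] == window * window
        assert np.allclose(merge_windows(ws), t)

    def test_unshifted_unpadded_mask_is_permissive(self):
        assert build_attention_mask(8, 8, 4, (0, 0)) is None

    def test_shifted_mask_blocks_cross_region_pairs_exactly(self):
        mask = build_attention_mask(8, 8, 4, (-2, -2))
        assert mask is not None
        # softmax weight for masked pairs is exactly zero
        logits = np.zeros_like(mask) + mask
        w = np.exp(logits - logits.max(axis=-1, keepdims=True))
        w /= w.sum(axis=-1, keepdims=True)
        assert np.all(w[mask < 0] == 0.0)
        # and unmasked pairs exist in every window
        assert np.all((mask == 0).sum(axis=-1) >= 1)


def _naive_global_attention(x, attn: WindowAttention):
    """Brute-force full self-attention oracle using the module's weights."""
    n, d = x.shape
    heads = attn.num_heads
    hd = d // heads
    qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
    q, k, v = qkv[:, :d], qkv[:, d:2 * d], qkv[:, 2 * d:]
    out = np.zeros_like(x)
    for h in range(heads):
        sl = slice(h * hd, (h + 1) * hd)
        logits = (q[:, sl] / np.sqrt(hd)) @ k[:, sl].T
        w = np.exp(logits - logits.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        out[:, sl] = w @ v[:, sl]
    return out @ attn.proj.weight.data + attn.proj.bias.data


class TestWindowAttention:
    def test_single_token_window_equals_value_projection(self, rng):
        attn = WindowAttention(6, 2, 1, np.random.default_rng(0),
                               use_relative_position_bias=False)
        x = rng.random((4, 1, 6)).astype(np.float32)
        out = attn(Tensor(x)).data
        d = 6
        qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
        v = qkv[..., 2 * d:]
        expected = v @ attn.proj.weight.data + attn.proj.bias.data
        assert np.allclose(out, expected, atol=1e-6)

    def test_uniform_tokens_give_uniform_output(self):
        attn = WindowAttention(8, 2, 2, np.random.default_rng(1),
                               use_relative_position_bias=False)
        x = np.full((1, 4, 8), 0.3, dtype=np.float32)
        out = attn(Tensor(x)).data
        assert np.allclose(out, out[0, 0], atol=1e-6)

    def test_window_covering_grid_equals_global_attention(self, rng):
        t = rng.random((6, 6, 8)).astype(np.float32)
        attn = WindowAttention(8, 2, 6, np.random.default_rng(5),
                               use_relative_position_bias=False)
        ws = partition_windows(t, 6)
        out = attn(Tensor(ws.windows), mask=ws.attention_mask, window_size=6).data
        oracle = _naive_global_attention(t.reshape(36, 8), attn)
        assert np.abs(out.reshape(36, 8) - oracle).max() < 1e-5

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            WindowAttention(7, 2, 4, np.random.default_rng(0))


class TestSwinBlock:
    def test_shape_preserved(self, rng):
        t = rng.random((9, 13, 8)).astype(np.float32)
        out = swin_block(t, shifted=True, num_heads=2, window_size=4, seed=0)
        assert out.shape == t.shape

    def test_shift_suppressed_on_single_window_grid(self, rng):
        # a grid no larger than one window: the shifted path collapses to W-MSA
        t = rng.random((4, 4, 8)).astype(np.float32)
        a = swin_block(t, shifted=False, num_heads=2, window_size=4, seed=3)
        b = swin_block(t, shifted=True, num_heads=2, window_size=4, seed=3)
        assert np.array_equal(a, b)

    def test_bit_stable_across_runs(self, rng):
        t = rng.random((8, 8, 8)).astype(np.float32)
        a = swin_block(t, shifted=True, num_heads=2, window_size=4, seed=1)
        b = swin_block(t, shifted=True, num_heads=2, window_size=4, seed=1)
        assert np.array_equal(a, b)

    def test_masked_shift_matches_unshifted_on_wraparound_free_input(self, rng):
        # constant input: attention output must be spatially constant in both modes
        t = np.full((8, 8, 4), 0.5, dtype=np.float32)
        out = swin_block(t, shifted=True, num_heads=2, window_size=4, seed=2)
        assert np.allclose(out, out[0, 0], atol=1e-5)


class TestPatchMerging:
    def test_8x8x96_becomes_4x4x192(self, rng):
        t = rng.random((8, 8, 96)).astype(np.float32)
        assert patch_merge(t).shape == (4, 4, 192)

    def test_token_count_ratio_is_four(self, rng):
        t = rng.random((10, 6, 8)).astype(np.float32)
        out = patch_merge(t)
        assert (t.shape[0] * t.shape[1]) / (out.shape[0] * out.shape[1]) == 4

    def test_constant_grid_gives_constant_output(self):
        t = np.full((6, 6, 8), 0.4, dtype=np.float32)
        out = patch_merge(t)
        assert np.allclose(out, out[0, 0], atol=1e-6)

    def test_odd_dims_padded(self, rng):
        t = rng.random((5, 7, 4)).astype(np.float32)
        assert patch_merge(t).shape == (3, 4, 8)


SMALL_CFG = BackboneConfig(embed_dim=8, depths=(1, 1, 1, 1), num_heads=(2, 2, 2, 2),
                           window_size=4, mlp_ratio=1.0)


class TestBackboneForward:
    def test_paper_config_shape_schedule_on_224(self):
        feats = backbone_forward(np.zeros((224, 224), dtype=np.float32),
                                 BackboneConfig(), seed=0)
        assert [f.shape for f in feats] == [
            (56, 56, 96), (28, 28, 192), (14, 14, 384), (7, 7, 768)]

    def test_zero_image_zero_biases_gives_zero_features(self):
        model = SwinBackbone(SMALL_CFG, np.random.default_rng(0))
        feats = model(np.zeros((32, 32), dtype=np.float32))
        for f in feats:
            assert np.allclose(f.data, 0.0, atol=1e-6)

    def test_doubling_image_doubles_token_grids(self, rng):
        a = backbone_forward(rng.random((32, 32)).astype(np.float32), SMALL_CFG)
        b = backbone_forward(rng.random((64, 64)).astype(np.float32), SMALL_CFG)
        for fa, fb in zip(a, b):
            assert fb.shape[0] == 2 * fa.shape[0] and fb.shape[1] == 2 * fa.shape[1]

    def test_ceil_schedule_on_odd_size(self, rng):
        feats = backbone_forward(rng.random((70, 50)).astype(np.float32), SMALL_CFG)
        h, w = 70, 50
        for s, f in enumerate(feats):
            expect_h, expect_w = -(-h // 4), -(-w // 4)
            for _ in range(s):
                expect_h, expect_w = -(-expect_h // 2), -(-expect_w // 2)
            assert f.shape == (expect_h, expect_w, 8 * 2 ** s)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(depths=(2, 2))
        with pytest.raises(ValueError):
            BackboneConfig(embed_dim=10, num_heads=(3, 3, 3, 3))


class TestGradients:
    def test_block_gradient_matches_finite_difference(self, rng):
        block = SwinBlock(6, 2, 3, shifted=True, mlp_ratio=2.0,
                          rng=np.random.default_rng(7))
        x = rng.random((5, 4, 6)).astype(np.float32)
        xt = Tensor(x, requires_grad=True)
        y = block(xt)
        loss = ag.mean(ag.mul(y, y))
        loss.backward()
        idx = (2, 1, 3)
        eps = 1e-3

        def f(a):
            out = block(Tensor(a)).data
            return float((out * out).mean())

        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        numeric = (f(xp) - f(xm)) / (2 * eps)
        assert xt.grad[idx] == pytest.approx(numeric, rel=0.02, abs=1e-4)

    def test_merging_gradient_matches_finite_difference(self, rng):
        merge = PatchMerging(4, np.random.default_rng(3))
        x = rng.random((4, 4, 4)).astype(np.float32)
        xt = Tensor(x, requires_grad=True)
        y = merge(xt)
        ag.mean(ag.mul(y, y)).backward()
        idx = (1, 2, 0)
        eps = 1e-3

        def f(a):
            out = merge(Tensor(a)).data
            return float((out * out).mean())

        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        numeric = (f(xp) - f(xm)) / (2 * eps)
        assert xt.grad[idx] == pytest.approx(numeric, rel=0.02, abs=1e-4)
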