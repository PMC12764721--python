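"""Windowed attention primitives: oracles, masking, shapes, and gradients."""

import numpy as np
import pytest
from scipy import special

from thermoseg import nn
from thermoseg.nn import Tensor
from thermoseg.swin import (
    AttnKind,
    HcmaAttention,
    PatchEmbed,
    PatchMerging,
    SwinBlock,
    SwinBlockConfig,
    WindowAttention,
    patch_partition,
    shift_attention_mask,
    window_partition,
    window_reverse,
)


def dense_attention_oracle(x_tokens, attn: WindowAttention, heads: int):
    """Brute-force multi-head attention over all tokens with the same
    projection weights and relative position bias as the module."""
    n, c = x_tokens.shape
    dh = c // heads
    w, b = attn.qkv.weight.data, attn.qkv.bias.data
    qkv = x_tokens @ w + b
    q, k, v = qkv[:, :c], qkv[:, c:2 * c], qkv[:, 2 * c:]
    bias = attn.bias_table.data[attn._rel_index]  # (N, N, heads)
    out = np.zeros((n, c))
    for h in range(heads):
        qh = q[:, h * dh:(h + 1) * dh]
        kh = k[:, h * dh:(h + 1) * dh]
        vh = v[:, h * dh:(h + 1) * dh]
        logits = qh @ kh.T / np.sqrt(dh) + bias[:, :, h]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        weights = e / e.sum(axis=1, keepdims=True)
        out[:, h * dh:(h + 1) * dh] = weights @ vh
    return out @ attn.proj.weight.data + attn.proj.bias.data


class TestWindowBookkeeping:
    def test_partition_reverse_roundtrip(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 8, 3)))
        back = window_reverse(window_partition(x, 4), 4, 8, 8)
        np.testing.assert_array_equal(back.numpy(), x.numpy())

    def test_partition_rejects_indivisible(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            window_partition(Tensor(rng.normal(size=(1, 6, 6, 2))), 4)


class TestPatchOps:
    def test_patch_partition_token_grid(self, rng):
        fm = patch_partition(rng.random((2, 64, 64)), patch_size=4,
                             embed_dim=16, rng=rng)
        assert fm.shape == (2, 16, 16, 16)
        assert fm.stage == 0

    def test_identity_projection_returns_pixels(self, rng):
        embed = PatchEmbed(1, 1, 1, rng)
        embed.proj.weight.data = np.array([[1.0]])
        embed.proj.bias.data = np.array([0.0])
        img = rng.random((1, 8, 8))
        fm = patch_partition(img, 1, 1, embed=embed)
        np.testing.assert_allclose(fm.data.numpy()[..., 0], img)

    def test_indivisible_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            patch_partition(rng.random((1, 64, 64)), patch_size=7,
                            embed_dim=8, rng=rng)

    def test_patch_merging_halves_spatial_doubles_channels(self, rng):
        merge = PatchMerging(16, rng)
        out = merge(Tensor(rng.normal(size=(2, 16, 16, 16))))
        assert out.shape == (2, 8, 8, 32)
        # token count drops by exactly 4
        assert (16 * 16) // (8 * 8) == 4

    def test_patch_merging_rejects_odd_dims(self, rng):
        with pytest.raises(ValueError, match="even"):
            PatchMerging(4, rng)(Tensor(rng.normal(size=(1, 5, 6, 4))))

    def test_patch_merging_constant_input_identity_sum(self, rng):
        merge = PatchMerging(2, rng)
        merge.proj.weight.data = np.tile(np.eye(4), (2, 1))[:8, :4]
        x = Tensor(np.full((1, 2, 2, 2), 3.0))
        out = merge(x).numpy()
        assert np.allclose(out, out[0, 0, 0, 0])  # still constant


class TestWindowAttention:
    def test_full_window_equals_dense_attention(self, rng):
        """Window = full 8x8 grid, no shift -> dense global attention."""
        cfg = SwinBlockConfig(dim=16, heads=4, window=8, shift=0)
        attn = WindowAttention(cfg, rng)
        x = rng.normal(size=(1, 8, 8, 16))
        out = attn(Tensor(x)).numpy()
        expected = dense_attention_oracle(x.reshape(64, 16), attn, heads=4)
        np.testing.assert_allclose(out.reshape(64, 16), expected, atol=1e-5)

    def test_attention_rows_are_distributions(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, shift=2)
        attn = WindowAttention(cfg, rng)
        weights = attn.attention_weights(Tensor(rng.normal(size=(2, 8, 8, 8))))
        assert np.all(weights >= 0)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-12)

    def test_shift_mask_blocks_cross_boundary_pairs_exactly(self, rng):
        """Tokens on opposite sides of the cyclic roll get exactly zero weight."""
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, shift=2)
        attn = WindowAttention(cfg, rng)
        weights = attn.attention_weights(Tensor(rng.normal(size=(1, 8, 8, 8))))
        mask = shift_attention_mask(8, 8, 4, 2)  # (nW, N, N)
        nw, n, _ = mask.shape
        w = weights.reshape(nw, cfg.heads, n, n).transpose(1, 0, 2, 3)
        blocked = w[:, mask < 0]
        assert blocked.size > 0
        assert np.all(blocked == 0.0)

    def test_constant_input_shift_equivariance(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, shift=2)
        attn = WindowAttention(cfg, rng)
        x = Tensor(np.full((1, 8, 8, 8), 0.7))
        out = attn(x).numpy()
        # constant field + permutation equivariance -> constant output
        assert np.abs(out - out[0, 0, 0]).max() < 1e-10

    def test_zero_value_projection_gives_zero_output(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4)
        attn = WindowAttention(cfg, rng)
        attn.qkv.weight.data[:, 2 * 8:] = 0.0   # value projection slice
        attn.qkv.bias.data[2 * 8:] = 0.0
        attn.proj.bias.data[:] = 0.0
        out = attn(Tensor(rng.normal(size=(1, 8, 8, 8)))).numpy()
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SwinBlockConfig(dim=10, heads=4, window=4)

    def test_shift_must_be_less_than_window(self):
        with pytest.raises(ValueError, match="shift"):
            SwinBlockConfig(dim=8, heads=2, window=4, shift=4)


class TestHcma:
    def test_gates_forced_open_recover_identity(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, attn_kind="SW_HCMA")
        hcma = HcmaAttention(cfg, rng)
        # large positive biases drive both sigmoids to ~1
        hcma.ch_fc2.weight.data[:] = 0.0
        hcma.ch_fc2.bias.data[:] = 40.0
        hcma.spatial_conv.weight.data[:] = 0.0
        hcma.spatial_conv.bias.data[:] = 40.0
        x = rng.normal(size=(1, 8, 8, 8))
        np.testing.assert_allclose(hcma(Tensor(x)).numpy(), x, atol=1e-8)

    def test_single_channel_closed_form(self, rng):
        """With one channel the channel gate is a per-window scalar; the full
        output is reproduced by an independent NumPy computation."""
        cfg = SwinBlockConfig(dim=1, heads=1, window=4, attn_kind="SW_HCMA")
        hcma = HcmaAttention(cfg, rng)
        x = rng.normal(size=(1, 4, 4, 1))
        out = hcma(Tensor(x)).numpy()

        win = x.reshape(1, 16, 1)
        avg_d, max_d = win.mean(axis=1), win.max(axis=1)

        def mlp(d):
            h = np.maximum(d @ hcma.ch_fc1.weight.data + hcma.ch_fc1.bias.data, 0)
            return h @ hcma.ch_fc2.weight.data + hcma.ch_fc2.bias.data

        gate = special.expit(mlp(avg_d) + mlp(max_d))   # scalar per window
        gated = win * gate[:, None, :]
        desc = np.concatenate([gated.mean(-1, keepdims=True),
                               gated.max(-1, keepdims=True)], axis=-1)
        desc = desc.reshape(1, 4, 4, 2)
        k = hcma.spatial_conv.weight.data
        dp = np.pad(desc, ((0, 0), (1, 1), (1, 1), (0, 0)))
        sp = np.zeros((1, 4, 4, 1))
        for i in range(4):
            for j in range(4):
                sp[0, i, j] = np.tensordot(dp[0, i:i + 3, j:j + 3], k,
                                           axes=([0, 1, 2], [0, 1, 2]))
        sp = special.expit(sp + hcma.spatial_conv.bias.data)
        expected = (gated.reshape(1, 4, 4, 1)) * sp
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_uniform_input_gives_spatially_constant_gate(self, rng):
        cfg = SwinBlockConfig(dim=4, heads=2, window=4, attn_kind="SW_HCMA")
        hcma = HcmaAttention(cfg, rng)
        out = hcma(Tensor(np.full((1, 8, 8, 4), 0.3))).numpy()
        # gates depend only on within-window position -> window-periodic output
        np.testing.assert_allclose(out[0, :4, :4], out[0, 4:, 4:], atol=1e-12)
        # and the window-centre gate is symmetric for a uniform field
        centre = out[0, 1:3, 1:3]
        assert np.abs(centre - centre[0, 0]).max() < 1e-12


class TestSwinBlock:
    @pytest.mark.parametrize("norm", ["layer_norm", "batch_norm"])
    def test_zeroed_output_layers_make_block_identity(self, rng, norm):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, norm_kind=norm)
        blk = SwinBlock(cfg, rng)
        blk.attn.proj.weight.data[:] = 0.0
        blk.attn.proj.bias.data[:] = 0.0
        blk.mlp.fc2.weight.data[:] = 0.0
        blk.mlp.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(2, 8, 8, 8))
        np.testing.assert_allclose(blk(Tensor(x)).numpy(), x, atol=1e-12)

    def test_alternating_blocks_shift_pattern(self, rng):
        """Stacked blocks alternate unshifted / half-window-shifted attention."""
        cfgs = [SwinBlockConfig(dim=8, heads=2, window=4,
                                shift=0 if i % 2 == 0 else 2,
                                attn_kind="W_MHSA" if i % 2 == 0 else "SW_MHSA")
                for i in range(2)]
        blocks = [SwinBlock(c, rng) for c in cfgs]
        assert blocks[0].attn.cfg.shift == 0
        assert blocks[1].attn.cfg.shift == 2
        x = Tensor(rng.normal(size=(1, 8, 8, 8)))
        y = blocks[1](blocks[0](x))
        assert y.shape == x.shape

    def test_gradient_matches_finite_differences(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, shift=2,
                              attn_kind="SW_MHSA")
        blk = SwinBlock(cfg, rng)
        x = Tensor(rng.normal(size=(2, 8, 8, 8)), requires_grad=True)
        (blk(x) ** 2).sum().backward()
        eps = 1e-6
        for idx in [(0, 1, 2, 3), (1, 7, 0, 5)]:
            hi = x.data.copy(); hi[idx] += eps
            lo = x.data.copy(); lo[idx] -= eps
            fd = ((blk(Tensor(hi)) ** 2).sum().item()
                  - (blk(Tensor(lo)) ** 2).sum().item()) / (2 * eps)
            assert fd == pytest.approx(x.grad[idx], rel=1e-3)

    def test_w_mhsa_with_shift_rejected(self, rng):
        cfg = SwinBlockConfig(dim=8, heads=2, window=4, shift=2,
                              attn_kind="W_MHSA")
        with pytest.raises(ValueError, match="shift"):
            SwinBlock(cfg, rng)


class TestFunctionalWrappers:
    def test_window_attention_wrapper_matches_module(self, rng):
        from thermoseg.swin import FeatureMap, window_attention
        cfg = SwinBlockConfig(dim=8, heads=2, window=4)
        attn = WindowAttention(cfg, rng)
        x = rng.normal(size=(1, 8, 8, 8))
        fm = window_attention(FeatureMap(Tensor(x), stage=1), cfg, attn=attn)
        assert fm.stage == 1
        np.testing.assert_array_equal(fm.data.numpy(), attn(Tensor(x)).numpy())

    def test_hcma_wrapper_enforces_attention_kind(self, rng):
        from thermoseg.swin import hcma_attention
        cfg = SwinBlockConfig(dim=8, heads=2, window=4)  # W_MHSA default
        with pytest.raises(ValueError, match="SW_HCMA"):
            hcma_attention(rng.normal(size=(1, 4, 4, 8)), cfg, rng=rng)

    def test_swin_block_wrapper_preserves_stage(self, rng):
        from thermoseg.swin import FeatureMap, swin_block
        cfg = SwinBlockConfig(dim=8, heads=2, window=4)
        fm = swin_block(FeatureMap(Tensor(rng.normal(size=(1, 8, 8, 8))),
                                   stage=2), cfg, rng=rng)
        assert fm.stage == 2 and fm.shape == (1, 8, 8, 8)
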