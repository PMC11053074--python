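"""Backbone primitives against dense-attention and shape-algebra oracles."""

import numpy as np
import pytest

from verdure.backbone import (BackboneConfig, ConfigurationError,
                              DimensionError, PatchMerging, ResSwinBlock,
                              SwinBackbone, SwinBlock, WindowAttention,
                              patch_partition, shifted_window_mask,
                              window_partition, window_reverse)
from verdure.nn import Tensor


class TestPatchPartition:
    def test_channel_and_grid_algebra(self, rng):
        image = rng.random((256, 256, 3))
        tokens = patch_partition(image, 4)
        assert tokens.shape == (64, 64, 48)

    def test_single_patch_is_flat_image(self, rng):
        image = rng.random((4, 4, 3))
        tokens = patch_partition(image, 4)
        assert tokens.shape == (1, 1, 48)
        # row-major pixels, channels last
        expected = image.reshape(-1)
        np.testing.assert_allclose(tokens.data.reshape(-1), expected,
                                   rtol=1e-6)

    def test_constant_image_gives_identical_tokens(self):
        image = np.full((8, 8, 3), 0.3)
        tokens = patch_partition(image, 4).data.reshape(4, 48)
        assert np.allclose(tokens, tokens[0])

    def test_non_divisible_axis_named(self):
        with pytest.raises(DimensionError, match="height"):
            patch_partition(np.zeros((6, 8, 3)), 4)
        with pytest.raises(DimensionError, match="width"):
            patch_partition(np.zeros((8, 6, 3)), 4)


class TestWindowPartition:
    @pytest.mark.parametrize("h,w,ws,shift", [
        (8, 8, 8, 0), (8, 8, 4, 2), (8, 8, 2, 1), (4, 8, 2, 0), (6, 6, 3, 1)])
    def test_inverse_is_identity(self, h, w, ws, shift, rng):
        x = Tensor(rng.random((2, h, w, 5)))
        windows = window_partition(x, ws, shift)
        assert windows.shape == (2 * (h // ws) * (w // ws), ws * ws, 5)
        back = window_reverse(windows, ws, h, w, shift)
        np.testing.assert_array_equal(back.data, x.data)

    def test_shift_matches_cyclic_roll_oracle(self, rng):
        x = rng.random((1, 8, 8, 1))
        windows = window_partition(Tensor(x), 4, 2).data
        rolled = np.roll(x, (-2, -2), axis=(1, 2))
        # first window of the shifted partition == top-left of rolled grid
        np.testing.assert_allclose(
            windows[0].reshape(4, 4), rolled[0, :4, :4, 0], rtol=1e-6)

    def test_non_divisible_grid_rejected(self, rng):
        with pytest.raises(DimensionError):
            window_partition(Tensor(rng.random((1, 6, 6, 2))), 4)


def dense_attention_oracle(tokens: np.ndarray, attn: WindowAttention,
                           keep: np.ndarray | None = None) -> np.ndarray:
    """Brute-force multi-head attention over one window (numpy only).

    ``keep`` optionally restricts attention to a token subset (a pre-shift
    region); other pairs are excluded from the softmax entirely.
    """
    L, C = tokens.shape
    heads = attn.heads
    hd = C // heads
    qkv = tokens @ attn.qkv.weight.data + attn.qkv.bias.data
    q, k, v = qkv[:, :C], qkv[:, C:2 * C], qkv[:, 2 * C:]
    bias = attn.rel_bias.data[attn._bias_index].reshape(L, L, heads)
    out = np.zeros((L, C))
    idx = np.arange(L) if keep is None else np.asarray(keep)
    for h in range(heads):
        qh = q[np.ix_(idx, np.arange(h * hd, (h + 1) * hd))]
        kh = k[np.ix_(idx, np.arange(h * hd, (h + 1) * hd))]
        vh = v[np.ix_(idx, np.arange(h * hd, (h + 1) * hd))]
        logits = qh @ kh.T * attn.scale + bias[np.ix_(idx, idx)][:, :, h]
        logits -= logits.max(axis=1, keepdims=True)
        weights = np.exp(logits)
        weights /= weights.sum(axis=1, keepdims=True)
        out[np.ix_(idx, np.arange(h * hd, (h + 1) * hd))] = weights @ vh
    return out @ attn.proj.weight.data + attn.proj.bias.data


class TestWindowAttention:
    def test_single_window_matches_dense_oracle(self, rng):
        attn = WindowAttention(dim=8, heads=2, window_size=4, rng=rng)
        tokens = rng.standard_normal((16, 8))
        out = attn(Tensor(tokens[None]))
        expected = dense_attention_oracle(tokens, attn)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-5)

    def test_zero_query_key_gives_window_mean_of_values(self, rng):
        attn = WindowAttention(dim=6, heads=1, window_size=2, rng=rng)
        C = 6
        attn.qkv.weight.data[:, :2 * C] = 0.0  # zero q and k projections
        attn.qkv.bias.data[:2 * C] = 0.0
        attn.rel_bias.data[:] = 0.0
        tokens = rng.standard_normal((4, C))
        out = attn(Tensor(tokens[None])).data[0]
        values = tokens @ attn.qkv.weight.data[:, 2 * C:] + attn.qkv.bias.data[2 * C:]
        expected = np.tile(values.mean(axis=0), (4, 1)) \
            @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_shifted_mask_equals_per_region_dense_attention(self, rng):
        # 4x4 grid, window 2, shift 1: masked attention must equal dense
        # attention run independently inside each pre-shift region
        H = W = 4
        ws, shift = 2, 1
        attn = WindowAttention(dim=8, heads=2, window_size=ws, rng=rng)
        x = rng.standard_normal((1, H, W, 8))
        windows = window_partition(Tensor(x), ws, shift)
        mask = shifted_window_mask(H, W, ws, shift)
        out = attn(windows, mask).data

        region = np.zeros((H, W))
        slices = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None))
        cnt = 0
        for hs in slices:
            for wsl in slices:
                region[hs, wsl] = cnt
                cnt += 1
        region_win = window_partition(
            Tensor(region[None, :, :, None]), ws, shift).data.reshape(-1, ws * ws)
        for w_idx in range(windows.shape[0]):
            tokens = windows.data[w_idx]
            expected = np.zeros_like(tokens)
            for rid in np.unique(region_win[w_idx]):
                keep = np.nonzero(region_win[w_idx] == rid)[0]
                expected[keep] = dense_attention_oracle(tokens, attn, keep)[keep]
            np.testing.assert_allclose(out[w_idx], expected, atol=1e-5)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            WindowAttention(dim=7, heads=2, window_size=2, rng=rng)


class TestSwinBlocks:
    def _zeroed_block(self, rng, cls, dim=8):
        block = cls(dim, 2, 2, 0, 2.0, rng)
        inner = block.inner if cls is ResSwinBlock else block
        inner.attn.proj.weight.data[:] = 0
        inner.attn.proj.bias.data[:] = 0
        inner.mlp.fc2.weight.data[:] = 0
        inner.mlp.fc2.bias.data[:] = 0
        return block

    def test_zeroed_projections_make_block_identity(self, rng):
        block = self._zeroed_block(rng, SwinBlock)
        x = rng.standard_normal((1, 4, 4, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-7)

    def test_zeroed_res_block_doubles_input(self, rng):
        block = self._zeroed_block(rng, ResSwinBlock)
        x = rng.standard_normal((1, 4, 4, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, 2 * x, atol=1e-7)

    def test_outer_shortcut_is_definitional(self, rng):
        res = ResSwinBlock(8, 2, 2, 1, 2.0, rng)
        x = Tensor(rng.standard_normal((1, 4, 4, 8)))
        np.testing.assert_allclose(res(x).data - res.inner(x).data, x.data,
                                   atol=1e-7)

    def test_shape_preserved(self, rng):
        block = SwinBlock(8, 2, 2, 1, 4.0, rng)
        x = Tensor(rng.standard_normal((2, 6, 4, 8)))
        assert block(x).shape == x.shape

    def test_gradient_contains_identity_path(self, rng):
        # d(out)/dx on a 2x2 grid includes the shortcut: with zeroed
        # projections the Jacobian is exactly the identity
        block = self._zeroed_block(rng, ResSwinBlock)
        x = Tensor(np.zeros((1, 2, 2, 8)), requires_grad=True)
        out = block(x)
        g = np.zeros(out.shape)
        g[0, 0, 0, 0] = 1.0
        out.backward(g)
        expected = np.zeros(x.shape)
        expected[0, 0, 0, 0] = 2.0  # both identity paths
        np.testing.assert_allclose(x.grad, expected, atol=1e-7)


class TestPatchMerging:
    def test_halves_grid_doubles_channels(self, rng):
        merge = PatchMerging(6, rng)
        x = Tensor(rng.standard_normal((1, 8, 4, 6)))
        assert merge(x).shape == (1, 4, 2, 12)

    def test_concatenation_order_is_row_major(self, rng):
        merge = PatchMerging(3, rng)
        x = rng.standard_normal((1, 2, 2, 3))
        out = merge(Tensor(x)).data
        concat = np.concatenate([x[0, 0, 0], x[0, 0, 1],
                                 x[0, 1, 0], x[0, 1, 1]])
        mu, sd = concat.mean(), concat.std()
        normed = (concat - mu) / np.sqrt(sd**2 + 1e-5)
        expected = normed @ merge.reduce.weight.data
        np.testing.assert_allclose(out[0, 0, 0], expected, atol=1e-5)

    def test_passthrough_projection_selects_first_block(self, rng):
        merge = PatchMerging(3, rng)
        merge.reduce.weight.data[:] = 0
        merge.reduce.weight.data[:3, :3] = np.eye(3)  # top-left passthrough
        x = rng.standard_normal((1, 2, 2, 3))
        out = merge(Tensor(x)).data[0, 0, 0, :3]
        concat = np.concatenate([x[0, 0, 0], x[0, 0, 1],
                                 x[0, 1, 0], x[0, 1, 1]])
        normed = (concat - concat.mean()) / np.sqrt(concat.std()**2 + 1e-5)
        np.testing.assert_allclose(out, normed[:3], atol=1e-5)

    def test_odd_grid_rejected(self, rng):
        with pytest.raises(DimensionError):
            PatchMerging(4, rng)(Tensor(rng.standard_normal((1, 3, 4, 4))))


class TestBackbone:
    def test_pyramid_shape_algebra(self, tiny_config, rng):
        bb = SwinBackbone(tiny_config, rng)
        feats = bb(rng.random((1, 64, 64, 3)))
        shapes = [f.shape for f in feats]
        assert shapes == [(1, 16, 16, 24), (1, 8, 8, 48),
                          (1, 4, 4, 96), (1, 2, 2, 192)]
        # every stage halves the grid and doubles the channels
        for a, b in zip(shapes, shapes[1:]):
            assert (a[1], a[2]) == (2 * b[1], 2 * b[2])
            assert 2 * a[3] == b[3]

    def test_reference_config_shapes_at_256(self, rng):
        bb = SwinBackbone(BackboneConfig(), rng)
        feats = bb(rng.random((1, 256, 256, 3)).astype(np.float32))
        assert [f.shape for f in feats] == [
            (1, 64, 64, 96), (1, 32, 32, 192), (1, 16, 16, 384),
            (1, 8, 8, 768)]

    def test_doubling_image_side_doubles_grids(self, tiny_config, rng):
        bb = SwinBackbone(tiny_config, rng)
        small = bb(rng.random((1, 64, 64, 3)))
        large = bb(rng.random((1, 128, 128, 3)))
        for s, l in zip(small, large):
            assert (2 * s.shape[1], 2 * s.shape[2]) == (l.shape[1], l.shape[2])
            assert s.shape[3] == l.shape[3]

    def test_parameter_count_invariant_to_input_size(self, tiny_config, rng):
        bb = SwinBackbone(tiny_config, rng)
        n0 = bb.num_parameters()
        bb(rng.random((1, 64, 64, 3)))
        bb(rng.random((1, 128, 128, 3)))
        assert bb.num_parameters() == n0

    def test_odd_depths_rejected(self):
        with pytest.raises(ConfigurationError, match="pairs"):
            BackboneConfig(embed_dim=24, depths=(1, 1, 1, 1),
                           heads=(2, 2, 4, 4), window_size=2)

    def test_indivisible_image_reports_padding(self, tiny_config, rng):
        bb = SwinBackbone(tiny_config, rng)
        with pytest.raises(DimensionError, match="pad"):
            bb(rng.random((1, 60, 64, 3)))
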