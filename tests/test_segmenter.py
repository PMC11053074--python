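"""Segmenter components, area gate, background masking."""

import numpy as np
import pytest

from verdure.backbone import DimensionError
from verdure.gating import GateOutcome
from verdure.nn import Tensor
from verdure.segmenter import (Aspp, AsppConfig, GreenerySegmenter,
                               PatchExpanding, ResSEBlock,
                               apply_background_mask, area_gate,
                               greenery_proportion)


class TestAspp:
    def test_preserves_spatial_size(self, rng):
        aspp = Aspp(6, AsppConfig(rates=(2, 3, 4)), rng)
        x = Tensor(rng.standard_normal((1, 6, 12, 12)))
        assert aspp(x).shape == (1, 6, 12, 12)

    def test_constant_input_pool_branch_constant(self, rng):
        aspp = Aspp(4, AsppConfig(rates=(1, 2, 3)), rng)
        x = Tensor(np.full((1, 4, 9, 9), 0.7))
        pooled = x.mean(axis=(2, 3), keepdims=True)
        from verdure.nn.functional import bilinear_resize
        branch = bilinear_resize(aspp.pool_proj(pooled), 9, 9).data
        assert np.allclose(branch, branch[:, :, :1, :1])

    def test_prefusion_width_is_five_branches(self, rng):
        aspp = Aspp(8, AsppConfig(), rng)
        assert aspp.fuse.weight.shape[1] == 5 * aspp.branch_channels

    def test_small_map_warns_but_runs(self, rng):
        aspp = Aspp(4, AsppConfig(rates=(3, 6, 12)), rng)
        with pytest.warns(UserWarning, match="dilated"):
            out = aspp(Tensor(rng.standard_normal((1, 4, 2, 2))))
        assert out.shape == (1, 4, 2, 2)

    def test_rates_must_increase(self):
        with pytest.raises(ValueError):
            AsppConfig(rates=(6, 3))


class TestResSE:
    def test_forced_zero_scale_is_identity(self, rng):
        block = ResSEBlock(8, rng, reduction=2)
        block.fc2.weight.data[:] = 0
        block.fc2.bias.data[:] = -1e4  # sigmoid -> 0
        x = rng.standard_normal((1, 6, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)

    def test_forced_unit_scale_doubles(self, rng):
        block = ResSEBlock(8, rng, reduction=2)
        block.fc2.weight.data[:] = 0
        block.fc2.bias.data[:] = 1e4  # sigmoid -> 1
        x = rng.standard_normal((1, 6, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, 2 * x, atol=1e-5)

    def test_matches_numpy_oracle(self, rng):
        block = ResSEBlock(6, rng, reduction=3)
        x = rng.standard_normal((2, 4, 4, 6))
        out = block(Tensor(x)).data
        squeeze = x.mean(axis=(1, 2), keepdims=True)
        h = np.maximum(squeeze @ block.fc1.weight.data + block.fc1.bias.data, 0)
        scale = 1 / (1 + np.exp(-(h @ block.fc2.weight.data + block.fc2.bias.data)))
        np.testing.assert_allclose(out, x * scale + x, atol=1e-5)

    def test_sequence_length_must_factor(self, rng):
        block = ResSEBlock(4, rng)
        with pytest.raises(DimensionError):
            block(Tensor(np.zeros((1, 7, 4))), grid_shape=(2, 3))


class TestPatchExpanding:
    def test_factor_two_halves_channels(self, rng):
        expand = PatchExpanding(192, 2, rng)
        x = Tensor(rng.standard_normal((1, 32, 32, 192)).astype(np.float32))
        assert expand(x).shape == (1, 64, 64, 96)

    def test_factor_four_keeps_channels(self, rng):
        expand = PatchExpanding(24, 4, rng)
        x = Tensor(rng.standard_normal((1, 16, 16, 24)))
        assert expand(x).shape == (1, 64, 64, 24)

    def test_expand_then_merge_restores_grid_shape(self, rng):
        from verdure.backbone import PatchMerging

        expand = PatchExpanding(8, 2, rng)
        merge = PatchMerging(4, rng)
        x = Tensor(rng.standard_normal((1, 4, 4, 8)))
        assert merge(expand(x)).shape == x.shape

    def test_unsupported_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            PatchExpanding(8, 3, rng)


class TestSegmentForward:
    def test_probability_map_shape_and_range(self, tiny_config, rng):
        model = GreenerySegmenter(tiny_config, rng)
        probs = model(rng.random((1, 64, 64, 3)).astype(np.float32))
        assert probs.shape == (1, 64, 64)
        assert np.all(probs.data > 0) and np.all(probs.data < 1)

    def test_thresholding_yields_binary_mask(self, tiny_config, rng):
        model = GreenerySegmenter(tiny_config, rng)
        mask = model.predict_mask(rng.random((64, 64, 3)).astype(np.float32))
        assert mask.shape == (64, 64)
        assert set(np.unique(mask)) <= {0, 1}


class TestGreeneryProportion:
    def test_extremes_and_quarter(self):
        assert greenery_proportion(np.ones((16, 16))) == 1.0
        assert greenery_proportion(np.zeros((16, 16))) == 0.0
        mask = np.zeros((256, 256))
        mask[:128, :128] = 1
        assert greenery_proportion(mask) == 0.25


class TestAreaGate:
    def test_below_threshold_filters(self):
        decision = area_gate(0.39, 0.4)
        assert decision.outcome is GateOutcome.FILTERED_AREA

    def test_boundary_passes(self):
        assert area_gate(0.40, 0.4).outcome is GateOutcome.PASS
        assert area_gate(1.0, 0.4).outcome is GateOutcome.PASS

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            area_gate(1.2, 0.4)


class TestBackgroundMask:
    def test_full_mask_is_identity(self, rng):
        image = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        np.testing.assert_array_equal(
            apply_background_mask(image, np.ones((8, 8))), image)

    def test_empty_mask_blacks_out(self, rng):
        image = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        assert apply_background_mask(image, np.zeros((8, 8))).sum() == 0

    def test_idempotent_and_preserves_foreground(self, rng):
        image = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        once = apply_background_mask(image, mask)
        twice = apply_background_mask(once, mask)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(once[mask == 1], image[mask == 1])

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            apply_background_mask(np.zeros((8, 8, 3)), np.zeros((4, 4)))
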