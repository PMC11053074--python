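"""Detector plumbing: anchors, box coding, RoI align, NMS, assignment."""

import numpy as np
import pytest

from verdure.boxes import DetectionSet, nms
from verdure.detector import (DetectorConfig, WaterDeficitDetector,
                              assign_training_targets, decode_boxes,
                              encode_boxes, generate_anchors,
                              postprocess_detections, roi_align)
from verdure.nn import Tensor


class TestAnchors:
    def test_count_per_level(self):
        anchors = generate_anchors([(8, 8)], scales=(16,), ratios=(0.5, 1, 2),
                                   strides=(4,))
        assert len(anchors) == 8 * 8 * 3

    def test_unit_ratio_is_square_of_scale(self):
        anchors = generate_anchors([(1, 1)], scales=(24,), ratios=(1.0,),
                                   strides=(4,))
        box = anchors.all[0]
        assert box[2] - box[0] == pytest.approx(24)
        assert box[3] - box[1] == pytest.approx(24)

    def test_centers_spaced_one_stride_apart(self):
        anchors = generate_anchors([(4, 4)], scales=(16,), ratios=(1.0,),
                                   strides=(8,)).all
        cx = (anchors[:, 0] + anchors[:, 2]) / 2
        row = cx.reshape(4, 4)[0]
        assert np.allclose(np.diff(row), 8)

    def test_empty_pyramid_rejected(self):
        with pytest.raises(ValueError):
            generate_anchors([])


class TestBoxCoding:
    def test_box_equal_anchor_is_zero(self):
        t = encode_boxes([(2, 3, 10, 12)], [(2, 3, 10, 12)])
        np.testing.assert_allclose(t, 0, atol=1e-12)

    def test_half_shift_example(self):
        t = encode_boxes([(5, 5, 15, 15)], [(0, 0, 10, 10)])[0]
        np.testing.assert_allclose(t, [0.5, 0.5, 0.0, 0.0], atol=1e-12)

    def test_roundtrip_identity_on_random_pairs(self, rng):
        anchors = np.sort(rng.uniform(0, 50, (100, 4)), axis=1)[:, [0, 2, 1, 3]]
        anchors[:, 2:] += 1.0
        boxes = anchors + rng.uniform(-3, 3, (100, 4))
        boxes[:, 2:] = np.maximum(boxes[:, 2:], boxes[:, :2] + 0.5)
        decoded = decode_boxes(encode_boxes(boxes, anchors), anchors)
        np.testing.assert_allclose(decoded, boxes, atol=1e-6)

    def test_zero_area_anchor_rejected(self):
        with pytest.raises(FloatingPointError):
            encode_boxes([(0, 0, 5, 5)], [(2, 2, 2, 8)])


class TestNms:
    def test_identical_boxes_keep_earliest(self):
        boxes = np.array([[0, 0, 10, 10]] * 3)
        keep = nms(boxes, np.array([0.5, 0.5, 0.5]), 0.5)
        assert list(keep) == [0]

    def test_survivors_below_iou_bound(self, rng):
        boxes = rng.uniform(0, 40, (30, 4))
        boxes[:, 2:] = boxes[:, :2] + rng.uniform(4, 12, (30, 2))
        scores = rng.random(30)
        keep = nms(boxes, scores, 0.4)
        from verdure.boxes import iou_matrix

        sub = iou_matrix(boxes[keep], boxes[keep])
        np.fill_diagonal(sub, 0)
        assert sub.max() <= 0.4 + 1e-9
        assert set(keep) <= set(range(30))


class TestRoiAlign:
    def test_constant_map_pools_constant(self):
        fmap = Tensor(np.full((3, 8, 8), 2.5))
        out = roi_align(fmap, [(1.0, 1.0, 6.0, 6.0)], output_size=4)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-6)

    def test_integer_aligned_box_on_ramp_averages_cells(self):
        ramp = np.tile(np.arange(8.0), (8, 1))[None]  # f[i, j] = j
        out = roi_align(Tensor(ramp), [(1.0, 1.0, 3.0, 3.0)], output_size=1,
                        sampling_ratio=4)
        # covered cells j = 1, 2 -> mean 1.5
        assert out.data[0, 0, 0, 0] == pytest.approx(1.5, abs=1e-6)

    def test_translation_equivariance(self, rng):
        fmap = rng.random((2, 12, 12))
        shifted = np.roll(fmap, (3, 2), axis=(1, 2))
        a = roi_align(Tensor(fmap), [(1, 1, 6, 6)], output_size=3)
        b = roi_align(Tensor(shifted), [(3, 4, 8, 9)], output_size=3)
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_degenerate_box_rejected(self):
        with pytest.raises(FloatingPointError):
            roi_align(Tensor(np.zeros((1, 4, 4))), [(2, 2, 2, 3)])

    @pytest.mark.usefixtures("f64")
    def test_gradient_matches_finite_differences(self, rng):
        x0 = rng.random((1, 6, 6))
        boxes = [(0.7, 1.1, 4.3, 5.2)]

        def value(arr):
            return float(roi_align(Tensor(arr), boxes, output_size=2).data.sum())

        t = Tensor(x0, requires_grad=True)
        roi_align(t, boxes, output_size=2).sum().backward()
        eps = 1e-6
        num = np.zeros_like(x0)
        for idx in np.ndindex(x0.shape):
            xp = x0.copy(); xp[idx] += eps
            xm = x0.copy(); xm[idx] -= eps
            num[idx] = (value(xp) - value(xm)) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-5)


class TestBoxHead:
    def test_zero_weights_give_uniform_scores(self, rng):
        from verdure.detector import BoxHead

        head = BoxHead(16, num_classes=2, rng=rng, hidden=8)
        head.cls.weight.data[:] = 0
        head.cls.bias.data[:] = 0
        probs, deltas = head(Tensor(rng.standard_normal((5, 16))))
        np.testing.assert_allclose(probs.data, 1 / 3, atol=1e-7)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-7)
        assert deltas.shape == (5, 8)


class TestTargetAssignment:
    def test_exact_match_is_positive_with_zero_target(self):
        gt = np.array([[4, 4, 12, 12]])
        labels, matched, targets = assign_training_targets(
            gt.copy(), gt, np.array([1]))
        assert labels[0] == 2 and matched[0] == 0
        np.testing.assert_allclose(targets[0], 0, atol=1e-12)

    def test_low_iou_is_background(self):
        proposals = np.array([[0, 0, 10, 10], [0, 0, 14.5, 10]])
        gt = np.array([[0, 0, 14.5, 10]])  # first proposal IoU ~0.69 -> pos rule
        labels, _, _ = assign_training_targets(
            np.array([[0, 0, 4, 10], [0, 0, 10, 10]]), gt, np.array([0]))
        # IoU of first proposal = 40/145 < 0.5 -> background
        assert labels[0] == 0 and labels[1] == 1

    def test_disjoint_and_empty_gt_are_background(self):
        proposals = np.array([[0, 0, 5, 5]])
        labels, _, _ = assign_training_targets(
            proposals, np.array([[20, 20, 30, 30]]), np.array([0]))
        assert labels[0] == 0 or labels[0] == 1  # may be forced as best match
        labels, _, _ = assign_training_targets(
            proposals, np.zeros((0, 4)), np.zeros(0, int))
        assert labels[0] == 0

    def test_best_proposal_forced_positive(self):
        proposals = np.array([[0, 0, 10, 10], [0, 0, 10.1, 10]])
        gt = np.array([[6, 0, 10, 10]])  # both proposals IoU 0.4 < 0.5
        labels, matched, _ = assign_training_targets(proposals, gt,
                                                     np.array([1]))
        assert (labels > 0).sum() >= 1  # the best one is kept


class TestPostprocess:
    def test_empty_input(self):
        out = postprocess_detections(np.zeros((0, 3)), np.zeros((0, 8)),
                                     np.zeros((0, 4)), (64, 64), 0.5, 0.5)
        assert len(out) == 0

    def test_duplicate_same_class_suppressed(self):
        probs = np.array([[0.05, 0.9, 0.05], [0.15, 0.8, 0.05]])
        deltas = np.zeros((2, 8))
        proposals = np.array([[0, 0, 10, 10], [0, 0, 10, 10]])
        out = postprocess_detections(probs, deltas, proposals, (64, 64),
                                     0.5, 0.5)
        assert len(out) == 1
        assert out.scores[0] == pytest.approx(0.9)

    def test_duplicate_different_class_both_survive(self):
        probs = np.array([[0.05, 0.9, 0.05], [0.15, 0.05, 0.8]])
        deltas = np.zeros((2, 8))
        proposals = np.array([[0, 0, 10, 10], [0, 0, 10, 10]])
        out = postprocess_detections(probs, deltas, proposals, (64, 64),
                                     0.5, 0.5)
        assert len(out) == 2
        assert set(out.class_ids) == {0, 1}

    def test_scores_sorted_descending(self):
        probs = np.array([[0.1, 0.6, 0.3], [0.1, 0.3, 0.6], [0.2, 0.7, 0.1]])
        deltas = np.zeros((3, 8))
        proposals = np.array([[0, 0, 10, 10], [20, 20, 30, 30],
                              [40, 40, 50, 50]])
        out = postprocess_detections(probs, deltas, proposals, (64, 64),
                                     0.5, 0.5)
        assert np.all(np.diff(out.scores) <= 1e-12)


class TestProposals:
    def test_uniform_objectness_keeps_deterministic_order_and_clips(
            self, tiny_config, rng):
        det = DetectorConfig(fpn_channels=16, anchor_scales=(8, 16, 32, 64),
                             rpn_topk_infer=20)
        model = WaterDeficitDetector(tiny_config, rng, det)
        pyramid = model.fpn(model.backbone(rng.random((1, 64, 64, 3))))
        anchors = model.anchors_for(pyramid)
        objectness = np.zeros(len(anchors))
        deltas = np.zeros((len(anchors), 4))
        boxes, scores = model.propose(objectness, deltas, anchors, (64, 64),
                                      topk=20)
        assert len(boxes) <= 20
        assert boxes[:, 0].min() >= 0 and boxes[:, 2].max() <= 64
        assert boxes[:, 1].min() >= 0 and boxes[:, 3].max() <= 64
        # rerun is bit-identical (no stochastic tie-breaking)
        boxes2, _ = model.propose(objectness, deltas, anchors, (64, 64),
                                  topk=20)
        np.testing.assert_array_equal(boxes, boxes2)


class TestDetectionSet:
    def test_unsorted_scores_rejected(self):
        with pytest.raises(ValueError):
            DetectionSet(np.array([[0, 0, 2, 2], [1, 1, 3, 3]]),
                         np.array([0.2, 0.9]), np.array([0, 0]))
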