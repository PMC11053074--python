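"""Detection/segmentation/classification metrics against hand-worked cases."""

import numpy as np
import pytest

from verdure.evaluation import (MAP_THRESHOLDS, average_precision, box_iou,
                                classifier_metrics, fps_from_latency,
                                map_range, mask_iou_dice)


class TestBoxIoU:
    def test_identical_and_disjoint(self):
        assert box_iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0
        assert box_iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_partial_overlap_fraction(self):
        # intersection 1, union 7
        assert box_iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)


class TestAveragePrecision:
    def test_perfect_detections(self):
        dets = [(0, 0.9, (0, 0, 10, 10)), (1, 0.8, (5, 5, 9, 9))]
        gts = {0: [(0, 0, 10, 10)], 1: [(5, 5, 9, 9)]}
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)

    def test_no_detections(self):
        assert average_precision([], {0: [(0, 0, 5, 5)]}, 0.5) == 0.0

    def test_empty_ground_truth_warns_zero(self):
        with pytest.warns(UserWarning):
            assert average_precision([(0, 0.9, (0, 0, 5, 5))], {}, 0.5) == 0.0

    def test_one_tp_one_fp_full_ap_at_half(self):
        # GT box; TP at IoU 0.8 (score 0.9) plus a lower-scored FP.
        dets = [(0, 0.9, (0, 0, 8, 10)), (0, 0.5, (50, 50, 60, 60))]
        gts = {0: [(0, 0, 10, 10)]}
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)
        assert average_precision(dets, gts, 0.85) == 0.0

    def test_low_scored_fp_never_raises_ap(self):
        dets = [(0, 0.9, (0, 0, 10, 10))]
        gts = {0: [(0, 0, 10, 10)]}
        base = average_precision(dets, gts, 0.5)
        with_fp = average_precision(
            dets + [(0, 0.0, (30, 30, 40, 40))], gts, 0.5)
        assert with_fp <= base

    def test_each_gt_matched_once(self):
        # a duplicate detection on an already-matched GT is a false positive;
        # placed before full recall it must depress the precision envelope
        dets = [(0, 0.9, (0, 0, 10, 10)), (0, 0.8, (0, 0, 10, 10)),
                (1, 0.7, (20, 20, 30, 30))]
        gts = {0: [(0, 0, 10, 10)], 1: [(20, 20, 30, 30)]}
        ap = average_precision(dets, gts, 0.5)
        # tp pattern (1, 0, 1): precision at full recall is 2/3
        expected = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert ap == pytest.approx(expected)


class TestMapRange:
    def test_single_threshold_equals_ap(self):
        dets = [(0, 0.9, (0, 0, 8, 10))]
        gts = {0: [(0, 0, 10, 10)]}
        assert map_range(dets, gts, thresholds=[0.5]) == pytest.approx(
            average_precision(dets, gts, 0.5))

    def test_iou_08_true_positive_scores_seven_ninths(self):
        dets = [(0, 0.9, (0, 0, 8, 10)), (0, 0.5, (50, 50, 60, 60))]
        gts = {0: [(0, 0, 10, 10)]}
        assert map_range(dets, gts) == pytest.approx(7 / 9)

    def test_monotone_in_threshold(self):
        dets = [(0, 0.9, (0, 0, 8, 10)), (0, 0.7, (20, 20, 26, 30))]
        gts = {0: [(0, 0, 10, 10)], 1: [(20, 20, 30, 30)]}
        aps = [average_precision(dets, gts, t) for t in MAP_THRESHOLDS]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_default_sweep_has_nine_thresholds(self):
        assert len(MAP_THRESHOLDS) == 9
        assert MAP_THRESHOLDS[0] == 0.5 and MAP_THRESHOLDS[-1] == 0.9


class TestClassifierMetrics:
    def test_all_correct_and_all_wrong(self):
        assert classifier_metrics([1, 0, 1], [1, 0, 1])["accuracy"] == 1.0
        assert classifier_metrics([0, 1, 0], [1, 0, 1])["accuracy"] == 0.0

    def test_counts_sum_to_n(self):
        m = classifier_metrics([1, 0, 1, 1], [1, 1, 0, 1])
        assert m["TP"] + m["TN"] + m["FP"] + m["FN"] == m["N"] == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classifier_metrics([1, 0], [1])


class TestMaskMetrics:
    def test_identical_disjoint_empty(self):
        a = np.zeros((4, 4), int); a[:2] = 1
        b = np.zeros((4, 4), int); b[2:] = 1
        assert mask_iou_dice(a, a) == (1.0, 1.0)
        assert mask_iou_dice(a, b) == (0.0, 0.0)
        z = np.zeros((4, 4), int)
        assert mask_iou_dice(z, z) == (1.0, 1.0)

    def test_half_overlap_equal_area(self):
        a = np.zeros((4, 4), int); a[:, :2] = 1
        b = np.zeros((4, 4), int); b[:, 1:3] = 1
        iou, dice = mask_iou_dice(a, b)
        assert iou == pytest.approx(1 / 3)
        assert dice == pytest.approx(1 / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_iou_dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestFps:
    def test_reciprocal_in_milliseconds(self):
        assert fps_from_latency(1000) == 1.0
        assert fps_from_latency(100) == 10.0
        assert fps_from_latency(50) == 2 * fps_from_latency(100)

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(ValueError):
            fps_from_latency(0)
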