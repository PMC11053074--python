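"""Evaluation metrics: mAP over an IoU sweep, classifier and mask metrics.

Detection accuracy is summarized as mean average precision (mAP) over a range
of IoU thresholds — by default 0.50 to 0.90 in steps of 0.05 (nine
thresholds), written mAP@[0.5, 0.9].  Throughput is reported as FPS =
1 / latency with latency in milliseconds.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_matrix

__all__ = [
    "MAP_THRESHOLDS", "box_iou", "average_precision", "map_range",
    "classifier_metrics", "mask_iou_dice", "fps_from_latency", "EvalReport",
    "measure_latency",
]

#: IoU thresholds 0.50:0.90:0.05.  COCO's 0.50:0.95 sweep is one config away.
MAP_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))
MAP_THRESHOLDS_COCO: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def box_iou(a, b) -> float:
    """Intersection over union of two boxes (half-open convention)."""
    a = a.as_array() if hasattr(a, "as_array") else np.asarray(a, float)
    b = b.as_array() if hasattr(b, "as_array") else np.asarray(b, float)
    return float(iou_matrix(a, b)[0, 0])


def _prepare(detections) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize detections to (image_ids, scores, boxes) arrays.

    ``detections`` is a list of ``(image_id, score, box)`` triples, already
    restricted to one class.
    """
    if len(detections) == 0:
        return np.zeros(0, int), np.zeros(0), np.zeros((0, 4))
    ids = np.array([d[0] for d in detections])
    scores = np.array([float(d[1]) for d in detections])
    boxes = np.array([np.asarray(d[2], float) for d in detections])
    return ids, scores, boxes


def average_precision(detections, ground_truth, iou_thr: float,
                      n_points: int = 101) -> float:
    """AP for one class at one IoU threshold.

    ``detections``: list of ``(image_id, score, box)``; ``ground_truth``:
    mapping ``image_id -> (M, 4)`` array of boxes.  Detections are matched
    greedily in order of (score descending, index ascending); each ground
    truth box can absorb at most one detection.  AP is the area under the
    interpolated precision-recall curve sampled at ``n_points`` evenly spaced
    recall levels (101-point interpolation by default; pass 11 for the older
    convention).
    """
    n_gt = sum(len(np.asarray(b).reshape(-1, 4)) for b in ground_truth.values())
    if n_gt == 0:
        warnings.warn("average_precision with empty ground truth; AP := 0")
        return 0.0
    ids, scores, boxes = _prepare(detections)
    if len(ids) == 0:
        return 0.0
    order = np.lexsort((np.arange(len(scores)), -scores))
    matched: dict[object, np.ndarray] = {
        k: np.zeros(len(np.asarray(v).reshape(-1, 4)), dtype=bool)
        for k, v in ground_truth.items()}
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        img = ids[i]
        if img not in ground_truth:
            continue
        gt = np.asarray(ground_truth[img], float).reshape(-1, 4)
        if len(gt) == 0:
            continue
        ious = iou_matrix(boxes[i], gt)[0]
        ious = np.where(matched[img], -1.0, ious)
        j = int(np.argmax(ious))
        if ious[j] >= iou_thr:
            matched[img][j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, len(tp) + 1)
    # interpolated precision: running max from the right
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    levels = np.linspace(0, 1, n_points)
    ap = 0.0
    for r in levels:
        idx = np.searchsorted(recall, r, side="left")
        ap += p_interp[idx] if idx < len(p_interp) else 0.0
    return float(ap / n_points)


def map_range(detections_by_class, ground_truth_by_class,
              thresholds=MAP_THRESHOLDS, n_points: int = 101) -> float:
    """Mean AP over IoU thresholds (and over classes when several are given).

    ``detections_by_class``: mapping ``class_id -> detection list`` (or a
    bare detection list for the single-class case); ``ground_truth_by_class``
    likewise.
    """
    if not len(thresholds):
        raise ValueError("thresholds must be non-empty")
    if not isinstance(detections_by_class, dict):
        detections_by_class = {0: detections_by_class}
        ground_truth_by_class = {0: ground_truth_by_class}
    aps = [
        average_precision(detections_by_class.get(c, []), gts, thr, n_points)
        for c, gts in ground_truth_by_class.items()
        for thr in thresholds
    ]
    return float(np.mean(aps)) if aps else 0.0


def classifier_metrics(predictions, labels) -> dict[str, float]:
    """Confusion counts and accuracy for binary verdicts (1 = positive)."""
    predictions = np.asarray(predictions).astype(int).reshape(-1)
    labels = np.asarray(labels).astype(int).reshape(-1)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    n = len(labels)
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn, "N": n,
            "accuracy": (tp + tn) / n if n else 0.0}


def mask_iou_dice(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """IoU and Dice of two binary masks; two empty masks agree perfectly."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    inter = int(np.sum(pred & gt))
    union = int(np.sum(pred | gt))
    total = int(pred.sum()) + int(gt.sum())
    if union == 0:
        return 1.0, 1.0
    return inter / union, 2.0 * inter / total


def fps_from_latency(latency_ms: float) -> float:
    """Frames per second from a per-image latency in milliseconds."""
    if latency_ms <= 0:
        raise ValueError("latency must be positive")
    return 1000.0 / latency_ms


def measure_latency(fn, image, repeats: int = 3) -> float:
    """Median wall-clock latency of ``fn(image)`` in milliseconds."""
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        fn(image)
        times.append((time.perf_counter() - t0) * 1000.0)
    return float(np.median(times))


@dataclass
class EvalReport:
    """Aggregated metrics for one evaluation run."""

    per_threshold_ap: dict[float, float] = field(default_factory=dict)
    mAP: float = 0.0
    classifier: dict[str, float] = field(default_factory=dict)
    mask_iou: float = 0.0
    mask_dice: float = 0.0
    latency_ms: float | None = None

    @property
    def fps(self) -> float | None:
        return None if self.latency_ms is None else fps_from_latency(self.latency_ms)

    def to_dict(self) -> dict:
        d = {"per_threshold_ap": {str(k): v for k, v in self.per_threshold_ap.items()},
             "mAP": self.mAP, "classifier": self.classifier,
             "mask_iou": self.mask_iou, "mask_dice": self.mask_dice}
        if self.latency_ms is not None:
            d["latency_ms"] = self.latency_ms
            d["fps"] = self.fps
        return d
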