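"""Axis-aligned box containers and geometry helpers.

Convention (frozen across the package): boxes are 0-based, half-open
``[x_min, x_max) x [y_min, y_max)`` in pixel coordinates, stored as
``(x_min, y_min, x_max, y_max)``.  Pascal VOC's 1-based inclusive
coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Box", "DetectionSet", "iou_matrix", "clip_boxes", "nms",
           "box_areas"]

CLASS_NAMES = ("water_deficient", "dead")


@dataclass(frozen=True)
class Box:
    """One scored, class-labelled box."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int = 0
    score: float = 1.0

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max],
                        dtype=float)


@dataclass
class DetectionSet:
    """Scored detections for one image, sorted by descending score.

    ``boxes`` is ``(N, 4)``; ``scores`` and ``class_ids`` are ``(N,)``.
    ``provenance`` records the model version and thresholds that produced
    the set.
    """

    boxes: np.ndarray
    scores: np.ndarray
    class_ids: np.ndarray
    image_ref: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        self.class_ids = np.asarray(self.class_ids, dtype=int).reshape(-1)
        if not (len(self.boxes) == len(self.scores) == len(self.class_ids)):
            raise ValueError("boxes, scores and class_ids must align")
        if len(self.scores) > 1 and np.any(np.diff(self.scores) > 1e-9):
            raise ValueError("detections must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        for b, s, c in zip(self.boxes, self.scores, self.class_ids):
            yield Box(*b, class_id=int(c), score=float(s))

    @staticmethod
    def empty(image_ref: str = "") -> "DetectionSet":
        return DetectionSet(np.zeros((0, 4)), np.zeros(0), np.zeros(0, int),
                            image_ref)


def box_areas(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    return (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union, ``(len(a), len(b))``."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = box_areas(a)[:, None] + box_areas(b)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def clip_boxes(boxes: np.ndarray, height: int, width: int) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, width)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, height)
    return boxes


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices.

    Deterministic tie rule: candidates are visited by (score descending,
    original index ascending), so equal-scored duplicates keep the earliest.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    ious = iou_matrix(boxes, boxes)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= ious[i] > iou_thr
        suppressed[i] = True
    return np.array(keep, dtype=int)
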