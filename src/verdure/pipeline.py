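"""Pipeline orchestration: gating workflow, analytics, splits, training.

The end-to-end flow for one captured frame:

1. the blur classifier scores the frame; blurry frames are filtered;
2. the segmenter masks the greenery; frames whose greenery proportion falls
   below the area threshold are filtered, all others have their background
   blacked out;
3. the detector finds water-deficient and dead plants on the masked frame,
   and the deficit ratio — union area of the predicted boxes over the
   greenery area — summarizes the stand's condition.

Whenever a frame is filtered, a re-shoot is scheduled after a waiting
period; a frame that has been re-shot ``max_reshoots`` times is flagged
terminal instead of being re-scheduled, so processing always terminates.

Training is stage-wise and sequential: each stage starts from the previous
stage's best backbone weights (matching names and shapes only) and earlier
stages stay frozen — they are separate models whose saved weights are never
revisited.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import DetectionSet
from .classifier import BlurClassifier, blur_gate, train_classifier
from .gating import GateDecision
from .segmenter import (GreenerySegmenter, apply_background_mask, area_gate,
                        greenery_proportion, train_segmenter)
from .detector import WaterDeficitDetector, train_detector

__all__ = ["SplitResult", "split_dataset", "CaptureRecord", "PipelineReport",
           "PipelineModels", "process_capture", "deficit_ratio",
           "train_multistage", "report_generate", "EventLogger"]


# ---------------------------------------------------------------------------
# dataset splitting


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive train/val/test index lists."""

    train: list[int]
    val: list[int]
    test: list[int]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def split_dataset(n: int, ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> SplitResult:
    """Random split with the frozen rounding rule.

    Indices are shuffled with ``seed``; ``train = floor(n * r_t / sum)``,
    and the remainder is divided ``val = floor(rem * r_v / (r_v + r_te))``,
    ``test = rem - val``.  With the default 8:1:1 ratio this reproduces
    e.g. 5808 -> (4646, 581, 581) and 3980 -> (3184, 398, 398).
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    r_train, r_val, r_test = ratios
    total = r_train + r_val + r_test
    order = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(n * r_train / total)
    rem = n - n_train
    n_val = math.floor(rem * r_val / (r_val + r_test))
    return SplitResult(
        train=[int(i) for i in order[:n_train]],
        val=[int(i) for i in order[n_train:n_train + n_val]],
        test=[int(i) for i in order[n_train + n_val:]])


# ---------------------------------------------------------------------------
# capture processing


@dataclass
class CaptureRecord:
    """One camera slot's current frame and its gating history."""

    image: np.ndarray
    capture_id: str = ""
    reshoot_count: int = 0
    terminal: bool = False
    history: list[GateDecision] = field(default_factory=list)


@dataclass
class PipelineReport:
    """Final analytics for a frame that passed every gate."""

    deficit_ratio: float
    greenery_area_px: int
    deficit_area_px: int
    detections: DetectionSet
    gates: list[GateDecision]
    capture_id: str = ""

    def to_dict(self) -> dict:
        return {
            "capture_id": self.capture_id,
            "deficit_ratio": self.deficit_ratio,
            "greenery_area_px": self.greenery_area_px,
            "deficit_area_px": self.deficit_area_px,
            "n_detections": len(self.detections),
            "gates": [g.outcome.value for g in self.gates],
        }


@dataclass
class PipelineModels:
    """The three trained stage models."""

    classifier: BlurClassifier
    segmenter: GreenerySegmenter
    detector: WaterDeficitDetector


def deficit_ratio(detections: DetectionSet, mask: np.ndarray,
                  union: bool = True) -> float:
    """Union area of predicted boxes over the greenery area, in [0, 1].

    The numerator counts each pixel once however many boxes cover it
    (overlapping plants are not double-counted); ``union=False`` switches to
    the plain sum of box areas.  Box pixel membership uses the package's
    center rule.  An empty greenery mask leaves the ratio undefined.
    """
    mask = np.asarray(mask)
    greenery = int((mask > 0).sum())
    if greenery == 0:
        raise ValueError("deficit ratio undefined: empty greenery mask")
    h, w = mask.shape
    if union:
        canvas = np.zeros((h, w), dtype=bool)
        for box in detections.boxes:
            x0, y0, x1, y1 = box
            xs = max(0, math.ceil(x0 - 0.5))
            xe = min(w, math.ceil(x1 - 0.5))
            ys = max(0, math.ceil(y0 - 0.5))
            ye = min(h, math.ceil(y1 - 0.5))
            if xe > xs and ye > ys:
                canvas[ys:ye, xs:xe] = True
        deficit = int(canvas.sum())
    else:
        deficit = 0
        for box in detections.boxes:
            x0, y0, x1, y1 = np.clip(box, [0, 0, 0, 0], [w, h, w, h])
            deficit += int(max(0.0, x1 - x0) * max(0.0, y1 - y0))
    if deficit > greenery:
        warnings.warn("deficit area exceeds greenery area; ratio clipped to 1")
    return min(1.0, deficit / greenery)


def process_capture(record: CaptureRecord, models: PipelineModels, *,
                    blur_threshold: float = 0.5, area_threshold: float = 0.4,
                    mask_threshold: float = 0.5, wait_s: float = 0.0,
                    max_reshoots: int = 3, now: float = 0.0,
                    log=None) -> GateDecision | PipelineReport:
    """Run one frame through the three gates.

    Returns the filtering :class:`GateDecision` as soon as any gate fires
    (with a re-shoot scheduled at ``now + wait_s`` unless the record has
    exhausted ``max_reshoots``, in which case it is flagged terminal), or
    the full :class:`PipelineReport` when every gate passes.  The detector
    is never invoked without a stage-2 PASS.
    """

    def filtered(decision: GateDecision) -> GateDecision:
        if record.reshoot_count >= max_reshoots:
            record.terminal = True
            decision.reshoot_at = None
        else:
            record.reshoot_count += 1
        record.history.append(decision)
        if log is not None:
            log({"capture_id": record.capture_id,
                 "outcome": decision.outcome.value, "scores": decision.scores,
                 "reshoot_at": decision.reshoot_at,
                 "terminal": record.terminal})
        return decision

    verdict = models.classifier.predict(record.image, threshold=blur_threshold)
    decision1 = blur_gate(verdict, now=now, wait_s=wait_s)
    if not decision1.passed:
        return filtered(decision1)
    record.history.append(decision1)

    mask = models.segmenter.predict_mask(record.image,
                                         threshold=mask_threshold)
    proportion = greenery_proportion(mask)
    decision2 = area_gate(proportion, area_threshold, now=now, wait_s=wait_s)
    if not decision2.passed:
        return filtered(decision2)
    record.history.append(decision2)

    masked = apply_background_mask(record.image, mask)
    detections = models.detector.detect(masked)
    ratio = deficit_ratio(detections, mask) if mask.any() else 0.0
    report = PipelineReport(
        deficit_ratio=ratio,
        greenery_area_px=int((mask > 0).sum()),
        deficit_area_px=int(round(ratio * (mask > 0).sum())),
        detections=detections,
        gates=list(record.history),
        capture_id=record.capture_id)
    if log is not None:
        log({"capture_id": record.capture_id, "outcome": "report",
             **report.to_dict()})
    return report


# ---------------------------------------------------------------------------
# stage-wise training


def train_multistage(datasets: dict, config, *, seed: int = 0,
                     log=None) -> tuple[PipelineModels, dict]:
    """Sequential three-stage training with frozen hand-over.

    ``datasets`` keys: ``cls`` -> ``(images, labels)``, ``seg`` ->
    ``(images, masks)``, ``det`` -> ``(images, annotations)``; each may add
    a ``*_val`` twin.  ``config`` is a :class:`~verdure.config.PipelineConfig`.
    Each stage initializes its backbone from the previous stage's best
    weights (matching names/shapes; everything else stays random), and the
    previous stage's saved weights are never modified again.
    """
    bb = config.backbone_config()
    cls_imgs, cls_labels = datasets["cls"]
    val = datasets.get("cls_val", (None, None))
    classifier, h1 = train_classifier(
        cls_imgs, cls_labels, bb, epochs=config.stage1.epochs,
        lr=config.stage1.lr, batch_size=config.batch_size, seed=seed,
        val_images=val[0], val_labels=val[1], log=log)
    stage1_state = classifier.state_dict()
    backbone_state = {k: v for k, v in stage1_state.items()
                     if k.startswith("backbone.")}

    seg_imgs, seg_masks = datasets["seg"]
    val = datasets.get("seg_val", (None, None))
    segmenter, h2 = train_segmenter(
        seg_imgs, seg_masks, bb, epochs=config.stage2.epochs,
        lr=config.stage2.lr, batch_size=config.batch_size,
        seed=seed + 1, init_state=backbone_state,
        val_images=val[0], val_masks=val[1], log=log)
    stage2_backbone = {k: v for k, v in segmenter.state_dict().items()
                      if k.startswith("backbone.")}

    det_imgs, det_anns = datasets["det"]
    detector, h3 = train_detector(
        det_imgs, det_anns, bb, det=config.detector_config(),
        epochs=config.stage3.epochs, lr=config.stage3.lr, seed=seed + 2,
        init_state=stage2_backbone, log=log)

    models = PipelineModels(classifier, segmenter, detector)
    history = {"stage1": h1, "stage2": h2, "stage3": h3,
               "stage1_state": stage1_state}
    return models, history


# ---------------------------------------------------------------------------
# reporting


def report_generate(rows, reference: str) -> dict:
    """Percentage-point improvements of ``reference`` over each other row.

    ``rows``: mapping ``model name -> mAP`` (percent scale) or a list of
    ``(name, mAP)`` pairs.  Returns the improvements and a rendered text
    table.
    """
    if not isinstance(rows, dict):
        rows = dict(rows)
    if reference not in rows:
        raise ValueError(f"reference row '{reference}' missing from table")
    ref = rows[reference]
    improvements = {name: round(ref - value, 10)
                    for name, value in rows.items() if name != reference}
    width = max((len(n) for n in rows), default=5)
    lines = [f"{'model':<{width}}  mAP    vs {reference}"]
    for name, value in rows.items():
        delta = "" if name == reference else f"+{ref - value:.1f}"
        lines.append(f"{name:<{width}}  {value:5.1f}  {delta}")
    return {"reference": reference, "rows": dict(rows),
            "improvements": improvements, "text": "\n".join(lines)}


class EventLogger:
    """Structured JSONL event log (one JSON object per line)."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.path, "a")

    def __call__(self, event: dict) -> None:
        self._fh.write(json.dumps(event, default=_jsonable) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
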