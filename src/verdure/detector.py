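"""Stage 3: region-proposal detection of water-deficient and dead plants.

A two-stage detector on the shared backbone: a lightweight top-down feature
pyramid, a region proposal network (RPN) over per-level anchors, RoI-aligned
region features, and a head predicting class scores plus per-class box
deltas.  There is no mask branch — the stage answers "where are the
water-deficient plants" with boxes only.

Boxes follow the package convention (0-based, half-open).  All tie-breaking
is deterministic: stable sort by (score descending, index ascending).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, PyramidFeatures, SwinBackbone
from .boxes import DetectionSet, box_areas, clip_boxes, iou_matrix, nms
from .losses import binary_cross_entropy, cross_entropy, smooth_l1
from .nn import Tensor, as_tensor
from .nn.functional import bilinear_resize

__all__ = ["DetectorConfig", "AnchorSet", "generate_anchors", "encode_boxes",
           "decode_boxes", "roi_align", "WaterDeficitDetector",
           "assign_training_targets", "postprocess_detections",
           "train_detector"]

STRIDES = (4, 8, 16, 32)

#: box-coder target weights (dx, dy, dw, dh): regression residuals are
#: scaled up so the smooth-L1 loss leaves its flat quadratic region and
#: localization learns at a rate comparable to classification
BOX_WEIGHTS = np.array([10.0, 10.0, 5.0, 5.0])


@dataclass(frozen=True)
class DetectorConfig:
    """Detector hyperparameters (anchors, proposal counts, thresholds)."""

    num_classes: int = 2
    fpn_channels: int = 128
    anchor_scales: tuple[float, ...] = (32.0, 64.0, 128.0, 256.0)
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_nms_iou: float = 0.7
    rpn_topk_train: int = 1000
    rpn_topk_infer: int = 300
    roi_size: int = 7
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    roi_pos_iou: float = 0.5

    def __post_init__(self):
        if len(self.anchor_scales) != 4:
            raise ValueError("one anchor scale per pyramid level (4) required")


@dataclass
class AnchorSet:
    """Anchor boxes per pyramid level, concatenated in level order."""

    per_level: list[np.ndarray]

    @property
    def all(self) -> np.ndarray:
        return np.concatenate(self.per_level, axis=0)

    def __len__(self) -> int:
        return sum(len(a) for a in self.per_level)


def generate_anchors(pyramid_shapes, scales=None, ratios=(0.5, 1.0, 2.0),
                     strides=STRIDES) -> AnchorSet:
    """One anchor scale per level, all aspect ratios at every location.

    ``pyramid_shapes`` is a list of ``(H, W)`` grid sizes.  Anchors are
    centered on the stride grid (cell centers), with area ``scale**2`` and
    height/width ratio ``r`` (a ratio-1 anchor is a square of side
    ``scale``).
    """
    if not pyramid_shapes:
        raise ValueError("empty pyramid")
    scales = scales if scales is not None else (32, 64, 128, 256)
    per_level = []
    for (h, w), scale, stride in zip(pyramid_shapes, scales, strides):
        cy = (np.arange(h) + 0.5) * stride
        cx = (np.arange(w) + 0.5) * stride
        cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
        anchors = []
        for r in ratios:
            ah = scale * np.sqrt(r)
            aw = scale / np.sqrt(r)
            anchors.append(np.stack([
                cxx - aw / 2, cyy - ah / 2, cxx + aw / 2, cyy + ah / 2],
                axis=-1))
        level = np.stack(anchors, axis=2).reshape(-1, 4)
        per_level.append(level)
    return AnchorSet(per_level)


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Center/log-size regression targets ``(dx, dy, dw, dh)``."""
    boxes = np.asarray(boxes, float).reshape(-1, 4)
    anchors = np.asarray(anchors, float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    if np.any(aw <= 0) or np.any(ah <= 0):
        raise FloatingPointError("zero-area anchor in encode_boxes")
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bcx = boxes[:, 0] + bw / 2
    bcy = boxes[:, 1] + bh / 2
    return np.stack([(bcx - acx) / aw, (bcy - acy) / ah,
                     np.log(bw / aw), np.log(bh / ah)], axis=1)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_boxes`."""
    deltas = np.asarray(deltas, float).reshape(-1, 4)
    anchors = np.asarray(anchors, float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    bcx = acx + deltas[:, 0] * aw
    bcy = acy + deltas[:, 1] * ah
    bw = aw * np.exp(deltas[:, 2])
    bh = ah * np.exp(deltas[:, 3])
    return np.stack([bcx - bw / 2, bcy - bh / 2,
                     bcx + bw / 2, bcy + bh / 2], axis=1)


# ---------------------------------------------------------------------------
# RoI align


def roi_align(fmap: Tensor, boxes: np.ndarray, output_size: int = 7,
              spatial_scale: float = 1.0, sampling_ratio: int = 2) -> Tensor:
    """Quantization-free region pooling by bilinear sampling.

    ``fmap`` is ``(C, H, W)``; ``boxes`` are in image coordinates and are
    multiplied by ``spatial_scale``.  Each output bin averages
    ``sampling_ratio**2`` regularly spaced bilinear samples; feature values
    sit at pixel centers.  Returns ``(N, C, output_size, output_size)``.
    """
    fmap = as_tensor(fmap)
    C, H, W = fmap.shape
    boxes = np.asarray(boxes, float).reshape(-1, 4) * spatial_scale
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise FloatingPointError("degenerate box in roi_align")
    N = len(boxes)
    out, sr = output_size, sampling_ratio
    # sample coordinates: (N, out*sr) per axis
    def axis_samples(lo, hi):
        binw = (hi - lo) / out
        offsets = (np.arange(out * sr) + 0.5) / sr  # in bin-units
        return lo[:, None] + offsets[None, :] * binw[:, None]

    xs = axis_samples(boxes[:, 0], boxes[:, 2])  # (N, out*sr)
    ys = axis_samples(boxes[:, 1], boxes[:, 3])
    u = np.clip(xs - 0.5, 0, W - 1)
    v = np.clip(ys - 0.5, 0, H - 1)
    j0 = np.clip(np.floor(u).astype(int), 0, W - 2) if W > 1 else np.zeros_like(u, int)
    i0 = np.clip(np.floor(v).astype(int), 0, H - 2) if H > 1 else np.zeros_like(v, int)
    fu = u - j0
    fv = v - i0

    data = fmap.data
    # gather rows then columns: (N, C, out*sr(y), out*sr(x))
    def gather(ii, jj, wy, wx):
        # ii: (N, Sy), jj: (N, Sx) -> values (N, C, Sy, Sx)
        vals = data[:, ii[:, :, None], jj[:, None, :]]  # (C, N, Sy, Sx)
        return vals.transpose(1, 0, 2, 3) * (wy[:, None, :, None] * wx[:, None, None, :])

    i1 = np.minimum(i0 + 1, H - 1)
    j1 = np.minimum(j0 + 1, W - 1)
    sampled = (gather(i0, j0, 1 - fv, 1 - fu) + gather(i0, j1, 1 - fv, fu)
               + gather(i1, j0, fv, 1 - fu) + gather(i1, j1, fv, fu))
    pooled = sampled.reshape(N, C, out, sr, out, sr).mean(axis=(3, 5))

    def backward(g):
        if not fmap.requires_grad:
            return
        gs = np.repeat(np.repeat(g, sr, axis=2), sr, axis=3) / (sr * sr)
        grad = np.zeros_like(data)
        for ii, jj, wy, wx in ((i0, j0, 1 - fv, 1 - fu), (i0, j1, 1 - fv, fu),
                               (i1, j0, fv, 1 - fu), (i1, j1, fv, fu)):
            contrib = gs * (wy[:, None, :, None] * wx[:, None, None, :])
            for n_idx in range(N):
                np.add.at(grad,
                          (slice(None), ii[n_idx][:, None], jj[n_idx][None, :]),
                          contrib[n_idx])
        fmap._accumulate(grad)

    return Tensor._make(pooled, [fmap], backward)


# ---------------------------------------------------------------------------
# network modules


class FeaturePyramid(nn.Module):
    """Top-down fusion of the four backbone levels to a common width."""

    def __init__(self, config: BackboneConfig, out_channels: int,
                 rng: np.random.Generator):
        c = config.embed_dim
        self.laterals = nn.ModuleList([
            nn.Linear(c * 2**i, out_channels, rng) for i in range(4)])
        self.smooth = nn.ModuleList([
            nn.Conv2d(out_channels, out_channels, 3, rng, padding=1)
            for _ in range(4)])

    def forward(self, feats: PyramidFeatures) -> list[Tensor]:
        """Returns NCHW maps at strides 4, 8, 16, 32."""
        laterals = [lat(f).transpose(0, 3, 1, 2)
                    for lat, f in zip(self.laterals, feats)]
        outs = [laterals[3]]
        for i in (2, 1, 0):
            up = bilinear_resize(outs[0], laterals[i].shape[2],
                                 laterals[i].shape[3])
            outs.insert(0, laterals[i] + up)
        return [s(o) for s, o in zip(self.smooth, outs)]


class RpnHead(nn.Module):
    """Shared 3x3 conv + two 1x1 heads: objectness and box deltas."""

    def __init__(self, channels: int, num_anchors: int,
                 rng: np.random.Generator):
        self.num_anchors = num_anchors
        self.conv = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.obj = nn.Conv2d(channels, num_anchors, 1, rng)
        self.reg = nn.Conv2d(channels, 4 * num_anchors, 1, rng)

    def forward(self, pyramid: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Flattened (per anchor) objectness logits and deltas, level order."""
        logits, deltas = [], []
        for p in pyramid:
            h = self.conv(p).relu()
            B, A = p.shape[0], self.num_anchors
            o = self.obj(h).transpose(0, 2, 3, 1).reshape(B, -1)
            d = self.reg(h).transpose(0, 2, 3, 1).reshape(B, -1, 4)
            logits.append(o)
            deltas.append(d)
        return nn.concat(logits, axis=1), nn.concat(deltas, axis=1)


class BoxHead(nn.Module):
    """Two hidden layers, then (K+1)-way scores and 4K per-class deltas."""

    def __init__(self, in_features: int, num_classes: int,
                 rng: np.random.Generator, hidden: int = 256):
        self.num_classes = num_classes
        self.fc1 = nn.Linear(in_features, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.cls = nn.Linear(hidden, num_classes + 1, rng)
        self.reg = nn.Linear(hidden, 4 * num_classes, rng)

    def forward(self, pooled: Tensor) -> tuple[Tensor, Tensor]:
        x = pooled.reshape(pooled.shape[0], -1)
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        return self.cls(x).softmax(axis=-1), self.reg(x)


class WaterDeficitDetector(nn.Module):
    """Backbone + feature pyramid + RPN + RoI head."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 det: DetectorConfig = DetectorConfig()):
        self.config = config
        self.det = det
        self.backbone = SwinBackbone(config, rng)
        self.fpn = FeaturePyramid(config, det.fpn_channels, rng)
        self.rpn = RpnHead(det.fpn_channels, len(det.aspect_ratios), rng)
        self.box_head = BoxHead(det.fpn_channels * det.roi_size**2,
                                det.num_classes, rng)

    # -- proposals --------------------------------------------------------

    def anchors_for(self, pyramid: list[Tensor]) -> AnchorSet:
        shapes = [(p.shape[2], p.shape[3]) for p in pyramid]
        return AnchorSet(generate_anchors(
            shapes, self.det.anchor_scales, self.det.aspect_ratios).per_level)

    def propose(self, objectness: np.ndarray, deltas: np.ndarray,
                anchors: AnchorSet, image_hw: tuple[int, int],
                topk: int) -> tuple[np.ndarray, np.ndarray]:
        """Decode, clip, NMS (0.7), keep top-k; deterministic tie order."""
        scores = 1.0 / (1.0 + np.exp(-objectness))
        boxes = decode_boxes(np.asarray(deltas) / BOX_WEIGHTS, anchors.all)
        boxes = clip_boxes(boxes, *image_hw)
        valid = (boxes[:, 2] - boxes[:, 0] > 1e-3) & \
                (boxes[:, 3] - boxes[:, 1] > 1e-3)
        idx = np.nonzero(valid)[0]
        order = idx[np.lexsort((idx, -scores[idx]))][:2000]
        keep = nms(boxes[order], scores[order], self.det.rpn_nms_iou)
        keep = order[keep][:topk]
        return boxes[keep], scores[keep]

    def roi_features(self, pyramid: list[Tensor], rois: np.ndarray) -> Tensor:
        """Pool each RoI from the pyramid level matching its size."""
        if len(rois) == 0:
            raise ValueError("no RoIs to pool")
        sizes = np.sqrt(box_areas(rois))
        scales = np.asarray(self.det.anchor_scales)
        level = np.argmin(np.abs(np.log2(sizes[:, None] / scales[None, :])
                                 + 1e-9), axis=1)
        pooled: list[Tensor | None] = [None] * len(rois)
        for lv in range(4):
            sel = np.nonzero(level == lv)[0]
            if len(sel) == 0:
                continue
            feats = roi_align(pyramid[lv][0], rois[sel],
                              output_size=self.det.roi_size,
                              spatial_scale=1.0 / STRIDES[lv])
            for slot, n_idx in enumerate(sel):
                pooled[n_idx] = feats[slot]
        return nn.stack(pooled, axis=0)

    # -- inference --------------------------------------------------------

    def detect(self, image: np.ndarray, score_thr: float | None = None,
               nms_iou: float | None = None) -> DetectionSet:
        x = _to_float(image)[None]
        pyramid = self.fpn(self.backbone(x))
        logits, deltas = self.rpn(pyramid)
        anchors = self.anchors_for(pyramid)
        proposals, _ = self.propose(logits.data[0], deltas.data[0], anchors,
                                    image.shape[:2], self.det.rpn_topk_infer)
        if len(proposals) == 0:
            return DetectionSet.empty()
        probs, reg = self.box_head(self.roi_features(pyramid, proposals))
        return postprocess_detections(
            probs.data, reg.data, proposals, image.shape[:2],
            self.det.score_threshold if score_thr is None else score_thr,
            self.det.nms_iou if nms_iou is None else nms_iou)


# ---------------------------------------------------------------------------
# target assignment and post-processing


def assign_training_targets(proposals: np.ndarray, gt_boxes: np.ndarray,
                            gt_classes: np.ndarray, pos_iou: float = 0.5
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label proposals against ground truth.

    Returns ``(labels, matched_gt, reg_targets)``: labels 0 = background,
    ``k+1`` = foreground class k; IoU >= ``pos_iou`` is positive, anything
    below is background, and each ground-truth box's best proposal is forced
    positive.  ``reg_targets`` encode the matched box against the proposal.
    """
    proposals = np.asarray(proposals, float).reshape(-1, 4)
    n = len(proposals)
    labels = np.zeros(n, dtype=int)
    matched = np.full(n, -1, dtype=int)
    targets = np.zeros((n, 4))
    gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
    if len(gt_boxes) == 0 or n == 0:
        return labels, matched, targets
    ious = iou_matrix(proposals, gt_boxes)
    best_gt = np.argmax(ious, axis=1)
    best_iou = ious[np.arange(n), best_gt]
    pos = best_iou >= pos_iou
    # every GT keeps its single best proposal even below the threshold
    for j in range(len(gt_boxes)):
        i = int(np.argmax(ious[:, j]))
        if ious[i, j] > 0:
            pos[i] = True
            best_gt[i] = j
    labels[pos] = np.asarray(gt_classes, int)[best_gt[pos]] + 1
    matched[pos] = best_gt[pos]
    if pos.any():
        targets[pos] = encode_boxes(gt_boxes[best_gt[pos]], proposals[pos])
    return labels, matched, targets


def postprocess_detections(class_probs: np.ndarray, deltas: np.ndarray,
                           proposals: np.ndarray, image_hw: tuple[int, int],
                           score_thr: float, nms_iou: float,
                           provenance: dict | None = None) -> DetectionSet:
    """Threshold, per-class NMS, global sort -> final :class:`DetectionSet`."""
    class_probs = np.asarray(class_probs, float)
    deltas = np.asarray(deltas, float)
    proposals = np.asarray(proposals, float).reshape(-1, 4)
    num_classes = class_probs.shape[1] - 1 if class_probs.size else 0
    all_boxes, all_scores, all_cls = [], [], []
    for k in range(num_classes):
        scores = class_probs[:, k + 1]
        keep = scores >= score_thr
        if not keep.any():
            continue
        boxes = decode_boxes(deltas[keep, 4 * k: 4 * k + 4] / BOX_WEIGHTS,
                             proposals[keep])
        boxes = clip_boxes(boxes, *image_hw)
        ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
        boxes, sc = boxes[ok], scores[keep][ok]
        if len(boxes) == 0:
            continue
        kept = nms(boxes, sc, nms_iou)
        all_boxes.append(boxes[kept])
        all_scores.append(sc[kept])
        all_cls.append(np.full(len(kept), k, dtype=int))
    if not all_boxes:
        return DetectionSet.empty()
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    cls = np.concatenate(all_cls)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return DetectionSet(boxes[order], scores[order], cls[order],
                        provenance=provenance or {})


def _to_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


# ---------------------------------------------------------------------------
# training


def train_detector(images, annotations, config: BackboneConfig, *,
                   det: DetectorConfig = DetectorConfig(), epochs: int = 100,
                   lr: float = 1e-5, seed: int = 0,
                   init_state: dict | None = None,
                   rpn_batch: int = 32, roi_batch: int = 32,
                   lr_schedule: str = "cosine", augment: bool = True,
                   log=None) -> tuple[WaterDeficitDetector, dict]:
    """Train RPN and RoI head jointly, one image per step.

    ``annotations``: list of ``(gt_boxes (M,4), gt_classes (M,))`` per image.
    The classification term is categorical cross-entropy over softmax
    scores; box terms are smooth L1 on the center/log-size residuals of
    positive samples.  Best-epoch weights (by training loss) are restored.
    """
    rng = np.random.default_rng(seed)
    model = WaterDeficitDetector(config, rng, det)
    if init_state is not None:
        model.load_state_dict(init_state, strict=False)
    opt = nn.Adam(model.parameters(), lr=lr)
    x = [(_to_float(im)) for im in images]
    history = {"loss": []}
    best = (np.inf, model.state_dict())
    n = len(x)
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            opt.set_cosine_lr(epoch, epochs)
        order = rng.permutation(n)
        losses = []
        for i in order:
            gt_boxes, gt_classes = annotations[i]
            gt_boxes = np.asarray(gt_boxes, float).reshape(-1, 4)
            gt_classes = np.asarray(gt_classes, int).reshape(-1)
            image = x[i]
            if augment:
                image, gt_boxes = _random_dihedral_with_boxes(
                    image, gt_boxes, rng)
            image_hw = image.shape[:2]
            pyramid = model.fpn(model.backbone(image[None]))
            logits, deltas = model.rpn(pyramid)
            anchors = model.anchors_for(pyramid)
            loss = _rpn_loss(logits[0], deltas[0], anchors.all, gt_boxes,
                             image_hw, rng, rpn_batch)
            proposals, _ = model.propose(
                logits.data[0], deltas.data[0], anchors, image_hw,
                det.rpn_topk_train)
            rois = np.concatenate([proposals, gt_boxes]) if len(gt_boxes) \
                else proposals
            if len(rois):
                loss = loss + _roi_loss(model, pyramid, rois, gt_boxes,
                                        gt_classes, rng, roi_batch, det)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_loss = float(np.mean(losses))
        history["loss"].append(epoch_loss)
        if epoch_loss < best[0]:
            best = (epoch_loss, model.state_dict())
        if log is not None:
            log({"stage": 3, "epoch": epoch, "loss": epoch_loss})
    model.load_state_dict(best[1])
    history["best_loss"] = best[0]
    return model, history


def _random_dihedral_with_boxes(image: np.ndarray, boxes: np.ndarray,
                                rng: np.random.Generator):
    """Random flip / 90-degree rotation of a square image and its boxes."""
    size = image.shape[0]
    k = int(rng.integers(4))
    flip = bool(rng.integers(2))
    image = np.rot90(image, k, axes=(0, 1))
    if flip:
        image = image[:, ::-1]
    out = boxes.copy()
    for _ in range(k):  # quarter turn: (x, y) -> (y, size - x)
        x0, y0, x1, y1 = out[:, 0].copy(), out[:, 1].copy(), \
            out[:, 2].copy(), out[:, 3].copy()
        out = np.stack([y0, size - x1, y1, size - x0], axis=1)
    if flip:
        x0, x1 = out[:, 0].copy(), out[:, 2].copy()
        out[:, 0] = size - x1
        out[:, 2] = size - x0
    return np.ascontiguousarray(image), out


def _rpn_loss(logits: Tensor, deltas: Tensor, anchors: np.ndarray,
              gt_boxes: np.ndarray, image_hw, rng, batch: int) -> Tensor:
    inside = ((anchors[:, 0] >= -16) & (anchors[:, 1] >= -16)
              & (anchors[:, 2] <= image_hw[1] + 16)
              & (anchors[:, 3] <= image_hw[0] + 16))
    labels = np.full(len(anchors), -1)  # -1 = ignored
    if len(gt_boxes):
        ious = iou_matrix(anchors, gt_boxes)
        best = ious.max(axis=1)
        labels[inside & (best < 0.3)] = 0
        labels[inside & (best >= 0.7)] = 1
        for j in range(len(gt_boxes)):
            col = np.where(inside, ious[:, j], -1.0)
            labels[int(np.argmax(col))] = 1
    else:
        labels[inside] = 0
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    n_pos = min(len(pos), batch // 2)
    pos = rng.choice(pos, n_pos, replace=False) if n_pos else pos[:0]
    n_neg = min(len(neg), batch - n_pos)
    neg = rng.choice(neg, n_neg, replace=False) if n_neg else neg[:0]
    sample = np.concatenate([pos, neg]).astype(int)
    if len(sample) == 0:
        return Tensor(0.0)
    obj = logits[sample].sigmoid()
    target = (labels[sample] == 1).astype(np.float32)
    loss = binary_cross_entropy(Tensor(target), obj)
    if len(pos) and len(gt_boxes):
        ious = iou_matrix(anchors[pos], gt_boxes)
        match = np.argmax(ious, axis=1)
        enc = encode_boxes(gt_boxes[match], anchors[pos]) * BOX_WEIGHTS
        residual = deltas[pos] - Tensor(enc)
        loss = loss + smooth_l1(residual, n=residual.size)
    return loss


def _roi_loss(model: WaterDeficitDetector, pyramid, rois, gt_boxes,
              gt_classes, rng, batch: int, det: DetectorConfig) -> Tensor:
    labels, matched, targets = assign_training_targets(
        rois, gt_boxes, gt_classes, det.roi_pos_iou)
    pos = np.nonzero(labels > 0)[0]
    neg = np.nonzero(labels == 0)[0]
    n_pos = min(len(pos), batch // 2)
    pos = rng.choice(pos, n_pos, replace=False) if n_pos else pos[:0]
    n_neg = min(len(neg), batch - n_pos)
    neg = rng.choice(neg, n_neg, replace=False) if n_neg else neg[:0]
    sample = np.concatenate([pos, neg]).astype(int)
    if len(sample) == 0:
        return Tensor(0.0)
    probs, reg = model.box_head(model.roi_features(pyramid, rois[sample]))
    onehot = np.eye(det.num_classes + 1)[labels[sample]]
    loss = cross_entropy(Tensor(onehot), probs)
    if len(pos):
        cls = labels[pos] - 1
        reg_pos = reg[:len(pos)]
        sel = np.stack([4 * cls, 4 * cls + 1, 4 * cls + 2, 4 * cls + 3],
                       axis=1)
        rows = np.repeat(np.arange(len(pos))[:, None], 4, axis=1)
        residual = reg_pos[rows, sel] - Tensor(targets[pos] * BOX_WEIGHTS)
        loss = loss + smooth_l1(residual, n=residual.size)
    return loss
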