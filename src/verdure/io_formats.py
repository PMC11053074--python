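"""Annotation and result I/O: labelme JSON, Pascal VOC XML, COCO JSON, masks.

Coordinate conventions (frozen):

* internal boxes: 0-based, half-open ``[min, max)``;
* Pascal VOC: 1-based, inclusive — read as ``(xmin-1, ymin-1, xmax, ymax)``,
  written back as the exact inverse, so integer boxes round-trip bit-exactly;
* COCO: 0-based ``(x, y, width, height)``;
* polygon rasterization: a pixel belongs to the mask iff its center
  ``(x + 0.5, y + 0.5)`` is inside the polygon under the even-odd rule.
  The rule matters: rasterized areas feed the greenery-area gate.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "AnnotationRecord", "labelme_read", "labelme_write", "voc_read",
    "voc_write", "coco_export", "rasterize_polygon", "mask_read",
    "mask_write", "image_read", "image_write",
]


class AnnotationParseError(ValueError):
    """Malformed annotation file; the message names the offending field."""


@dataclass
class AnnotationRecord:
    """Polygon and box annotations for one image.

    ``polygons``: list of ``(label, points)`` with ``points`` an ``(N, 2)``
    float array of (x, y) pixel coordinates (sub-pixel allowed).
    ``boxes``: list of ``(label, (x_min, y_min, x_max, y_max))`` in the
    internal half-open convention.
    """

    image_path: str
    height: int
    width: int
    polygons: list[tuple[str, np.ndarray]] = field(default_factory=list)
    boxes: list[tuple[str, tuple[float, float, float, float]]] = field(
        default_factory=list)

    def validate(self) -> None:
        for label, pts in self.polygons:
            if not label:
                raise AnnotationParseError("polygon with empty label")
            pts = np.asarray(pts)
            if pts[:, 0].min() < 0 or pts[:, 0].max() > self.width \
                    or pts[:, 1].min() < 0 or pts[:, 1].max() > self.height:
                raise AnnotationParseError(
                    f"polygon '{label}' extends outside the image")
        for label, (x0, y0, x1, y1) in self.boxes:
            if not label:
                raise AnnotationParseError("box with empty label")
            if x1 <= x0 or y1 <= y0:
                raise AnnotationParseError(f"degenerate box for '{label}'")


# ---------------------------------------------------------------------------
# labelme JSON


def labelme_read(path) -> AnnotationRecord:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise AnnotationParseError(f"{path}: invalid JSON ({e})") from e
    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in doc:
            raise AnnotationParseError(f"{path}: missing field '{key}'")
    polys = []
    for i, shape in enumerate(doc["shapes"]):
        for key in ("label", "points"):
            if key not in shape:
                raise AnnotationParseError(
                    f"{path}: shapes[{i}] missing field '{key}'")
        if shape.get("shape_type", "polygon") != "polygon":
            continue  # only polygon shapes are used
        polys.append((shape["label"], np.asarray(shape["points"], dtype=float)))
    return AnnotationRecord(
        image_path=doc.get("imagePath", ""),
        height=int(doc["imageHeight"]), width=int(doc["imageWidth"]),
        polygons=polys)


def labelme_write(record: AnnotationRecord, path) -> None:
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": [
            {"label": label,
             "points": np.asarray(pts, dtype=float).tolist(),
             "group_id": None,
             "shape_type": "polygon",
             "flags": {}}
            for label, pts in record.polygons
        ],
        "imagePath": record.image_path,
        "imageData": None,
        "imageHeight": record.height,
        "imageWidth": record.width,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# Pascal VOC XML


def voc_read(path) -> AnnotationRecord:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise AnnotationParseError(f"{path}: invalid XML ({e})") from e
    size = root.find("size")
    if size is None:
        raise AnnotationParseError(f"{path}: missing field 'size'")
    height = int(size.findtext("height"))
    width = int(size.findtext("width"))
    boxes = []
    for i, obj in enumerate(root.findall("object")):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise AnnotationParseError(
                f"{path}: object[{i}] missing 'name' or 'bndbox'")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            text = bnd.findtext(key)
            if text is None:
                raise AnnotationParseError(
                    f"{path}: object[{i}]/bndbox missing '{key}'")
            vals[key] = float(text)
        # VOC is 1-based inclusive; internal is 0-based half-open
        x0, y0 = vals["xmin"] - 1, vals["ymin"] - 1
        x1, y1 = vals["xmax"], vals["ymax"]
        if x1 <= x0 or y1 <= y0:
            raise AnnotationParseError(
                f"{path}: object[{i}] has xmax <= xmin or ymax <= ymin")
        boxes.append((name, (x0, y0, x1, y1)))
    return AnnotationRecord(
        image_path=root.findtext("filename") or "",
        height=height, width=width, boxes=boxes)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def voc_write(record: AnnotationRecord, path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = ""
    ET.SubElement(root, "filename").text = record.image_path
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = "3"
    for label, (x0, y0, x1, y1) in record.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(x0 + 1)
        ET.SubElement(bnd, "ymin").text = _fmt(y0 + 1)
        ET.SubElement(bnd, "xmax").text = _fmt(x1)
        ET.SubElement(bnd, "ymax").text = _fmt(y1)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# COCO JSON


def coco_export(records_or_detections, out_path, *, class_names=None,
                mode: str = "auto") -> dict:
    """Export detections or annotations as COCO-style JSON.

    ``records_or_detections`` is a list of ``(image_id, DetectionSet)`` pairs
    (results mode) or ``(image_id, AnnotationRecord)`` pairs (instances
    mode).  Internal half-open boxes become ``(x, y, w, h)``.  Image ids must
    be unique.
    """
    from .boxes import CLASS_NAMES, DetectionSet

    class_names = list(class_names or CLASS_NAMES)
    ids = [img_id for img_id, _ in records_or_detections]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids in COCO export")

    images, annotations = [], []
    ann_id = 1
    for img_id, payload in records_or_detections:
        if isinstance(payload, DetectionSet):
            for box in payload:
                annotations.append({
                    "id": ann_id, "image_id": img_id,
                    "category_id": int(box.class_id) + 1,
                    "bbox": [box.x_min, box.y_min,
                             box.x_max - box.x_min, box.y_max - box.y_min],
                    "score": box.score, "area": box.area, "iscrowd": 0})
                ann_id += 1
            images.append({"id": img_id})
        else:
            rec: AnnotationRecord = payload
            images.append({"id": img_id, "file_name": rec.image_path,
                           "height": rec.height, "width": rec.width})
            for label, (x0, y0, x1, y1) in rec.boxes:
                annotations.append({
                    "id": ann_id, "image_id": img_id,
                    "category_id": class_names.index(label) + 1,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0), "iscrowd": 0})
                ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i + 1, "name": n}
                       for i, n in enumerate(class_names)],
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(doc, indent=2))
    return doc


# ---------------------------------------------------------------------------
# polygon rasterization and raster I/O


def rasterize_polygon(points: np.ndarray, height: int, width: int) -> np.ndarray:
    """Even-odd scanline fill on pixel centers.

    A pixel (x, y) is set iff the point ``(x + 0.5, y + 0.5)`` is strictly
    inside the polygon under the even-odd (crossing-number) rule, using
    half-open edge spans so shared vertices are counted once.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return np.zeros((height, width), dtype=np.uint8)
    mask = np.zeros((height, width), dtype=np.uint8)
    x1s, y1s = pts[:, 0], pts[:, 1]
    x2s, y2s = np.roll(pts[:, 0], -1), np.roll(pts[:, 1], -1)
    for row in range(height):
        yc = row + 0.5
        lo = np.minimum(y1s, y2s)
        hi = np.maximum(y1s, y2s)
        hit = (lo <= yc) & (yc < hi)
        if not hit.any():
            continue
        t = (yc - y1s[hit]) / (y2s[hit] - y1s[hit])
        xs = np.sort(x1s[hit] + t * (x2s[hit] - x1s[hit]))
        for a, b in zip(xs[0::2], xs[1::2]):
            start = max(0, int(np.ceil(a - 0.5)))
            stop = min(width, int(np.ceil(b - 0.5)))
            if stop > start:
                mask[row, start:stop] = 1
    return mask


def mask_write(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a single-channel PNG with 0/255 encoding."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def mask_read(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def image_write(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def image_read(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
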