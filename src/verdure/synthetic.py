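"""Synthetic vertical-greenery scenes with full ground truth.

Real vertical-greenery imagery shows a vegetated region of varying size and
position against a built background, with water-deficient or dead plants
appearing as brown/yellow patches inside the greenery, and a share of frames
degraded by defocus, motion or poor light.  This module emulates exactly that
structure so every pipeline stage can be trained and evaluated without any
external download:

* background — grey, wall-like texture;
* greenery — one smooth random polygon filled with green speckle, targeted
  to cover a requested fraction of the frame;
* deficit — elliptical brown ("water_deficient") or yellow ("dead") blobs
  placed inside the greenery, each with a tight axis-aligned box;
* degradations — gaussian blur, motion blur, low light or additive noise,
  applied to the "blurry"-labelled share of the dataset.

Everything is deterministic given ``(config, seed)``.  The stored mask is
the even-odd rasterization of the stored polygon, so annotations and rasters
are consistent by construction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .boxes import CLASS_NAMES
from .io_formats import (AnnotationRecord, image_write, labelme_write,
                         mask_write, rasterize_polygon, voc_write)

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "degrade_image",
           "generate_dataset", "DEGRADATION_KINDS"]

DEGRADATION_KINDS = ("none", "gaussian_blur", "motion_blur", "low_light", "noise")

#: default strength ranges per degradation kind, in each kind's natural
#: units (blur sigma, kernel length in pixels, dimming factor, noise sigma
#: on the 0-255 intensity scale)
DEFAULT_STRENGTHS = {
    "gaussian_blur": (2.0, 4.0),
    "motion_blur": (6.0, 12.0),
    "low_light": (1.5, 4.0),
    "noise": (20.0, 50.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters for one scene family.

    ``greenery_coverage`` is the target fraction of frame pixels covered by
    the greenery polygon; the renderer iterates until the rasterized mask is
    within ±0.05 of the value drawn from this range.  Blob sizes are ellipse
    semi-axes in units of the image side.
    """

    image_size: int = 256
    greenery_coverage: tuple[float, float] = (0.45, 0.75)
    n_deficit: tuple[int, int] = (1, 3)
    blob_size: tuple[float, float] = (0.04, 0.09)
    degradation: str = "none"
    degradation_strength: tuple[float, float] | None = None  # per-kind default

    def __post_init__(self):
        lo, hi = self.greenery_coverage
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("greenery_coverage must satisfy 0 <= lo <= hi <= 1")
        if self.blob_size[0] <= 0 or self.n_deficit[0] < 0:
            raise ValueError("blob sizes must be positive, counts non-negative")
        if self.degradation not in DEGRADATION_KINDS:
            raise ValueError(f"unknown degradation '{self.degradation}'")


@dataclass
class SyntheticScene:
    """One rendered scene with ground truth for all three stages."""

    image: np.ndarray            # (H, W, 3) uint8
    label: str                   # "clear" or "blurry"
    mask: np.ndarray             # (H, W) uint8 {0, 1}
    polygons: list[tuple[str, np.ndarray]]
    boxes: list[tuple[str, tuple[float, float, float, float]]]
    meta: dict = field(default_factory=dict)

    def annotation(self, image_path: str = "") -> AnnotationRecord:
        h, w = self.mask.shape
        return AnnotationRecord(image_path=image_path, height=h, width=w,
                                polygons=self.polygons, boxes=self.boxes)


def _smooth_polygon(rng: np.random.Generator, size: int,
                    coverage: float) -> np.ndarray:
    """Random star-shaped polygon rescaled until it covers ``coverage``."""
    n_vertices = 48
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    profile = np.ones(n_vertices)
    for k in range(2, 6):
        profile += rng.uniform(0.02, 0.10) * np.cos(
            k * theta + rng.uniform(0, 2 * np.pi))
    cx = size * rng.uniform(0.40, 0.60)
    cy = size * rng.uniform(0.40, 0.60)
    radius = size * np.sqrt(coverage / np.pi)
    pts = None
    for _ in range(8):
        x = cx + radius * profile * np.cos(theta)
        y = cy + radius * profile * np.sin(theta)
        pts = np.clip(np.stack([x, y], axis=1), 0.0, float(size))
        got = rasterize_polygon(pts, size, size).mean()
        if abs(got - coverage) <= 0.02:
            break
        radius *= np.sqrt(max(coverage, 1e-3) / max(got, 1e-3))
    return pts


def _green_texture(rng: np.random.Generator, shape) -> np.ndarray:
    base = np.array([62.0, 120.0, 48.0])
    tex = base + rng.normal(0, 18, size=shape + (3,))
    # leaf-scale speckle: smoothed luminance modulation
    lum = ndimage.gaussian_filter(rng.normal(0, 30, size=shape), 1.5)
    return np.clip(tex + lum[..., None] * np.array([0.4, 1.0, 0.3]), 0, 255)


def _wall_texture(rng: np.random.Generator, shape) -> np.ndarray:
    base = np.array([168.0, 160.0, 150.0])
    tex = base + rng.normal(0, 10, size=shape + (3,))
    rows = np.linspace(-12, 12, shape[0])[:, None, None]
    return np.clip(tex + rows, 0, 255)


_BLOB_COLORS = {
    "water_deficient": np.array([134.0, 92.0, 38.0]),   # dry brown
    "dead": np.array([182.0, 164.0, 72.0]),             # straw yellow
}


def generate_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Render one scene deterministically from ``(config, seed)``."""
    rng = np.random.default_rng(seed)
    size = config.image_size
    coverage = rng.uniform(*config.greenery_coverage)
    poly = _smooth_polygon(rng, size, coverage)
    mask = rasterize_polygon(poly, size, size)

    image = _wall_texture(rng, (size, size))
    green = _green_texture(rng, (size, size))
    image[mask == 1] = green[mask == 1]

    boxes = []
    n_blobs = int(rng.integers(config.n_deficit[0], config.n_deficit[1] + 1))
    inside = np.argwhere(mask == 1)
    yy, xx = np.mgrid[0:size, 0:size]
    placed = 0
    attempts = 0
    while placed < n_blobs and attempts < 40 * max(1, n_blobs) and len(inside):
        attempts += 1
        cy, cx = inside[rng.integers(len(inside))]
        a = size * rng.uniform(*config.blob_size)
        b = size * rng.uniform(*config.blob_size)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not ellipse.any():
            continue
        ys, xs = np.nonzero(ellipse)
        box = (float(xs.min()), float(ys.min()),
               float(xs.max() + 1), float(ys.max() + 1))
        bx0, by0, bx1, by1 = (int(box[0]), int(box[1]), int(box[2]), int(box[3]))
        box_pixels = (bx1 - bx0) * (by1 - by0)
        overlap = mask[by0:by1, bx0:bx1].sum() / box_pixels
        if overlap < 0.9:
            continue
        cls = CLASS_NAMES[int(rng.integers(len(CLASS_NAMES)))]
        color = _BLOB_COLORS[cls] + rng.normal(0, 8, size=3)
        paint = ellipse & (mask == 1)
        jitter = rng.normal(0, 10, size=(int(paint.sum()), 3))
        image[paint] = np.clip(color + jitter, 0, 255)
        boxes.append((cls, box))
        placed += 1

    image = np.clip(image, 0, 255).astype(np.uint8)
    label = "clear"
    meta = {"seed": int(seed), "coverage_target": float(coverage),
            "coverage_actual": float(mask.mean()),
            "degradation": "none", "n_deficit": placed}
    if config.degradation != "none":
        lo, hi = (config.degradation_strength
                  or DEFAULT_STRENGTHS[config.degradation])
        strength = float(rng.uniform(lo, hi))
        image = degrade_image(image, config.degradation, strength,
                              seed=int(rng.integers(2**31)))
        label = "blurry"
        meta["degradation"] = config.degradation
        meta["degradation_strength"] = strength
    return SyntheticScene(image=image, label=label, mask=mask,
                          polygons=[("greenery", poly)], boxes=boxes,
                          meta=meta)


def degrade_image(image: np.ndarray, kind: str, strength: float,
                  seed: int = 0) -> np.ndarray:
    """Apply one parametric degradation; ``strength = 0`` is the identity."""
    if kind not in DEGRADATION_KINDS:
        raise ValueError(f"unknown degradation '{kind}'")
    if strength < 0:
        raise ValueError("strength must be non-negative")
    img = np.asarray(image, dtype=float)
    if strength == 0 or kind == "none":
        return np.asarray(image, dtype=np.uint8).copy()
    if kind == "gaussian_blur":
        out = np.stack([ndimage.gaussian_filter(img[..., c], strength)
                        for c in range(3)], axis=-1)
    elif kind == "motion_blur":
        length = max(2, int(round(strength)))
        angle = np.random.default_rng(seed).uniform(0, np.pi)
        t = np.linspace(-(length - 1) / 2, (length - 1) / 2, length)
        ky = t * np.sin(angle)
        kx = t * np.cos(angle)
        half = length // 2 + 1
        kernel = np.zeros((2 * half + 1, 2 * half + 1))
        iy = np.round(ky).astype(int) + half
        ix = np.round(kx).astype(int) + half
        kernel[iy, ix] += 1.0
        kernel /= kernel.sum()
        out = np.stack([ndimage.convolve(img[..., c], kernel, mode="nearest")
                        for c in range(3)], axis=-1)
    elif kind == "low_light":
        out = img / (1.0 + strength)
    elif kind == "noise":
        out = img + np.random.default_rng(seed).normal(0, strength, img.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def generate_dataset(n_clear: int, n_blurry: int, config: SceneConfig,
                     seed: int, out_dir) -> dict:
    """Write a full dataset (images, masks, annotations, manifest, splits).

    Layout under ``out_dir``: ``images/``, ``masks/``, ``labelme/``,
    ``voc/``, ``manifest.csv``, ``splits.json``.  Returns the manifest as a
    list of row dicts plus the split, all reproducible from ``(config,
    seed)``.
    """
    from .pipeline import split_dataset

    out = Path(out_dir)
    for sub in ("images", "masks", "labelme", "voc"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    total = n_clear + n_blurry
    for i in range(total):
        blurry = i >= n_clear
        cfg = config
        if blurry:
            kind = DEGRADATION_KINDS[1:][int(rng.integers(4))]
            cfg = replace(config, degradation=kind)
        else:
            cfg = replace(config, degradation="none")
        scene = generate_scene(cfg, seed=int(rng.integers(2**31)))
        stem = f"scene_{i:04d}"
        image_write(scene.image, out / "images" / f"{stem}.png")
        mask_write(scene.mask, out / "masks" / f"{stem}.png")
        rec = scene.annotation(image_path=f"images/{stem}.png")
        labelme_write(rec, out / "labelme" / f"{stem}.json")
        voc_write(rec, out / "voc" / f"{stem}.xml")
        rows.append({"image": f"images/{stem}.png", "label": scene.label,
                     "mask": f"masks/{stem}.png",
                     "labelme": f"labelme/{stem}.json",
                     "voc": f"voc/{stem}.xml"})
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    split = split_dataset(total, seed=seed)
    (out / "splits.json").write_text(json.dumps(
        {"train": split.train, "val": split.val, "test": split.test}))
    return {"rows": rows, "split": split}
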