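"""Stage 2: U-shaped greenery segmentation, the area gate, black-masking.

The segmenter is a symmetric encoder-decoder on token grids.  The encoder is
the shared four-stage backbone; an atrous spatial pyramid pooling (ASPP)
block at the end of the encoder aggregates context at several dilation rates;
the decoder mirrors the encoder with patch-expanding upsampling.  Each skip
connection passes the encoder feature through a residual
squeeze-and-excitation (Res-SE) block, concatenates it with the decoder
feature, and restores the decoder width with a linear layer.  A final 4x
patch expansion and a linear projection with sigmoid give a full-resolution
greenery probability map.

Downstream analytics: the greenery proportion (fraction of mask pixels on),
the area gate (frames under 40 % greenery by default are filtered), and
black-masking of non-greenery pixels before detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import (BackboneConfig, DimensionError, SwinBackbone,
                       SwinBlock)
from .gating import GateDecision, GateOutcome
from .losses import binary_cross_entropy
from .nn import Tensor, as_tensor
from .nn.functional import bilinear_resize

__all__ = ["AsppConfig", "Aspp", "ResSEBlock", "PatchExpanding",
           "GreenerySegmenter", "train_segmenter", "greenery_proportion",
           "area_gate", "apply_background_mask", "DEFAULT_AREA_THRESHOLD",
           "DEFAULT_MASK_THRESHOLD"]

DEFAULT_AREA_THRESHOLD = 0.4
DEFAULT_MASK_THRESHOLD = 0.5


@dataclass(frozen=True)
class AsppConfig:
    """Dilation rates and per-branch width of the atrous pyramid.

    Five branches total: a 1x1 convolution, one 3x3 dilated convolution per
    rate, and a global-average-pool branch restored by bilinear upsampling.
    """

    rates: tuple[int, ...] = (3, 6, 12)
    branch_channels: int | None = None  # None: match the input width

    def __post_init__(self):
        if list(self.rates) != sorted(set(self.rates)) or not self.rates:
            raise ValueError("rates must be strictly increasing and non-empty")


class Aspp(nn.Module):
    """Atrous spatial pyramid pooling over a ``(B, C, H, W)`` feature map."""

    def __init__(self, in_channels: int, config: AsppConfig,
                 rng: np.random.Generator):
        self.config = config
        bc = config.branch_channels or in_channels
        self.branch_channels = bc
        self.conv1 = nn.Conv2d(in_channels, bc, 1, rng)
        self.dilated = nn.ModuleList([
            nn.Conv2d(in_channels, bc, 3, rng, padding=r, dilation=r)
            for r in config.rates])
        self.pool_proj = nn.Conv2d(in_channels, bc, 1, rng)
        self.fuse = nn.Conv2d(bc * (2 + len(config.rates)), in_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, C, H, W = x.shape
        largest = 2 * max(self.config.rates) + 1
        if min(H, W) < largest:
            warnings.warn(
                f"ASPP input {H}x{W} smaller than the {largest}-pixel extent "
                "of the most dilated kernel; zero padding dominates")
        branches = [self.conv1(x)]
        branches += [conv(x) for conv in self.dilated]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        branches.append(bilinear_resize(self.pool_proj(pooled), H, W))
        return self.fuse(nn.concat(branches, axis=1))


class ResSEBlock(nn.Module):
    """Residual squeeze-and-excitation channel reweighting.

    Squeeze: global average over positions.  Excitation: bottleneck
    ``C -> C/reduction -> C`` with a sigmoid.  Output: ``x * scale + x`` —
    the identity term keeps the unweighted features intact.
    Accepts ``(B, L, C)`` token sequences or ``(B, H, W, C)`` grids.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x: Tensor, grid_shape: tuple[int, int] | None = None) -> Tensor:
        x = as_tensor(x)
        if x.ndim == 3 and grid_shape is not None:
            h, w = grid_shape
            if h * w != x.shape[1]:
                raise DimensionError(
                    f"sequence length {x.shape[1]} does not factor into "
                    f"{h}x{w}")
        axes = tuple(range(1, x.ndim - 1))
        squeeze = x.mean(axis=axes, keepdims=True)
        scale = self.fc2(self.fc1(squeeze).relu()).sigmoid()
        return x * scale + x


class PatchExpanding(nn.Module):
    """Upsample a token grid by redistributing channels to finer positions.

    factor 2: project C -> 2C, rearrange each token to a 2x2 neighborhood of
    C/2-channel tokens (grid sides x2, channels halved).  factor 4: project
    C -> 16C, rearrange to 4x4 (grid sides x4, channels unchanged).
    """

    def __init__(self, channels: int, factor: int, rng: np.random.Generator):
        if factor == 2:
            if channels % 2:
                raise ValueError("factor-2 expansion needs even channels")
            self.out_channels = channels // 2
            proj = 2 * channels
        elif factor == 4:
            self.out_channels = channels
            proj = 16 * channels
        else:
            raise ValueError(f"unsupported expansion factor {factor}")
        self.factor = factor
        self.proj = nn.Linear(channels, proj, rng, bias=False)
        self.norm = nn.LayerNorm(self.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, H, W, C = x.shape
        f = self.factor
        y = self.proj(x).reshape(B, H, W, f, f, self.out_channels)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, H * f, W * f,
                                                  self.out_channels)
        return self.norm(y)


class GreenerySegmenter(nn.Module):
    """Encoder (shared backbone) + ASPP bottleneck + mirrored decoder."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator,
                 aspp: AsppConfig = AsppConfig(), se_reduction: int = 16):
        self.config = config
        self.backbone = SwinBackbone(config, rng)
        c = config.embed_dim
        self.aspp = Aspp(8 * c, aspp, rng)
        ws, sh, mr = config.window_size, config.shift, config.mlp_ratio
        self.expands = nn.ModuleList([
            PatchExpanding(8 * c, 2, rng),
            PatchExpanding(4 * c, 2, rng),
            PatchExpanding(2 * c, 2, rng)])
        self.skip_se = nn.ModuleList([
            ResSEBlock(4 * c, rng, se_reduction),
            ResSEBlock(2 * c, rng, se_reduction),
            ResSEBlock(c, rng, se_reduction)])
        self.skip_fuse = nn.ModuleList([
            nn.Linear(8 * c, 4 * c, rng),
            nn.Linear(4 * c, 2 * c, rng),
            nn.Linear(2 * c, c, rng)])
        heads = config.heads
        self.dec_blocks = nn.ModuleList([
            nn.ModuleList([SwinBlock(4 * c, heads[2], ws, 0, mr, rng),
                           SwinBlock(4 * c, heads[2], ws, sh, mr, rng)]),
            nn.ModuleList([SwinBlock(2 * c, heads[1], ws, 0, mr, rng),
                           SwinBlock(2 * c, heads[1], ws, sh, mr, rng)]),
            nn.ModuleList([SwinBlock(c, heads[0], ws, 0, mr, rng),
                           SwinBlock(c, heads[0], ws, sh, mr, rng)])])
        self.final_expand = PatchExpanding(c, 4, rng)
        self.out_proj = nn.Linear(c, 1, rng)

    def forward(self, images) -> Tensor:
        """Per-pixel greenery probability map ``(B, H, W)`` in (0, 1)."""
        x = as_tensor(images)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        feats = self.backbone(x)
        skips = [feats.s16, feats.s8, feats.s4]
        d = feats.s32
        d = self.aspp(d.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1)
        for level, (expand, se, fuse, blocks, enc) in enumerate(zip(
                self.expands, self.skip_se, self.skip_fuse, self.dec_blocks,
                skips)):
            d = expand(d)
            if d.shape[:3] != enc.shape[:3]:
                raise RuntimeError(
                    f"pipeline error at skip level {level}: decoder grid "
                    f"{d.shape[1:3]} vs encoder grid {enc.shape[1:3]}")
            d = fuse(nn.concat([se(enc), d], axis=-1))
            for block in blocks:
                d = block(d)
        d = self.final_expand(d)
        return self.out_proj(d).reshape(d.shape[0], d.shape[1], d.shape[2]).sigmoid()

    def predict_mask(self, image: np.ndarray,
                     threshold: float = DEFAULT_MASK_THRESHOLD) -> np.ndarray:
        """Threshold the probability map into a {0,1} uint8 mask."""
        x = _to_float(image)[None]
        probs = self.forward(x).data[0]
        return (probs >= threshold).astype(np.uint8)


def greenery_proportion(mask: np.ndarray) -> float:
    """Fraction of pixels labelled greenery; depends only on the mask."""
    mask = np.asarray(mask)
    return float((mask > 0).mean())


def area_gate(proportion: float, threshold: float = DEFAULT_AREA_THRESHOLD,
              now: float = 0.0, wait_s: float = 0.0) -> GateDecision:
    """FILTERED_AREA iff ``proportion < threshold`` (strictly below)."""
    if not (0.0 <= proportion <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("proportion and threshold must lie in [0, 1]")
    if proportion < threshold:
        return GateDecision(GateOutcome.FILTERED_AREA,
                            scores={"greenery_proportion": proportion},
                            timestamp=now, reshoot_at=now + wait_s)
    return GateDecision(GateOutcome.PASS,
                        scores={"greenery_proportion": proportion},
                        timestamp=now)


def apply_background_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Black out non-greenery pixels; greenery pixels pass through untouched."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise DimensionError(
            f"image {image.shape[:2]} and mask {mask.shape} sizes differ")
    return image * (mask > 0)[..., None].astype(image.dtype)


def _to_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def train_segmenter(images: np.ndarray, masks: np.ndarray,
                    config: BackboneConfig, *, epochs: int = 100,
                    lr: float = 5e-5, batch_size: int = 4, seed: int = 0,
                    init_state: dict | None = None,
                    val_images: np.ndarray | None = None,
                    val_masks: np.ndarray | None = None,
                    log=None) -> tuple[GreenerySegmenter, dict]:
    """Train with per-pixel binary cross-entropy; returns the best-loss model.

    ``init_state`` may hold a previously trained stage's parameters; every
    entry whose name and shape match is copied in (the backbone transfers,
    heads stay randomly initialized).
    """
    rng = np.random.default_rng(seed)
    model = GreenerySegmenter(config, rng)
    if init_state is not None:
        model.load_state_dict(init_state, strict=False)
    opt = nn.Adam(model.parameters(), lr=lr)
    x = np.stack([_to_float(im) for im in images])
    y = np.stack([np.asarray(m, dtype=np.float32) for m in masks])
    history = {"loss": [], "val_loss": []}
    best = (np.inf, model.state_dict())
    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            probs = model(x[idx])
            loss = binary_cross_entropy(Tensor(y[idx]), probs)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_loss = float(np.mean(losses))
        history["loss"].append(epoch_loss)
        monitor = epoch_loss
        if val_images is not None:
            vx = np.stack([_to_float(im) for im in val_images])
            vp = model(vx).data
            vloss = binary_cross_entropy(
                np.stack([np.asarray(m, np.float32) for m in val_masks]), vp)
            history["val_loss"].append(float(vloss))
            monitor = float(vloss)
        if monitor < best[0]:
            best = (monitor, model.state_dict())
        if log is not None:
            log({"stage": 2, "epoch": epoch, "L_mask": epoch_loss})
    model.load_state_dict(best[1])
    history["best_loss"] = best[0]
    return model, history
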