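"""Hierarchical shifted-window attention backbone.

The feature extractor shared by all three pipeline stages.  An input image is
cut into non-overlapping ``patch_size``-pixel patches, each flattened along
the channel axis, linearly embedded to ``embed_dim`` channels, and pushed
through four stages of window-based multi-head self-attention.  Between
stages, patch merging halves each side of the token grid and doubles the
channel count, producing a feature pyramid at strides 4, 8, 16 and 32.

Attention is computed inside ``window_size``-token windows (W-MSA); every
second block cyclically shifts the grid by half a window (SW-MSA) so that
information crosses window borders, with an additive mask keeping tokens
from different pre-shift regions apart.  Blocks therefore come in pairs.
Stages 2-4 use residual ("Res-Swin") blocks: the standard pre-norm
transformer block wrapped head-to-tail in one extra identity shortcut.

Token grids are tensors of shape ``(B, H, W, C)`` — row-major spatial layout,
channels last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

__all__ = [
    "BackboneConfig", "PyramidFeatures", "patch_partition", "LinearEmbed",
    "window_partition", "window_reverse", "shifted_window_mask",
    "WindowAttention", "SwinBlock", "ResSwinBlock", "PatchMerging",
    "SwinBackbone",
]

_NEG_INF = -1e9


class DimensionError(ValueError):
    """A spatial size does not satisfy a divisibility requirement."""


class ConfigurationError(ValueError):
    """An architecture hyperparameter combination is invalid."""


@dataclass(frozen=True)
class BackboneConfig:
    """Hyperparameters of the four-stage backbone.

    Defaults follow the tiny variant used throughout the pipeline papers:
    ``embed_dim`` C = 96, block repetitions (2, 4, 2, 2), 4-pixel patches.
    ``shift_size`` defaults to half the window.
    """

    embed_dim: int = 96
    depths: tuple[int, int, int, int] = (2, 4, 2, 2)
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    window_size: int = 8
    shift_size: int | None = None
    patch_size: int = 4
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if len(self.depths) != 4:
            raise ConfigurationError("depths must have exactly 4 entries")
        if any(d % 2 != 0 or d < 2 for d in self.depths):
            raise ConfigurationError(
                "each stage depth must be a positive even number: shifted and "
                "non-shifted attention blocks are used in pairs")
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2**i) % h != 0:
                raise ConfigurationError(
                    f"stage {i + 1} channels {self.embed_dim * 2**i} not "
                    f"divisible by head count {h}")
        if self.shift != 0 and self.shift >= self.window_size:
            raise ConfigurationError("shift_size must be < window_size")

    @property
    def shift(self) -> int:
        return self.window_size // 2 if self.shift_size is None else self.shift_size

    def stage_channels(self, stage: int) -> int:
        return self.embed_dim * 2**stage

    def validate_image_size(self, height: int, width: int) -> None:
        """Check every divisibility constraint the four stages impose."""
        for axis, size in (("height", height), ("width", width)):
            if size % self.patch_size:
                raise DimensionError(
                    f"image {axis} {size} not divisible by patch size "
                    f"{self.patch_size}")
            tokens = size // self.patch_size
            need = self.window_size * 8
            if tokens % 8 or (tokens // 8) % self.window_size:
                pad = (-size) % (self.patch_size * need)
                raise DimensionError(
                    f"image {axis} {size} incompatible with 4-stage "
                    f"downsampling and window {self.window_size}; pad by "
                    f"{pad} pixels to {size + pad}")


class PyramidFeatures(NamedTuple):
    """Per-stage token grids at strides 4, 8, 16, 32 (channels C..8C)."""

    s4: Tensor
    s8: Tensor
    s16: Tensor
    s32: Tensor

    def __iter__(self):
        return iter((self.s4, self.s8, self.s16, self.s32))


# ---------------------------------------------------------------------------
# token-grid primitives


def patch_partition(image, patch_size: int) -> Tensor:
    """Cut an image into flattened non-overlapping patches.

    ``image`` is ``(H, W, 3)`` or ``(B, H, W, 3)``.  Each token holds its
    patch's pixels flattened row-major with channels last, i.e. the value
    order is (dy=0,dx=0,R), (dy=0,dx=0,G), (dy=0,dx=0,B), (dy=0,dx=1,R), ...
    A ``patch_size`` of 4 therefore yields 48 channels.
    """
    x = as_tensor(image)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape((1,) + x.shape)
    B, H, W, C = x.shape
    if C != 3:
        raise DimensionError(f"expected a 3-channel image, got {C} channels")
    for axis, size in (("height", H), ("width", W)):
        if size % patch_size:
            raise DimensionError(
                f"image {axis} {size} not divisible by patch size {patch_size}")
    gh, gw = H // patch_size, W // patch_size
    x = x.reshape(B, gh, patch_size, gw, patch_size, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # (B, gh, gw, py, px, C)
    x = x.reshape(B, gh, gw, patch_size * patch_size * C)
    return x.reshape(gh, gw, -1) if squeeze else x


class LinearEmbed(nn.Module):
    """Affine projection of raw patch tokens to C channels, then layer norm."""

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.proj = nn.Linear(in_channels, embed_dim, rng)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[-1] != self.in_channels:
            raise DimensionError(
                f"expected {self.in_channels} input channels, got "
                f"{tokens.shape[-1]}")
        return self.norm(self.proj(tokens))


def window_partition(tokens: Tensor, window_size: int, shift: int = 0) -> Tensor:
    """Group a ``(B, H, W, C)`` grid into ``(B·nW, window², C)`` windows.

    A non-zero ``shift`` first cyclically rolls the grid by ``(-shift,
    -shift)`` so that the fixed window lattice covers shifted content.
    """
    x = as_tensor(tokens)
    B, H, W, C = x.shape
    for axis, size in (("height", H), ("width", W)):
        if size % window_size:
            raise DimensionError(
                f"grid {axis} {size} not divisible by window {window_size}")
    if shift:
        x = x.roll((-shift, -shift), axis=(1, 2))
    nh, nw = H // window_size, W // window_size
    x = x.reshape(B, nh, window_size, nw, window_size, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * nh * nw, window_size * window_size, C)


def window_reverse(windows: Tensor, window_size: int, height: int, width: int,
                   shift: int = 0) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    nh, nw = height // window_size, width // window_size
    x = as_tensor(windows)
    B = x.shape[0] // (nh * nw)
    x = x.reshape(B, nh, nw, window_size, window_size, x.shape[-1])
    x = x.transpose(0, 1, 3, 2, 4, 5)
    x = x.reshape(B, height, width, x.shape[-1])
    if shift:
        x = x.roll((shift, shift), axis=(1, 2))
    return x


def shifted_window_mask(height: int, width: int, window_size: int,
                        shift: int) -> np.ndarray | None:
    """Additive attention mask for the shifted-window case.

    Returns ``(nW, window², window²)`` with 0 for token pairs from the same
    pre-shift region and a large negative value otherwise, or ``None`` for
    the unshifted case.
    """
    if shift == 0:
        return None
    region = np.zeros((height, width))
    h_slices = (slice(0, -window_size), slice(-window_size, -shift),
                slice(-shift, None))
    w_slices = h_slices
    cnt = 0
    for hs in h_slices:
        for ws in w_slices:
            region[hs, ws] = cnt
            cnt += 1
    ids = window_partition(Tensor(region[None, :, :, None]), window_size,
                           shift=shift).data.reshape(-1, window_size**2)
    diff = ids[:, :, None] - ids[:, None, :]
    return np.where(diff != 0, _NEG_INF, 0.0)


class WindowAttention(nn.Module):
    """Multi-head self-attention within a window, with relative-position bias.

    The bias is a learned table indexed by the relative (dy, dx) offset of
    each token pair, shared across windows — the standard positional term for
    window attention.
    """

    def __init__(self, dim: int, heads: int, window_size: int,
                 rng: np.random.Generator):
        if dim % heads:
            raise ConfigurationError(
                f"channels {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.window_size = window_size
        self.scale = (dim // heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        ws = window_size
        self.rel_bias = nn.Parameter(
            0.02 * rng.standard_normal(((2 * ws - 1) ** 2, heads)))
        coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :] + ws - 1
        self._bias_index = (rel[0] * (2 * ws - 1) + rel[1]).reshape(-1)

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        N, L, C = windows.shape
        hd = C // self.heads
        qkv = self.qkv(windows).reshape(N, L, 3, self.heads, hd)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, N, heads, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = self.rel_bias[self._bias_index].reshape(L, L, self.heads)
        attn = attn + bias.transpose(2, 0, 1)
        if mask is not None:
            nW = mask.shape[0]
            attn = attn.reshape(N // nW, nW, self.heads, L, L)
            attn = attn + mask[None, :, None, :, :]
            attn = attn.reshape(N, self.heads, L, L)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, C)
        return self.proj(out)


class Mlp(nn.Module):
    """Two-layer perceptron with a GELU non-linearity."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(nn.Module):
    """Pre-norm transformer block on a token grid.

    ``u = x + MSA(LN(x)); out = u + MLP(LN(u))`` with (shifted-)window
    attention as the MSA.  ``shift`` must be 0 or ``window // 2``; blocks are
    used in (0, w/2) pairs so attention diffuses across window borders.
    """

    def __init__(self, dim: int, heads: int, window_size: int, shift: int,
                 mlp_ratio: float, rng: np.random.Generator,
                 residual_zero_init: bool = True):
        self.window_size = window_size
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window_size, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        if residual_zero_init:
            # start each residual branch at zero so the block is the identity
            # at initialization; stabilizes training of small models
            self.attn.proj.weight.data[:] = 0.0
            self.mlp.fc2.weight.data[:] = 0.0
        self._mask_cache: dict[tuple[int, int], np.ndarray | None] = {}

    def _mask(self, H: int, W: int) -> np.ndarray | None:
        key = (H, W)
        if key not in self._mask_cache:
            self._mask_cache[key] = shifted_window_mask(
                H, W, self.window_size, self.shift)
        return self._mask_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        shortcut = x
        h = self.norm1(x)
        win = window_partition(h, self.window_size, self.shift)
        win = self.attn(win, self._mask(H, W))
        h = window_reverse(win, self.window_size, H, W, self.shift)
        u = shortcut + h
        return u + self.mlp(self.norm2(u))


class ResSwinBlock(nn.Module):
    """A :class:`SwinBlock` with one extra head-to-tail identity shortcut.

    ``out = swin_block(x) + x``.  The outer identity path keeps the original
    features flowing untouched through deep stages, which counteracts
    degradation and overfitting as depth grows.
    """

    def __init__(self, dim: int, heads: int, window_size: int, shift: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.inner = SwinBlock(dim, heads, window_size, shift, mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.inner(x) + x


class PatchMerging(nn.Module):
    """Downsample a token grid 2x while doubling channels.

    The four tokens of each 2x2 neighborhood are concatenated in row-major
    order — (0,0), (0,1), (1,0), (1,1) — to 4C channels, layer-normalized,
    and linearly projected to 2C.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        for axis, size in (("height", H), ("width", W)):
            if size % 2:
                raise DimensionError(
                    f"patch merging requires an even grid {axis}, got {size}")
        parts = [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
                 x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]]
        merged = nn.concat(parts, axis=-1)
        return self.reduce(self.norm(merged))


class SwinBackbone(nn.Module):
    """Four-stage hierarchical feature extractor returning a feature pyramid.

    Stage 1: linear embedding + plain block pair(s).  Stages 2-4: patch
    merging followed by Res-Swin blocks.  Output channels are C, 2C, 4C, 8C
    at strides 4, 8, 16, 32.  The parameter count depends only on the
    configuration, never on the input image size.
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        c = config.embed_dim
        ws, sh = config.window_size, config.shift
        self.embed = LinearEmbed(3 * config.patch_size**2, c, rng)

        def make_blocks(dim, heads, depth, residual):
            cls = ResSwinBlock if residual else SwinBlock
            return nn.ModuleList([
                cls(dim, heads, ws, 0 if i % 2 == 0 else sh,
                    config.mlp_ratio, rng)
                for i in range(depth)])

        self.stage1 = make_blocks(c, config.heads[0], config.depths[0],
                                  residual=False)
        self.merges = nn.ModuleList([
            PatchMerging(c * 2**i, rng) for i in range(3)])
        self.stages = nn.ModuleList([
            make_blocks(c * 2 ** (i + 1), config.heads[i + 1],
                        config.depths[i + 1], residual=True)
            for i in range(3)])

    def forward(self, image) -> PyramidFeatures:
        x = as_tensor(image)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        self.config.validate_image_size(x.shape[1], x.shape[2])
        x = patch_partition(x, self.config.patch_size)
        x = self.embed(x)
        for block in self.stage1:
            x = block(x)
        levels = [x]
        for merge, blocks in zip(self.merges, self.stages):
            x = merge(x)
            for block in blocks:
                x = block(x)
            levels.append(x)
        return PyramidFeatures(*levels)
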