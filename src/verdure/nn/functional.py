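"""Stateless differentiable operations built on :class:`~verdure.nn.tensor.Tensor`."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "bilinear_resize", "linear"]


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map over the last axis: ``x @ weight + bias``.

    ``weight`` has shape ``(in_features, out_features)``.  Fused into a
    single graph node: the weight gradient is accumulated through one
    flattened GEMM instead of a batched product followed by a reduction.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    data = x.data @ weight.data
    if bias is not None:
        data += bias.data
    n_in, n_out = weight.shape

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.reshape(-1, n_out).sum(axis=0))
        if weight.requires_grad:
            weight._accumulate(
                x.data.reshape(-1, n_in).T @ g.reshape(-1, n_out))
        if x.requires_grad:
            x._accumulate(g @ weight.data.T)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(data, parents, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on ``(B, C, H, W)`` input.

    ``weight`` has shape ``(out_channels, in_channels, kh, kw)``.  Dilation
    inserts ``dilation - 1`` zeros between kernel taps, which is how the
    atrous pyramid enlarges its receptive field without extra parameters.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    B, C, H, W = x.shape
    O, Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C} vs weight {Cw}")
    eff_kh = dilation * (kh - 1) + 1
    eff_kw = dilation * (kw - 1) + 1
    out_h = (H + 2 * padding - eff_kh) // stride + 1
    out_w = (W + 2 * padding - eff_kw) // stride + 1
    if out_h <= 0 or out_w <= 0:
        raise ValueError("conv2d output would be empty; increase padding")

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.empty((B, C, kh, kw, out_h, out_w), dtype=xp.dtype)
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u, v] = xp[:, :,
                                  u * dilation: u * dilation + out_h * stride: stride,
                                  v * dilation: v * dilation + out_w * stride: stride]
    data = np.einsum("ocuv,bcuvhw->bohw", weight.data, cols, optimize=True)
    if bias is not None:
        data = data + bias.data[:, None, None]

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("bohw,bcuvhw->ocuv", g, cols, optimize=True))
        if x.requires_grad:
            gcols = np.einsum("ocuv,bohw->bcuvhw", weight.data, g, optimize=True)
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :,
                        u * dilation: u * dilation + out_h * stride: stride,
                        v * dilation: v * dilation + out_w * stride: stride] += gcols[:, :, u, v]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(data, parents, backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-normalized bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the last two axes of a ``(..., H, W)`` tensor.

    Expressed as two fixed matrix products, so the gradient falls out of the
    matmul rule with no bespoke backward pass.
    """
    x = as_tensor(x)
    H, W = x.shape[-2], x.shape[-1]
    if (H, W) == (out_h, out_w):
        return x
    rh = Tensor(_interp_matrix(H, out_h))
    rw = Tensor(_interp_matrix(W, out_w).T)
    return (rh @ x) @ rw if x.ndim > 1 else rh @ x
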