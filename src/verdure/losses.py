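"""Training losses: cross-entropy, binary cross-entropy, smooth L1.

The combined objective is the unweighted sum ``Loss = L_cls + L_mask +
L_box``, interpreted per stage: the classifier trains on ``L_cls`` alone, the
segmenter on ``L_mask`` alone, and the detector on ``L_cls + L_box`` (it has
no mask branch).  All reductions are means over elements so the terms are on
comparable scales.

Each loss accepts either plain numpy input (returns a float) or autodiff
tensors (returns a :class:`~verdure.nn.Tensor` for backpropagation).
Probabilities are clamped to ``[EPS, 1 - EPS]`` with ``EPS = 1e-12`` before
any logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["EPS", "LossBundle", "cross_entropy", "binary_cross_entropy",
           "smooth_l1", "total_loss"]

EPS = 1e-12


@dataclass(frozen=True)
class LossBundle:
    """Per-term loss values; ``total`` is their plain sum."""

    L_cls: float
    L_mask: float
    L_box: float

    @property
    def total(self) -> float:
        return self.L_cls + self.L_mask + self.L_box


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def cross_entropy(y, y_hat):
    """Categorical cross-entropy ``-sum_i y_i log(y_hat_i)``.

    ``y`` is one-hot (or a batch of one-hot rows); ``y_hat`` holds
    probabilities.  For batched input the mean over rows is returned.
    """
    if _is_tensor(y, y_hat):
        y = y if isinstance(y, Tensor) else Tensor(y)
        p = y_hat.clip(EPS, 1.0)
        per_row = -(y * p.log()).sum(axis=-1)
        return per_row.mean() if per_row.ndim else per_row
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS, 1.0)
    per_row = -(y * np.log(p)).sum(axis=-1)
    return float(np.mean(per_row))


def binary_cross_entropy(y, y_hat):
    """Elementwise ``-[y log p + (1-y) log(1-p)]``, averaged over elements."""
    if _is_tensor(y, y_hat):
        y = y if isinstance(y, Tensor) else Tensor(y)
        p = y_hat.clip(EPS, 1.0 - EPS)
        val = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
        return val.mean() if val.ndim else val
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS, 1.0 - EPS)
    val = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.mean(val))


def smooth_l1(deltas, n: int | None = None):
    """Huber-style box-regression loss.

    Per residual: ``0.5 d**2`` when ``|d| < 1``, else ``|d| - 0.5``; averaged
    over ``n`` residuals (``n`` defaults to the number of elements).  With no
    residuals the loss is defined as 0 and a warning is emitted (no positive
    anchors in the batch).
    """
    if isinstance(deltas, Tensor):
        count = deltas.size if n is None else n
        if count == 0:
            warnings.warn("smooth_l1 over zero residuals; returning 0")
            return Tensor(0.0)
        a = deltas.abs()
        quad = (deltas * deltas) * 0.5
        lin = a - 0.5
        small = Tensor((np.abs(deltas.data) < 1.0).astype(deltas.data.dtype))
        return (quad * small + lin * (1.0 - small)).sum() * (1.0 / count)
    d = np.asarray(deltas, dtype=float).ravel()
    count = d.size if n is None else n
    if count == 0:
        warnings.warn("smooth_l1 over zero residuals; returning 0")
        return 0.0
    vals = np.where(np.abs(d) < 1.0, 0.5 * d**2, np.abs(d) - 0.5)
    return float(vals.sum() / count)


def total_loss(L_cls: float = 0.0, L_mask: float = 0.0,
               L_box: float = 0.0) -> LossBundle:
    """Bundle the three terms; components must be non-negative."""
    for name, v in (("L_cls", L_cls), ("L_mask", L_mask), ("L_box", L_box)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return LossBundle(float(L_cls), float(L_mask), float(L_box))
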