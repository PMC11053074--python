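"""Parameterized building blocks (module system, linear, layer norm, conv)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "ModuleList", "Parameter", "Linear", "LayerNorm", "Conv2d",
           "Sequential"]


class Parameter(Tensor):
    """A tensor that is updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and flat state dicts."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> list[str]:
        """Copy matching arrays into parameters; returns names left untouched."""
        skipped = []
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name in state and state[name].shape == p.data.shape:
                p.data[...] = state[name]
            else:
                skipped.append(name)
        if strict and skipped:
            raise KeyError(f"missing or mismatched parameters: {skipped}")
        return skipped

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m):
        self.items.append(m)


class Sequential(Module):
    def __init__(self, *modules):
        self.items = list(modules)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self.items):
            full = f"{prefix}.items.{i}" if prefix else f"items.{i}"
            yield from m.named_parameters(full)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draw truncated at two standard deviations (re-draw on excess)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift.

    Implemented as one fused graph node (the closed-form backward of layer
    normalization) rather than a chain of primitives — it is the most
    frequently applied operation in the network.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        mu = x.data.mean(axis=-1, keepdims=True)
        xc = x.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        gamma, beta = self.gamma, self.beta
        data = xhat * gamma.data + beta.data
        n = x.data.shape[-1]

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, n).sum(axis=0))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
            if x.requires_grad:
                gh = g * gamma.data
                mean_gh = gh.mean(axis=-1, keepdims=True)
                mean_ghx = (gh * xhat).mean(axis=-1, keepdims=True)
                x._accumulate(inv * (gh - mean_gh - xhat * mean_ghx))

        return Tensor._make(data, (x, gamma, beta), backward)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0, dilation: int = 1,
                 stride: int = 1, bias: bool = True):
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.padding = padding
        self.dilation = dilation
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)
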