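"""Parameterized layers on top of the autodiff core."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, maxpool2x2

__all__ = ["Module", "Conv2d", "Linear", "MaxPool2d", "ReLU", "Sequential"]

DTYPE = np.float32


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"{name}: shape {arr.shape} != expected {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """Stride-1 convolution with 'same'-style explicit padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: int = 0,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        init: str = "he",
        init_std: float = 0.01,
        init_gain: float = 1.0,
    ):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        if init == "he":
            std = init_gain * math.sqrt(2.0 / fan_in)
        elif init == "gaussian":
            std = init_std
        else:
            raise ValueError(f"unknown init scheme {init!r}")
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True)
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding, dilation=self.dilation)

    def reinit(self, rng: np.random.Generator, std: float) -> None:
        """Gaussian re-initialization: weights ~ N(0, std^2), biases 0."""
        self.weight.data = rng.normal(0.0, std, size=self.weight.data.shape).astype(DTYPE)
        self.bias.data = np.zeros_like(self.bias.data)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_features, out_features)).astype(DTYPE), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
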