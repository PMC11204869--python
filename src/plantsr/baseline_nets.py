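"""Lightweight reference SR networks for benchmarking: SRCNN, VDSR, EDSR.

These are the standard published configurations, rebuilt so the harness can
be validated against their well-known parameter budgets:

* SRCNN — 3 layers (9-5-5) on RGB, pre-upsampling: 69,251 parameters
  (0.069 M).
* VDSR — 20 bias-free 3×3 convolutions at 64 channels with a global
  residual over the bicubic-upscaled input, pre-upsampling: 667,008
  parameters (0.667 M).
* EDSR (baseline) — 16 residual blocks at 64 features, post-upsampling
  pixel-shuffle tail: 1,369,859 (×2) / 1,554,499 (×3) / 1,517,571 (×4)
  parameters.

Pre-upsampling networks consume the bicubic-interpolated LR image at target
size and refine it; post-upsampling networks work at LR size and upscale at
the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plantsr import nn
from plantsr.nn import Tensor

BASELINE_NAMES = ("srcnn", "vdsr", "edsr")


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    scale: int

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}")
        if self.scale not in (2, 3, 4):
            raise ValueError(f"scale must be 2, 3 or 4, got {self.scale}")

    @property
    def upsampling_style(self) -> str:
        return "pre" if self.name in ("srcnn", "vdsr") else "post"


class SRCNN(nn.Module):
    upsampling_style = "pre"
    scale = 1  # operates at target resolution

    def __init__(self, rng: np.random.Generator) -> None:
        self.conv1 = nn.Conv2d(3, 64, 9, rng=rng)
        self.conv2 = nn.Conv2d(64, 32, 5, rng=rng)
        self.conv3 = nn.Conv2d(32, 3, 5, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.conv1(x))
        y = nn.relu(self.conv2(y))
        return self.conv3(y)


class VDSR(nn.Module):
    upsampling_style = "pre"
    scale = 1

    def __init__(self, rng: np.random.Generator) -> None:
        # bias-free convolutions throughout (the published 0.667 M budget)
        layers: list[nn.Module] = [nn.Conv2d(3, 64, 3, bias=False, rng=rng), nn.ReLU()]
        for _ in range(18):
            layers += [nn.Conv2d(64, 64, 3, bias=False, rng=rng), nn.ReLU()]
        layers.append(nn.Conv2d(64, 3, 3, bias=False, rng=rng))
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        # learns the residual between the interpolated input and the target
        return nn.add(x, self.body(x))


class _EDSRResBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        self.conv1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return nn.add(x, self.conv2(nn.relu(self.conv1(x))))


class _PixelShuffleStage(nn.Module):
    def __init__(self, channels: int, s: int, rng: np.random.Generator) -> None:
        self.conv = nn.Conv2d(channels, channels * s * s, 3, rng=rng)
        self.s = s

    def forward(self, x: Tensor) -> Tensor:
        return nn.pixel_shuffle(self.conv(x), self.s)


class EDSR(nn.Module):
    """Baseline EDSR: 16 residual blocks, 64 features, residual scaling 1."""

    upsampling_style = "post"

    def __init__(self, scale: int, rng: np.random.Generator) -> None:
        if scale not in (2, 3, 4):
            raise ValueError(f"unsupported scale {scale}")
        self.scale = scale
        self.head = nn.Conv2d(3, 64, 3, rng=rng)
        self.blocks = [_EDSRResBlock(64, rng) for _ in range(16)]
        self.body_conv = nn.Conv2d(64, 64, 3, rng=rng)
        if scale == 4:
            stages = [_PixelShuffleStage(64, 2, rng), _PixelShuffleStage(64, 2, rng)]
        else:
            stages = [_PixelShuffleStage(64, scale, rng)]
        self.upsampler = nn.Sequential(*stages)
        self.tail = nn.Conv2d(64, 3, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.head(x)
        y = f
        for block in self.blocks:
            y = block(y)
        y = nn.add(f, self.body_conv(y))
        return self.tail(self.upsampler(y))


def build_srcnn(seed: int = 0) -> SRCNN:
    return SRCNN(np.random.default_rng(seed))


def build_vdsr(seed: int = 0) -> VDSR:
    return VDSR(np.random.default_rng(seed))


def build_edsr(scale: int, seed: int = 0) -> EDSR:
    return EDSR(scale, np.random.default_rng(seed))


def build_baseline(spec: BaselineSpec, seed: int = 0) -> nn.Module:
    if spec.name == "srcnn":
        return build_srcnn(seed)
    if spec.name == "vdsr":
        return build_vdsr(seed)
    return build_edsr(spec.scale, seed)
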