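"""Layer/module abstractions on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from plantsr.nn import tensor as T
from plantsr.nn.tensor import DTYPE, Tensor


class Module:
    """Base class: parameter registration, state dicts, train-free forward."""

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={missing}, extra={extra}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


def count_parameters(module: Module) -> int:
    """Total number of trainable scalar parameters."""
    return sum(p.data.size for p in module.parameters())


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # Kaiming-uniform with the conventional a=sqrt(5) leaky slope: U(±1/sqrt(fan_in))
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' spatial padding.

    ``pad_mode="replicate"`` (default) pads with edge values, matching the
    boundary convention of classical resamplers and avoiding the dark
    border fringes zero padding produces on image-valued tensors;
    ``pad_mode="zeros"`` gives the plain zero-padded convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        bias: bool = True,
        pad: int | None = None,
        pad_mode: str = "replicate",
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.pad = k // 2 if pad is None else pad
        if pad_mode not in ("replicate", "zeros"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.pad_mode = pad_mode
        fan_in = in_channels * k * k
        self.weight = Tensor(
            _uniform_init(rng, (out_channels, in_channels, k, k), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_uniform_init(rng, (out_channels,), fan_in), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if self.pad_mode == "replicate" and self.pad > 0:
            return T.conv2d(T.replicate_pad(x, self.pad), self.weight, self.bias, 0)
        return T.conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            _uniform_init(rng, (out_features, in_features), in_features),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_uniform_init(rng, (out_features,), in_features), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)
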