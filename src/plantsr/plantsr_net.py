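"""The PlantSR super-resolution network.

Three stages operating at low-resolution spatial size, followed by a
sub-pixel reconstruction head:

* shallow feature extraction — one 3×3 convolution ``H_SF0`` producing F0,
  then ``m`` residual groups ``H_SF1`` producing F1;
* deep feature extraction — ``n`` residual groups ``H_DF`` producing F_DF;
* reconstruction — ``H_UP``: a channel-expanding convolution (C → C·s²),
  a pixel-shuffle ×s, and a final convolution down to RGB, applied to the
  fused features F0 + F1 + F_DF.

Each residual group (RG) stacks four Residual SE-attention Blocks (RSEBs)
and adds a group-level skip from its input. An RSEB computes
``x + SE(conv(relu(conv(x))))`` where SE is squeeze-and-excitation channel
attention: global average pooling to per-channel descriptors, a bottleneck
C → C/r → C gating network, a sigmoid, and channel-wise rescaling.

No batch normalization is used anywhere, following the EDSR lineage of SR
residual networks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from plantsr import nn
from plantsr.image_io import RasterImage, UNIT_FLOAT, to_unit_float
from plantsr.nn import Tensor

SUPPORTED_SCALES = (2, 3, 4)

# Depth presets per scale: deeper deep-feature module at larger scales.
DEFAULT_N_PER_SCALE = {2: 4, 3: 8, 4: 12}


@dataclass(frozen=True)
class PlantSRConfig:
    """Hyperparameters that fully determine a PlantSR network."""

    scale: int = 2
    channels: int = 64
    m: int = 2  # residual groups in the shallow module H_SF1
    n: int | None = None  # residual groups in the deep module H_DF
    rseb_per_rg: int = 4
    se_reduction: int = 16
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.scale not in SUPPORTED_SCALES:
            raise ValueError(f"scale must be one of {SUPPORTED_SCALES}, got {self.scale}")
        if self.m < 0:
            raise ValueError("m must be ≥ 0")
        n = self.resolved_n
        if n < 1:
            raise ValueError("n must be ≥ 1")
        if self.channels < self.se_reduction or self.channels % self.se_reduction:
            raise ValueError(
                f"channels ({self.channels}) must be a positive multiple of "
                f"se_reduction ({self.se_reduction})"
            )

    @property
    def resolved_n(self) -> int:
        return DEFAULT_N_PER_SCALE[self.scale] if self.n is None else self.n


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention with a C/r bottleneck."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator) -> None:
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = nn.global_avg_pool(x)
        s = nn.relu(self.fc1(s))
        s = nn.sigmoid(self.fc2(s))
        return nn.channel_scale(x, s)


class RSEB(nn.Module):
    """Residual SE-attention block: x + SE(conv(relu(conv(x))))."""

    def __init__(
        self, channels: int, reduction: int, kernel: int, rng: np.random.Generator
    ) -> None:
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        self.conv1 = nn.Conv2d(channels, channels, kernel, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, kernel, rng=rng)
        self.se = SEBlock(channels, reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(nn.relu(self.conv1(x)))
        return nn.add(x, self.se(y))


class ResidualGroup(nn.Module):
    """A stack of RSEBs, a fusing convolution, and a group-level skip.

    The trailing convolution (the convention of channel-attention residual
    networks) makes the group an exact identity map when its convolution
    weights are zeroed, which keeps the whole network analyzable: zeroed
    groups collapse it to the reconstruction head applied to 3·F0.
    """

    def __init__(
        self,
        channels: int,
        reduction: int,
        n_blocks: int,
        kernel: int,
        rng: np.random.Generator,
    ) -> None:
        self.blocks = [RSEB(channels, reduction, kernel, rng) for _ in range(n_blocks)]
        self.conv = nn.Conv2d(channels, channels, kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for block in self.blocks:
            y = block(y)
        return nn.add(x, self.conv(y))


class PlantSR(nn.Module):
    def __init__(self, cfg: PlantSRConfig, rng: np.random.Generator) -> None:
        c, k, r = cfg.channels, cfg.kernel, cfg.se_reduction
        self.cfg = cfg
        self.scale = cfg.scale
        self.head = nn.Conv2d(3, c, k, rng=rng)
        self.shallow_groups = [
            ResidualGroup(c, r, cfg.rseb_per_rg, k, rng) for _ in range(cfg.m)
        ]
        self.deep_groups = [
            ResidualGroup(c, r, cfg.rseb_per_rg, k, rng) for _ in range(cfg.resolved_n)
        ]
        s = cfg.scale
        self.up_conv = nn.Conv2d(c, c * s * s, k, rng=rng)
        self.tail = nn.Conv2d(c, 3, k, rng=rng)

    def reconstruct(self, fused: Tensor) -> Tensor:
        """H_UP: expand channels, pixel-shuffle ×s, project to RGB."""
        y = nn.pixel_shuffle(self.up_conv(fused), self.scale)
        return self.tail(y)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected NCHW RGB input, got shape {x.data.shape}")
        f0 = self.head(x)
        f1 = f0
        for g in self.shallow_groups:
            f1 = g(f1)
        f_df = f1
        for g in self.deep_groups:
            f_df = g(f_df)
        fused = nn.add(nn.add(f0, f1), f_df)
        return self.reconstruct(fused)


def build_rseb(
    channels: int, se_reduction: int, kernel: int = 3, seed: int = 0
) -> RSEB:
    """Build a single residual SE-attention block (mainly for testing)."""
    return RSEB(channels, se_reduction, kernel, np.random.default_rng(seed))


def _cubic_phase_filters(s: int, k: int) -> np.ndarray:
    """(s, s, k, k) filters so that conv→pixel-shuffle interpolates ×s.

    With center-aligned coordinates, HR pixel (s·i + p) samples the LR grid
    at offset d = (2p + 1 − s) / (2s) from pixel i. Each phase holds the
    Keys cubic kernel evaluated at the taps a k×k kernel can reach
    (truncated to |j| ≤ k//2) and renormalized to sum 1 — the closest
    approximation to bicubic interpolation the layer can represent.
    """
    from plantsr.degradation import cubic_weight

    c = k // 2
    filters = np.zeros((s, s, k, k))
    taps = []
    for p in range(s):
        d = (2 * p + 1 - s) / (2 * s)
        w = np.array([cubic_weight(d - j) for j in range(-c, c + 1)])
        taps.append(w / w.sum())
    for p in range(s):
        for q in range(s):
            filters[p, q] = np.outer(taps[p], taps[q])
    return filters


def _interpolation_init(net: PlantSR) -> None:
    """Start the network as a classical-interpolation upscaler.

    Upsampling layers initialized to reproduce classical interpolation
    (the bilinear-deconvolution / ICNR lineage) give residual SR networks a
    sensible starting point: the first forward pass already matches an
    interpolation baseline, and training refines it instead of first
    rediscovering the color mapping. Concretely: the head extracts RGB/3
    into the first three feature channels, every residual group starts as
    the identity (zero-initialized fusing convolution, as in zero-init
    residual-branch schemes), the channel-expanding convolution holds
    truncated-cubic phase filters, and the tail reads the shuffled channels
    back out. All remaining weights keep their random initialization but
    are silenced by the zeroed fusion convolutions.
    """
    cfg = net.cfg
    c_mid = net.head.weight.data.shape[2] // 2
    net.head.weight.data[:] = 0
    net.head.bias.data[:] = 0
    for ch in range(3):
        # fused features are F0+F1+F_DF = 3·F0 at init, hence the 1/3
        net.head.weight.data[ch, ch, c_mid, c_mid] = 1.0 / 3.0
    for group in net.shallow_groups + net.deep_groups:
        group.conv.weight.data[:] = 0
        group.conv.bias.data[:] = 0
    s, k = cfg.scale, cfg.kernel
    phases = _cubic_phase_filters(s, k)
    net.up_conv.weight.data[:] = 0
    net.up_conv.bias.data[:] = 0
    for ch in range(3):
        for p in range(s):
            for q in range(s):
                net.up_conv.weight.data[ch * s * s + p * s + q, ch] = phases[p, q]
    net.tail.weight.data[:] = 0
    net.tail.bias.data[:] = 0
    for ch in range(3):
        net.tail.weight.data[ch, ch, k // 2, k // 2] = 1.0


def build_plantsr(cfg: PlantSRConfig, seed: int = 0, init: str = "interp") -> PlantSR:
    """Construct a PlantSR network.

    ``init="interp"`` (default) applies the interpolation-equivalent
    initialization, so an untrained network reproduces bilinear upscaling;
    ``init="random"`` keeps plain Kaiming-style random weights.
    """
    net = PlantSR(cfg, np.random.default_rng(seed))
    if init == "interp":
        _interpolation_init(net)
    elif init != "random":
        raise ValueError(f"unknown init scheme {init!r}")
    return net


def count_parameters(network: nn.Module) -> int:
    """Total trainable scalar parameters of any network in this package."""
    return nn.count_parameters(network)


def image_to_batch(img: RasterImage) -> np.ndarray:
    """HWC unit-float image → 1×C×H×W float32 array."""
    if img.value_range != UNIT_FLOAT:
        img = to_unit_float(img)
    return img.pixels.transpose(2, 0, 1)[None].astype(np.float32)


def batch_to_image(arr: np.ndarray, clamp: bool = True) -> RasterImage:
    """1×C×H×W array → HWC unit-float image, clamped to [0, 1] for export."""
    out = np.asarray(arr[0], dtype=np.float64).transpose(1, 2, 0)
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return RasterImage(out, UNIT_FLOAT)


def forward(network: nn.Module, lr: RasterImage) -> RasterImage:
    """Super-resolve a single image; output dims are scale× the input dims.

    The returned image is clamped to [0, 1] (export convention); during
    training the raw network output is used for the loss instead.
    """
    if lr.channels != 3:
        raise ValueError("super-resolution input must be RGB")
    out = network(Tensor(image_to_batch(lr)))
    return batch_to_image(out.data)


def save_checkpoint(
    network: nn.Module,
    path: str | Path,
    extra: dict | None = None,
) -> None:
    """Save weights as ``.npz`` with a JSON sidecar describing the model."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **network.state_dict())
    meta: dict = dict(extra or {})
    cfg = getattr(network, "cfg", None)
    if cfg is not None:
        meta["config"] = asdict(cfg)
    meta.setdefault("arch", type(network).__name__)
    meta.setdefault("scale", getattr(network, "scale", None))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a checkpoint's weights and its JSON sidecar metadata."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return state, meta


def load_plantsr(path: str | Path) -> PlantSR:
    """Rebuild a PlantSR network from a checkpoint written by save_checkpoint."""
    state, meta = load_checkpoint(path)
    if "config" not in meta:
        raise ValueError(f"checkpoint {path} has no PlantSR config sidecar")
    net = build_plantsr(PlantSRConfig(**meta["config"]))
    net.load_state_dict(state)
    return net
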