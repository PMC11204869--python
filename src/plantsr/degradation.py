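"""Bicubic resampling: the HR→LR degradation operator and classical baseline.

Single-image super-resolution benchmarks conventionally synthesize the
low-resolution input by bicubic downsampling of the ground-truth image with
the Keys cubic kernel (a = −0.5), antialiasing (kernel support widened by
the zoom factor when shrinking), center-aligned coordinates, and
edge-replicating boundaries — the convention of MATLAB's ``imresize`` that
dominates the SR literature. The same operator, run in the upscaling
direction, is the "Bicubic" baseline every learned model is compared to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plantsr.image_io import RasterImage, UINT8, UNIT_FLOAT

DEFAULT_A = -0.5


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the HR→LR operator.

    scale
        Integer downsampling factor (2, 3 or 4).
    antialias
        Widen the kernel by the zoom factor when downsampling (imresize
        convention). Plain decimation-style bicubic is obtained with False.
    a
        Sharpness parameter of the Keys cubic kernel.
    """

    scale: int = 2
    antialias: bool = True
    a: float = DEFAULT_A

    def __post_init__(self) -> None:
        if self.scale not in (2, 3, 4):
            raise ValueError(f"scale must be 2, 3 or 4, got {self.scale}")


def cubic_weight(t, a: float = DEFAULT_A):
    """Keys cubic kernel.

    ``(a+2)|t|³ − (a+3)|t|² + 1`` for |t| ≤ 1,
    ``a|t|³ − 5a|t|² + 8a|t| − 4a`` for 1 < |t| < 2, else 0.
    """
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.where(
        t <= 1,
        (a + 2) * t**3 - (a + 3) * t**2 + 1,
        np.where(t < 2, a * (t**3 - 5 * t**2 + 8 * t - 4), 0.0),
    )
    return out if out.ndim else float(out)


def _resample_weights(
    in_size: int, out_size: int, a: float, antialias: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-output-pixel source indices and kernel weights along one axis.

    Output pixel ``i`` samples the input at ``u = (i + 0.5)/zoom − 0.5``
    (center alignment). When shrinking with antialias, the kernel is dilated
    by ``1/zoom`` so its footprint covers the source pixels being merged.
    Out-of-range taps are clamped to the edge (boundary replication), and
    weights are renormalized to sum to 1.
    """
    zoom = out_size / in_size
    if antialias and zoom < 1:
        kernel_scale = zoom
        support = 2.0 / zoom
    else:
        kernel_scale = 1.0
        support = 2.0
    i = np.arange(out_size, dtype=np.float64)
    u = (i + 0.5) / zoom - 0.5
    left = np.floor(u - support).astype(np.int64) + 1
    n_taps = int(np.ceil(2 * support)) + 1
    idx = left[:, None] + np.arange(n_taps)[None, :]
    weights = cubic_weight((u[:, None] - idx) * kernel_scale, a)
    weights /= weights.sum(axis=1, keepdims=True)
    idx = np.clip(idx, 0, in_size - 1)
    return idx, weights


def _resize_axis(arr: np.ndarray, out_size: int, axis: int, a: float, antialias: bool) -> np.ndarray:
    idx, w = _resample_weights(arr.shape[axis], out_size, a, antialias)
    moved = np.moveaxis(arr, axis, 0)
    out = np.einsum("ot,ot...->o...", w, moved[idx])
    return np.moveaxis(out, 0, axis)


def resize_bicubic(
    img: RasterImage,
    out_h: int,
    out_w: int,
    cfg: DegradationConfig | None = None,
) -> RasterImage:
    """Separable bicubic resize to ``out_h × out_w``.

    uint8 inputs are processed in float and rounded/clamped back to uint8;
    unit-float inputs stay float and are clamped to [0, 1].
    """
    if out_h < 1 or out_w < 1:
        raise ValueError(f"output size must be ≥ 1, got {out_h}×{out_w}")
    cfg = cfg or DegradationConfig()
    arr = img.pixels.astype(np.float64)
    arr = _resize_axis(arr, out_h, 0, cfg.a, cfg.antialias)
    arr = _resize_axis(arr, out_w, 1, cfg.a, cfg.antialias)
    if img.value_range == UINT8:
        rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
        return RasterImage(np.clip(rounded, 0, 255).astype(np.uint8), UINT8)
    return RasterImage(np.clip(arr, 0.0, 1.0), UNIT_FLOAT)


def resize_bicubic_array(
    arr: np.ndarray, out_h: int, out_w: int, cfg: DegradationConfig | None = None
) -> np.ndarray:
    """Float-array variant of :func:`resize_bicubic` without range clamping."""
    cfg = cfg or DegradationConfig()
    arr = np.asarray(arr, dtype=np.float64)
    arr = _resize_axis(arr, out_h, 0, cfg.a, cfg.antialias)
    return _resize_axis(arr, out_w, 1, cfg.a, cfg.antialias)


def make_lr_hr_pair(
    hr: RasterImage, cfg: DegradationConfig
) -> tuple[RasterImage, RasterImage]:
    """Crop HR to a multiple of the scale and synthesize its LR counterpart.

    The HR image is cropped at the top-left corner so both dimensions are
    divisible by ``cfg.scale``; the LR image is the bicubic downsample of the
    crop by that factor. Deterministic: no randomness anywhere.
    """
    s = cfg.scale
    if hr.height < s or hr.width < s:
        raise ValueError(
            f"HR image {hr.height}×{hr.width} is smaller than scale {s}"
        )
    ch, cw = (hr.height // s) * s, (hr.width // s) * s
    hr_cropped = RasterImage(hr.pixels[:ch, :cw].copy(), hr.value_range)
    lr = resize_bicubic(hr_cropped, ch // s, cw // s, cfg)
    return lr, hr_cropped
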