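"""Image-quality and counting-error metrics.

Image quality is scored with PSNR and SSIM on 8-bit values (dynamic range
L = MAX = 255), with no border cropping and no luminance conversion by
default; an optional Y-channel/border-shave path is provided for
cross-benchmark comparison. Counting accuracy is scored with MAE and RMSE
over per-image (ground truth, predicted) object counts.

PSNR = 10·log10(MAX²/MSE).

SSIM = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2)),
with C1 = (0.01 L)² and C2 = (0.03 L)². Two evaluation modes are offered:
``global`` applies the formula once per channel over the whole image (the
literal single-window reading), while ``windowed`` (default) computes the
standard local map with an 11×11 Gaussian window of σ = 1.5 and averages —
the convention of the original SSIM paper and of SR benchmark tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from plantsr.image_io import RasterImage

PSNR_INF = math.inf


@dataclass(frozen=True)
class MetricConfig:
    max_val: float = 255.0
    ssim_mode: str = "windowed"  # "windowed" | "global"
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.max_val <= 0:
            raise ValueError("max_val must be positive")
        if self.ssim_mode not in ("windowed", "global"):
            raise ValueError(f"unknown ssim_mode {self.ssim_mode!r}")

    @property
    def c1(self) -> float:
        return (0.01 * self.max_val) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.max_val) ** 2


@dataclass(frozen=True)
class CountRecord:
    """Ground-truth and predicted object count for one image."""

    y_true: float
    y_pred: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.y_true < 0 or self.y_pred < 0:
            raise ValueError("counts must be non-negative")


def _as_float(img: RasterImage | np.ndarray) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def mse(x: RasterImage | np.ndarray, y: RasterImage | np.ndarray) -> float:
    """Mean squared error over all pixels and channels."""
    xa, ya = _as_float(x), _as_float(y)
    _check_shapes(xa, ya)
    return float(np.mean((xa - ya) ** 2))


def psnr(
    x: RasterImage | np.ndarray,
    y: RasterImage | np.ndarray,
    cfg: MetricConfig | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    cfg = cfg or MetricConfig()
    err = mse(x, y)
    if err == 0:
        return PSNR_INF
    return 10.0 * math.log10(cfg.max_val**2 / err)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2
    g = np.exp(-((np.arange(size) - half) ** 2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _ssim_global_channel(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return float(
        ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def _ssim_windowed_channel(
    x: np.ndarray, y: np.ndarray, c1: float, c2: float, win: np.ndarray
) -> float:
    k = win.shape[0]
    w = win.ravel()
    xw = sliding_window_view(x, (k, k)).reshape(-1, k * k)
    yw = sliding_window_view(y, (k, k)).reshape(-1, k * k)
    mu_x = xw @ w
    mu_y = yw @ w
    # weighted second moments; variance via E[x²] − E[x]²
    ex2 = (xw**2) @ w
    ey2 = (yw**2) @ w
    exy = (xw * yw) @ w
    var_x = ex2 - mu_x**2
    var_y = ey2 - mu_y**2
    cov = exy - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def ssim(
    x: RasterImage | np.ndarray,
    y: RasterImage | np.ndarray,
    cfg: MetricConfig | None = None,
) -> float:
    """Structural similarity index, averaged over channels."""
    cfg = cfg or MetricConfig()
    xa, ya = _as_float(x), _as_float(y)
    _check_shapes(xa, ya)
    if xa.ndim == 2:
        xa, ya = xa[:, :, None], ya[:, :, None]
    vals = []
    if cfg.ssim_mode == "global":
        for c in range(xa.shape[2]):
            vals.append(_ssim_global_channel(xa[:, :, c], ya[:, :, c], cfg.c1, cfg.c2))
    else:
        k = cfg.window_size
        if xa.shape[0] < k or xa.shape[1] < k:
            raise ValueError(
                f"image {xa.shape[:2]} smaller than SSIM window {k}×{k}"
            )
        win = _gaussian_window(k, cfg.window_sigma)
        for c in range(xa.shape[2]):
            vals.append(
                _ssim_windowed_channel(xa[:, :, c], ya[:, :, c], cfg.c1, cfg.c2, win)
            )
    return float(np.mean(vals))


def rgb_to_luminance(img: RasterImage | np.ndarray) -> np.ndarray:
    """ITU-R BT.601 Y channel on the 8-bit scale (16–235 nominal range)."""
    arr = _as_float(img)
    if arr.shape[2] != 3:
        raise ValueError("luminance conversion requires an RGB image")
    r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
    return (65.481 * r + 128.553 * g + 24.966 * b) / 255.0 + 16.0


def shave_border(arr: np.ndarray, border: int) -> np.ndarray:
    """Crop ``border`` pixels from every side (cross-benchmark convention)."""
    if border == 0:
        return arr
    if 2 * border >= min(arr.shape[0], arr.shape[1]):
        raise ValueError("border too large for image")
    return arr[border:-border, border:-border]


def mae(records: Iterable[CountRecord]) -> float:
    """Mean absolute counting error, (1/n) Σ |ŷᵢ − yᵢ|."""
    recs = list(records)
    if not recs:
        raise ValueError("mae requires at least one record")
    return float(np.mean([abs(r.y_pred - r.y_true) for r in recs]))


def rmse(records: Iterable[CountRecord]) -> float:
    """Root mean square counting error, sqrt((1/n) Σ (ŷᵢ − yᵢ)²)."""
    recs = list(records)
    if not recs:
        raise ValueError("rmse requires at least one record")
    return float(np.sqrt(np.mean([(r.y_pred - r.y_true) ** 2 for r in recs])))


def read_count_csv(path: str | Path) -> list[CountRecord]:
    """Read counting records from a CSV with columns image_id,y_true,y_pred
    (or just y_true,y_pred)."""
    records = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            records.append(
                CountRecord(
                    y_true=float(row["y_true"]),
                    y_pred=float(row["y_pred"]),
                    image_id=row.get("image_id", str(i)),
                )
            )
    return records


def write_metric_csv(
    path: str | Path, rows: Sequence[dict], summary: dict | None = None
) -> None:
    """Write per-image metric rows plus an optional 'mean' summary row."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
        if summary is not None:
            writer.writerow(summary)
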