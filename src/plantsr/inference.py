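"""Full-image super-resolution with tiling, folder preprocessing, and the
detection-cutoff rescaling rule.

Large inputs are processed as overlapping tiles in the LR frame; each tile
is super-resolved independently and the results are assembled at s× scale
with averaging over overlap regions. With an overlap larger than the
network's receptive-field growth, the tiled result matches the untiled
forward pass away from tile seams.

When an upscaled image feeds a point-detection counting pipeline, any
distance threshold expressed in pixels (such as the k-d-tree cutoff used to
merge nearby point predictions) must grow by the same scale factor, since
all pixel distances in the upscaled frame are multiplied by s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from plantsr import nn
from plantsr.image_io import (
    ImageFormatError,
    RasterImage,
    UINT8,
    UNIT_FLOAT,
    read_image,
    to_uint8,
    to_unit_float,
    write_image,
)
from plantsr.nn import Tensor


@dataclass(frozen=True)
class TilingPlan:
    """Tiling of the LR frame: tile side, overlap, and averaging at seams."""

    tile: int = 128
    overlap: int = 16

    def __post_init__(self) -> None:
        if self.overlap < 0:
            raise ValueError("overlap must be ≥ 0")
        if self.tile <= self.overlap:
            raise ValueError(
                f"tile ({self.tile}) must be larger than overlap ({self.overlap})"
            )


def _tile_starts(length: int, tile: int, overlap: int) -> list[int]:
    if length <= tile:
        return [0]
    step = tile - overlap
    starts = list(range(0, length - tile, step))
    starts.append(length - tile)
    return sorted(set(starts))


def upscale_image(
    network: nn.Module, img: RasterImage, plan: TilingPlan | None = None
) -> RasterImage:
    """Super-resolve one RGB image tile by tile; output dims = input × s.

    Overlapping output regions are averaged. The result is a unit-float
    image clamped to [0, 1].
    """
    if img.channels != 3:
        raise ValueError("super-resolution input must be RGB")
    plan = plan or TilingPlan()
    s = getattr(network, "scale", 1)
    lr = to_unit_float(img) if img.value_range == UINT8 else img
    h, w = lr.height, lr.width
    acc = np.zeros((h * s, w * s, 3), dtype=np.float64)
    weight = np.zeros((h * s, w * s, 1), dtype=np.float64)
    trim = plan.overlap // 2
    for top in _tile_starts(h, plan.tile, plan.overlap):
        for left in _tile_starts(w, plan.tile, plan.overlap):
            th = min(plan.tile, h - top)
            tw = min(plan.tile, w - left)
            tile = lr.pixels[top : top + th, left : left + tw]
            x = Tensor(tile.transpose(2, 0, 1)[None].astype(np.float32))
            out = network(x).data[0].astype(np.float64).transpose(1, 2, 0)
            # drop half the overlap along interior tile edges: those output
            # pixels are corrupted by the tile's own boundary padding
            t0 = trim if top > 0 else 0
            b0 = trim if top + th < h else 0
            l0 = trim if left > 0 else 0
            r0 = trim if left + tw < w else 0
            out = out[t0 * s : (th - b0) * s, l0 * s : (tw - r0) * s]
            ys = slice((top + t0) * s, (top + th - b0) * s)
            xs = slice((left + l0) * s, (left + tw - r0) * s)
            acc[ys, xs] += out
            weight[ys, xs] += 1.0
    sr = acc / weight
    return RasterImage(np.clip(sr, 0.0, 1.0), UNIT_FLOAT)


@dataclass
class FolderReport:
    """Outcome of a folder-level upscaling run."""

    entries: list[dict] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return sum(1 for e in self.entries if e["status"] == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.entries if e["status"] == "failed")


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def upscale_folder(
    in_dir: str | Path,
    out_dir: str | Path,
    network: nn.Module,
    plan: TilingPlan | None = None,
    overwrite: bool = True,
) -> FolderReport:
    """Upscale every decodable image in ``in_dir`` into ``out_dir``.

    Outputs keep the input basename (always written as PNG). Unreadable
    files are recorded as failures and processing continues. An empty
    folder yields an empty report.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = FolderReport()
    files = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    for path in files:
        out_path = out_dir / (path.stem + ".png")
        if out_path.exists() and not overwrite:
            report.entries.append(
                {"file": path.name, "status": "skipped", "reason": "exists"}
            )
            continue
        try:
            img = read_image(path)
            sr = upscale_image(network, img, plan)
            write_image(to_uint8(sr), out_path)
            report.entries.append(
                {
                    "file": path.name,
                    "status": "ok",
                    "in_size": (img.height, img.width),
                    "out_size": (sr.height, sr.width),
                }
            )
        except (ImageFormatError, OSError, ValueError) as exc:
            report.entries.append(
                {"file": path.name, "status": "failed", "reason": str(exc)}
            )
    return report


def scale_distance_cutoff(cutoff: float, scale: int) -> float:
    """Rescale a pixel-distance threshold into the s×-upscaled frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if scale < 1:
        raise ValueError("scale must be ≥ 1")
    return cutoff * scale
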