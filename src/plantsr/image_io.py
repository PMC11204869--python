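"""Raster image I/O, dataset manifests, and pixel-representation conversions.

The toolkit works on 8-bit RGB images. Internally two representations are
used: ``uint8`` arrays with values in [0, 255] (the storage and metric
convention, dynamic range L = 255) and unit-float arrays in [0, 1] (the
training convention). Conversion divides by 255; reconversion rounds half
away from zero and clamps, so the round-trip is exact on every uint8 value.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

UINT8 = "uint8"
UNIT_FLOAT = "unit_float"

_VALID_RANGES = (UINT8, UNIT_FLOAT)


class ImageFormatError(ValueError):
    """Raised when a file exists but cannot be decoded as an image."""


@dataclass
class RasterImage:
    """An H×W×C pixel array with an explicit value-range convention.

    Parameters
    ----------
    pixels
        Array of shape ``(height, width, channels)``; dtype ``uint8`` for the
        ``"uint8"`` range, floating point for ``"unit_float"``.
    value_range
        Either ``"uint8"`` (integers in [0, 255]) or ``"unit_float"``
        (floats in [0, 1]).
    """

    pixels: np.ndarray
    value_range: str = UINT8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be H×W×C, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image dimensions must be ≥ 1, got {px.shape[:2]}")
        if px.shape[2] not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {px.shape[2]}")
        if self.value_range not in _VALID_RANGES:
            raise ValueError(f"value_range must be one of {_VALID_RANGES}")
        if self.value_range == UINT8 and px.dtype != np.uint8:
            raise ValueError(f"uint8 range requires uint8 dtype, got {px.dtype}")
        if self.value_range == UNIT_FLOAT and not np.issubdtype(px.dtype, np.floating):
            raise ValueError(f"unit_float range requires float dtype, got {px.dtype}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    split: str  # "train" or "test"
    category: str | None = None


@dataclass
class DatasetManifest:
    """Listing of HR images with a train/test split and optional labels."""

    root: Path
    entries: list[ManifestEntry] = field(default_factory=list)

    def paths(self, split: str) -> list[Path]:
        return [e.path for e in self.entries if e.split == split]

    @property
    def train(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == "train"]

    @property
    def test(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == "test"]


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG or JPEG file as a uint8 RGB :class:`RasterImage`.

    Grayscale sources are promoted to three identical channels; any alpha
    channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"cannot decode {path} as an image") from exc
    return RasterImage(arr, UINT8)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write an image to PNG/JPEG (format chosen by extension).

    Unit-float images are converted to uint8 first.
    """
    if img.value_range == UNIT_FLOAT:
        img = to_uint8(img)
    px = img.pixels
    if px.shape[2] == 1:
        px = px[:, :, 0]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(px).save(path)


def to_unit_float(img: RasterImage) -> RasterImage:
    """Convert a uint8 image to unit-float range by dividing by 255."""
    if img.value_range == UNIT_FLOAT:
        warnings.warn("image is already unit-float; returning unchanged", stacklevel=2)
        return img
    return RasterImage(img.pixels.astype(np.float64) / 255.0, UNIT_FLOAT)


def to_uint8(img: RasterImage) -> RasterImage:
    """Convert a unit-float image to uint8.

    Values are scaled by 255, rounded half away from zero, and clamped to
    [0, 255]; on non-negative inputs this is ``floor(v·255 + 0.5)``.
    """
    if img.value_range == UINT8:
        warnings.warn("image is already uint8; returning unchanged", stacklevel=2)
        return img
    return RasterImage(float_array_to_uint8(img.pixels), UINT8)


def float_array_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Array-level unit-float → uint8 with round-half-away-from-zero."""
    scaled = np.asarray(arr, dtype=np.float64) * 255.0
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def load_manifest(
    root: str | Path,
    listing: str | Path | None = None,
    validate: bool = False,
) -> DatasetManifest:
    """Load a dataset manifest from a directory tree or a listing file.

    Directory convention: ``root/train/`` and ``root/test/`` contain the HR
    images; the immediate parent directory name below the split (if any) is
    taken as the category label. Alternatively ``listing`` names a CSV file
    with columns ``path,split[,category]`` where paths are relative to
    ``root``. Entries are sorted by path within each split so ordering is
    deterministic across runs.
    """
    root = Path(root)
    entries: list[ManifestEntry] = []
    if listing is not None:
        with open(listing, newline="") as fh:
            for row in csv.DictReader(fh):
                p = root / row["path"]
                if not p.exists():
                    raise FileNotFoundError(f"manifest listing references missing file: {p}")
                entries.append(
                    ManifestEntry(p, row["split"], row.get("category") or None)
                )
    else:
        for split in ("train", "test"):
            split_dir = root / split
            if not split_dir.is_dir():
                raise FileNotFoundError(f"expected split directory {split_dir}")
            for p in sorted(split_dir.rglob("*")):
                if p.suffix.lower() in _IMAGE_SUFFIXES:
                    category = p.parent.name if p.parent != split_dir else None
                    entries.append(ManifestEntry(p, split, category))
    entries.sort(key=lambda e: (e.split, str(e.path)))
    manifest = DatasetManifest(root=root, entries=entries)
    for split in ("train", "test"):
        if not manifest.paths(split):
            raise ValueError(f"manifest split '{split}' is empty under {root}")
    if validate:
        for e in manifest.entries:
            read_image(e.path)
    return manifest


def extract_patch(img: RasterImage, top: int, left: int, size: int) -> RasterImage:
    """Extract a ``size``×``size`` crop with top-left corner (top, left).

    The patch must lie fully inside the image; there is no implicit padding.
    The returned pixels are an independent copy.
    """
    if top < 0 or left < 0 or top + size > img.height or left + size > img.width:
        raise IndexError(
            f"patch (top={top}, left={left}, size={size}) exceeds "
            f"image bounds {img.height}×{img.width}"
        )
    return RasterImage(img.pixels[top : top + size, left : left + size].copy(), img.value_range)
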