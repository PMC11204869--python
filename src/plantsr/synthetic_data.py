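"""Procedural plant-like imagery for exercising the SR pipeline end to end.

Real plant photographs combine fine, band-limited texture (leaf venation,
needle edges, seed boundaries) with smooth illumination — exactly the
structure that bicubic downsampling destroys and a super-resolution model
must restore. The generator emulates that statistical shape with seeded
random sinusoidal gratings (venation-like oscillation), thresholded ridge
lines (sharp edges), and a low-frequency illumination field, mapped through
a green-dominant palette. Everything is bit-deterministic in the seed.

Counting scenes place non-overlapping shaded disks (seed/fruit-like blobs)
on a textured background with known ground-truth count and centers, for the
MAE/RMSE harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from plantsr.image_io import (
    DatasetManifest,
    RasterImage,
    UINT8,
    load_manifest,
    write_image,
)

CATEGORIES = ("angiosperm", "gymnosperm", "fern", "bryophyte")

# per-category green-dominant base tones (RGB, uint8 scale)
_PALETTES = {
    "angiosperm": (58, 122, 48),
    "gymnosperm": (38, 92, 62),
    "fern": (72, 138, 42),
    "bryophyte": (88, 112, 36),
}


@dataclass(frozen=True)
class SynthSpec:
    height: int = 96
    width: int = 96
    seed: int = 0
    n_frequencies: int = 24
    edge_density: float = 0.15
    palette: tuple[int, int, int] = _PALETTES["angiosperm"]

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("synthetic images must be at least 16×16")


def _grating_field(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of random sinusoidal gratings with energy up to ~0.45 cycles/px."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    field = np.zeros((spec.height, spec.width))
    # log-uniform frequencies; roughly 1/sqrt(f) amplitudes keep the spectrum
    # natural-image-like while leaving >1% of power above the half-Nyquist of
    # a ×2-downsampled grid (0.125 cycles/px)
    freqs = np.exp(rng.uniform(np.log(0.02), np.log(0.45), size=spec.n_frequencies))
    thetas = rng.uniform(0, 2 * np.pi, size=spec.n_frequencies)
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_frequencies)
    for f, th, ph in zip(freqs, thetas, phases):
        amp = 1.0 / np.sqrt(f / 0.02)
        field += amp * np.sin(
            2 * np.pi * f * (np.cos(th) * xx + np.sin(th) * yy) + ph
        )
    return field


def _ridge_lines(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Thin bright veins: zero-crossing ridges of smooth random fields."""
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    ridges = np.zeros((spec.height, spec.width))
    n_veins = max(2, int(round(8 * spec.edge_density / 0.15)))
    for _ in range(n_veins):
        f = rng.uniform(0.008, 0.03)
        th = rng.uniform(0, 2 * np.pi)
        ph = rng.uniform(0, 2 * np.pi)
        bend = rng.uniform(0.3, 1.2)
        v = np.sin(
            2 * np.pi * f * (np.cos(th) * xx + np.sin(th) * yy)
            + bend * np.sin(2 * np.pi * f * 2.7 * (np.cos(th) * yy - np.sin(th) * xx))
            + ph
        )
        width = rng.uniform(0.05, 0.12)
        ridges += np.exp(-((v / width) ** 2))
    return np.clip(ridges, 0, 1.5)


def gen_plant_texture(spec: SynthSpec) -> RasterImage:
    """Generate one deterministic plant-like HR texture as uint8 RGB."""
    rng = np.random.default_rng(spec.seed)
    gratings = _grating_field(spec, rng)
    gratings = (gratings - gratings.mean()) / (gratings.std() + 1e-12)
    ridges = _ridge_lines(spec, rng)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    gy, gx = rng.uniform(-1, 1, size=2)
    illum = 0.25 * (gy * yy / spec.height + gx * xx / spec.width)
    field = 0.5 + 0.16 * gratings + 0.28 * ridges + illum
    field = np.clip(field, 0.0, 1.0)
    base = np.array(spec.palette, dtype=np.float64) / 255.0
    # darker ground tone toward field=0, brighter leaf tone toward field=1
    lo, hi = base * 0.35, np.clip(base * 1.55 + 0.08, 0, 1)
    rgb = lo[None, None] + field[:, :, None] * (hi - lo)[None, None]
    return RasterImage(
        np.clip(np.floor(rgb * 255.0 + 0.5), 0, 255).astype(np.uint8), UINT8
    )


def gen_sr_dataset(
    root: str | Path,
    n_train: int,
    n_test: int,
    size: int = 96,
    seed: int = 0,
    overwrite: bool = False,
) -> DatasetManifest:
    """Write a train/test tree of synthetic HR PNGs and return its manifest.

    Category labels cycle over four pseudo-taxa. Regeneration with the same
    arguments produces byte-identical files.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be ≥ 1")
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} exists and is not empty; pass overwrite=True")
    counts = {"train": n_train, "test": n_test}
    idx = 0
    for split, n in counts.items():
        for i in range(n):
            category = CATEGORIES[idx % len(CATEGORIES)]
            spec = SynthSpec(
                height=size,
                width=size,
                seed=(seed * 1_000_003 + idx) % (2**31),
                palette=_PALETTES[category],
            )
            img = gen_plant_texture(spec)
            write_image(img, root / split / category / f"img_{idx:04d}.png")
            idx += 1
    return load_manifest(root)


def gen_counting_scene(
    n_objects: int,
    size: int = 256,
    radius_range: tuple[float, float] = (6.0, 12.0),
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[RasterImage, int, list[tuple[float, float]]]:
    """A textured scene with ``n_objects`` non-overlapping shaded disks.

    Returns the image, the ground-truth count, and the (row, col) centers.
    Raises if the requested packing is infeasible after bounded retries.
    """
    rng = np.random.default_rng(seed)
    bg = gen_plant_texture(
        SynthSpec(height=size, width=size, seed=int(rng.integers(2**31)))
    )
    canvas = bg.pixels.astype(np.float64) * 0.55  # dimmed backdrop
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_objects):
        placed = False
        for _ in range(max_tries):
            r = rng.uniform(*radius_range)
            cy = rng.uniform(r + 1, size - r - 1)
            cx = rng.uniform(r + 1, size - r - 1)
            if all(
                np.hypot(cy - oy, cx - ox) > r + orad + 1.0
                for (oy, ox), orad in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {n_objects} non-overlapping objects of radii "
                f"{radius_range} in a {size}×{size} scene"
            )
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    base_tone = np.array([214.0, 188.0, 122.0])  # seed-like beige
    for (cy, cx), r in zip(centers, radii):
        d = np.hypot(yy - cy, xx - cx)
        mask = d <= r
        shade = np.clip(1.15 - 0.55 * (d / r) ** 2, 0, 1.15)
        tint = rng.uniform(0.85, 1.05)
        for c in range(3):
            canvas[:, :, c] = np.where(
                mask, base_tone[c] * tint * shade, canvas[:, :, c]
            )
    img = RasterImage(np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8), UINT8)
    return img, len(centers), centers


def write_counting_scene(
    out_png: str | Path,
    n_objects: int,
    size: int = 256,
    radius_range: tuple[float, float] = (6.0, 12.0),
    seed: int = 0,
) -> Path:
    """Write a counting scene PNG plus a JSON ground-truth sidecar."""
    img, count, centers = gen_counting_scene(n_objects, size, radius_range, seed)
    out_png = Path(out_png)
    write_image(img, out_png)
    sidecar = out_png.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"count": count, "centers": centers, "seed": seed}, indent=2)
    )
    return sidecar
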