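"""Patch-based SR training: sampling, L1 loss, Adam loop, checkpointing.

Each training batch draws 32 HR patches (64×64 for scales 2 and 4, 63×63
for scale 3) uniformly from the training images, synthesizes the matching
LR patches by bicubic degradation, and applies horizontal-flip augmentation
independently per patch. The L1 pixel loss between the network output and
the HR patch is minimized with Adam at an initial learning rate of 1e-4
(no decay schedule). After every epoch the model is scored by PSNR/SSIM on
the evaluation set and the best-PSNR epoch is kept (earliest epoch wins
ties). Loss is computed in unit-float space; evaluation converts to uint8
so PSNR uses the 8-bit dynamic range.

Fine-tuning (transfer learning to a new image domain, e.g. close-up fruit
or seed photographs) is the same loop initialized from a pretrained
checkpoint, with the parent checkpoint recorded as provenance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from plantsr import nn
from plantsr.degradation import DegradationConfig, resize_bicubic_array
from plantsr.image_io import (
    DatasetManifest,
    RasterImage,
    UINT8,
    read_image,
    to_uint8,
    to_unit_float,
)
from plantsr.metrics import MetricConfig, psnr as psnr_metric, ssim as ssim_metric
from plantsr.nn import Tensor
from plantsr.plantsr_net import (
    batch_to_image,
    load_checkpoint,
    load_plantsr,
    save_checkpoint,
)

logger = logging.getLogger("plantsr.training")


def default_patch_size(scale: int) -> int:
    """HR patch side: 64 for scales 2 and 4, 63 for scale 3."""
    return 63 if scale == 3 else 64


@dataclass
class TrainConfig:
    scale: int = 2
    batch_size: int = 32
    patch_size: int | None = None  # HR patch side; None → per-scale default
    lr0: float = 1e-4
    batches_per_epoch: int = 100
    epochs: int = 1
    seed: int = 0
    hflip: bool = True
    antialias: bool = True
    log_every: int = 10

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        if self.lr0 < 0:
            raise ValueError("lr0 must be ≥ 0")
        if self.resolved_patch_size % self.scale:
            raise ValueError(
                f"patch_size {self.resolved_patch_size} must be divisible by "
                f"scale {self.scale}"
            )

    @property
    def resolved_patch_size(self) -> int:
        return self.patch_size if self.patch_size else default_patch_size(self.scale)


@dataclass
class CheckpointRecord:
    epoch: int
    test_psnr: float
    test_ssim: float
    weights_path: Path | None = None
    is_best: bool = False
    parent: Path | None = None


class _ImageCache:
    """Loads HR training images once, as unit-float arrays."""

    def __init__(self) -> None:
        self._store: dict[str, np.ndarray] = {}

    def get(self, path: Path) -> np.ndarray:
        key = str(path)
        if key not in self._store:
            img = read_image(path)
            self._store[key] = img.pixels.astype(np.float64) / 255.0
        return self._store[key]


def sample_batch(
    manifest: DatasetManifest,
    cfg: TrainConfig,
    rng: np.random.Generator,
    cache: _ImageCache | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one training batch of (LR, HR) patch pairs.

    Returns float32 arrays of shape (B, 3, ps/s, ps/s) and (B, 3, ps, ps)
    in unit-float range. The stream of batches is a pure function of the
    (seeded) generator state, the manifest, and the config.
    """
    cache = cache or _ImageCache()
    ps = cfg.resolved_patch_size
    s = cfg.scale
    deg = DegradationConfig(scale=s, antialias=cfg.antialias)
    usable: list[np.ndarray] = []
    for entry in manifest.train:
        arr = cache.get(entry.path)
        if arr.shape[0] < ps or arr.shape[1] < ps:
            warnings.warn(
                f"skipping {entry.path}: smaller than patch size {ps}", stacklevel=2
            )
            continue
        usable.append(arr)
    if not usable:
        raise ValueError(f"no training image is at least {ps}×{ps}")
    hr_batch = np.empty((cfg.batch_size, 3, ps, ps), dtype=np.float32)
    lr_batch = np.empty((cfg.batch_size, 3, ps // s, ps // s), dtype=np.float32)
    for b in range(cfg.batch_size):
        arr = usable[int(rng.integers(len(usable)))]
        top = int(rng.integers(arr.shape[0] - ps + 1))
        left = int(rng.integers(arr.shape[1] - ps + 1))
        hr = arr[top : top + ps, left : left + ps]
        if cfg.hflip and rng.random() < 0.5:
            hr = hr[:, ::-1]
        lr = np.clip(resize_bicubic_array(hr, ps // s, ps // s, deg), 0.0, 1.0)
        hr_batch[b] = hr.transpose(2, 0, 1)
        lr_batch[b] = lr.transpose(2, 0, 1)
    return lr_batch, hr_batch


def l1_loss(sr: Tensor | np.ndarray, hr: Tensor | np.ndarray) -> Tensor:
    """Mean absolute pixel difference between SR output and HR target."""
    if not isinstance(sr, Tensor):
        sr = Tensor(sr)
    if not isinstance(hr, Tensor):
        hr = Tensor(hr)
    return nn.l1_mean(sr, hr)


def _prepare_input(lr_batch: np.ndarray, model: nn.Module, ps: int) -> np.ndarray:
    """Pre-upsampling models consume the bicubic-interpolated LR patch."""
    if getattr(model, "upsampling_style", "post") != "pre":
        return lr_batch
    out = np.empty((lr_batch.shape[0], 3, ps, ps), dtype=np.float32)
    for b in range(lr_batch.shape[0]):
        hwc = lr_batch[b].transpose(1, 2, 0).astype(np.float64)
        up = np.clip(resize_bicubic_array(hwc, ps, ps), 0.0, 1.0)
        out[b] = up.transpose(2, 0, 1)
    return out


def super_resolve_image(model: nn.Module, lr: RasterImage) -> RasterImage:
    """Run a model on one LR image, handling pre/post-upsampling styles."""
    lr_f = to_unit_float(lr) if lr.value_range == UINT8 else lr
    scale = getattr(model, "scale", 1)
    arr = lr_f.pixels
    if getattr(model, "upsampling_style", "post") == "pre":
        raise ValueError(
            "pre-upsampling models need the target size; use evaluate_model"
        )
    x = Tensor(arr.transpose(2, 0, 1)[None].astype(np.float32))
    return batch_to_image(model(x).data)


def evaluate_model(
    model: nn.Module,
    eval_images: list[RasterImage | Path | str],
    scale: int,
    antialias: bool = True,
    metric_cfg: MetricConfig | None = None,
) -> dict:
    """PSNR/SSIM of a model against HR images degraded at ``scale``.

    Each HR image is cropped to a multiple of the scale, degraded to LR,
    super-resolved, converted to uint8, and scored against the HR crop.
    """
    from plantsr.degradation import make_lr_hr_pair

    metric_cfg = metric_cfg or MetricConfig()
    deg = DegradationConfig(scale=scale, antialias=antialias)
    rows = []
    for item in eval_images:
        hr = item if isinstance(item, RasterImage) else read_image(item)
        lr, hr_c = make_lr_hr_pair(hr, deg)
        lr_f = to_unit_float(lr)
        if getattr(model, "upsampling_style", "post") == "pre":
            up = np.clip(
                resize_bicubic_array(lr_f.pixels, hr_c.height, hr_c.width), 0.0, 1.0
            )
            x = Tensor(up.transpose(2, 0, 1)[None].astype(np.float32))
        else:
            x = Tensor(lr_f.pixels.transpose(2, 0, 1)[None].astype(np.float32))
        sr = to_uint8(batch_to_image(model(x).data))
        rows.append(
            {
                "image_id": getattr(item, "name", str(len(rows))),
                "psnr": psnr_metric(sr, hr_c, metric_cfg),
                "ssim": ssim_metric(sr, hr_c, metric_cfg),
            }
        )
    return {
        "psnr": float(np.mean([r["psnr"] for r in rows])),
        "ssim": float(np.mean([r["ssim"] for r in rows])),
        "rows": rows,
    }


def bicubic_baseline(
    eval_images: list[RasterImage | Path | str],
    scale: int,
    antialias: bool = True,
    metric_cfg: MetricConfig | None = None,
) -> dict:
    """PSNR/SSIM of plain bicubic upscaling on the same degraded inputs."""
    from plantsr.degradation import make_lr_hr_pair, resize_bicubic

    metric_cfg = metric_cfg or MetricConfig()
    deg = DegradationConfig(scale=scale, antialias=antialias)
    rows = []
    for item in eval_images:
        hr = item if isinstance(item, RasterImage) else read_image(item)
        lr, hr_c = make_lr_hr_pair(hr, deg)
        up = resize_bicubic(lr, hr_c.height, hr_c.width)
        rows.append(
            {
                "image_id": str(len(rows)),
                "psnr": psnr_metric(up, hr_c, metric_cfg),
                "ssim": ssim_metric(up, hr_c, metric_cfg),
            }
        )
    return {
        "psnr": float(np.mean([r["psnr"] for r in rows])),
        "ssim": float(np.mean([r["ssim"] for r in rows])),
        "rows": rows,
    }


def train(
    model: nn.Module,
    manifest: DatasetManifest,
    cfg: TrainConfig,
    eval_set: list[RasterImage | Path | str] | None = None,
    out_dir: str | Path | None = None,
    parent: Path | None = None,
) -> tuple[dict, CheckpointRecord]:
    """Run the Adam/L1 training loop and return (history, best checkpoint).

    ``history["loss"]`` holds one entry per optimization step and
    ``history["eval"]`` one (psnr, ssim) entry per epoch. Checkpoints are
    written under ``out_dir`` (if given) as ``epoch_XXX.npz`` plus
    ``best.npz``.
    """
    if eval_set is None:
        eval_set = [read_image(e.path) for e in manifest.test]
    if not eval_set:
        raise ValueError("evaluation set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    cache = _ImageCache()
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr0)
    history: dict = {"loss": [], "eval": []}
    records: list[CheckpointRecord] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    step = 0
    for epoch in range(cfg.epochs):
        for _ in range(cfg.batches_per_epoch):
            lr_batch, hr_batch = sample_batch(manifest, cfg, rng, cache)
            x = _prepare_input(lr_batch, model, cfg.resolved_patch_size)
            out = model(Tensor(x))
            loss = l1_loss(out, hr_batch)
            val = float(loss.data)
            if not math.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss ({val}) at epoch {epoch}, step {step}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            history["loss"].append(val)
            if step % cfg.log_every == 0:
                logger.info("epoch %d step %d loss %.5f", epoch, step, val)
            step += 1
        scores = evaluate_model(model, eval_set, cfg.scale, cfg.antialias)
        history["eval"].append({"epoch": epoch, **{k: scores[k] for k in ("psnr", "ssim")}})
        logger.info(
            "epoch %d eval psnr %.3f dB ssim %.4f", epoch, scores["psnr"], scores["ssim"]
        )
        weights_path = None
        if out_dir is not None:
            weights_path = out_dir / f"epoch_{epoch:03d}.npz"
            save_checkpoint(model, weights_path, extra={"epoch": epoch})
        records.append(
            CheckpointRecord(
                epoch=epoch,
                test_psnr=scores["psnr"],
                test_ssim=scores["ssim"],
                weights_path=weights_path,
                parent=parent,
            )
        )
    best = select_best(records)
    if out_dir is not None:
        if best.weights_path is not None:
            state, _ = load_checkpoint(best.weights_path)
            model.load_state_dict(state)
        best_path = out_dir / "best.npz"
        save_checkpoint(
            model,
            best_path,
            extra={"epoch": best.epoch, "parent": str(parent) if parent else None},
        )
        best.weights_path = best_path
        _write_metrics_csv(out_dir / "metrics.csv", records)
    history["records"] = records
    history["model"] = model
    return history, best


def select_best(records: list[CheckpointRecord]) -> CheckpointRecord:
    """Mark and return the argmax-PSNR record; ties go to the earliest epoch."""
    if not records:
        raise ValueError("no checkpoint records")
    best = max(records, key=lambda r: (r.test_psnr, -r.epoch))
    for r in records:
        r.is_best = r is best
    return best


def _write_metrics_csv(path: Path, records: list[CheckpointRecord]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "test_psnr", "test_ssim", "is_best"])
        for r in records:
            writer.writerow([r.epoch, f"{r.test_psnr:.4f}", f"{r.test_ssim:.6f}", int(r.is_best)])


def fine_tune(
    pretrained: str | Path,
    new_manifest: DatasetManifest,
    cfg: TrainConfig,
    eval_set: list[RasterImage | Path | str] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, CheckpointRecord]:
    """Continue training a pretrained PlantSR checkpoint on a new domain.

    The checkpoint's scale must match ``cfg.scale``; the parent checkpoint
    path is recorded on every resulting record (provenance).
    """
    pretrained = Path(pretrained)
    model = load_plantsr(pretrained)
    if model.scale != cfg.scale:
        raise ValueError(
            f"checkpoint scale {model.scale} does not match config scale {cfg.scale}"
        )
    return train(
        model, new_manifest, cfg, eval_set=eval_set, out_dir=out_dir, parent=pretrained
    )
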