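"""Self-contained benchmark experiments runnable on one CPU in minutes.

These drive the package end to end on synthetic data: the overfit smoke
experiment checks that a small PlantSR trained briefly on a handful of
textured images surpasses the bicubic baseline on those same images — the
minimal demonstration that the training loop optimizes the right objective
and that super-resolution has something to add over classical
interpolation.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

from plantsr.image_io import read_image
from plantsr.plantsr_net import PlantSRConfig, build_plantsr
from plantsr.synthetic_data import gen_sr_dataset
from plantsr.training import TrainConfig, bicubic_baseline, evaluate_model, train

# the smoke-test network: small enough to train on CPU, deep enough to
# exercise every architectural element (both RG stacks, SE attention, head)
SMOKE_CONFIG = PlantSRConfig(scale=2, channels=16, m=1, n=2, se_reduction=4)


def overfit_smoke_experiment(
    seed: int = 0,
    n_images: int = 8,
    image_size: int = 96,
    steps: int = 200,
    batch_size: int = 32,
    lr0: float = 1e-4,
    workdir: str | Path | None = None,
) -> dict:
    """Train a tiny PlantSR ×2 briefly and score it against bicubic.

    Generates ``n_images`` synthetic HR images, runs ``steps`` Adam steps of
    patch training on them, and evaluates PSNR/SSIM of the trained model and
    of bicubic upscaling on those same images (an overfitting check, not a
    generalization claim). Returns the scores plus the loss history.
    """
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    root = Path(ctx.name) if ctx else Path(workdir)
    try:
        manifest = gen_sr_dataset(
            root / "data", n_train=n_images, n_test=2, size=image_size, seed=seed
        )
        eval_images = [read_image(e.path) for e in manifest.train]
        bic = bicubic_baseline(eval_images, scale=SMOKE_CONFIG.scale)
        net = build_plantsr(SMOKE_CONFIG, seed=seed)
        init = evaluate_model(net, eval_images, SMOKE_CONFIG.scale)
        cfg = TrainConfig(
            scale=SMOKE_CONFIG.scale,
            batch_size=batch_size,
            lr0=lr0,
            batches_per_epoch=steps,
            epochs=1,
            seed=seed,
        )
        history, best = train(net, manifest, cfg, eval_set=eval_images)
        return {
            "bicubic_psnr": bic["psnr"],
            "bicubic_ssim": bic["ssim"],
            "init_psnr": init["psnr"],
            "net_psnr": best.test_psnr,
            "net_ssim": best.test_ssim,
            "psnr_gain_over_bicubic": best.test_psnr - bic["psnr"],
            "loss": history["loss"],
            "steps": steps,
            "n_images": n_images,
        }
    finally:
        if ctx:
            ctx.cleanup()
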