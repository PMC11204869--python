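import numpy as np
import pytest

from plantsr.image_io import read_image
from plantsr.plantsr_net import PlantSRConfig, build_plantsr, save_checkpoint
from plantsr.training import (
    CheckpointRecord,
    TrainConfig,
    bicubic_baseline,
    fine_tune,
    l1_loss,
    sample_batch,
    select_best,
    train,
)

TINY = PlantSRConfig(scale=2, channels=8, m=0, n=1, se_reduction=4)


class TestTrainConfig:
    def test_default_patch_sizes_per_scale(self):
        assert TrainConfig(scale=2).resolved_patch_size == 64
        assert TrainConfig(scale=3).resolved_patch_size == 63
        assert TrainConfig(scale=4).resolved_patch_size == 64

    def test_patch_size_must_divide_by_scale(self):
        with pytest.raises(ValueError):
            TrainConfig(scale=2, patch_size=63)


class TestSampleBatch:
    def test_shapes_at_scale_2(self, synth_dataset):
        cfg = TrainConfig(scale=2, batch_size=32)
        rng = np.random.default_rng(0)
        lr, hr = sample_batch(synth_dataset, cfg, rng)
        assert hr.shape == (32, 3, 64, 64)
        assert lr.shape == (32, 3, 32, 32)

    def test_reseeded_stream_is_identical(self, synth_dataset):
        cfg = TrainConfig(scale=2, batch_size=4)
        a1 = sample_batch(synth_dataset, cfg, np.random.default_rng(7))
        a2 = sample_batch(synth_dataset, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_consecutive_batches_differ(self, synth_dataset):
        cfg = TrainConfig(scale=2, batch_size=4)
        rng = np.random.default_rng(0)
        b1 = sample_batch(synth_dataset, cfg, rng)
        b2 = sample_batch(synth_dataset, cfg, rng)
        assert not np.array_equal(b1[1], b2[1])

    def test_patch_values_match_source_without_flip(self, synth_dataset):
        cfg = TrainConfig(scale=2, batch_size=1, patch_size=32, hflip=False)
        rng = np.random.default_rng(3)
        # replicate the sampling arithmetic to locate the drawn patch
        img_idx = np.random.default_rng(3).integers(8)
        lr, hr = sample_batch(synth_dataset, cfg, rng)
        src = read_image(synth_dataset.train[img_idx].path).pixels / 255.0
        probe = hr[0].transpose(1, 2, 0)
        # the patch must appear somewhere in the chosen source image
        found = False
        for top in range(src.shape[0] - 32 + 1):
            for left in range(src.shape[1] - 32 + 1):
                if np.allclose(src[top : top + 32, left : left + 32], probe, atol=1e-6):
                    found = True
                    break
            if found:
                break
        assert found

    def test_all_images_too_small_raises(self, synth_dataset):
        cfg = TrainConfig(scale=2, patch_size=128)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            sample_batch(synth_dataset, cfg, np.random.default_rng(0))


class TestL1Loss:
    def test_identical_batches_zero(self, rng):
        x = rng.random((2, 3, 4, 4)).astype(np.float32)
        assert float(l1_loss(x, x).data) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random((2, 3, 4, 4)).astype(np.float32) * 0.5
        assert float(l1_loss(x + 0.1, x).data) == pytest.approx(0.1, abs=1e-6)

    def test_matches_hand_sum(self, rng):
        x = rng.normal(size=(1, 1, 2, 2)).astype(np.float32)
        assert float(l1_loss(x, np.zeros_like(x)).data) == pytest.approx(
            np.abs(x).mean(), rel=1e-6
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 5, 5)))


class TestTrainLoop:
    def test_history_accounting(self, synth_dataset, tmp_path):
        net = build_plantsr(TINY, seed=0)
        cfg = TrainConfig(scale=2, batch_size=2, patch_size=32, epochs=1,
                          batches_per_epoch=10, seed=0)
        history, best = train(net, synth_dataset, cfg, out_dir=tmp_path / "run")
        assert len(history["loss"]) == 10
        assert len(history["eval"]) == 1
        assert best.is_best
        assert (tmp_path / "run" / "best.npz").exists()
        assert (tmp_path / "run" / "metrics.csv").exists()

    def test_zero_lr_leaves_weights_unchanged(self, synth_dataset):
        net = build_plantsr(TINY, seed=0)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        cfg = TrainConfig(scale=2, batch_size=2, patch_size=32, epochs=1,
                          batches_per_epoch=3, lr0=0.0, seed=0)
        train(net, synth_dataset, cfg)
        after = net.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_best_selection_argmax_with_earliest_tie_break(self):
        recs = [
            CheckpointRecord(0, 20.0, 0.5),
            CheckpointRecord(1, 25.0, 0.6),
            CheckpointRecord(2, 25.0, 0.7),
            CheckpointRecord(3, 24.0, 0.6),
        ]
        best = select_best(recs)
        assert best.epoch == 1
        assert sum(r.is_best for r in recs) == 1


class TestFineTune:
    def test_zero_steps_preserves_weights(self, synth_dataset, tmp_path):
        net = build_plantsr(TINY, seed=0)
        ckpt = tmp_path / "pre.npz"
        save_checkpoint(net, ckpt)
        cfg = TrainConfig(scale=2, batch_size=2, patch_size=32, epochs=1,
                          batches_per_epoch=0, seed=0)
        history, best = fine_tune(ckpt, synth_dataset, cfg)
        tuned = history["model"].state_dict()
        for k, v in net.state_dict().items():
            np.testing.assert_array_equal(tuned[k], v)

    def test_provenance_records_parent(self, synth_dataset, tmp_path):
        net = build_plantsr(TINY, seed=0)
        ckpt = tmp_path / "pre.npz"
        save_checkpoint(net, ckpt)
        cfg = TrainConfig(scale=2, batch_size=2, patch_size=32, epochs=1,
                          batches_per_epoch=1, seed=0)
        _, best = fine_tune(ckpt, synth_dataset, cfg)
        assert best.parent == ckpt

    def test_scale_mismatch_rejected(self, synth_dataset, tmp_path):
        net = build_plantsr(TINY, seed=0)
        ckpt = tmp_path / "pre.npz"
        save_checkpoint(net, ckpt)
        cfg = TrainConfig(scale=3, batch_size=2, patch_size=33, epochs=1,
                          batches_per_epoch=1)
        with pytest.raises(ValueError, match="scale"):
            fine_tune(ckpt, synth_dataset, cfg)

    def test_adapts_to_new_domain(self, synth_dataset, tmp_path):
        """Fine-tuning on a shifted second domain reduces its training loss."""
        net = build_plantsr(TINY, seed=0)
        ckpt = tmp_path / "pre.npz"
        save_checkpoint(net, ckpt)
        cfg = TrainConfig(scale=2, batch_size=8, patch_size=32, epochs=1,
                          batches_per_epoch=30, seed=1)
        history, _ = fine_tune(ckpt, synth_dataset, cfg)
        losses = history["loss"]
        assert np.median(losses[-10:]) < np.median(losses[:10])


class TestBicubicBaseline:
    def test_reasonable_range_on_synthetic_images(self, synth_dataset):
        imgs = [read_image(e.path) for e in synth_dataset.test]
        scores = bicubic_baseline(imgs, scale=2)
        assert 15.0 < scores["psnr"] < 60.0
        assert 0.3 < scores["ssim"] <= 1.0
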