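import numpy as np
import pytest

from plantsr.degradation import (
    DegradationConfig,
    cubic_weight,
    make_lr_hr_pair,
    resize_bicubic,
    resize_bicubic_array,
)
from plantsr.image_io import RasterImage


def oracle_resize(arr, out_h, out_w, a=-0.5, antialias=True):
    """Direct dense 2-D kernel-summation resize (independent of the
    separable implementation): for every output pixel, loop over all input
    pixels, accumulate clamped-index kernel products, and normalize."""
    in_h, in_w = arr.shape[:2]

    def axis_weights(in_size, out_size, i):
        zoom = out_size / in_size
        ks = zoom if (antialias and zoom < 1) else 1.0
        u = (i + 0.5) / zoom - 0.5
        js = np.arange(-6, in_size + 6)
        w = np.array([cubic_weight((u - j) * ks, a) for j in js])
        return js, w

    out = np.zeros((out_h, out_w) + arr.shape[2:])
    for i in range(out_h):
        js_y, wy = axis_weights(in_h, out_h, i)
        for j in range(out_w):
            js_x, wx = axis_weights(in_w, out_w, j)
            acc = 0.0
            norm = 0.0
            for jy, vy in zip(js_y, wy):
                if vy == 0:
                    continue
                cy = min(max(jy, 0), in_h - 1)
                for jx, vx in zip(js_x, wx):
                    if vx == 0:
                        continue
                    cx = min(max(jx, 0), in_w - 1)
                    acc = acc + vy * vx * arr[cy, cx]
                    norm += vy * vx
            out[i, j] = acc / norm
    return out


class TestCubicWeight:
    def test_center_is_one(self):
        assert cubic_weight(0.0) == 1.0

    @pytest.mark.parametrize("t", [1.0, 2.0, -1.0, -2.0, 2.5])
    def test_knots_and_tail_are_zero(self, t):
        assert cubic_weight(t) == pytest.approx(0.0, abs=1e-15)

    def test_half_offset_closed_form(self):
        # (a+2)/8 − (a+3)/4 + 1 with a=−0.5 → 0.5625
        assert cubic_weight(0.5) == pytest.approx(0.5625, abs=1e-15)

    def test_kernel_is_even(self):
        t = np.linspace(0, 2.2, 23)
        np.testing.assert_allclose(cubic_weight(t), cubic_weight(-t), atol=0)

    def test_integer_shifts_partition_unity(self):
        # interpolation weights at any fractional phase sum to 1
        for phase in np.linspace(0, 1, 17):
            w = sum(cubic_weight(phase - j) for j in range(-2, 3))
            assert w == pytest.approx(1.0, abs=1e-12)


class TestResizeBicubic:
    def test_constant_image_stays_constant(self):
        img = RasterImage(np.full((7, 9, 3), 100, dtype=np.uint8))
        out = resize_bicubic(img, 13, 5)
        assert (out.pixels == 100).all()

    def test_identity_resize(self, random_uint8_image):
        out = resize_bicubic(random_uint8_image, 24, 17)
        np.testing.assert_array_equal(out.pixels, random_uint8_image.pixels)

    def test_zero_size_output_raises(self, random_uint8_image):
        with pytest.raises(ValueError):
            resize_bicubic(random_uint8_image, 0, 5)

    @pytest.mark.parametrize(
        "in_shape,out_shape",
        [((5, 5), (13, 13)), ((8, 8), (4, 4)), ((6, 9), (14, 5))],
    )
    def test_matches_dense_summation_oracle(self, rng, in_shape, out_shape):
        arr = rng.random(in_shape)
        got = resize_bicubic_array(arr, *out_shape)
        want = oracle_resize(arr, *out_shape)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_matches_oracle_without_antialias(self, rng):
        arr = rng.random((8, 8))
        cfg = DegradationConfig(scale=2, antialias=False)
        got = resize_bicubic_array(arr, 4, 4, cfg)
        want = oracle_resize(arr, 4, 4, antialias=False)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_interior_matches_pillow_convention(self, rng):
        # Pillow implements the same center-aligned antialiased Keys resize;
        # conventions differ only at the replicated border
        from PIL import Image

        arr = rng.random((32, 40)).astype(np.float32)
        im = Image.fromarray(arr, mode="F")
        for out_size in [(16, 20), (64, 80)]:
            theirs = np.asarray(im.resize(out_size[::-1], Image.BICUBIC))
            ours = resize_bicubic_array(arr.astype(np.float64), *out_size)
            m = 6
            np.testing.assert_allclose(
                ours[m:-m, m:-m], theirs[m:-m, m:-m], atol=1e-6
            )

    def test_low_frequency_survives_round_trip_checkerboard_does_not(self):
        yy, xx = np.mgrid[0:32, 0:32]
        smooth = 0.5 + 0.3 * np.sin(2 * np.pi * yy / 32) * np.cos(2 * np.pi * xx / 32)
        checker = ((yy + xx) % 2).astype(np.float64)
        cfg = DegradationConfig(scale=2)
        for arr, tol, should_recover in [(smooth, 0.02, True), (checker, 0.02, False)]:
            lr = resize_bicubic_array(arr, 16, 16, cfg)
            back = resize_bicubic_array(lr, 32, 32, cfg)
            err = np.abs(back - arr)[4:-4, 4:-4].max()
            assert (err < tol) == should_recover


class TestMakeLrHrPair:
    def test_crop_to_multiple_of_scale(self):
        hr = RasterImage(np.zeros((65, 65, 3), dtype=np.uint8))
        lr, hr_c = make_lr_hr_pair(hr, DegradationConfig(scale=2))
        assert hr_c.shape[:2] == (64, 64)
        assert lr.shape[:2] == (32, 32)

    def test_63px_input_at_scale_3(self):
        hr = RasterImage(np.zeros((63, 63, 3), dtype=np.uint8))
        lr, hr_c = make_lr_hr_pair(hr, DegradationConfig(scale=3))
        assert lr.shape[:2] == (21, 21)

    def test_constant_hr_gives_constant_lr(self):
        hr = RasterImage(np.full((12, 12, 3), 77, dtype=np.uint8))
        lr, _ = make_lr_hr_pair(hr, DegradationConfig(scale=3))
        assert (lr.pixels == 77).all()

    def test_deterministic(self, random_uint8_image):
        cfg = DegradationConfig(scale=4)
        a1, b1 = make_lr_hr_pair(random_uint8_image, cfg)
        a2, b2 = make_lr_hr_pair(random_uint8_image, cfg)
        np.testing.assert_array_equal(a1.pixels, a2.pixels)
        np.testing.assert_array_equal(b1.pixels, b2.pixels)

    def test_too_small_image_raises(self):
        hr = RasterImage(np.zeros((2, 2, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            make_lr_hr_pair(hr, DegradationConfig(scale=3))
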