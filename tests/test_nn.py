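"""Gradient and behaviour checks for the NumPy autograd engine.

Every operation's backward pass is validated against central finite
differences on small random tensors (float64 copies keep the comparison
meaningful despite the engine's float32 storage).
"""

import numpy as np
import pytest

from plantsr import nn
from plantsr.nn import Tensor
from plantsr.nn.tensor import _conv2d_raw


def finite_diff(f, arr, idx, eps=1e-3):
    ap = arr.copy()
    ap[idx] += eps
    am = arr.copy()
    am[idx] -= eps
    return (f(ap) - f(am)) / (2 * eps)


def check_grad_wrt(f_tensor, f_plain, arr, n_probes, rng, tol=2e-3):
    """Compare autograd gradient of a scalar loss with finite differences."""
    x = Tensor(arr.astype(np.float32), requires_grad=True)
    loss = f_tensor(x)
    loss.backward()
    for _ in range(n_probes):
        idx = tuple(rng.integers(s) for s in arr.shape)
        fd = finite_diff(f_plain, arr.astype(np.float64), idx)
        assert x.grad[idx] == pytest.approx(fd, abs=tol), f"at index {idx}"


class TestElementwiseGrads:
    def test_relu_sigmoid_chain(self, rng):
        arr = rng.normal(size=(2, 3, 4, 4))

        def f_tensor(x):
            out = nn.sigmoid(nn.relu(x))
            return nn.l1_mean(out, Tensor(np.zeros_like(out.data)))

        def f_plain(a):
            v = 1 / (1 + np.exp(-np.maximum(a, 0)))
            return np.abs(v).mean()

        check_grad_wrt(f_tensor, f_plain, arr, 6, rng)

    def test_add_mul_broadcasting(self, rng):
        a = rng.normal(size=(2, 3, 1, 1))
        b = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        ta = Tensor(a.astype(np.float32), requires_grad=True)
        out = nn.mul(nn.add(ta, Tensor(b)), Tensor(b))
        loss = nn.l1_mean(out, Tensor(np.zeros_like(out.data)))
        loss.backward()
        assert ta.grad.shape == a.shape

        def f_plain(av):
            return np.abs((av + b) * b).mean()

        idx = (1, 2, 0, 0)
        fd = finite_diff(f_plain, a, idx)
        assert ta.grad[idx] == pytest.approx(fd, abs=2e-3)


class TestConvGrads:
    def test_conv_input_weight_bias_grads(self, rng):
        x = rng.normal(size=(2, 2, 5, 5))
        w = rng.normal(size=(3, 2, 3, 3)) * 0.5
        b = rng.normal(size=(3,))
        tw = Tensor(w.astype(np.float32), requires_grad=True)
        tb = Tensor(b.astype(np.float32), requires_grad=True)
        tx = Tensor(x.astype(np.float32), requires_grad=True)
        out = nn.conv2d(tx, tw, tb, pad=1)
        loss = nn.l1_mean(out, Tensor(np.zeros_like(out.data)))
        loss.backward()

        def loss_of(xv, wv, bv):
            o = _conv2d_raw(xv, wv, 1) + bv[None, :, None, None]
            return np.abs(o).mean()

        for t, arr, plain in [
            (tx, x, lambda v: loss_of(v, w, b)),
            (tw, w, lambda v: loss_of(x, v, b)),
            (tb, b, lambda v: loss_of(x, w, v)),
        ]:
            for _ in range(4):
                idx = tuple(rng.integers(s) for s in arr.shape)
                fd = finite_diff(plain, arr, idx)
                assert t.grad[idx] == pytest.approx(fd, abs=3e-3), idx

    def test_conv_output_values_against_direct_sum(self, rng):
        x = rng.normal(size=(1, 1, 4, 4))
        w = rng.normal(size=(1, 1, 3, 3))
        out = _conv2d_raw(x, w, 1)
        # hand-evaluate one interior output pixel
        want = (x[0, 0, 0:3, 1:4] * w[0, 0]).sum()
        assert out[0, 0, 1, 2] == pytest.approx(want, rel=1e-6)


class TestStructuralOps:
    def test_pixel_shuffle_rearrangement(self):
        x = np.arange(16).reshape(1, 4, 2, 2).astype(np.float32)
        out = nn.pixel_shuffle(Tensor(x), 2)
        assert out.data.shape == (1, 1, 4, 4)
        # output pixel (0,0) block comes from channels [0..3] at (0,0)
        np.testing.assert_array_equal(
            out.data[0, 0, :2, :2], [[0, 4], [8, 12]]
        )

    def test_pixel_shuffle_round_trip_grad(self, rng):
        arr = rng.normal(size=(1, 9, 2, 2))

        def f_tensor(x):
            return nn.l1_mean(
                nn.pixel_shuffle(x, 3), Tensor(np.zeros((1, 1, 6, 6), np.float32))
            )

        def f_plain(a):
            o = a.reshape(1, 1, 3, 3, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(1, 1, 6, 6)
            return np.abs(o).mean()

        check_grad_wrt(f_tensor, f_plain, arr, 5, rng)

    def test_global_avg_pool_and_channel_scale(self, rng):
        arr = rng.normal(size=(2, 4, 3, 3))

        def f_tensor(x):
            s = nn.sigmoid(nn.global_avg_pool(x))
            return nn.l1_mean(
                nn.channel_scale(x, s), Tensor(np.zeros_like(x.data))
            )

        def f_plain(a):
            s = 1 / (1 + np.exp(-a.mean(axis=(2, 3))))
            return np.abs(a * s[:, :, None, None]).mean()

        check_grad_wrt(f_tensor, f_plain, arr, 6, rng)


class TestReplicatePad:
    def test_forward_matches_numpy_edge_pad(self, rng):
        arr = rng.normal(size=(1, 2, 3, 4)).astype(np.float32)
        out = nn.replicate_pad(Tensor(arr), 2)
        np.testing.assert_array_equal(
            out.data, np.pad(arr, ((0, 0), (0, 0), (2, 2), (2, 2)), mode="edge")
        )

    def test_gradient_folds_onto_edges(self, rng):
        arr = rng.normal(size=(1, 1, 3, 3))

        def f_tensor(x):
            return nn.l1_mean(
                nn.replicate_pad(x, 1), Tensor(np.zeros((1, 1, 5, 5), np.float32))
            )

        def f_plain(a):
            return np.abs(np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")).mean()

        check_grad_wrt(f_tensor, f_plain, arr, 6, rng)


class TestAdam:
    def test_zero_lr_leaves_parameters_unchanged(self, rng):
        p = Tensor(rng.normal(size=(4,)).astype(np.float32), requires_grad=True)
        before = p.data.copy()
        opt = nn.Adam([p], lr=0.0)
        p.grad = np.ones(4, dtype=np.float32)
        opt.step()
        np.testing.assert_array_equal(p.data, before)

    def test_first_step_magnitude_is_lr(self, rng):
        # with bias correction the first Adam step is ≈ lr·sign(g)
        p = Tensor(np.zeros(3, dtype=np.float32), requires_grad=True)
        opt = nn.Adam([p], lr=1e-2)
        p.grad = np.array([0.5, -2.0, 10.0], dtype=np.float32)
        opt.step()
        np.testing.assert_allclose(p.data, [-1e-2, 1e-2, -1e-2], rtol=1e-4)

    def test_converges_on_quadratic(self):
        p = Tensor(np.array([5.0], dtype=np.float32), requires_grad=True)
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            p.grad = 2 * p.data
            opt.step()
        assert abs(float(p.data[0])) < 1e-2


class TestModuleSystem:
    def test_state_dict_round_trip(self, tiny_plantsr, rng):
        state = tiny_plantsr.state_dict()
        clone_state = {k: v + 1.0 for k, v in state.items()}
        tiny_plantsr.load_state_dict(clone_state)
        try:
            assert all(
                np.allclose(tiny_plantsr.state_dict()[k], state[k] + 1.0)
                for k in state
            )
        finally:
            tiny_plantsr.load_state_dict(state)

    def test_load_rejects_mismatched_keys(self, tiny_plantsr):
        state = tiny_plantsr.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError):
            tiny_plantsr.load_state_dict(state)
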