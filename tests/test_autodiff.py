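import numpy as np
import pytest

from conftest import check_grad
from lvquant.autodiff import (Tensor, batch_norm_train, concatenate, conv3d,
                              conv_transpose3d, leaky_relu, maxpool3d_hw2,
                              no_grad, normalize_affine, relu, sigmoid,
                              softmax)


class TestElementwise:
    def test_add_mul_broadcast_grads(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((1, 4))
        check_grad(lambda x, y: x * y + x, a, b, wrt=0)
        check_grad(lambda x, y: x * y + y, a, b, wrt=1)

    def test_matmul_grads(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((4, 5))
        check_grad(lambda x, y: x @ y, a, b, wrt=0)
        check_grad(lambda x, y: x @ y, a, b, wrt=1)

    def test_exp_log_grads(self, rng):
        a = np.abs(rng.standard_normal((4, 3))) + 0.5
        check_grad(lambda x: x.exp(), a)
        check_grad(lambda x: x.log(), a)

    def test_relu_and_leaky(self, rng):
        a = rng.standard_normal((5, 5)) + 0.01   # keep away from the kink
        check_grad(relu, a)
        check_grad(lambda x: leaky_relu(x, 0.2), a)
        x = Tensor(np.array([-2.0, 3.0]), requires_grad=True)
        assert np.allclose(leaky_relu(x, 0.25).data, [-0.5, 3.0])

    def test_sigmoid_values_and_stability(self):
        x = Tensor(np.array([0.0, 800.0, -800.0]))
        s = sigmoid(x).data
        assert np.allclose(s, [0.5, 1.0, 0.0])
        assert np.isfinite(s).all()

    def test_sigmoid_grad(self, rng):
        check_grad(sigmoid, rng.standard_normal((3, 3)))

    def test_softmax_rows_sum_to_one_and_grad(self, rng):
        a = rng.standard_normal((4, 6))
        p = softmax(Tensor(a), axis=-1).data
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)
        check_grad(lambda x: softmax(x, axis=-1) * Tensor(np.arange(6.0)), a)

    def test_clip_sum_mean_reshape_transpose_grads(self, rng):
        a = rng.standard_normal((2, 3, 4))
        check_grad(lambda x: x.clip(-0.5, 0.5) * 2.0, a)
        check_grad(lambda x: x.sum(axis=1), a)
        check_grad(lambda x: x.mean(axis=(0, 2)), a)
        check_grad(lambda x: x.reshape(6, 4).transpose(1, 0) * 3.0, a)

    def test_getitem_grad(self, rng):
        a = rng.standard_normal((4, 5))
        check_grad(lambda x: x[1:3, ::2] * 2.0, a)

    def test_concatenate_grads(self, rng):
        a, b = rng.standard_normal((2, 3)), rng.standard_normal((4, 3))
        check_grad(lambda x, y: concatenate([x, y], axis=0), a, b, wrt=0)
        check_grad(lambda x, y: concatenate([x, y], axis=0), a, b, wrt=1)


def conv3d_oracle(x, w, b, stride, padding):
    """Direct 6-loop convolution for small shapes."""
    N, C, D, H, W = x.shape
    Co, _, kd, kh, kw = w.shape
    sd, sh, sw = stride
    pd, ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    out = np.zeros((N, Co, Do, Ho, Wo))
    for n in range(N):
        for o in range(Co):
            for d in range(Do):
                for i in range(Ho):
                    for j in range(Wo):
                        patch = xp[n, :, d * sd:d * sd + kd,
                                   i * sh:i * sh + kh, j * sw:j * sw + kw]
                        out[n, o, d, i, j] = (patch * w[o]).sum()
            if b is not None:
                out[n, o] += b[o]
    return out


class TestConv:
    @pytest.mark.parametrize("stride,padding", [
        ((1, 1, 1), (0, 0, 0)),
        ((1, 1, 1), (1, 1, 1)),
        ((1, 2, 2), (0, 1, 1)),
        ((2, 2, 2), (1, 0, 1)),
    ])
    def test_conv3d_matches_oracle(self, rng, stride, padding):
        x = rng.standard_normal((2, 3, 4, 6, 6))
        w = rng.standard_normal((4, 3, 3, 3, 3))
        b = rng.standard_normal(4)
        got = conv3d(Tensor(x), Tensor(w), Tensor(b),
                     stride=stride, padding=padding).data
        want = conv3d_oracle(x, w, b, stride, padding)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_conv3d_grads(self, rng):
        x = rng.standard_normal((1, 2, 3, 4, 4))
        w = rng.standard_normal((3, 2, 3, 3, 3))
        b = rng.standard_normal(3)
        op = lambda x_, w_, b_: conv3d(x_, w_, b_, stride=(1, 1, 1),
                                       padding=(1, 1, 1))
        check_grad(op, x, w, b, wrt=0)
        check_grad(op, x, w, b, wrt=1)
        check_grad(op, x, w, b, wrt=2)

    def test_conv3d_channel_mismatch(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 3, 4, 4)))
        w = Tensor(rng.standard_normal((3, 5, 1, 1, 1)))
        with pytest.raises(ValueError, match="channel"):
            conv3d(x, w)

    def test_conv_transpose_upsamples_and_grads(self, rng):
        x = rng.standard_normal((1, 3, 2, 3, 3))
        w = rng.standard_normal((3, 2, 1, 2, 2))
        out = conv_transpose3d(Tensor(x), Tensor(w), stride=(1, 2, 2))
        assert out.shape == (1, 2, 2, 6, 6)
        check_grad(lambda a, b: conv_transpose3d(a, b, stride=(1, 2, 2)),
                   x, w, wrt=0)
        check_grad(lambda a, b: conv_transpose3d(a, b, stride=(1, 2, 2)),
                   x, w, wrt=1)

    def test_maxpool_values_and_grads(self, rng):
        x = rng.standard_normal((2, 2, 3, 4, 6))
        out = maxpool3d_hw2(Tensor(x))
        assert out.shape == (2, 2, 3, 2, 3)
        want = x.reshape(2, 2, 3, 2, 2, 3, 2).max(axis=(4, 6))
        np.testing.assert_allclose(out.data, want)
        check_grad(maxpool3d_hw2, x)


class TestNormalization:
    def test_group_norm_matches_manual(self, rng):
        x = rng.standard_normal((2, 4, 3, 5, 5))
        gamma, beta = np.ones(4), np.zeros(4)
        y, _, _ = normalize_affine(Tensor(x), Tensor(gamma), Tensor(beta),
                                   group_shape=(2, 2, -1),
                                   affine_shape=(1, 4, 1, 1, 1))
        xg = x.reshape(2, 2, -1)
        want = ((xg - xg.mean(-1, keepdims=True))
                / np.sqrt(xg.var(-1, keepdims=True) + 1e-5)).reshape(x.shape)
        np.testing.assert_allclose(y.data, want, atol=1e-10)

    def test_normalize_affine_grads(self, rng):
        x = rng.standard_normal((2, 4, 2, 3, 3))
        gamma = rng.standard_normal(4) + 1.0
        beta = rng.standard_normal(4)
        op = lambda a, g, b: normalize_affine(
            a, g, b, group_shape=(2, 2, -1), affine_shape=(1, 4, 1, 1, 1))[0]
        check_grad(op, x, gamma, beta, wrt=0, atol=1e-4)
        check_grad(op, x, gamma, beta, wrt=1)
        check_grad(op, x, gamma, beta, wrt=2)

    def test_batch_norm_train_grads_and_stats(self, rng):
        x = rng.standard_normal((3, 2, 2, 4, 4))
        gamma = rng.standard_normal(2) + 1.0
        beta = rng.standard_normal(2)
        y, mu, var = batch_norm_train(Tensor(x), Tensor(gamma), Tensor(beta))
        np.testing.assert_allclose(mu, x.mean(axis=(0, 2, 3, 4)), atol=1e-12)
        np.testing.assert_allclose(var, x.var(axis=(0, 2, 3, 4)), atol=1e-12)
        weight = Tensor(rng.standard_normal(y.shape))
        op = lambda a, g, b: batch_norm_train(a, g, b)[0] * weight
        check_grad(op, x, gamma, beta, wrt=0, atol=1e-4)


class TestTape:
    def test_no_grad_builds_no_tape(self, rng):
        x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
        with no_grad():
            y = (x * 2.0).sum()
        assert y._prev == ()
        y2 = (x * 2.0).sum()
        assert y2._prev != ()

    def test_grad_accumulates_over_reuse(self):
        x = Tensor(np.array([3.0]), requires_grad=True)
        (x * x).sum().backward()
        np.testing.assert_allclose(x.grad, [6.0])

    def test_detach_cuts_the_graph(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = (x * 3.0).detach() * x
        y.sum().backward()
        np.testing.assert_allclose(x.grad, [6.0])  # only the outer factor
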