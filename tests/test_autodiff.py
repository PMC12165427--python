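"""Gradient checks for the autodiff engine against central finite differences,
plus structural checks of conv3d against scipy.ndimage."""

import numpy as np
import pytest
from scipy import ndimage

from glioseg3d.autodiff import (
    Parameter,
    Tensor,
    concat,
    conv3d,
    dropout,
    instance_norm,
    linear,
    no_grad,
    resize_trilinear,
    softmax,
)


def numeric_grad(fn, x, eps=1e-6):
    """Central finite differences of a scalar fn wrt array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        f_plus = fn(x)
        x[idx] = orig - eps
        f_minus = fn(x)
        x[idx] = orig
        g[idx] = (f_plus - f_minus) / (2 * eps)
        it.iternext()
    return g


def check_grad(op, x_arr, atol=1e-6, rtol=1e-4):
    x = Tensor(x_arr.copy(), requires_grad=True)
    out = op(x)
    out.backward()
    num = numeric_grad(lambda arr: op(Tensor(arr)).item(), x_arr.copy())
    np.testing.assert_allclose(x.grad, num, atol=atol, rtol=rtol)


@pytest.fixture
def rng64():
    return np.random.default_rng(3)


class TestElementwiseGrads:
    @pytest.mark.parametrize(
        "op",
        [
            lambda x: (x * 3.0 + 1.0).sum(),
            lambda x: (x * x).sum(),
            lambda x: (x / (x + 2.0)).sum(),
            lambda x: (x ** 3.0).sum(),
            lambda x: (x + 1.5).log().sum(),
            lambda x: x.exp().sum(),
            lambda x: x.sigmoid().sum(),
            lambda x: x.leaky_relu(0.01).sum(),
            lambda x: x.relu().sum(),
            lambda x: (x.mean(axis=0) * np.arange(4.0)).sum(),
        ],
        ids=["affine", "square", "div", "pow", "log", "exp", "sigmoid",
             "leaky_relu", "relu", "mean_axis"],
    )
    def test_matches_finite_differences(self, op, rng64):
        x = rng64.uniform(0.2, 1.0, size=(3, 4))
        check_grad(op, x)

    def test_clip_gradient_masked(self):
        x = Tensor(np.array([-2.0, 0.5, 2.0]), requires_grad=True)
        x.clip(0.0, 1.0).sum().backward()
        np.testing.assert_array_equal(x.grad, [0.0, 1.0, 0.0])

    def test_broadcasting_backward(self, rng64):
        a = Tensor(rng64.standard_normal((3, 1)), requires_grad=True)
        b = Tensor(rng64.standard_normal((1, 4)), requires_grad=True)
        (a * b).sum().backward()
        assert a.grad.shape == (3, 1)
        assert b.grad.shape == (1, 4)

    def test_grad_accumulates_over_reuse(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = x * 3.0 + x * 4.0
        y.backward()
        np.testing.assert_allclose(x.grad, [7.0])


class TestSoftmax:
    def test_forward_normalized(self, rng64):
        x = Tensor(rng64.standard_normal((4, 5)))
        s = softmax(x, axis=0)
        np.testing.assert_allclose(s.data.sum(axis=0), 1.0, atol=1e-12)

    def test_gradient(self, rng64):
        x_arr = rng64.standard_normal((3, 4))
        w = rng64.standard_normal((3, 4))
        check_grad(lambda x: (softmax(x, axis=0) * w).sum(), x_arr)


class TestConv3d:
    def test_matches_scipy_correlate(self, rng64):
        x = rng64.standard_normal((2, 6, 7, 5))
        w = rng64.standard_normal((3, 2, 3, 3, 3))
        out = conv3d(Tensor(x), Tensor(w)).data
        ref = np.zeros((3, 6, 7, 5))
        for co in range(3):
            for ci in range(2):
                ref[co] += ndimage.correlate(x[ci], w[co, ci], mode="constant")
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_dilation_matches_scipy(self, rng64):
        x = rng64.standard_normal((1, 8, 8, 8))
        w = rng64.standard_normal((1, 1, 3, 3, 3))
        out = conv3d(Tensor(x), Tensor(w), dilation=2).data
        wk = np.zeros((5, 5, 5))
        wk[::2, ::2, ::2] = w[0, 0]
        ref = ndimage.correlate(x[0], wk, mode="constant")
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_stride_2_subsamples(self, rng64):
        x = rng64.standard_normal((2, 6, 6, 4))
        w = rng64.standard_normal((3, 2, 3, 3, 3))
        out = conv3d(Tensor(x), Tensor(w), stride=2).data
        full = conv3d(Tensor(x), Tensor(w)).data
        np.testing.assert_allclose(out, full[:, ::2, ::2, ::2], atol=1e-10)

    def test_weight_and_input_gradients(self, rng64):
        x_arr = rng64.standard_normal((2, 4, 4, 4))
        w_arr = rng64.standard_normal((2, 2, 3, 3, 3))
        b_arr = rng64.standard_normal(2)
        proj = rng64.standard_normal((2, 4, 4, 4))

        def forward(xa, wa, ba):
            return (conv3d(Tensor(xa), Tensor(wa), Tensor(ba)) * proj).sum().item()

        x = Tensor(x_arr.copy(), requires_grad=True)
        w = Tensor(w_arr.copy(), requires_grad=True)
        b = Tensor(b_arr.copy(), requires_grad=True)
        (conv3d(x, w, b) * proj).sum().backward()
        gx = numeric_grad(lambda a: forward(a, w_arr, b_arr), x_arr.copy())
        gw = numeric_grad(lambda a: forward(x_arr, a, b_arr), w_arr.copy())
        gb = numeric_grad(lambda a: forward(x_arr, w_arr, a), b_arr.copy())
        np.testing.assert_allclose(x.grad, gx, atol=1e-6, rtol=1e-4)
        np.testing.assert_allclose(w.grad, gw, atol=1e-6, rtol=1e-4)
        np.testing.assert_allclose(b.grad, gb, atol=1e-6, rtol=1e-4)

    def test_strided_gradients(self, rng64):
        x_arr = rng64.standard_normal((1, 4, 4, 4))
        w_arr = rng64.standard_normal((2, 1, 3, 3, 3))

        def forward(xa, wa):
            return (conv3d(Tensor(xa), Tensor(wa), stride=2) ** 2.0).sum().item()

        x = Tensor(x_arr.copy(), requires_grad=True)
        w = Tensor(w_arr.copy(), requires_grad=True)
        (conv3d(x, w, stride=2) ** 2.0).sum().backward()
        gx = numeric_grad(lambda a: forward(a, w_arr), x_arr.copy())
        gw = numeric_grad(lambda a: forward(x_arr, a), w_arr.copy())
        np.testing.assert_allclose(x.grad, gx, atol=1e-6, rtol=1e-4)
        np.testing.assert_allclose(w.grad, gw, atol=1e-6, rtol=1e-4)


class TestInstanceNorm:
    def test_normalizes_per_channel(self, rng64):
        x = rng64.standard_normal((3, 4, 4, 4)) * 5 + 2
        gamma = Tensor(np.ones(3))
        beta = Tensor(np.zeros(3))
        out = instance_norm(Tensor(x), gamma, beta).data
        np.testing.assert_allclose(out.mean(axis=(1, 2, 3)), 0.0, atol=1e-7)
        np.testing.assert_allclose(out.std(axis=(1, 2, 3)), 1.0, atol=1e-3)

    def test_gradients(self, rng64):
        x_arr = rng64.standard_normal((2, 3, 3, 3))
        g_arr = rng64.standard_normal(2)
        b_arr = rng64.standard_normal(2)
        proj = rng64.standard_normal((2, 3, 3, 3))

        def forward(xa, ga, ba):
            return (instance_norm(Tensor(xa), Tensor(ga), Tensor(ba)) * proj).sum().item()

        x = Tensor(x_arr.copy(), requires_grad=True)
        gm = Tensor(g_arr.copy(), requires_grad=True)
        bt = Tensor(b_arr.copy(), requires_grad=True)
        (instance_norm(x, gm, bt) * proj).sum().backward()
        np.testing.assert_allclose(
            x.grad, numeric_grad(lambda a: forward(a, g_arr, b_arr), x_arr.copy()),
            atol=1e-5, rtol=1e-3,
        )
        np.testing.assert_allclose(
            gm.grad, numeric_grad(lambda a: forward(x_arr, a, b_arr), g_arr.copy()),
            atol=1e-6, rtol=1e-4,
        )
        np.testing.assert_allclose(
            bt.grad, numeric_grad(lambda a: forward(x_arr, g_arr, a), b_arr.copy()),
            atol=1e-6, rtol=1e-4,
        )


class TestResize:
    def test_identity_resize(self, rng64):
        x = rng64.standard_normal((2, 4, 5, 6))
        out = resize_trilinear(Tensor(x), (4, 5, 6)).data
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_upsample_constant_preserved(self):
        x = np.full((1, 2, 2, 2), 3.5)
        out = resize_trilinear(Tensor(x), (8, 8, 8)).data
        np.testing.assert_allclose(out, 3.5, atol=1e-12)

    def test_adjoint_property(self, rng64):
        # <A x, y> == <x, A^T y> — the backward pass is the exact adjoint
        x_arr = rng64.standard_normal((1, 3, 3, 3))
        y = rng64.standard_normal((1, 6, 6, 6))
        x = Tensor(x_arr, requires_grad=True)
        out = resize_trilinear(x, (6, 6, 6))
        (out * y).sum().backward()
        lhs = float((out.data * y).sum())
        rhs = float((x_arr * x.grad).sum())
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_gradient(self, rng64):
        x_arr = rng64.standard_normal((1, 3, 3, 3))
        w = rng64.standard_normal((1, 5, 5, 5))
        check_grad(lambda x: (resize_trilinear(x, (5, 5, 5)) * w).sum(), x_arr)


class TestMisc:
    def test_concat_backward_splits(self, rng64):
        a = Tensor(rng64.standard_normal((2, 3)), requires_grad=True)
        b = Tensor(rng64.standard_normal((4, 3)), requires_grad=True)
        w = np.arange(18.0).reshape(6, 3)
        (concat([a, b], axis=0) * w).sum().backward()
        np.testing.assert_allclose(a.grad, w[:2])
        np.testing.assert_allclose(b.grad, w[2:])

    def test_linear_gradients(self, rng64):
        x_arr = rng64.standard_normal(5)
        w_arr = rng64.standard_normal((3, 5))
        b_arr = rng64.standard_normal(3)

        def forward(xa, wa, ba):
            return (linear(Tensor(xa), Tensor(wa), Tensor(ba)) ** 2.0).sum().item()

        x = Tensor(x_arr.copy(), requires_grad=True)
        w = Tensor(w_arr.copy(), requires_grad=True)
        b = Tensor(b_arr.copy(), requires_grad=True)
        (linear(x, w, b) ** 2.0).sum().backward()
        np.testing.assert_allclose(
            x.grad, numeric_grad(lambda a: forward(a, w_arr, b_arr), x_arr.copy()),
            atol=1e-6, rtol=1e-4,
        )
        np.testing.assert_allclose(
            w.grad, numeric_grad(lambda a: forward(x_arr, a, b_arr), w_arr.copy()),
            atol=1e-6, rtol=1e-4,
        )

    def test_dropout_eval_identity(self, rng64):
        x = Tensor(rng64.standard_normal((4, 4)))
        out = dropout(x, 0.5, np.random.default_rng(0), training=False)
        assert out is x

    def test_dropout_scaling_unbiased(self):
        x = Tensor(np.ones((100, 100)))
        out = dropout(x, 0.3, np.random.default_rng(0), training=True)
        assert abs(out.data.mean() - 1.0) < 0.02

    def test_no_grad_blocks_taping(self):
        x = Tensor(np.ones(3), requires_grad=True)
        with no_grad():
            y = x * 2.0
        assert not y.requires_grad
        assert y._backward is None

    def test_parameter_is_float32(self):
        p = Parameter(np.zeros((2, 2)))
        assert p.data.dtype == np.float32
        assert p.requires_grad
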