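"""Autodiff engine: analytic gradients vs central differences, optimizer smoke."""

import numpy as np
import pytest

from propseg import nn
from propseg.metrics import cross_entropy


def numerical_gradient(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(build_loss, params, tol=1e-5):
    loss = build_loss()
    loss.backward()
    for name, p in params.items():
        analytic = p.grad.copy()
        numeric = numerical_gradient(lambda: float(build_loss().data), p.data)
        err = np.abs(analytic - numeric).max() / (np.abs(numeric).max() + 1e-12)
        assert err < tol, f"{name}: relative error {err:.2e}"
        p.grad = None


@pytest.fixture
def f64(rng):
    def make(*shape, grad=False):
        t = nn.Tensor(rng.normal(size=shape)) if not grad else \
            nn.Parameter(rng.normal(size=shape))
        return t
    return make


class TestGradients:
    def test_conv2d(self, rng, f64):
        x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(4, 3, 3, 3)))
        b = nn.Parameter(rng.normal(size=4))
        y = rng.integers(0, 2, (2, 4, 6, 6)).astype(float)
        assert_grads_match(lambda: nn.bce_with_logits(nn.conv2d(x, w, b), y),
                           {"x": x, "w": w, "b": b})

    def test_conv_transpose2d(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        w = nn.Parameter(rng.normal(size=(3, 5, 2, 2)))
        b = nn.Parameter(rng.normal(size=5))
        y = rng.integers(0, 2, (2, 5, 8, 8)).astype(float)
        assert_grads_match(
            lambda: nn.bce_with_logits(nn.conv_transpose2d(x, w, b, 2), y),
            {"x": x, "w": w, "b": b})

    def test_pool_upsample_chain(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 8, 8)), requires_grad=True)
        y = rng.integers(0, 2, (2, 3, 8, 8)).astype(float)

        def build():
            h = nn.upsample_nearest(nn.maxpool2d(x), 2)
            g = nn.upsample_nearest(nn.avgpool2d(x, 4), 4)
            return nn.bce_with_logits(nn.add(nn.relu(h), g), y)

        assert_grads_match(build, {"x": x})

    def test_batchnorm_train_and_eval(self, rng):
        bn = nn.BatchNorm2d(3, dtype=np.float64)
        x = nn.Tensor(rng.normal(size=(4, 3, 5, 5)), requires_grad=True)
        y = rng.integers(0, 2, (4, 3, 5, 5)).astype(float)

        def build():
            bn.running_mean[:] = 0.0  # keep stats fixed across finite differences
            bn.running_var[:] = 1.0
            return nn.bce_with_logits(bn(x), y)

        assert_grads_match(build, {"x": x, "gamma": bn.gamma, "beta": bn.beta})
        bn.eval()
        assert_grads_match(build, {"x": x, "gamma": bn.gamma, "beta": bn.beta})

    def test_concat_and_scale(self, rng):
        a = nn.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        b = nn.Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        y = rng.integers(0, 2, (1, 5, 4, 4)).astype(float)
        assert_grads_match(
            lambda: nn.smul(nn.bce_with_logits(nn.concat([a, b]), y), 0.7),
            {"a": a, "b": b})


class TestOps:
    def test_bce_matches_probability_cross_entropy(self, rng):
        z = rng.normal(size=(5, 5))
        y = rng.integers(0, 2, (5, 5)).astype(float)
        p = 1.0 / (1.0 + np.exp(-z))
        assert float(nn.bce_with_logits(nn.Tensor(z), y).data) == pytest.approx(
            cross_entropy(p, y), abs=1e-9)

    def test_maxpool_values(self):
        x = nn.Tensor(np.arange(16.0).reshape(1, 1, 4, 4))
        out = nn.maxpool2d(x).data
        np.testing.assert_array_equal(out[0, 0], [[5, 7], [13, 15]])

    def test_sigmoid_range(self, rng):
        s = nn.sigmoid(nn.Tensor(rng.normal(scale=50, size=100))).data
        assert np.all((s >= 0) & (s <= 1))


class TestAdam:
    def test_loss_decreases_on_quadratic(self, rng):
        target = rng.normal(size=(4, 4))
        p = nn.Parameter(np.zeros((4, 4)))
        opt = nn.Adam([p], lr=0.05)

        def loss_val():
            diff = p.data - target
            p.grad = 2 * diff
            return float((diff ** 2).sum())

        first = loss_val()
        for _ in range(200):
            loss_val()
            opt.step()
        assert loss_val() < 0.01 * first
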