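"""Segmentation net: shape contracts, probability range, ablation equivalence."""

import numpy as np
import pytest

from propseg import nn
from propseg.config import ModelConfig, desk_config
from propseg.context_net import ContextInput
from propseg.model import PropSegModel
from propseg.seg_net import SegNet, binarize

from conftest import tiny_config


class TestShapes:
    @pytest.mark.parametrize("size", [32, 64, 128])
    def test_output_matches_input_size(self, size):
        cfg = ModelConfig(image_size=size, depth=4, channels=(2, 2, 2, 2),
                          kernels=(3, 3, 3, 3)).validate()
        net = SegNet(cfg, np.random.default_rng(0))
        net.eval()
        x = nn.Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
        assert net(x).data.shape == (1, 1, size, size)

    def test_indivisible_size_rejected_at_build(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(image_size=24, depth=4, channels=(2, 2, 2, 2),
                        kernels=(3, 3, 3, 3)).validate()

    def test_wrong_input_size_rejected(self):
        cfg = tiny_config()
        net = SegNet(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            net(nn.Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32)))

    def test_probabilities_in_unit_interval(self, rng):
        model = PropSegModel(tiny_config(seed=9))
        img = rng.normal(size=(32, 32))
        ctx = ContextInput(None, rng.normal(size=(32, 32)), None)
        prob = model.predict_proba(img, ctx)
        assert prob.shape == (32, 32)
        assert np.all((prob >= 0) & (prob <= 1))


class TestAblation:
    def test_disabled_context_equals_zero_context(self, rng):
        """The no-context variant must equal the same net fed zero features."""
        cfg_on = tiny_config(seed=4, context_enabled=True)
        cfg_off = tiny_config(seed=4, context_enabled=False)
        on, off = PropSegModel(cfg_on), PropSegModel(cfg_off)
        on.eval()
        off.eval()
        img = nn.Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        # same seed -> identical seg-net weights; zero pyramid == disabled path
        zero_out = on.seg_net(img, None).data
        off_out, _ = off(img, nn.Tensor(rng.normal(
            size=(1, 3, 32, 32)).astype(np.float32)))
        np.testing.assert_array_equal(off_out.data, zero_out)

    def test_disabled_context_ignores_context_exactly(self, rng):
        model = PropSegModel(tiny_config(seed=4, context_enabled=False))
        model.eval()
        img = rng.normal(size=(32, 32))
        base = model.predict_proba(img, ContextInput(None, None, None))
        for _ in range(5):
            ctx = ContextInput((rng.random((32, 32)) > 0.5).astype(np.uint8),
                               rng.normal(size=(32, 32)),
                               rng.normal(size=(32, 32)))
            np.testing.assert_array_equal(model.predict_proba(img, ctx), base)

    def test_enabled_context_responds_to_context(self, rng):
        model = PropSegModel(tiny_config(seed=4, context_enabled=True))
        model.eval()
        img = rng.normal(size=(32, 32))
        a = model.predict_proba(img, ContextInput(None, None, None))
        b = model.predict_proba(img, ContextInput(
            np.ones((32, 32), dtype=np.uint8), rng.normal(size=(32, 32)), None))
        assert not np.array_equal(a, b)


class TestBinarize:
    def test_all_high_probability(self):
        np.testing.assert_array_equal(binarize(np.full((3, 3), 0.9), 0.5),
                                      np.ones((3, 3), dtype=np.uint8))

    def test_tie_goes_to_background(self):
        np.testing.assert_array_equal(binarize(np.full((3, 3), 0.5), 0.5),
                                      np.zeros((3, 3), dtype=np.uint8))

    def test_matches_elementwise_oracle(self, rng):
        prob = rng.random((17, 17))
        out = binarize(prob, 0.3)
        oracle = np.array([[1 if v > 0.3 else 0 for v in row] for row in prob])
        np.testing.assert_array_equal(out, oracle)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.0)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = PropSegModel(desk_config(seed=8, channels=(2, 3, 4)))
        model.eval()
        img = rng.normal(size=(64, 64))
        ctx = ContextInput(None, None, rng.normal(size=(64, 64)))
        before = model.predict_proba(img, ctx)
        model.save(tmp_path / "m.npz")
        back = PropSegModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict_proba(img, ctx), before)
        assert back.config == model.config
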