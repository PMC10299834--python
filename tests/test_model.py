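"""Tests of the CNN architecture, forward pass and prediction rules."""

import numpy as np
import pytest

from pawstrike import model as M

from .oracles import block_output_shape, naive_conv2d_same, naive_maxpool2, naive_softmax

TINY = M.ModelConfig(n_classes=8, input_shape=(30, 8, 8), fc_hidden=(16, 8), dtype="float64")


class TestConfig:
    def test_first_filter_bank_is_4x4x30x30(self):
        cfg = M.ModelConfig(n_classes=8, input_shape=(30, 240, 320))
        assert cfg.conv_specs[0] == (4, 4, 30, 30)

    def test_three_conv_three_fc(self):
        cfg = M.ModelConfig(n_classes=11)
        assert len(cfg.conv_specs) == 3
        assert cfg.fc_widths[-1] == 11

    def test_spatial_dims_follow_pool_arithmetic(self):
        cfg = M.ModelConfig(n_classes=8, input_shape=(30, 240, 320))
        h, w = 240, 320
        expected = []
        for _ in range(3):
            h, w = (h + 1) // 2, (w + 1) // 2
            expected.append((h, w))
        assert cfg.spatial_dims() == expected
        assert cfg.spatial_dims()[-1] == block_output_shape(240, 320)

    def test_invalid_configs_rejected(self):
        with pytest.raises(M.ConfigError):
            M.ModelConfig(n_classes=1)
        with pytest.raises(M.ConfigError):
            M.ModelConfig(n_classes=8, conv_channels=(30, 30))

    def test_parameter_count_is_config_function(self):
        cfg = TINY
        params = M.init_params(cfg, seed=0)
        assert M.count_parameters(cfg) == sum(t.size for t in params.tensors())


class TestInit:
    def test_deterministic(self):
        a = M.init_params(TINY, seed=9)
        b = M.init_params(TINY, seed=9)
        for ta, tb in zip(a.tensors(), b.tensors()):
            assert np.array_equal(ta, tb)

    def test_he_variance(self):
        # fan-in-scaled init: sample variance ~ 2/fan_in within 10%
        params = M.init_params(
            M.ModelConfig(n_classes=8, input_shape=(30, 16, 16), dtype="float64"), seed=1
        )
        w = params.conv_w[0]
        fan_in = 4 * 4 * 30
        assert np.var(w) == pytest.approx(2.0 / fan_in, rel=0.10)
        assert not params.conv_b[0].any()

    def test_shapes_validated(self):
        params = M.init_params(TINY, seed=0)
        params.conv_w[1] = params.conv_w[1][:, :, :, :-1]
        with pytest.raises(M.ConfigError):
            params.validate()


class TestForward:
    def test_zero_weights_give_zero_logits(self, rng):
        params = M.init_params(TINY, seed=0)
        for t in params.tensors():
            t[...] = 0.0
        x = rng.uniform(size=(3, 30, 8, 8))
        assert not M.forward(params, x).any()

    def test_leaky_relu_definition(self):
        assert M.leaky_relu(np.array([-1.0]), 0.2)[0] == pytest.approx(-0.2)
        assert M.leaky_relu(np.array([3.0]), 0.2)[0] == 3.0

    def test_forward_matches_loop_oracle(self, rng):
        # full network vs. an independently coded direct convolution,
        # leaky ReLU and ceil-mode 2x2 max pooling
        params = M.init_params(TINY, seed=3)
        x = rng.uniform(size=(1, 30, 8, 8))
        got = M.forward(params, x)

        a = np.ascontiguousarray(x[0].transpose(1, 2, 0))
        for w, b in zip(params.conv_w, params.conv_b):
            z = naive_conv2d_same(a, w, b)
            a = naive_maxpool2(np.where(z >= 0, z, 0.2 * z))
        h = a.reshape(-1)
        for i, (w, b) in enumerate(zip(params.fc_w, params.fc_b)):
            h = h @ w + b
            if i < 2:
                h = np.where(h >= 0, h, 0.2 * h)
        np.testing.assert_allclose(got[0], h, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        params = M.init_params(TINY, seed=0)
        with pytest.raises(M.ShapeError):
            M.forward(params, rng.uniform(size=(2, 30, 9, 8)))


class TestSoftmax:
    def test_uniform_logits(self):
        p = M.softmax_probs(np.zeros((1, 8)))
        np.testing.assert_allclose(p, 0.125)

    def test_extreme_logits_do_not_overflow(self):
        p = M.softmax_probs(np.array([[1000.0, 0.0]]))
        assert p[0, 0] == pytest.approx(1.0) and np.isfinite(p).all()

    def test_matches_naive_on_small_logits(self, rng):
        logits = rng.normal(size=(5, 11))
        np.testing.assert_allclose(
            M.softmax_probs(logits), naive_softmax(logits), atol=1e-12
        )

    def test_simplex_property(self, rng):
        logits = rng.normal(scale=50, size=(20, 8))
        p = M.softmax_probs(logits)
        assert (p > 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestPredict:
    def test_argmax_prediction_and_low_tie_break(self, rng):
        params = M.init_params(TINY, seed=0)
        # force logits through the final bias only
        for t in params.tensors():
            t[...] = 0.0
        params.fc_b[2][3] = 5.0
        x = rng.uniform(size=(30, 8, 8))
        assert M.predict_clip(params, x) == 3
        params.fc_b[2][:] = 0.0
        params.fc_b[2][2] = params.fc_b[2][5] = 1.0  # tie -> lower frequency
        assert M.predict_clip(params, x) == 2


class TestActivations:
    def test_six_layers_with_consistent_shapes(self, rng):
        cfg = M.ModelConfig(n_classes=8, input_shape=(30, 48, 80))
        params = M.init_params(cfg, seed=0)
        maps = M.extract_activations(params, rng.uniform(size=(30, 48, 80)))
        assert len(maps) == 6
        dims = cfg.spatial_dims()
        for m, (h, w) in zip(maps[:3], dims):
            assert m.shape == (h, w, cfg.conv_channels[0])
        assert maps[3].shape == (256,)
        assert maps[4].shape == (64,)
        assert maps[5].shape == (8,)

    def test_zero_input_zero_bias_gives_zero_maps(self):
        params = M.init_params(TINY, seed=0)
        maps = M.extract_activations(params, np.zeros((30, 8, 8)))
        assert all(not np.abs(m).max() for m in maps)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        params = M.init_params(TINY, seed=4)
        path = tmp_path / "ckpt.npz"
        M.save_params(params, path)
        loaded = M.load_params(path)
        assert loaded.config == params.config
        for a, b in zip(params.tensors(), loaded.tensors()):
            assert np.array_equal(a, b)
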