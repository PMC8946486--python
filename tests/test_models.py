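import numpy as np
import pytest

from bpwave._nn import AdaptiveNorm, BatchNorm2D, Conv2D, LeakyReLU
from bpwave.models import (
    CANSpec,
    LSTMSpec,
    build_can,
    build_lstm,
    half_mse_loss,
)


class TestCANArchitecture:
    def test_forward_shape(self, rng):
        net = build_can(CANSpec(channels=6), seed=0)
        out = net.forward(rng.normal(size=(3, 4, 250)))
        assert out.shape == (3, 250)
        out4d = net.forward(rng.normal(size=(2, 4, 250, 1)))
        assert out4d.shape == (2, 250)

    def test_ten_layer_groups(self):
        net = build_can(CANSpec(channels=4))
        assert net.n_layer_groups == 10

    def test_dilation_schedule_is_powers_of_two(self):
        spec = CANSpec()
        assert spec.dilation_schedule == (1, 2, 4, 8, 16, 32, 64, 128)
        with pytest.raises(ValueError, match="dilation"):
            CANSpec(dilation_schedule=(1, 2, 4, 8, 16, 32, 64, 127))
        with pytest.raises(ValueError, match="schedule"):
            CANSpec(n_dilated_blocks=7)

    def test_spatial_size_preserved_through_every_block(self, rng):
        """All eight dilated blocks (and the plain block) keep 4 x L."""
        net = build_can(CANSpec(channels=5), seed=1)
        x = rng.normal(size=(2, 4, 250, 1))
        for gname, block in net.net.groups[:-1]:
            for layer in block:
                x = layer.forward(x, training=False)
            assert x.shape[1:3] == (4, 250), gname

    def test_receptive_field_spans_window(self, rng):
        """Perturbing one input column must reach outputs across a span of
        at least 2*(1+2+...+128) columns, clipped to the window — i.e. the
        dilation ladder gives the output full-window temporal context."""
        net = build_can(CANSpec(channels=4), seed=3)
        x = rng.normal(size=(1, 4, 250))
        base = net.forward(x)
        bumped = x.copy()
        bumped[0, :, 125] += 1.0
        delta = np.abs(net.forward(bumped) - base)[0]
        changed = np.flatnonzero(delta > 1e-12)
        span = changed.max() - changed.min() + 1
        assert span >= min(2 * (2**8 - 1), 250)

    def test_describe_lists_ten_groups(self):
        rows = build_can(CANSpec(channels=4)).describe()
        assert len(rows) == 10
        assert rows[0][0] == "dilated_1" and rows[-1][0] == "regression"


class TestAdaptiveNorm:
    def test_identity_at_initialization(self, rng):
        layer = AdaptiveNorm(channels=6)
        x = rng.normal(size=(2, 4, 50, 6))
        np.testing.assert_array_equal(layer.forward(x, training=True), x)

    def test_blends_batchnorm_path(self, rng):
        layer = AdaptiveNorm(channels=3, lambda_init=0.0, mu_init=1.0)
        x = rng.normal(size=(4, 4, 20, 3)) * 5 + 2
        out = layer.forward(x, training=True)
        np.testing.assert_allclose(out.mean(axis=(0, 1, 2)), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=(0, 1, 2)), 1.0, atol=1e-3)


class TestLSTMArchitecture:
    def test_sequence_to_sequence_shape(self, rng):
        net = build_lstm(LSTMSpec(hidden_units=16), seed=0)
        out = net.forward(rng.normal(size=(3, 250, 2)))
        assert out.shape == (3, 250)

    def test_recurrent_parameter_count(self):
        """Gate-stacked weights: 1600x2 input, 1600x400 recurrent, 1600 bias."""
        spec = LSTMSpec(input_dims=2, hidden_units=400)
        assert spec.gate_rows == 1600
        assert spec.recurrent_layer_parameters == 1600 * 2 + 1600 * 400 + 1600
        net = build_lstm(spec, seed=0)
        assert net.lstm.params["Wx"].shape == (1600, 2)
        assert net.lstm.params["Wh"].shape == (1600, 400)
        assert net.lstm.params["b"].shape == (1600,)

    def test_forward_deterministic(self, rng):
        net = build_lstm(LSTMSpec(hidden_units=8), seed=2)
        x = rng.normal(size=(2, 40, 2))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))


class TestHalfMseLoss:
    def test_printed_example(self):
        assert half_mse_loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(2.5)

    def test_zero_at_identity(self, rng):
        y = rng.normal(size=(3, 50))
        assert half_mse_loss(y, y) == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(50):
            n = rng.integers(2, 30)
            t = rng.normal(size=n)
            y = rng.normal(size=n)
            brute = 0.0
            for tp, yp in zip(t, y):
                brute += 0.5 * (tp - yp) ** 2
            assert half_mse_loss(t, y) == pytest.approx(brute, abs=1e-9)

    def test_quadratic_homogeneity(self, rng):
        t = rng.normal(size=20)
        y = np.zeros(20)
        assert half_mse_loss(3 * t, y) == pytest.approx(9 * half_mse_loss(t, y))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            half_mse_loss(np.zeros(3), np.zeros(4))


def _gradcheck(net, x, y, eps=1e-6):
    """Worst relative error of analytic vs central-difference gradients."""
    pred = net.forward(x, training=True)
    net.zero_grad()
    net.backward((pred - y) / len(x))
    worst = 0.0
    rng = np.random.default_rng(0)
    for _name, owner, key in net.parameters():
        p = owner.params[key]
        flat = p.reshape(-1)
        for i in rng.choice(p.size, size=min(3, p.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = half_mse_loss(y, net.forward(x, training=True))
            flat[i] = orig - eps
            lm = half_mse_loss(y, net.forward(x, training=True))
            flat[i] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = owner.grads[key].reshape(-1)[i]
            denom = max(1.0, abs(numeric), abs(analytic))
            worst = max(worst, abs(numeric - analytic) / denom)
    return worst


class TestBackpropagation:
    """Hand-written backward passes against finite differences."""

    def test_can_gradients(self, rng):
        net = build_can(
            CANSpec(in_cols=16, channels=3, n_dilated_blocks=3,
                    dilation_schedule=(1, 2, 4)), seed=5)
        x = rng.normal(size=(3, 4, 16))
        y = rng.normal(size=(3, 16))
        assert _gradcheck(net, x, y) < 1e-6

    def test_lstm_gradients(self, rng):
        net = build_lstm(LSTMSpec(hidden_units=5), seed=5)
        x = rng.normal(size=(3, 12, 2))
        y = rng.normal(size=(3, 12))
        assert _gradcheck(net, x, y) < 1e-6

    def test_single_layer_input_gradients(self, rng):
        """Input gradients of conv/BN/activation via directional probe."""
        for layer in (Conv2D(3, 4, kernel=(3, 3), dilation=2,
                             rng=np.random.default_rng(1)),
                      BatchNorm2D(3), LeakyReLU(0.2)):
            x = rng.normal(size=(2, 4, 10, 3))
            direction = rng.normal(size=x.shape)
            y0 = layer.forward(x, training=True)
            dy = rng.normal(size=y0.shape)
            layer.zero_grad()
            dx = layer.backward(dy)
            eps = 1e-6
            yp = layer.forward(x + eps * direction, training=True)
            ym = layer.forward(x - eps * direction, training=True)
            numeric = np.sum(dy * (yp - ym)) / (2 * eps)
            analytic = np.sum(dx * direction)
            assert numeric == pytest.approx(analytic, rel=1e-5, abs=1e-7)
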