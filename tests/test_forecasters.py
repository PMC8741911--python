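"""LSTM cell contract, model builders, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from lfpclean import (
    ForecastModelSpec,
    LstmCellParams,
    TrainConfig,
    build_cnn_lstm,
    build_custom,
    build_lstm,
    lstm_cell_step,
    train_forecaster,
)
from lfpclean._autodiff import Tensor
from lfpclean.errors import ArchitectureError, ShapeError
from lfpclean.forecasters import make_examples
from scipy.signal import lfilter


def _random_cell(rng, hidden=3, inputs=2) -> LstmCellParams:
    p = LstmCellParams.zeros(hidden, inputs)
    for name in ("W_fh", "W_fx", "W_ih", "W_ix", "W_ch", "W_cx", "W_oh", "W_ox",
                 "b_f", "b_i", "b_c", "b_o"):
        setattr(p, name, rng.standard_normal(getattr(p, name).shape))
    return p


def _ar2_segments(n_segments=30, seg_len=120, seed=0):
    """Seeded stationary AR(2) segments for small training fixtures."""
    rng = np.random.default_rng(seed)
    segs = []
    for _ in range(n_segments):
        e = rng.standard_normal(seg_len + 200)
        segs.append(lfilter([1.0], [1.0, -1.4, 0.65], e)[200:])
    return segs


class TestLstmCell:
    def test_zero_weights_give_half_open_gates(self):
        p = LstmCellParams.zeros(3, 2)
        h, c = lstm_cell_step(np.zeros(2), np.zeros(3), np.zeros(3), p)
        np.testing.assert_allclose(p.f_t, 0.5)
        np.testing.assert_allclose(p.i_t, 0.5)
        np.testing.assert_allclose(p.o_t, 0.5)
        np.testing.assert_allclose(p.c_tilde_t, 0.0)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_saturated_forget_gate_preserves_state(self):
        p = LstmCellParams.zeros(3, 2)
        p.b_f += 60.0   # forget gate -> 1: keep everything
        p.b_i -= 60.0   # update gate -> 0: add nothing
        c_prev = np.array([0.3, -1.2, 2.0])
        _, c = lstm_cell_step(np.ones(2), np.zeros(3), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)

    def test_matches_independent_gate_by_gate_evaluation(self, rng):
        """Independent oracle: each gate evaluated separately with expit."""
        p = _random_cell(rng)
        x, h0, c0 = rng.standard_normal(2), rng.standard_normal(3), rng.standard_normal(3)
        h, c = lstm_cell_step(x, h0, c0, p)
        f = expit(p.W_fh.dot(h0) + p.W_fx.dot(x) + p.b_f)
        i = expit(p.W_ih.dot(h0) + p.W_ix.dot(x) + p.b_i)
        ct = np.tanh(p.W_ch.dot(h0) + p.W_cx.dot(x) + p.b_c)
        o = expit(p.W_oh.dot(h0) + p.W_ox.dot(x) + p.b_o)
        c_exp = f * c0 + i * ct
        np.testing.assert_allclose(c, c_exp, atol=1e-10)
        np.testing.assert_allclose(h, o * np.tanh(c_exp), atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            lstm_cell_step(np.zeros(5), np.zeros(3), np.zeros(3), LstmCellParams.zeros(3, 2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_gate_ranges_for_arbitrary_inputs(self, seed):
        """Sigmoid gates stay in (0,1); candidate and hidden state in (-1,1)."""
        rng = np.random.default_rng(seed)
        p = _random_cell(rng)
        scale = 10.0 ** rng.integers(-2, 3)
        x = scale * rng.standard_normal(2)
        h0 = np.tanh(rng.standard_normal(3))
        c0 = rng.standard_normal(3)
        h, c = lstm_cell_step(x, h0, c0, p)
        for gate in (p.f_t, p.i_t, p.o_t):
            assert np.all(gate >= 0.0) and np.all(gate <= 1.0)
        assert np.all(np.abs(p.c_tilde_t) <= 1.0)
        assert np.all(np.abs(h) <= 1.0)


class TestBuilders:
    @pytest.mark.parametrize("input_len,hidden", [(1200, 120), (250, 25), (200, 20)])
    def test_one_tenth_hidden_rule(self, input_len, hidden):
        model = build_lstm(ForecastModelSpec("lstm", input_len, 10))
        assert model.spec.hidden_size == hidden

    def test_parameter_count_closed_form(self):
        h = 20
        model = build_lstm(ForecastModelSpec("lstm", 200, 10))
        assert model.n_parameters == 4 * (h * (1 + h) + h) + (h + 1) * 10

    def test_tiny_input_clamps_hidden_with_warning(self):
        with pytest.warns(UserWarning):
            model = build_lstm(ForecastModelSpec("lstm", 4, 1))
        assert model.spec.hidden_size == 1

    def test_cnn_lstm_has_16_rows(self):
        model = build_cnn_lstm(ForecastModelSpec("cnn_lstm", 100, 5))
        assert len(model.summary()) == 16

    def test_cnn_lstm_dilation_ladder(self):
        from lfpclean._layers import CausalConv1d
        model = build_cnn_lstm(ForecastModelSpec("cnn_lstm", 100, 5))
        dilations = [l.dilation for l in model.layers if isinstance(l, CausalConv1d)]
        assert dilations == [1, 2, 4, 8, 16]

    def test_cnn_lstm_pooling_is_stride_5(self):
        """After size-1 stride-5 pooling the recurrent stack sees floor(T/5) steps."""
        from lfpclean._layers import GRULayer
        model = build_cnn_lstm(ForecastModelSpec("cnn_lstm", 100, 5))
        x = Tensor(np.zeros((2, 100, 1)))
        for layer in model.layers:
            x = layer.forward(x)
            if isinstance(layer, GRULayer):
                break
        assert x.data.shape[1] == 100 // 5

    def test_cnn_lstm_rejects_short_inputs(self):
        with pytest.raises(ArchitectureError):
            build_cnn_lstm(ForecastModelSpec("cnn_lstm", 60, 5))

    def test_forecast_matches_manual_forward_pass(self, rng):
        """Network forecast equals a step-by-step cell recursion plus the
        linear read-out, run outside the training engine."""
        model = build_lstm(ForecastModelSpec("lstm", 30, 3), seed=5)
        model.norm_mean, model.norm_std = 0.1, 0.7
        ctx = rng.standard_normal(30)
        got = model.forecast(ctx)
        lstm = model.layers[1]
        dense = model.layers[2]
        cell = LstmCellParams.from_fused(lstm.Wx.data, lstm.Wh.data, lstm.b.data)
        z = (ctx - model.norm_mean) / model.norm_std
        h, c = np.zeros(lstm.hidden_size), np.zeros(lstm.hidden_size)
        for x_t in z:
            h, c = lstm_cell_step(np.array([x_t]), h, c, cell)
        manual = (h @ dense.W.data + dense.b.data) * model.norm_std + model.norm_mean
        np.testing.assert_allclose(got, manual, atol=1e-10)


class TestTraining:
    def test_zero_signal_fixture_has_zero_loss_from_the_start(self):
        """On an all-zero (noise-free) fixture the freshly built network is
        already optimal: gates see zero input, the read-out bias is zero, so
        the first validation loss is the irreducible 0."""
        segs = [np.zeros(60) for _ in range(6)]
        model = build_lstm(ForecastModelSpec("lstm", 20, 2), seed=0)
        _, hist = train_forecaster(model, segs, segs, TrainConfig(max_epochs=1, seed=0))
        assert hist.val_loss[0] == pytest.approx(0.0, abs=1e-20)

    def test_training_reduces_validation_loss_on_ar2(self):
        segs = _ar2_segments(seed=3)
        model = build_lstm(ForecastModelSpec("lstm", 40, 5), seed=3)
        cfg = TrainConfig(max_epochs=50, batch_size=64, learning_rate=3e-3,
                          patience=50, seed=3)
        _, hist = train_forecaster(model, segs[:24], segs[24:], cfg)
        assert hist.val_loss[-1] < hist.val_loss[0]

    def test_identical_seeds_are_bit_reproducible(self):
        segs = _ar2_segments(n_segments=8, seg_len=60, seed=1)
        weights = []
        for _ in range(2):
            model = build_lstm(ForecastModelSpec("lstm", 20, 2), seed=9)
            train_forecaster(model, segs[:6], segs[6:],
                             TrainConfig(max_epochs=3, batch_size=32, seed=9))
            weights.append(model.weights())
        for key in weights[0]:
            np.testing.assert_array_equal(weights[0][key], weights[1][key])

    def test_cnn_lstm_trains_without_error(self):
        segs = _ar2_segments(n_segments=6, seg_len=110, seed=2)
        model = build_cnn_lstm(ForecastModelSpec("cnn_lstm", 80, 10), seed=2)
        _, hist = train_forecaster(model, segs[:4], segs[4:],
                                   TrainConfig(max_epochs=2, batch_size=8, seed=2))
        assert len(hist.train_loss) == 2
        assert np.isfinite(hist.train_loss).all()

    def test_custom_stack_builds_and_forecasts(self):
        stack = [
            {"type": "conv", "filters": 8, "kernel": 3, "dilation": 1},
            {"type": "elu"},
            {"type": "lstm", "units": 6},
        ]
        model = build_custom(stack, input_len=40, output_len=4, seed=0)
        assert model.forecast(np.zeros(40)).shape == (4,)

    def test_make_examples_geometry(self):
        segs = [np.arange(100.0)]
        X, Y = make_examples(segs, input_len=20, output_len=5, stride=5)
        assert X.shape == (16, 20) and Y.shape == (16, 5)
        np.testing.assert_array_equal(Y[0], np.arange(20.0, 25.0))
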