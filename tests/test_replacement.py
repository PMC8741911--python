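"""Recursive forecasting recursion and artefact-window substitution."""

import numpy as np
import pytest

from lfpclean import (
    LabelArray,
    Recording,
    label_windows,
    recursive_forecast,
    replace_artefacts,
)
from lfpclean.errors import PropagationError, ShapeError
from lfpclean.signal_core import WindowGrid


class CountingStub:
    """Constant predictor that counts invocations and records contexts."""

    def __init__(self, input_len, output_len, value=1.0):
        self.input_len = input_len
        self.output_len = output_len
        self.value = value
        self.calls = 0
        self.contexts = []

    def forecast(self, ctx):
        self.calls += 1
        self.contexts.append(np.array(ctx))
        return np.full(self.output_len, self.value)


class TestRecursiveForecast:
    def test_invocation_count_is_ceil_horizon_over_output(self):
        stub = CountingStub(50, 10)
        out = recursive_forecast(stub, np.zeros(50), 200)
        assert stub.calls == 20
        assert out.shape == (200,)

    def test_short_horizon_truncates_single_call(self):
        stub = CountingStub(50, 10)
        out = recursive_forecast(stub, np.zeros(50), 5)
        assert stub.calls == 1
        assert out.shape == (5,)

    def test_constant_predictor_gives_constant_sequence(self):
        stub = CountingStub(20, 7, value=3.25)
        np.testing.assert_array_equal(recursive_forecast(stub, np.zeros(20), 30),
                                      np.full(30, 3.25))

    def test_context_slides_over_own_predictions(self):
        stub = CountingStub(20, 10, value=2.0)
        ctx = np.arange(20.0)
        recursive_forecast(stub, ctx, 20)
        np.testing.assert_array_equal(stub.contexts[0], ctx)
        np.testing.assert_array_equal(stub.contexts[1],
                                      np.concatenate([ctx[10:], np.full(10, 2.0)]))

    def test_non_finite_prediction_raises_with_step(self):
        class NanStub:
            input_len, output_len = 10, 5
            def forecast(self, ctx):
                return np.full(5, np.nan)

        with pytest.raises(PropagationError, match="step 0"):
            recursive_forecast(NanStub(), np.zeros(10), 5)

    def test_wrong_context_length_rejected(self):
        with pytest.raises(ShapeError):
            recursive_forecast(CountingStub(50, 10), np.zeros(49), 10)


def _labelled_recording(bits, window_len=50, fs=1000.0, rng=None):
    bits = np.asarray(bits)
    rng = rng or np.random.default_rng(0)
    rec = Recording(rng.standard_normal((1, bits.size * window_len)), fs=fs)
    labels = LabelArray(bits, WindowGrid(window_len, bits.size, fs))
    return rec, labels


class TestReplaceArtefacts:
    def test_all_clean_is_identity(self):
        rec, labels = _labelled_recording(np.zeros(6, dtype=int))
        stub = CountingStub(200, 50)
        cleaned, log = replace_artefacts(rec, labels, stub)
        np.testing.assert_array_equal(cleaned.data, rec.data)
        assert log.n_replaced == 0 and log.n_unreplaceable == 0
        assert stub.calls == 0

    def test_consecutive_windows_share_the_forecast_context(self):
        """The second artefact window's context must include the forecast
        that replaced the first, not the original artefactual samples."""
        rec, labels = _labelled_recording([0, 0, 0, 0, 1, 1])
        stub = CountingStub(200, 50, value=7.0)
        cleaned, log = replace_artefacts(rec, labels, stub, context_len=200)
        assert log.channels[0].replaced == [4, 5]
        np.testing.assert_array_equal(stub.contexts[0], rec.data[0, 0:200])
        np.testing.assert_array_equal(
            stub.contexts[1],
            np.concatenate([rec.data[0, 50:200], np.full(50, 7.0)]),
        )
        np.testing.assert_array_equal(cleaned.data[0, 200:300], np.full(100, 7.0))

    def test_artefact_at_start_is_unreplaceable_and_untouched(self):
        rec, labels = _labelled_recording([1, 0, 0, 0, 0, 0])
        cleaned, log = replace_artefacts(rec, labels, CountingStub(200, 50))
        np.testing.assert_array_equal(cleaned.data, rec.data)
        assert log.channels[0].unreplaceable[0][0] == 0
        assert log.n_replaced == 0

    def test_untouched_samples_are_bit_identical_and_length_preserved(self):
        rng = np.random.default_rng(4)
        bits = np.zeros(20, dtype=int)
        bits[[6, 7, 13]] = 1
        rec, labels = _labelled_recording(bits, rng=rng)
        cleaned, log = replace_artefacts(rec, labels, CountingStub(100, 25, value=0.0))
        assert cleaned.data.shape == rec.data.shape
        mask = np.ones(rec.n_samples, dtype=bool)
        for w in (6, 7, 13):
            mask[w * 50 : (w + 1) * 50] = False
        np.testing.assert_array_equal(cleaned.data[0, mask], rec.data[0, mask])
        assert log.n_replaced == 3

    def test_replacement_is_per_channel(self):
        rng = np.random.default_rng(5)
        rec = Recording(rng.standard_normal((2, 300)), fs=100.0)
        labels = LabelArray(np.array([[0, 0, 0, 0, 1, 0], [0, 0, 0, 0, 0, 0]]),
                            WindowGrid(50, 6, 100.0))
        cleaned, log = replace_artefacts(rec, labels, CountingStub(100, 50, value=0.0))
        np.testing.assert_array_equal(cleaned.data[1], rec.data[1])
        assert log.channels[0].replaced == [4]
        assert log.channels[1].replaced == []

    def test_long_runs_warn_about_compounding_error(self):
        rec, labels = _labelled_recording([0, 0, 0, 0, 1, 1])
        with pytest.warns(UserWarning, match="compounds"):
            replace_artefacts(rec, labels, CountingStub(200, 50), max_run_windows=1)

    def test_idempotent_on_relabelled_output(self, small_fixture):
        """Re-running replacement on the cleaned signal (labels recomputed with
        the same threshold) replaces no more windows than the first pass."""
        fx = small_fixture
        stub = CountingStub(fx.grid.window_len, fx.grid.window_len, value=0.0)
        cleaned, log1 = replace_artefacts(fx.contaminated, fx.labels, stub)
        relabelled = label_windows(cleaned, fx.grid, fx.threshold)
        _, log2 = replace_artefacts(cleaned, relabelled, stub)
        assert log2.n_replaced + log2.n_unreplaceable <= log1.n_replaced + log1.n_unreplaceable
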