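"""Threshold derivation, window labelling, segment extraction and splits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lfpclean import (
    LabelArray,
    Recording,
    ThresholdSpec,
    build_config_grid,
    derive_threshold,
    extract_artefactual_segments,
    extract_clean_segments,
    extract_segments,
    label_windows,
    make_windows,
    split_segments,
    window_power,
)
from lfpclean.errors import (
    GeometryError,
    InsufficientDataError,
    InvalidEpochError,
    InvalidGridError,
)
from lfpclean.signal_core import WindowGrid


GRID = WindowGrid(window_len=10, n_windows=10, fs=100.0)


def _labels(bits, window_len=10, fs=100.0) -> LabelArray:
    bits = np.asarray(bits)
    return LabelArray(bits, WindowGrid(window_len, bits.size, fs))


def _rec_for(labels: LabelArray, rng=None) -> Recording:
    rng = rng or np.random.default_rng(0)
    n = labels.grid.n_windows * labels.grid.window_len
    return Recording(rng.standard_normal((1, n)), fs=labels.grid.fs)


class TestDeriveThreshold:
    def test_constant_epoch(self):
        thr = derive_threshold([np.full(30, 2.0)], GRID)
        assert thr.thresholds[0] == pytest.approx(4.0)
        assert thr.provenance == "derived_from_clean_epochs"

    def test_max_over_epochs(self):
        zeros = np.zeros(20)
        square = np.tile([1.0, -1.0], 10)
        assert derive_threshold([zeros, square], GRID).thresholds[0] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self, rng):
        epochs = [rng.standard_normal(rng.integers(10, 55)) for _ in range(10)]
        oracle = max(
            window_power(e[w * 10 : (w + 1) * 10])
            for e in epochs
            for w in range(len(e) // 10)
        )
        assert derive_threshold(epochs, GRID).thresholds[0] == pytest.approx(oracle, rel=1e-12)

    def test_short_epoch_rejected(self):
        with pytest.raises(InvalidEpochError):
            derive_threshold([np.zeros(5)], GRID)


class TestLabelWindows:
    def test_all_below_threshold(self, rng):
        rec = Recording(rng.uniform(-0.5, 0.5, (1, 100)), fs=100.0)
        grid = make_windows(rec, 0.1)
        labels = label_windows(rec, grid, ThresholdSpec.manual(10.0))
        assert labels.labels.sum() == 0

    def test_exact_equality_is_clean(self):
        rec = Recording(np.ones((1, 20)), fs=100.0)
        grid = make_windows(rec, 0.1)
        labels = label_windows(rec, grid, ThresholdSpec.manual(1.0))
        assert labels.labels.sum() == 0  # strict exceedance: ties stay clean

    def test_injected_windows_and_only_those_flagged(self, rng):
        rec = Recording(rng.uniform(-1, 1, (1, 200)), fs=100.0)
        grid = make_windows(rec, 0.1)
        data = rec.data.copy()
        hot = [3, 7, 15]
        for w in hot:
            data[0, w * 10 : (w + 1) * 10] += 50.0
        contaminated = Recording(data, fs=100.0)
        clean_powers = [
            window_power(data[0, w * 10 : (w + 1) * 10])
            for w in range(grid.n_windows) if w not in hot
        ]
        thr = ThresholdSpec(np.array([max(clean_powers)]))
        labels = label_windows(contaminated, grid, thr)
        assert sorted(np.flatnonzero(labels.labels[0])) == hot


class TestExtraction:
    def test_all_artefactual_gives_no_clean_segments(self):
        labels = _labels(np.ones(10, dtype=int))
        segs = extract_clean_segments(_rec_for(labels), labels, 0.2)
        assert segs.n_clean == 0

    def test_greedy_scan_hand_trace(self):
        labels = _labels([0, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        segs = extract_clean_segments(_rec_for(labels), labels, 0.2)
        assert segs.n_clean == 4
        assert [start for _, start in segs.clean_positions] == [0, 20, 50, 70]

    def test_all_clean_floor_division(self):
        labels = _labels(np.zeros(10, dtype=int))
        segs = extract_clean_segments(_rec_for(labels), labels, 0.2)
        assert segs.n_clean == 5

    def test_segments_copy_the_samples(self):
        labels = _labels(np.zeros(10, dtype=int))
        rec = _rec_for(labels)
        segs = extract_clean_segments(rec, labels, 0.2)
        np.testing.assert_array_equal(segs.clean_segments[0], rec.data[0, :20])

    def test_geometry_must_be_multiple_of_window(self):
        labels = _labels(np.zeros(10, dtype=int))
        with pytest.raises(GeometryError):
            extract_clean_segments(_rec_for(labels), labels, 0.25)

    def test_no_artefacts_gives_no_artefactual_segments(self):
        labels = _labels(np.zeros(8, dtype=int))
        segs = extract_artefactual_segments(_rec_for(labels), labels, 0.8, 0.4)
        assert segs.n_artefactual == 0

    def test_artefactual_hand_trace(self):
        labels = _labels([0, 0, 0, 0, 1, 1, 0, 0])
        segs = extract_artefactual_segments(_rec_for(labels), labels, 0.8, 0.4)
        assert segs.n_artefactual == 1
        samples, seg_labels = segs.artefactual_segments[0]
        assert list(np.flatnonzero(seg_labels)) == [4, 5]
        assert samples.size == 80

    def test_artefact_without_clean_prefix_excluded(self):
        labels = _labels([1, 0, 0, 0, 0, 0, 0, 0])
        segs = extract_artefactual_segments(_rec_for(labels), labels, 0.8, 0.4)
        assert segs.n_artefactual == 0

    def test_prefix_of_artefactual_segment_is_clean(self, small_fixture):
        k = small_fixture.grid.window_len
        prefix_w = small_fixture.segments.clean_prefix_len // k
        for _, labels in small_fixture.segments.artefactual_segments:
            assert labels[:prefix_w].sum() == 0
            assert labels.sum() >= 1

    @given(st.lists(st.integers(0, 1), min_size=8, max_size=60))
    def test_clean_and_artefactual_never_overlap(self, bits):
        """One shared scan: clean and artefactual segments partition disjoint
        sample ranges."""
        labels = _labels(bits)
        segs = extract_segments(_rec_for(labels), labels, 0.4, 0.2)
        spans = [(s, s + segs.segment_len) for _, s in segs.clean_positions]
        spans += [(s, s + segs.segment_len) for _, s in segs.artefactual_positions]
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0


class TestSplit:
    def _segset(self, n):
        labels = _labels(np.zeros(2 * n, dtype=int))
        return extract_clean_segments(_rec_for(labels), labels, 0.2)

    def test_paper_fractions_small(self):
        out = split_segments(self._segset(10), (0.8, 0.1, 0.1), seed=0)
        assert (out.split.count("train"), out.split.count("val"), out.split.count("test")) == (8, 1, 1)

    def test_paper_fractions_large(self):
        labels = _labels(np.zeros(2000, dtype=int), window_len=2)
        segs = extract_clean_segments(
            Recording(np.zeros((1, 4000)), fs=100.0), labels, 0.04
        )
        out = split_segments(segs, (0.8, 0.1, 0.1), seed=3)
        assert (out.split.count("train"), out.split.count("val"), out.split.count("test")) == (800, 100, 100)

    def test_same_seed_same_assignment(self):
        a = split_segments(self._segset(10), seed=42)
        b = split_segments(self._segset(10), seed=42)
        assert a.split == b.split

    def test_partition_property(self):
        out = split_segments(self._segset(17), seed=1)
        assert len(out.split) == out.n_clean
        assert set(out.split) == {"train", "val", "test"}

    def test_too_few_segments_rejected(self):
        with pytest.raises(InsufficientDataError):
            split_segments(self._segset(2))


class TestConfigGrid:
    def test_treadmill_grid_has_54_configurations(self):
        grid = build_config_grid(np.round(np.arange(0.1, 1.0, 0.1), 1), [1, 5, 10, 25, 50, 100])
        assert len(grid) == 54

    def test_sleep_grid_has_15_configurations(self):
        grid = build_config_grid([1, 2, 3], [1, 25, 50, 125, 250])
        assert len(grid) == 15
        assert grid[0] == (1, 1) and grid[-1] == (3, 250)  # input-major order

    def test_single_configuration(self):
        assert build_config_grid([1], [1]) == [(1, 1)]

    def test_duplicates_rejected(self):
        with pytest.raises(InvalidGridError):
            build_config_grid([1, 1], [1])
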