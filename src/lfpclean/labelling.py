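"""Power-threshold artefact labelling and segment extraction.

The labelling rule is deliberately simple: a window is artefactual iff its
mean-squared power *strictly* exceeds a per-channel threshold.  Thresholds
are either supplied manually or derived as the maximum window power observed
in user-designated artefact-free epochs, so that by construction no clean
epoch window would be flagged.

Segment extraction walks each channel's window grid left to right with a
single greedy, non-overlapping scan that classifies each candidate segment
as *clean* (every window below threshold), *artefactual* (clean prefix of a
given length followed by at least one artefact window), or skips forward
past the blocking artefact.  Using one shared scan guarantees clean and
artefactual segments never overlap in sample coverage, which keeps training
data and replacement targets disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    DimensionError,
    GeometryError,
    InsufficientDataError,
    InvalidEpochError,
    InvalidGridError,
    InvalidInputError,
)
from .signal_core import Recording, WindowGrid, window_powers

__all__ = [
    "ThresholdSpec",
    "LabelArray",
    "SegmentSet",
    "derive_threshold",
    "label_windows",
    "extract_segments",
    "extract_clean_segments",
    "extract_artefactual_segments",
    "split_segments",
    "build_config_grid",
]

Provenance = Literal["manual", "derived_from_clean_epochs"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-channel power thresholds in mV^2."""

    thresholds: np.ndarray
    provenance: Provenance = "manual"

    def __post_init__(self) -> None:
        arr = np.atleast_1d(np.asarray(self.thresholds, dtype=np.float64))
        if arr.ndim != 1:
            raise DimensionError("thresholds must be a vector (one per channel)")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidInputError("thresholds must be finite and non-negative")
        object.__setattr__(self, "thresholds", arr)

    @classmethod
    def manual(cls, value: float, n_channels: int = 1) -> "ThresholdSpec":
        """A single manually chosen threshold applied to every channel."""
        return cls(np.full(n_channels, float(value)), provenance="manual")

    def for_channels(self, n_channels: int) -> np.ndarray:
        """Threshold vector broadcast/validated against ``n_channels``."""
        if self.thresholds.size == n_channels:
            return self.thresholds
        if self.thresholds.size == 1:
            return np.full(n_channels, self.thresholds[0])
        raise DimensionError(
            f"{self.thresholds.size} thresholds for {n_channels} channels"
        )


@dataclass(frozen=True)
class LabelArray:
    """Binary per-window artefact labels (channels x windows) on a grid."""

    labels: np.ndarray
    grid: WindowGrid

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise DimensionError("labels must be 2-D (channels x windows)")
        if not np.isin(arr, (0, 1)).all():
            raise InvalidInputError("labels must be binary")
        if arr.shape[1] != self.grid.n_windows:
            raise DimensionError(
                f"{arr.shape[1]} label columns for a grid of {self.grid.n_windows} windows"
            )
        object.__setattr__(self, "labels", arr.astype(np.int8))

    @property
    def n_channels(self) -> int:
        return self.labels.shape[0]

    @property
    def artefact_fraction(self) -> float:
        return float(self.labels.mean()) if self.labels.size else 0.0


@dataclass
class SegmentSet:
    """Fixed-length segments extracted from a labelled recording.

    ``clean_segments`` hold only below-threshold windows and feed model
    training; each ``artefactual_segments`` entry pairs the raw samples with
    its per-window labels and is guaranteed an artefact-free prefix of
    ``clean_prefix_len`` samples.  ``split`` assigns every clean segment to
    train/val/test once :func:`split_segments` has run.
    """

    clean_segments: list[np.ndarray] = field(default_factory=list)
    artefactual_segments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    segment_len: int = 0
    clean_prefix_len: int = 0
    fs: float = 0.0
    clean_positions: list[tuple[int, int]] = field(default_factory=list)
    artefactual_positions: list[tuple[int, int]] = field(default_factory=list)
    split: list[str] = field(default_factory=list)
    seed: int | None = None

    def by_split(self, which: str) -> list[np.ndarray]:
        if not self.split:
            raise InsufficientDataError("segments have not been split yet")
        return [s for s, w in zip(self.clean_segments, self.split) if w == which]

    @property
    def n_clean(self) -> int:
        return len(self.clean_segments)

    @property
    def n_artefactual(self) -> int:
        return len(self.artefactual_segments)


def derive_threshold(clean_epochs: Sequence[np.ndarray], grid: WindowGrid) -> ThresholdSpec:
    """Maximum window power over user-supplied artefact-free epochs.

    Each epoch is a 1-D sample vector (single channel / pooled channels) or a
    2-D channels x samples block; 2-D epochs yield per-channel maxima.  Every
    epoch must contain at least one full window.
    """
    if not clean_epochs:
        raise InvalidEpochError("no clean epochs supplied")
    maxima: list[np.ndarray] = []
    n_channels = None
    for k, epoch in enumerate(clean_epochs):
        arr = np.asarray(epoch, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.shape[1] < grid.window_len:
            raise InvalidEpochError(
                f"epoch {k} has {arr.shape[1]} samples, shorter than one window of {grid.window_len}"
            )
        if n_channels is None:
            n_channels = arr.shape[0]
        elif arr.shape[0] != n_channels:
            raise DimensionError("clean epochs disagree on channel count")
        rec = Recording(arr, fs=grid.fs)
        sub = WindowGrid(grid.window_len, arr.shape[1] // grid.window_len, grid.fs)
        maxima.append(window_powers(rec, sub).max(axis=1))
    return ThresholdSpec(np.max(maxima, axis=0), provenance="derived_from_clean_epochs")


def label_windows(recording: Recording, grid: WindowGrid, thr: ThresholdSpec) -> LabelArray:
    """Label each window 1 iff its power strictly exceeds its channel threshold."""
    powers = window_powers(recording, grid)
    thresholds = thr.for_channels(recording.n_channels)
    return LabelArray((powers > thresholds[:, None]).astype(np.int8), grid)


def _segment_geometry(grid: WindowGrid, seconds: float, what: str) -> int:
    n_samples = int(round(seconds * grid.fs))
    if n_samples <= 0 or n_samples % grid.window_len != 0:
        raise GeometryError(
            f"{what} of {seconds} s ({n_samples} samples) is not a positive multiple "
            f"of the {grid.window_len}-sample label window"
        )
    return n_samples // grid.window_len


def _scan_channel(labels_row: np.ndarray, k: int, prefix_k: int):
    """Greedy left-to-right scan; yields ('clean'|'artefactual', start_window)."""
    n = labels_row.size
    i = 0
    while i + k <= n:
        win = labels_row[i : i + k]
        art = np.flatnonzero(win)
        if art.size == 0:
            yield "clean", i
            i += k
        elif art[0] >= prefix_k:
            yield "artefactual", i
            i += k
        else:
            i += int(art[0]) + 1  # jump past the blocking artefact in the prefix


def extract_segments(
    recording: Recording,
    labels: LabelArray,
    segment_seconds: float,
    clean_prefix_seconds: float | None = None,
) -> SegmentSet:
    """One greedy scan per channel, collecting clean and artefactual segments.

    With ``clean_prefix_seconds=None`` only fully clean segments are
    collected (the scan skips anything containing an artefact window).
    """
    grid = labels.grid
    if labels.n_channels != recording.n_channels:
        raise DimensionError("label array channel count does not match recording")
    k = _segment_geometry(grid, segment_seconds, "segment length")
    if clean_prefix_seconds is None:
        prefix_k = k
        prefix_len = 0
    else:
        prefix_k = _segment_geometry(grid, clean_prefix_seconds, "clean prefix")
        if prefix_k >= k:
            raise GeometryError("clean prefix must be shorter than the segment")
        prefix_len = prefix_k * grid.window_len
    seg_len = k * grid.window_len
    out = SegmentSet(segment_len=seg_len, clean_prefix_len=prefix_len, fs=recording.fs)
    for ch in range(recording.n_channels):
        row = labels.labels[ch]
        for kind, start_w in _scan_channel(row, k, prefix_k):
            start = start_w * grid.window_len
            samples = recording.data[ch, start : start + seg_len].copy()
            if kind == "clean":
                out.clean_segments.append(samples)
                out.clean_positions.append((ch, start))
            else:
                out.artefactual_segments.append(
                    (samples, row[start_w : start_w + k].copy())
                )
                out.artefactual_positions.append((ch, start))
    return out


def extract_clean_segments(
    recording: Recording, labels: LabelArray, segment_seconds: float
) -> SegmentSet:
    """All non-overlapping segments whose windows are all label 0."""
    return extract_segments(recording, labels, segment_seconds, clean_prefix_seconds=None)


def extract_artefactual_segments(
    recording: Recording,
    labels: LabelArray,
    segment_seconds: float,
    clean_prefix_seconds: float,
) -> SegmentSet:
    """Segments with >=1 artefact window and an artefact-free prefix."""
    full = extract_segments(recording, labels, segment_seconds, clean_prefix_seconds)
    return SegmentSet(
        artefactual_segments=full.artefactual_segments,
        artefactual_positions=full.artefactual_positions,
        segment_len=full.segment_len,
        clean_prefix_len=full.clean_prefix_len,
        fs=full.fs,
    )


def split_segments(
    segs: SegmentSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SegmentSet:
    """Randomly assign clean segments to train/val/test.

    Validation and test counts are ``round(fraction * n)``; the remainder
    goes to the training set.  The assignment is a seeded permutation, so the
    same seed always reproduces the same split.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError(f"fractions must be positive and sum to 1, got {fractions}")
    n = segs.n_clean
    if n < 3:
        raise InsufficientDataError(f"need at least 3 clean segments to split, have {n}")
    n_val = int(round(f_val * n))
    n_test = int(round(f_test * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise InsufficientDataError(f"split {fractions} of {n} segments leaves an empty set")
    order = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=object)
    assignment[order[:n_train]] = "train"
    assignment[order[n_train : n_train + n_val]] = "val"
    assignment[order[n_train + n_val :]] = "test"
    out = SegmentSet(**{**segs.__dict__})
    out.split = list(assignment)
    out.seed = seed
    return out


def build_config_grid(
    input_lengths: Iterable[float], output_lengths: Iterable[int]
) -> list[tuple[float, int]]:
    """Cartesian product of input durations and output sample counts.

    Ordered input-major, matching how per-configuration models are trained
    and reported.  Duplicate or non-positive entries are rejected.
    """
    ins = list(input_lengths)
    outs = list(output_lengths)
    if not ins or not outs:
        raise InvalidGridError("both grid axes must be non-empty")
    if len(set(ins)) != len(ins) or len(set(outs)) != len(outs):
        raise InvalidGridError("duplicate grid entries")
    if min(ins) <= 0 or min(outs) <= 0:
        raise InvalidGridError("grid entries must be strictly positive")
    return [(i, o) for i in ins for o in outs]
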