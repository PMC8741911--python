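"""Core signal containers and windowing geometry.

A :class:`Recording` is a channels x samples voltage matrix (millivolts after
the load-time scale factor has been applied) with its sampling frequency.
A :class:`WindowGrid` partitions each channel into contiguous,
non-overlapping, left-aligned windows of fixed length; the trailing partial
window is excluded.  Per-window signal power -- the quantity that drives
artefact labelling -- is the mean squared amplitude of the window, which is
comparable across windows regardless of window length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, InvalidInputError, InvalidScaleError, InvalidWindowError

__all__ = [
    "Recording",
    "WindowGrid",
    "make_windows",
    "window_power",
    "window_powers",
    "scale_recording",
]


@dataclass(frozen=True)
class Recording:
    """A multi-channel voltage time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in millivolts.  A 1-D
        array is promoted to a single channel.
    fs
        Sampling frequency in Hz, strictly positive.
    scale
        The multiplicative factor that was applied on load (bookkeeping
        only; ``data`` already includes it).
    channel_ids
        Ordered channel labels; defaults to ``ch0, ch1, ...``.
    """

    data: np.ndarray
    fs: float
    scale: float = 1.0
    channel_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise DimensionError(f"recording data must be 2-D (channels x samples), got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("recording contains non-finite samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidInputError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "data", arr)
        if not self.channel_ids:
            object.__setattr__(self, "channel_ids", tuple(f"ch{i}" for i in range(arr.shape[0])))
        elif len(self.channel_ids) != arr.shape[0]:
            raise DimensionError(
                f"{len(self.channel_ids)} channel ids for {arr.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WindowGrid:
    """Contiguous non-overlapping window partition of a recording."""

    window_len: int
    n_windows: int
    fs: float

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise InvalidWindowError(f"window_len must be >= 1, got {self.window_len}")
        if self.n_windows < 0:
            raise InvalidWindowError(f"n_windows must be >= 0, got {self.n_windows}")

    @property
    def window_seconds(self) -> float:
        return self.window_len / self.fs

    def window_slice(self, w: int) -> slice:
        """Sample slice of window ``w``."""
        if not 0 <= w < self.n_windows:
            raise IndexError(f"window {w} outside grid of {self.n_windows}")
        return slice(w * self.window_len, (w + 1) * self.window_len)


def make_windows(recording: Recording, window_seconds: float) -> WindowGrid:
    """Partition ``recording`` into non-overlapping windows of ``window_seconds``.

    The window length in samples is ``round(window_seconds * fs)``; the number
    of windows is the floor of samples over window length, so a trailing
    partial window is dropped.
    """
    if window_seconds * recording.fs < 1:
        raise InvalidWindowError(
            f"window of {window_seconds} s is shorter than one sample at fs={recording.fs}"
        )
    window_len = int(round(window_seconds * recording.fs))
    if window_len > recording.n_samples:
        raise InvalidWindowError(
            f"window of {window_len} samples longer than recording of {recording.n_samples}"
        )
    return WindowGrid(window_len=window_len, n_windows=recording.n_samples // window_len, fs=recording.fs)


def window_power(samples: np.ndarray) -> float:
    """Mean squared amplitude of a window, in mV^2.

    Zero iff every sample is zero; invariant to sample order; scales with the
    square of any amplitude factor.
    """
    arr = np.asarray(samples, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("window_power of an empty window")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("window_power of non-finite samples")
    return float(np.mean(arr * arr))


def window_powers(recording: Recording, grid: WindowGrid) -> np.ndarray:
    """Per-window power matrix of shape ``(n_channels, n_windows)``."""
    total = grid.n_windows * grid.window_len
    if total > recording.n_samples or grid.fs != recording.fs:
        raise DimensionError("window grid does not fit the recording")
    trimmed = recording.data[:, :total]
    blocks = trimmed.reshape(recording.n_channels, grid.n_windows, grid.window_len)
    return np.mean(blocks * blocks, axis=2)


def scale_recording(recording: Recording, factor: float) -> Recording:
    """Multiply every sample by ``factor`` (fs and channel ids unchanged)."""
    if not np.isfinite(factor) or factor == 0:
        raise InvalidScaleError(f"scale factor must be finite and nonzero, got {factor}")
    return replace(
        recording,
        data=recording.data * float(factor),
        scale=recording.scale * float(factor),
    )
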