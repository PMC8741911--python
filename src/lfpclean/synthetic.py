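"""Synthetic LFP-like fixtures with ground-truth artefacts.

The baseline emulates stationary band-limited background activity: an AR(2)
process whose complex pole pair puts a spectral resonance at a chosen
frequency (default 8 Hz, a rodent theta-band peak, at 250 Hz sampling),
scaled to a target standard deviation in millivolts.  Artefact events --
high-amplitude transients, high-frequency bursts and baseline jumps, the
phenomenology of instrumental/movement artefacts -- are injected by a
seeded Bernoulli-per-window point process, and the affected windows are
returned as a ground-truth label array so labelling, training and
replacement can all be tested without any external recording.

No claim of physiological realism is made beyond "high power relative to
background in otherwise stationary activity"; see the methods note for what
this does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import scipy.signal

from .errors import InsufficientDataError, InvalidInputError, StabilityError
from .labelling import (
    LabelArray,
    SegmentSet,
    ThresholdSpec,
    extract_segments,
    label_windows,
    split_segments,
)
from .signal_core import Recording, WindowGrid, make_windows, window_powers

__all__ = [
    "ArtefactEvent",
    "SynthSpec",
    "SyntheticFixture",
    "generate_baseline",
    "inject_artefacts",
    "make_fixture",
    "make_fixture_dataset",
]

_KINDS = ("amplitude_transient", "hf_burst", "baseline_jump")


@dataclass(frozen=True)
class ArtefactEvent:
    """One artefact family: waveform kind, amplitude (in units of the
    background standard deviation), duration and mean rate."""

    kind: str
    amplitude: float = 10.0
    duration_s: float = 1.0
    rate_per_min: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown artefact kind {self.kind!r}; choose from {_KINDS}")
        if self.rate_per_min < 0 or self.duration_s <= 0 or self.amplitude <= 0:
            raise InvalidInputError("event rate must be >= 0, duration and amplitude > 0")


_DEFAULT_EVENTS = (
    ArtefactEvent("amplitude_transient", amplitude=10.0, duration_s=1.0, rate_per_min=2.0),
    ArtefactEvent("hf_burst", amplitude=10.0, duration_s=1.0, rate_per_min=1.0),
)


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic recording; the seed fixes everything.

    Defaults mirror a sleep-study-style recording: 250 Hz sampling, 600 s,
    1-s labelling windows, ~0.05 mV background, sparse 10x-amplitude events.
    """

    fs: float = 250.0
    duration_s: float = 600.0
    sigma: float = 0.05
    peak_hz: float = 8.0
    pole_radius: float = 0.98
    ar: tuple[float, ...] | None = None
    label_window_s: float = 1.0
    events: tuple[ArtefactEvent, ...] = _DEFAULT_EVENTS
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.sigma < 0:
            raise InvalidInputError("fs and duration must be positive, sigma non-negative")
        for ev in self.events:
            if ev.duration_s >= self.duration_s:
                raise InvalidInputError(
                    f"event duration {ev.duration_s} s not shorter than recording {self.duration_s} s"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def ar_coefficients(self) -> np.ndarray:
        """AR coefficients phi such that y_t = phi_1 y_{t-1} + ... + e_t."""
        if self.ar is not None:
            return np.asarray(self.ar, dtype=np.float64)
        theta = 2.0 * np.pi * self.peak_hz / self.fs
        r = self.pole_radius
        return np.array([2.0 * r * np.cos(theta), -r * r])


def generate_baseline(spec: SynthSpec) -> Recording:
    """Zero-mean stationary AR background, scaled to ``spec.sigma`` mV."""
    phi = spec.ar_coefficients()
    roots = np.roots(np.concatenate([[1.0], -phi]))
    if np.any(np.abs(roots) >= 1.0):
        raise StabilityError(f"AR coefficients {phi} are non-stationary (|root| >= 1)")
    rng = np.random.default_rng(spec.seed)
    burn = max(2000, 20 * phi.size)
    data = np.empty((spec.n_channels, spec.n_samples))
    for ch in range(spec.n_channels):
        noise = rng.standard_normal(spec.n_samples + burn)
        y = scipy.signal.lfilter([1.0], np.concatenate([[1.0], -phi]), noise)[burn:]
        sd = np.std(y)
        data[ch] = 0.0 if spec.sigma == 0.0 else y * (spec.sigma / sd)
    return Recording(data, fs=spec.fs)


def _event_waveform(kind: str, n: int, amp: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if kind == "amplitude_transient":
        return sign * amp * np.sin(np.pi * np.arange(n) / n)  # half-sine deflection
    if kind == "hf_burst":
        f_hf = 0.24 * fs  # well above the background resonance
        return amp * np.sin(2.0 * np.pi * f_hf * t) * scipy.signal.windows.tukey(n, 0.1)
    return sign * amp * np.ones(n)  # baseline_jump


def inject_artefacts(
    recording: Recording, spec: SynthSpec
) -> tuple[Recording, LabelArray]:
    """Add seeded artefact events; return the contaminated recording and the
    ground-truth window labels.

    Events are placed window-by-window: each labelling window independently
    starts an event of each kind with probability ``rate_per_min / 60 *
    window_seconds``.  Amplitudes are multiples of the channel's background
    RMS, so a multiplier m yields affected-window power of order m^2/2 times
    the background mean power -- far above any threshold derived from clean
    activity once m is ~10.
    """
    grid = make_windows(recording, spec.label_window_s)
    truth = np.zeros((recording.n_channels, grid.n_windows), dtype=np.int8)
    if all(ev.rate_per_min == 0 for ev in spec.events):
        return recording, LabelArray(truth, grid)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    data = recording.data.copy()
    window_minutes = grid.window_seconds / 60.0
    for ch in range(recording.n_channels):
        sigma_ch = float(np.std(recording.data[ch])) or spec.sigma or 1.0
        for ev in spec.events:
            n_ev = int(round(ev.duration_s * recording.fs))
            if n_ev > recording.n_samples:
                raise InvalidInputError("event longer than the recording")
            p = min(ev.rate_per_min * window_minutes, 1.0)
            hits = rng.random(grid.n_windows) < p
            for w in np.flatnonzero(hits):
                start = w * grid.window_len
                stop = min(start + n_ev, recording.n_samples)
                wave = _event_waveform(ev.kind, stop - start, ev.amplitude * sigma_ch,
                                       recording.fs, rng)
                data[ch, start:stop] += wave
                first_w, last_w = w, min((stop - 1) // grid.window_len, grid.n_windows - 1)
                truth[ch, first_w : last_w + 1] = 1
    return dc_replace(recording, data=data), LabelArray(truth, grid)


@dataclass
class SyntheticFixture:
    """Everything a pipeline test needs, produced from one seed."""

    spec: SynthSpec
    clean: Recording
    contaminated: Recording
    truth: LabelArray
    grid: WindowGrid
    threshold: ThresholdSpec
    labels: LabelArray
    segments: SegmentSet


def make_fixture(
    spec: SynthSpec,
    segment_seconds: float = 4.0,
    clean_prefix_seconds: float = 1.0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SyntheticFixture:
    """Generate -> inject -> threshold -> label -> extract -> split.

    The per-channel threshold is the maximum window power over the
    ground-truth artefact-free windows, i.e. exactly the clean-epoch maximum
    a careful annotator would derive.
    """
    clean = generate_baseline(spec)
    contaminated, truth = inject_artefacts(clean, spec)
    grid = truth.grid
    powers = window_powers(contaminated, grid)
    thresholds = np.empty(contaminated.n_channels)
    for ch in range(contaminated.n_channels):
        clean_w = truth.labels[ch] == 0
        if not clean_w.any():
            raise InsufficientDataError(f"channel {ch} has no artefact-free windows")
        thresholds[ch] = powers[ch, clean_w].max()
    threshold = ThresholdSpec(thresholds, provenance="derived_from_clean_epochs")
    labels = label_windows(contaminated, grid, threshold)
    segments = extract_segments(contaminated, labels, segment_seconds, clean_prefix_seconds)
    segments = split_segments(segments, fractions, seed=spec.seed)
    return SyntheticFixture(
        spec=spec, clean=clean, contaminated=contaminated, truth=truth,
        grid=grid, threshold=threshold, labels=labels, segments=segments,
    )


def make_fixture_dataset(
    spec: SynthSpec,
    segment_seconds: float = 4.0,
    clean_prefix_seconds: float = 1.0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SegmentSet:
    """The split :class:`SegmentSet` of the standard fixture pipeline."""
    return make_fixture(spec, segment_seconds, clean_prefix_seconds, fractions).segments
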