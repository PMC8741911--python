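"""Quantitative evaluation: horizon RMSE, training loss, periodograms and
window-power distribution summaries.

The headline error metric is the multi-step forecast RMSE

    RMSE = sqrt( sum_i sum_j (x_ij - xhat_ij)^2 / N )

over N test examples and S forecast samples each -- note the denominator is
N alone, so for i.i.d. residuals the value grows like sqrt(S).  The
per-point variant ``rmse / sqrt(S)`` is horizon-invariant and is reported
alongside for comparing grids with different output lengths.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .errors import DimensionError, InsufficientDataError, InvalidInputError
from .labelling import SegmentSet
from .replacement import recursive_forecast
from .signal_core import window_power

__all__ = [
    "EvalReport",
    "PowerSummary",
    "rmse",
    "rmse_per_point",
    "half_mse_loss",
    "evaluate_over_horizon",
    "periodogram",
    "power_distribution",
]

_QUANTILES = (5, 25, 50, 75, 95)


def _as_examples(x: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be an N x S matrix, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def rmse(forecasts: np.ndarray, truth: np.ndarray) -> float:
    """Horizon RMSE with denominator N (the number of examples)."""
    f = _as_examples(forecasts, "forecasts")
    t = _as_examples(truth, "truth")
    if f.shape != t.shape:
        raise DimensionError(f"shape mismatch: forecasts {f.shape} vs truth {t.shape}")
    return float(np.sqrt(np.sum((f - t) ** 2) / f.shape[0]))


def rmse_per_point(forecasts: np.ndarray, truth: np.ndarray) -> float:
    """Horizon-invariant variant: ``rmse / sqrt(S)``."""
    f = _as_examples(forecasts, "forecasts")
    return rmse(forecasts, truth) / np.sqrt(f.shape[1])


def half_mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Training loss: half the squared-error sum per time step, ``(1/2S) * sum``."""
    p = _as_examples(pred, "pred")
    t = _as_examples(truth, "truth")
    if p.shape != t.shape:
        raise DimensionError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return float(np.sum((p - t) ** 2) / (2.0 * p.shape[1]))


@dataclass
class EvalReport:
    """Forecast evaluation over a fixed horizon."""

    rmse: float
    rmse_per_point: float
    horizon: int
    n_examples: int
    per_example_sse: np.ndarray
    seconds_per_forecast: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise InvalidInputError("rmse cannot be negative")


def evaluate_over_horizon(
    model,
    test: SegmentSet | Sequence[np.ndarray],
    horizon: int,
) -> EvalReport:
    """Recursive-forecast each test segment and score the fixed horizon.

    Every segment contributes one example: the first ``input_len`` samples
    seed the recursion and the next ``horizon`` true samples are the target.
    Using one common horizon makes models with different output lengths
    comparable.
    """
    if isinstance(test, SegmentSet):
        segments = test.by_split("test") if test.split else test.clean_segments
    else:
        segments = list(test)
    if not segments:
        raise InsufficientDataError("empty test set")
    need = model.input_len + horizon
    forecasts, truths = [], []
    t0 = time.perf_counter()
    for seg in segments:
        seg = np.asarray(seg, dtype=np.float64).ravel()
        if seg.size < need:
            raise InsufficientDataError(
                f"test segment of {seg.size} samples shorter than input+horizon = {need}"
            )
        forecasts.append(recursive_forecast(model, seg[: model.input_len], horizon))
        truths.append(seg[model.input_len : need])
    elapsed = (time.perf_counter() - t0) / len(segments)
    F = np.stack(forecasts)
    T = np.stack(truths)
    return EvalReport(
        rmse=rmse(F, T),
        rmse_per_point=rmse_per_point(F, T),
        horizon=horizon,
        n_examples=len(segments),
        per_example_sse=np.sum((F - T) ** 2, axis=1),
        seconds_per_forecast=elapsed,
    )


def periodogram(
    signal: np.ndarray,
    fs: float,
    db: bool = True,
    floor_db: float = -120.0,
    window: str = "boxcar",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram; power in dB by default.

    Uses 'spectrum' scaling so the linear power bins sum to the signal's
    mean square (Parseval); zero-power bins are floored at ``floor_db``.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if x.size < 8:
        raise InvalidInputError(f"periodogram needs >= 8 samples, got {x.size}")
    freqs, power = scipy.signal.periodogram(x, fs=fs, window=window, scaling="spectrum")
    if not db:
        return freqs, power
    with np.errstate(divide="ignore"):
        pdb = 10.0 * np.log10(power)
    return freqs, np.maximum(pdb, floor_db)


@dataclass
class PowerSummary:
    """Per-segment power quantiles for one signal group."""

    label: str
    powers: np.ndarray
    quantiles: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=np.float64)
        if self.powers.size == 0:
            raise InvalidInputError(f"group {self.label!r} is empty")
        if not self.quantiles:
            vals = np.percentile(self.powers, _QUANTILES)
            self.quantiles = {q: float(v) for q, v in zip(_QUANTILES, vals)}

    @property
    def median(self) -> float:
        return self.quantiles[50]


def power_distribution(
    groups: Mapping[str, Sequence[np.ndarray]],
) -> list[PowerSummary]:
    """Mean-squared power per segment, summarised by quantiles per group.

    Typical groups are ``normal`` (artefact-free), ``artefactual`` (before
    replacement) and ``replaced`` (after); a successful replacement pulls
    the replaced distribution down toward the normal one.
    """
    out = []
    for label, segments in groups.items():
        if not len(segments):
            raise InvalidInputError(f"group {label!r} is empty")
        powers = np.array([window_power(s) for s in segments])
        out.append(PowerSummary(label=label, powers=powers))
    return out
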