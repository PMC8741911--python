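"""Recursive sliding-window forecasting and in-place artefact substitution.

The sliding-window recursion uses the model's own output as part of the next
context: each call forecasts ``output_len`` samples, the context advances
over them, and the final call is truncated to the remaining horizon.  During
substitution, a run of consecutive artefact windows is replaced by one
recursion seeded from the samples immediately preceding the run; windows
replaced earlier contribute their forecast values to later contexts, so the
method stays channel-independent end to end.  Artefact-free samples are
never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .errors import InvalidInputError, PropagationError, ShapeError
from .labelling import LabelArray
from .signal_core import Recording

__all__ = ["ReplacementLog", "recursive_forecast", "replace_artefacts"]


@dataclass
class ChannelLog:
    replaced: list[int] = field(default_factory=list)
    unreplaceable: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class ReplacementLog:
    """Bookkeeping of which artefact windows were (not) replaced, per channel."""

    channels: dict[int, ChannelLog] = field(default_factory=dict)
    context_len: int = 0
    model_description: str = ""

    def channel(self, ch: int) -> ChannelLog:
        return self.channels.setdefault(ch, ChannelLog())

    @property
    def n_replaced(self) -> int:
        return sum(len(c.replaced) for c in self.channels.values())

    @property
    def n_unreplaceable(self) -> int:
        return sum(len(c.unreplaceable) for c in self.channels.values())


def recursive_forecast(model, context: np.ndarray, horizon: int) -> np.ndarray:
    """Forecast ``horizon`` samples by feeding predictions back into the context.

    Invokes ``model.forecast`` exactly ``ceil(horizon / output_len)`` times;
    the last call's output is truncated to the remaining horizon.
    """
    ctx = np.asarray(context, dtype=np.float64).ravel()
    if ctx.size != model.input_len:
        raise ShapeError(f"context of {ctx.size} samples, model expects {model.input_len}")
    if horizon < 1:
        raise InvalidInputError(f"horizon must be >= 1, got {horizon}")
    out = np.empty(horizon)
    filled = 0
    step = 0
    while filled < horizon:
        pred = np.asarray(model.forecast(ctx), dtype=np.float64).ravel()
        if not np.all(np.isfinite(pred)):
            raise PropagationError(f"non-finite forecast at recursion step {step}")
        take = min(pred.size, horizon - filled)
        out[filled : filled + take] = pred[:take]
        filled += take
        ctx = np.concatenate([ctx, pred])[-model.input_len :]
        step += 1
    return out


def _artefact_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """(start_window, n_windows) for each maximal run of consecutive labels 1."""
    idx = np.flatnonzero(row)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e] - idx[s] + 1)) for s, e in zip(starts, ends)]


def replace_artefacts(
    recording: Recording,
    labels: LabelArray,
    model,
    context_len: int | None = None,
    max_run_windows: int | None = None,
) -> tuple[Recording, ReplacementLog]:
    """Overwrite every artefact-labelled window with recursive forecasts.

    Each artefact run is forecast in one recursion from the ``context_len``
    samples immediately preceding it in the (progressively cleaned) channel.
    Runs whose context would extend before the start of the recording are
    logged unreplaceable and left unchanged.  All other samples are
    bit-identical to the input.

    Runs longer than ``max_run_windows`` (default: no limit) are still
    replaced but emit a warning: pure recursion compounds forecast error, so
    very long substitutions drift toward the process mean.
    """
    context_len = int(context_len or model.input_len)
    if context_len != model.input_len:
        raise ShapeError(
            f"context_len {context_len} does not match model input_len {model.input_len}"
        )
    if labels.n_channels != recording.n_channels:
        raise ShapeError("label array channel count does not match recording")
    w = labels.grid.window_len
    cleaned = recording.data.copy()
    log = ReplacementLog(
        context_len=context_len,
        model_description=f"{type(model).__name__}({model.input_len}->{model.output_len})",
    )
    for ch in range(recording.n_channels):
        chlog = log.channel(ch)
        for start_w, n_runs in _artefact_runs(labels.labels[ch]):
            start = start_w * w
            windows = list(range(start_w, start_w + n_runs))
            if start < context_len:
                chlog.unreplaceable.extend(
                    (wi, "insufficient context before run") for wi in windows
                )
                continue
            if max_run_windows is not None and n_runs > max_run_windows:
                warnings.warn(
                    f"channel {ch}: artefact run of {n_runs} windows exceeds "
                    f"max_run_windows={max_run_windows}; recursive forecast error compounds",
                    stacklevel=2,
                )
            ctx = cleaned[ch, start - context_len : start]
            pred = recursive_forecast(model, ctx, n_runs * w)
            cleaned[ch, start : start + n_runs * w] = pred
            chlog.replaced.extend(windows)
    return dc_replace(recording, data=cleaned), log
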