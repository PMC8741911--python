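"""Forecasting models: single-hidden-layer LSTM, dilated CNN-LSTM, and the
linear ARMAX baseline (see :mod:`lfpclean.armax`).

All network forecasters share one contract: a context of ``input_len``
consecutive samples maps to ``output_len`` future samples.  The plain LSTM
follows the one-tenth rule -- the hidden layer has ``round(input_len / 10)``
units -- with a linear read-out.  The CNN-LSTM stacks causal dilated
convolutions (kernel 5, 32 filters, dilations 1, 2, 4, 8, 16), stride-5
temporal downsampling, then GRU(128) -> LSTM(64) -> dropout -> LSTM(32) ->
dropout -> linear regression output.

Training minimises the half-mean-squared-error of the predicted responses
per time step, ``loss = (1 / 2S) * sum_ij (x_ij - xhat_ij)^2``, with Adam
(first-moment decay 0.9, initial learning rate 1e-4).  Inputs and targets
are z-scored with training-set statistics; forecasts are returned
de-normalised in millivolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._autodiff import Tensor
from ._layers import (
    Adam,
    BatchNorm,
    CausalConv1d,
    Dense,
    Dropout,
    EluActivation,
    GRULayer,
    Identity,
    Layer,
    LSTMLayer,
    StridePool,
)
from .errors import (
    ArchitectureError,
    DivergenceError,
    InsufficientDataError,
    InvalidInputError,
    ShapeError,
)
from .labelling import SegmentSet

__all__ = [
    "LstmCellParams",
    "lstm_cell_step",
    "ForecastModelSpec",
    "TrainConfig",
    "TrainingHistory",
    "NeuralForecaster",
    "build_lstm",
    "build_cnn_lstm",
    "build_custom",
    "train_forecaster",
    "forecast",
]


# ---------------------------------------------------------------------------
# The LSTM cell, stated with one weight matrix per gate.
# ---------------------------------------------------------------------------
@dataclass
class LstmCellParams:
    """Weights of a single LSTM cell with explicit per-gate matrices.

    The forget gate decides what is kept from the previous cell state:
    ``f_t = sigma(W_fh h_{t-1} + W_fx x_t + b_f)``; a value of 1 preserves
    the stored information, 0 discards it.  After :func:`lstm_cell_step` the
    gate activations of the last step are retained for inspection.
    """

    W_fh: np.ndarray
    W_fx: np.ndarray
    W_ih: np.ndarray
    W_ix: np.ndarray
    W_ch: np.ndarray
    W_cx: np.ndarray
    W_oh: np.ndarray
    W_ox: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    # gate values at the most recent step (filled by lstm_cell_step)
    f_t: np.ndarray | None = None
    i_t: np.ndarray | None = None
    c_tilde_t: np.ndarray | None = None
    o_t: np.ndarray | None = None

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LstmCellParams":
        z = np.zeros
        return cls(
            z((hidden, hidden)), z((hidden, inputs)),
            z((hidden, hidden)), z((hidden, inputs)),
            z((hidden, hidden)), z((hidden, inputs)),
            z((hidden, hidden)), z((hidden, inputs)),
            z(hidden), z(hidden), z(hidden), z(hidden),
        )

    @classmethod
    def from_fused(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray) -> "LstmCellParams":
        """Unpack the fused (f, i, c~, o) weights used by :class:`LSTMLayer`."""
        H = Wh.shape[0]
        s = [slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H), slice(3 * H, 4 * H)]
        return cls(
            Wh[:, s[0]].T, Wx[:, s[0]].T,
            Wh[:, s[1]].T, Wx[:, s[1]].T,
            Wh[:, s[2]].T, Wx[:, s[2]].T,
            Wh[:, s[3]].T, Wx[:, s[3]].T,
            b[s[0]], b[s[1]], b[s[2]], b[s[3]],
        )


def _sigma(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LstmCellParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns ``(h_t, c_t)``.

    Computes, in order: forget gate f, update gate i, cell input c~,
    new cell state ``c_t = f * c_{t-1} + i * c~``, output gate o and hidden
    state ``h_t = o * tanh(c_t)``.  Gate values are stored on ``params``.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=np.float64))
    H, D = params.W_fx.shape
    if x_t.shape != (D,) or h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ShapeError(
            f"cell expects x ({D},), h ({H},), c ({H},); got {x_t.shape}, {h_prev.shape}, {c_prev.shape}"
        )
    f = _sigma(params.W_fh @ h_prev + params.W_fx @ x_t + params.b_f)
    i = _sigma(params.W_ih @ h_prev + params.W_ix @ x_t + params.b_i)
    c_tilde = np.tanh(params.W_ch @ h_prev + params.W_cx @ x_t + params.b_c)
    c_t = f * c_prev + i * c_tilde
    o = _sigma(params.W_oh @ h_prev + params.W_ox @ x_t + params.b_o)
    h_t = o * np.tanh(c_t)
    params.f_t, params.i_t, params.c_tilde_t, params.o_t = f, i, c_tilde, o
    return h_t, c_t


# ---------------------------------------------------------------------------
# Model specs and builders
# ---------------------------------------------------------------------------
Architecture = Literal["lstm", "cnn_lstm", "custom"]


@dataclass
class ForecastModelSpec:
    """Geometry of a sequence forecaster."""

    architecture: Architecture
    input_len: int
    output_len: int
    hidden_size: int | None = None

    def __post_init__(self) -> None:
        if self.output_len < 1 or self.input_len < self.output_len:
            raise InvalidInputError(
                f"need input_len >= output_len >= 1, got {self.input_len}, {self.output_len}"
            )


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the reference protocol: Adam with first-moment decay
    ("momentum") 0.9, initial learning rate 1e-4, and a batch size of 128
    (516 for the larger 2 kHz-style corpora).  ``seed`` drives batch
    shuffling; pass the same master seed to the model builders for fully
    reproducible runs.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    batch_size: int = 128
    max_epochs: int = 100
    validation_frequency: int = 1
    patience: int = 10
    stride: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise InvalidInputError("learning_rate must be > 0 and batch_size >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


@dataclass
class _Row:
    name: str
    description: str
    ops: list[Layer]


class NeuralForecaster:
    """A trained (or trainable) sequence regressor.

    Holds the layer stack as a list of named rows (so the architecture can
    be inspected like a layer table), the model spec, and the z-score
    normalisation fitted on the training set.
    """

    def __init__(self, spec: ForecastModelSpec, rows: list[_Row]):
        self.spec = spec
        self.rows = rows
        self.norm_mean = 0.0
        self.norm_std = 1.0
        self.trained = False

    # -- geometry ----------------------------------------------------------
    @property
    def input_len(self) -> int:
        return self.spec.input_len

    @property
    def output_len(self) -> int:
        return self.spec.output_len

    @property
    def layers(self) -> list[Layer]:
        return [op for row in self.rows for op in row.ops]

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def summary(self) -> list[tuple[int, str, str]]:
        """Layer table: (index, type, description) per architecture row."""
        return [(k + 1, row.name, row.description) for k, row in enumerate(self.rows)]

    # -- computation -------------------------------------------------------
    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def forecast(self, context: np.ndarray) -> np.ndarray:
        """Forecast ``output_len`` samples (mV) from an ``input_len`` context."""
        ctx = np.asarray(context, dtype=np.float64).ravel()
        if ctx.size != self.input_len:
            raise ShapeError(f"context of {ctx.size} samples, model expects {self.input_len}")
        z = (ctx - self.norm_mean) / self.norm_std
        out = self.forward(Tensor(z.reshape(1, -1, 1)), training=False)
        return out.data.ravel() * self.norm_std + self.norm_mean

    # -- serialisation -----------------------------------------------------
    def weights(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                out[f"layer{k:02d}_{layer.kind}_p{j}"] = p.data
            if isinstance(layer, BatchNorm):
                out[f"layer{k:02d}_running_mean"] = layer.running_mean
                out[f"layer{k:02d}_running_var"] = layer.running_var
        return out

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                key = f"layer{k:02d}_{layer.kind}_p{j}"
                if weights[key].shape != p.data.shape:
                    raise ShapeError(f"weight {key} has shape {weights[key].shape}, expected {p.data.shape}")
                p.data = np.array(weights[key], dtype=np.float64)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(weights[f"layer{k:02d}_running_mean"])
                layer.running_var = np.array(weights[f"layer{k:02d}_running_var"])


def build_lstm(spec: ForecastModelSpec, seed: int = 0) -> NeuralForecaster:
    """Input -> LSTM(round(input_len / 10)) -> linear output of ``output_len``."""
    if spec.architecture != "lstm":
        raise ArchitectureError(f"build_lstm called with architecture {spec.architecture!r}")
    hidden = spec.hidden_size or int(round(spec.input_len / 10))
    if hidden < 1:
        warnings.warn(
            f"input_len={spec.input_len} gives a hidden size below 1; clamping to 1",
            stacklevel=2,
        )
        hidden = 1
    spec.hidden_size = hidden
    rng = np.random.default_rng(seed)
    rows = [
        _Row("sequenceInput", f"{spec.input_len} samples", [Identity("sequenceInput")]),
        _Row("lstm", f"{hidden}", [LSTMLayer(1, hidden, rng)]),
        _Row("regression", f"{spec.output_len}", [Dense(hidden, spec.output_len, rng)]),
    ]
    return NeuralForecaster(spec, rows)


def build_cnn_lstm(spec: ForecastModelSpec, seed: int = 0) -> NeuralForecaster:
    """The 16-row convolutional-recurrent stack.

    Causal dilated convolutions realise the folded 2-D convolutions along
    time with a singleton second dimension; the size-1 stride-5 average
    pooling is stride-5 temporal subsampling.  The dilation-16 kernel spans
    65 samples, so contexts shorter than 80 samples are rejected.
    """
    if spec.architecture != "cnn_lstm":
        raise ArchitectureError(f"build_cnn_lstm called with architecture {spec.architecture!r}")
    if spec.input_len < 80:
        raise ArchitectureError(
            f"cnn_lstm needs input_len >= 80 for the dilation-16 kernels, got {spec.input_len}"
        )
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def conv(cin: int, d: int) -> CausalConv1d:
        return CausalConv1d(cin, 32, 5, d, rng)

    rows = [
        _Row("sequenceInput", f"{spec.input_len} samples", [Identity("sequenceInput")]),
        _Row("sequenceFolding", "-", [Identity("sequenceFolding")]),
        _Row("convolution2d", "size=5, filters=32, dilation=1", [conv(1, 1)]),
        _Row("batchNormalization+elu", "-", [BatchNorm(32), EluActivation()]),
        _Row("convolution2d+elu", "size=5, filters=32, dilation=2", [conv(32, 2), EluActivation()]),
        _Row("convolution2d+elu", "size=5, filters=32, dilation=4", [conv(32, 4), EluActivation()]),
        _Row("convolution2d+elu", "size=5, filters=32, dilation=8", [conv(32, 8), EluActivation()]),
        _Row("convolution2d+elu", "size=5, filters=32, dilation=16", [conv(32, 16), EluActivation()]),
        _Row("averagePooling2d", "size=1, stride=5", [StridePool(5)]),
        _Row("sequenceUnfolding", "with flattening", [Identity("sequenceUnfolding")]),
        _Row("gru", "128", [GRULayer(32, 128, rng, return_sequences=True)]),
        _Row("lstm", "64", [LSTMLayer(128, 64, rng, return_sequences=True)]),
        _Row("dropout", "0.25", [Dropout(0.25, drop_rng)]),
        _Row("lstm", "32", [LSTMLayer(64, 32, rng, return_sequences=False)]),
        _Row("dropout", "0.25", [Dropout(0.25, drop_rng)]),
        _Row("regression", f"{spec.output_len}", [Dense(32, spec.output_len, rng)]),
    ]
    return NeuralForecaster(spec, rows)


def build_custom(
    layer_stack: Sequence[dict],
    input_len: int,
    output_len: int,
    seed: int = 0,
) -> NeuralForecaster:
    """Build a forecaster from a user-provided layer-stack description.

    Each entry is a dict with a ``type`` key among ``lstm``, ``gru``,
    ``conv``, ``batchnorm``, ``elu``, ``dropout``, ``pool`` and ``dense``;
    the final layer must produce ``output_len`` features.  Recurrent layers
    return sequences unless they are the last recurrent layer in the stack.
    """
    spec = ForecastModelSpec("custom", input_len, output_len)
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    recurrent_idx = [k for k, d in enumerate(layer_stack) if d.get("type") in ("lstm", "gru")]
    if not recurrent_idx and not any(d.get("type") == "dense" for d in layer_stack):
        raise ArchitectureError("custom stack needs at least one lstm/gru/dense layer")
    rows: list[_Row] = [_Row("sequenceInput", f"{input_len} samples", [Identity("sequenceInput")])]
    features = 1
    sequence = True
    for k, desc in enumerate(layer_stack):
        kind = desc.get("type")
        if kind == "conv":
            layer = CausalConv1d(features, desc.get("filters", 32), desc.get("kernel", 5),
                                 desc.get("dilation", 1), rng)
            features = layer.filters
        elif kind == "batchnorm":
            layer = BatchNorm(features)
        elif kind == "elu":
            layer = EluActivation()
        elif kind == "dropout":
            layer = Dropout(desc.get("p", 0.25), drop_rng)
        elif kind == "pool":
            layer = StridePool(desc.get("stride", 5))
        elif kind in ("lstm", "gru"):
            if not sequence:
                raise ArchitectureError("recurrent layer after the sequence was collapsed")
            units = desc["units"]
            ret_seq = k != recurrent_idx[-1]
            cls = LSTMLayer if kind == "lstm" else GRULayer
            layer = cls(features, units, rng, return_sequences=ret_seq)
            features = units
            sequence = ret_seq
        elif kind == "dense":
            units = desc.get("units", output_len)
            layer = Dense(features, units, rng)
            features = units
        else:
            raise ArchitectureError(f"unknown layer type {kind!r}")
        rows.append(_Row(layer.kind, layer.describe(), [layer]))
    if features != output_len:
        rows.append(_Row("regression", f"{output_len}", [Dense(features, output_len, rng)]))
    else:
        rows[-1].name = "regression"
    return NeuralForecaster(spec, rows)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------
def make_examples(
    segments: Sequence[np.ndarray], input_len: int, output_len: int, stride: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Slice segments into (context, target) pairs with a sliding window."""
    stride = stride or output_len
    xs, ys = [], []
    need = input_len + output_len
    for seg in segments:
        seg = np.asarray(seg, dtype=np.float64).ravel()
        for start in range(0, seg.size - need + 1, stride):
            xs.append(seg[start : start + input_len])
            ys.append(seg[start + input_len : start + need])
    if not xs:
        raise InsufficientDataError(
            f"no training examples: segments shorter than input+output = {need} samples"
        )
    return np.stack(xs), np.stack(ys)


def _half_mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).sum() * (0.5 / target.shape[1])


def train_forecaster(
    model: NeuralForecaster,
    train: SegmentSet | Sequence[np.ndarray],
    val: SegmentSet | Sequence[np.ndarray],
    cfg: TrainConfig | None = None,
) -> tuple[NeuralForecaster, TrainingHistory]:
    """Train a network forecaster with Adam on the half-MSE loss.

    Segments are z-scored with training-set statistics (stored on the
    model); validation loss is computed every ``validation_frequency``
    epochs and early stopping restores the best validation weights after
    ``patience`` stagnant checks.
    """
    cfg = cfg or TrainConfig()
    train_segs = train.by_split("train") if isinstance(train, SegmentSet) and train.split else (
        train.clean_segments if isinstance(train, SegmentSet) else list(train))
    val_segs = val.by_split("val") if isinstance(val, SegmentSet) and val.split else (
        val.clean_segments if isinstance(val, SegmentSet) else list(val))
    if not train_segs or not val_segs:
        raise InsufficientDataError("empty training or validation set")

    X, Y = make_examples(train_segs, model.input_len, model.output_len, cfg.stride)
    Xv, Yv = make_examples(val_segs, model.input_len, model.output_len, cfg.stride)
    mu = float(np.mean(X))
    sd = float(np.std(X))
    if sd == 0.0:
        sd = 1.0
    model.norm_mean, model.norm_std = mu, sd
    X = (X - mu) / sd; Y = (Y - mu) / sd
    Xv = (Xv - mu) / sd; Yv = (Yv - mu) / sd

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate, beta1=cfg.beta1)
    history = TrainingHistory()
    best_val = np.inf
    best_weights: dict[str, np.ndarray] | None = None
    stagnant = 0

    def val_loss() -> float:
        out = model.forward(Tensor(Xv[:, :, None]), training=False)
        return float(_half_mse(out, Yv).data)

    n = X.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            out = model.forward(Tensor(X[idx][:, :, None]), training=True)
            loss = _half_mse(out, Y[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(lval)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if epoch % cfg.validation_frequency == 0 or epoch == cfg.max_epochs - 1:
            v = val_loss()
            if not np.isfinite(v):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            history.val_loss.append(v)
            if v < best_val:
                best_val = v
                best_weights = {k: w.copy() for k, w in model.weights().items()}
                history.best_epoch = epoch
                stagnant = 0
            else:
                stagnant += 1
                if stagnant >= cfg.patience:
                    history.stopped_epoch = epoch
                    break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.train_loss) - 1
    if best_weights is not None:
        model.load_weights(best_weights)
    model.trained = True
    return model, history


def forecast(model, context: np.ndarray) -> np.ndarray:
    """Forecast with any model exposing the ``forecast(context)`` contract."""
    return model.forecast(np.asarray(context, dtype=np.float64))
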