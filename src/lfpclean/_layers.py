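"""Network layers and the Adam optimiser for the forecasting models.

Dense, causal dilated convolution, batch normalisation and dropout are thin
autodiff compositions; the recurrent layers (LSTM, GRU) register as single
fused tape nodes whose backward pass is a hand-written
backpropagation-through-time loop in NumPy.  All parameters are float64
tensors initialised from a caller-supplied :class:`numpy.random.Generator`,
so model construction and training are fully seeded.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, custom_op, elu, sigmoid, tanh
from .errors import ShapeError

__all__ = [
    "Layer",
    "Dense",
    "LSTMLayer",
    "GRULayer",
    "CausalConv1d",
    "BatchNorm",
    "Dropout",
    "EluActivation",
    "StridePool",
    "Identity",
    "Adam",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters, a forward pass and a one-line description."""

    kind: str = "layer"

    def params(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor, training: bool = False) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> str:
        return ""

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())


class Identity(Layer):
    """Structural marker layer (sequence input / folding / unfolding)."""

    def __init__(self, kind: str, description: str = "-"):
        self.kind = kind
        self._desc = description

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return x

    def describe(self) -> str:
        return self._desc


class Dense(Layer):
    kind = "fullyConnected"

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.W = Tensor(_glorot(rng, in_features, out_features, (in_features, out_features)), requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[-1] != self.in_features:
            raise ShapeError(f"dense layer expects {self.in_features} features, got {x.data.shape[-1]}")
        return x @ self.W + self.b

    def describe(self) -> str:
        return f"{self.out_features}"


class LSTMLayer(Layer):
    """LSTM over a (batch, time, features) sequence.

    Gate order along the fused weight axis is forget, input, candidate,
    output, mirroring the cell equations: ``f = sigma(W_fh h + W_fx x + b_f)``
    and so on, with ``c_t = f c_{t-1} + i c~_t`` and ``h_t = o tanh(c_t)``.
    """

    kind = "lstm"

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        H = hidden_size
        self.Wx = Tensor(_glorot(rng, input_size, H, (input_size, 4 * H)), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, H, H, (H, 4 * H)), requires_grad=True)
        self.b = Tensor(np.zeros(4 * H), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def describe(self) -> str:
        return f"{self.hidden_size}"

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        X = x.data
        if X.ndim != 3 or X.shape[2] != self.input_size:
            raise ShapeError(f"lstm expects (batch, time, {self.input_size}), got {X.shape}")
        B, T, _ = X.shape
        H = self.hidden_size
        Wx, Wh, b = self.Wx.data, self.Wh.data, self.b.data
        pre = X.reshape(B * T, -1) @ Wx + b
        pre = pre.reshape(B, T, 4 * H)
        F = np.empty((B, T, H)); I = np.empty((B, T, H))
        G = np.empty((B, T, H)); O = np.empty((B, T, H))
        C = np.empty((B, T, H)); TC = np.empty((B, T, H))
        Hs = np.empty((B, T, H))
        h = np.zeros((B, H)); c = np.zeros((B, H))
        for t in range(T):
            z = pre[:, t] + h @ Wh
            f = 1.0 / (1.0 + np.exp(-z[:, :H]))
            i = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            F[:, t], I[:, t], G[:, t], O[:, t] = f, i, g, o
            C[:, t], TC[:, t], Hs[:, t] = c, tc, h
        value = Hs if self.return_sequences else Hs[:, -1]
        layer = self

        def back(dY: np.ndarray) -> None:
            dZ = np.empty((B, T, 4 * H))
            dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
            dWh = np.zeros_like(Wh)
            for t in range(T - 1, -1, -1):
                dh = dh_next.copy()
                if layer.return_sequences:
                    dh += dY[:, t]
                elif t == T - 1:
                    dh += dY
                f, i, g, o = F[:, t], I[:, t], G[:, t], O[:, t]
                tc = TC[:, t]
                c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
                h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc * tc)
                df = dc * c_prev
                di = dc * g
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [df * f * (1 - f), di * i * (1 - i), dg * (1 - g * g), do * o * (1 - o)],
                    axis=1,
                )
                dZ[:, t] = dz
                dWh += h_prev.T @ dz
                dh_next = dz @ Wh.T
            flat = dZ.reshape(B * T, 4 * H)
            layer.Wx.accumulate(X.reshape(B * T, -1).T @ flat)
            layer.Wh.accumulate(dWh)
            layer.b.accumulate(flat.sum(axis=0))
            x.accumulate((flat @ Wx.T).reshape(B, T, -1))

        return custom_op(value, (x, self.Wx, self.Wh, self.b), back)


class GRULayer(Layer):
    """GRU over a (batch, time, features) sequence; fused gate order z, r, n."""

    kind = "gru"

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        H = hidden_size
        self.Wx = Tensor(_glorot(rng, input_size, H, (input_size, 3 * H)), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, H, H, (H, 3 * H)), requires_grad=True)
        self.b = Tensor(np.zeros(3 * H), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def describe(self) -> str:
        return f"{self.hidden_size}"

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        X = x.data
        if X.ndim != 3 or X.shape[2] != self.input_size:
            raise ShapeError(f"gru expects (batch, time, {self.input_size}), got {X.shape}")
        B, T, _ = X.shape
        H = self.hidden_size
        Wx, Wh, b = self.Wx.data, self.Wh.data, self.b.data
        pre = (X.reshape(B * T, -1) @ Wx + b).reshape(B, T, 3 * H)
        Z = np.empty((B, T, H)); R = np.empty((B, T, H))
        N = np.empty((B, T, H)); HN = np.empty((B, T, H))
        Hs = np.empty((B, T, H))
        h = np.zeros((B, H))
        for t in range(T):
            hz = h @ Wh
            z = 1.0 / (1.0 + np.exp(-(pre[:, t, :H] + hz[:, :H])))
            r = 1.0 / (1.0 + np.exp(-(pre[:, t, H:2 * H] + hz[:, H:2 * H])))
            hn = hz[:, 2 * H:]
            n = np.tanh(pre[:, t, 2 * H:] + r * hn)
            h = (1.0 - z) * n + z * h
            Z[:, t], R[:, t], N[:, t], HN[:, t], Hs[:, t] = z, r, n, hn, h
        value = Hs if self.return_sequences else Hs[:, -1]
        layer = self

        def back(dY: np.ndarray) -> None:
            dX = np.empty((B, T, 3 * H))
            dWh = np.zeros_like(Wh)
            dh_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dh_next.copy()
                if layer.return_sequences:
                    dh += dY[:, t]
                elif t == T - 1:
                    dh += dY
                z, r, n, hn = Z[:, t], R[:, t], N[:, t], HN[:, t]
                h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
                dz = dh * (h_prev - n)
                dn = dh * (1.0 - z)
                dh_prev = dh * z
                dn_pre = dn * (1.0 - n * n)
                dr = dn_pre * hn
                dhn = dn_pre * r
                dz_pre = dz * z * (1.0 - z)
                dr_pre = dr * r * (1.0 - r)
                dxz = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
                dhz = np.concatenate([dz_pre, dr_pre, dhn], axis=1)
                dX[:, t] = dxz
                dWh += h_prev.T @ dhz
                dh_next = dh_prev + dhz @ Wh.T
            flat = dX.reshape(B * T, 3 * H)
            layer.Wx.accumulate(X.reshape(B * T, -1).T @ flat)
            layer.Wh.accumulate(dWh)
            layer.b.accumulate(flat.sum(axis=0))
            x.accumulate((flat @ Wx.T).reshape(B, T, -1))

        return custom_op(value, (x, self.Wx, self.Wh, self.b), back)


class CausalConv1d(Layer):
    """Dilated causal convolution along time on (batch, time, channels).

    Left-padded with zeros so output step t sees only inputs <= t; no future
    samples leak into a forecast.
    """

    kind = "convolution"

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size
        self.W = Tensor(_glorot(rng, fan_in, filters, (kernel_size, in_channels, filters)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def describe(self) -> str:
        return f"size={self.kernel_size}, filters={self.filters}, dilation={self.dilation}"

    @property
    def receptive_field(self) -> int:
        return (self.kernel_size - 1) * self.dilation + 1

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        X = x.data
        if X.ndim != 3 or X.shape[2] != self.in_channels:
            raise ShapeError(f"conv expects (batch, time, {self.in_channels}), got {X.shape}")
        B, T, _ = X.shape
        K, d = self.kernel_size, self.dilation
        pad = (K - 1) * d
        Xp = np.pad(X, ((0, 0), (pad, 0), (0, 0)))
        W, bvec = self.W.data, self.b.data
        Y = np.zeros((B, T, self.filters)) + bvec
        for j in range(K):
            Y += Xp[:, j * d : j * d + T, :] @ W[j]
        layer = self

        def back(dY: np.ndarray) -> None:
            dW = np.zeros_like(W)
            dXp = np.zeros_like(Xp)
            flat_dY = dY.reshape(B * T, -1)
            for j in range(K):
                seg = Xp[:, j * d : j * d + T, :].reshape(B * T, -1)
                dW[j] = seg.T @ flat_dY
                dXp[:, j * d : j * d + T, :] += dY @ W[j].T
            layer.W.accumulate(dW)
            layer.b.accumulate(flat_dY.sum(axis=0))
            x.accumulate(dXp[:, pad:, :])

        return custom_op(Y, (x, self.W, self.b), back)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, time) with running stats."""

    kind = "batchNormalization"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        X = x.data
        if training:
            mean = X.mean(axis=(0, 1))
            var = X.var(axis=(0, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (X - mean) * inv_std
        Y = self.gamma.data * xhat + self.beta.data
        layer = self
        m = X.shape[0] * X.shape[1]

        def back(dY: np.ndarray) -> None:
            layer.gamma.accumulate((dY * xhat).sum(axis=(0, 1)))
            layer.beta.accumulate(dY.sum(axis=(0, 1)))
            dxhat = dY * layer.gamma.data
            if training:
                dx = (inv_std / m) * (
                    m * dxhat
                    - dxhat.sum(axis=(0, 1))
                    - xhat * (dxhat * xhat).sum(axis=(0, 1))
                )
            else:
                dx = dxhat * inv_std
            x.accumulate(dx)

        return custom_op(Y, (x, self.gamma, self.beta), back)


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def describe(self) -> str:
        return f"{self.p}"

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class EluActivation(Layer):
    kind = "elu"

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return elu(x)


class StridePool(Layer):
    """Average pooling of size 1 with a stride: pure temporal subsampling."""

    kind = "averagePooling"

    def __init__(self, stride: int):
        self.stride = stride

    def describe(self) -> str:
        return f"size=1, stride={self.stride}"

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return x[:, :: self.stride, :]


class Adam:
    """Adam optimiser; beta1 is the first-moment (momentum) decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._m[k] = b1 * self._m[k] + (1 - b1) * p.grad
            self._v[k] = b2 * self._v[k] + (1 - b2) * p.grad ** 2
            mhat = self._m[k] / (1 - b1 ** self.t)
            vhat = self._v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
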