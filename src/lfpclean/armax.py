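"""ARMAX baseline: linear polynomial model fitted per forecasting context.

The model is ``A(q) y_t = sum_i B_i(q) x_ti + C(q) e(t)`` with
``A(q) = 1 + a_1 q^-1 + ... + a_na q^-na`` (so a pure AR(1) process
``y_t = 0.9 y_{t-1}`` has ``a_1 = -0.9``), ``C(q) = 1 + c_1 q^-1 + ...``
on the white-noise disturbance, and optional exogenous polynomials B_i.
With no reference channel (the default, channel-independent case) the model
reduces to ARMA, k = 0.

Pure-AR fits use exact least squares on the lagged design, which recovers
noise-free autoregressions to machine precision; fits with a moving-average
part are maximum-likelihood via statsmodels.  Forecasting is the standard
recursion with future disturbances set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, InvalidInputError

__all__ = ["ArmaxSpec", "fit_armax", "armax_forecast", "ArmaxForecaster"]

_AUTO_GRID = [(na, 0, 0) for na in (1, 2, 3, 4, 5, 8)] + [(na, 0, 1) for na in (1, 2, 4)]


@dataclass
class ArmaxSpec:
    """Fitted polynomial orders and coefficients."""

    n_a: int
    n_b: int
    n_c: int
    a: np.ndarray                       # a_1 .. a_na of A(q)
    b: list[np.ndarray] = field(default_factory=list)   # one vector per exogenous input
    c: np.ndarray = field(default_factory=lambda: np.empty(0))  # c_1 .. c_nc of C(q)
    k: int = 0                          # number of exogenous inputs
    noise_var: float = 0.0
    stable: bool = True

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.a.size != self.n_a or self.c.size != self.n_c:
            raise FitError("coefficient vector lengths do not match the stated orders")

    @property
    def ar_roots(self) -> np.ndarray:
        """Roots of the AR characteristic polynomial (stable iff all |root| < 1)."""
        if self.n_a == 0:
            return np.empty(0)
        return np.roots(np.concatenate([[1.0], self.a]))


def _ols_ar(y: np.ndarray, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares AR fit; returns (a coefficients, residuals)."""
    if y.size <= n_a:
        raise FitError(f"context of {y.size} samples cannot fit AR({n_a})")
    design = np.column_stack([y[n_a - j - 1 : y.size - j - 1] for j in range(n_a)])
    target = y[n_a:]
    try:
        phi, *_ = np.linalg.lstsq(design, target, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError(f"singular design in AR({n_a}) fit") from exc
    resid = target - design @ phi
    return -phi, resid


def fit_armax(
    context: np.ndarray,
    orders: tuple[int, int, int] | str = "auto",
    exog: np.ndarray | None = None,
) -> ArmaxSpec:
    """Fit an ARMA(X) model to a context vector.

    ``orders`` is ``(n_a, n_b, n_c)`` or ``"auto"``, which selects the
    orders by AIC over a small grid.  The context must be at least ten times
    the total number of estimated coefficients.
    """
    y = np.asarray(context, dtype=np.float64).ravel()
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("context contains non-finite samples")
    if orders == "auto":
        best: tuple[float, ArmaxSpec] | None = None
        for cand in _AUTO_GRID:
            if y.size < 10 * sum(cand) or y.size <= sum(cand) + 2:
                continue
            try:
                spec = fit_armax(y, cand, exog=exog)
            except FitError:
                continue
            n_params = sum(cand)
            n_eff = y.size - cand[0]
            aic = n_eff * np.log(max(spec.noise_var, 1e-300)) + 2 * n_params
            if best is None or aic < best[0]:
                best = (aic, spec)
        if best is None:
            raise FitError("automatic order selection found no feasible model")
        return best[1]

    n_a, n_b, n_c = orders
    if min(orders) < 0 or n_a + n_b + n_c == 0:
        raise FitError(f"invalid orders {orders}")
    k = 0 if exog is None else np.atleast_2d(exog).shape[1]
    if n_b > 0 and k == 0:
        raise FitError("n_b > 0 requires an exogenous input")
    if y.size < 10 * (n_a + n_b + n_c):
        raise FitError(
            f"context of {y.size} samples too short for orders {orders} "
            f"(need >= {10 * (n_a + n_b + n_c)})"
        )

    if n_c == 0 and k == 0:
        a, resid = _ols_ar(y, n_a)
        spec = ArmaxSpec(n_a, 0, 0, a, noise_var=float(np.mean(resid**2)))
    else:
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = SARIMAX(
                    y, exog=exog, order=(n_a, 0, n_c), trend="n",
                    enforce_stationarity=False, enforce_invertibility=False,
                ).fit(disp=False)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise FitError(f"ARMAX fit failed for orders {orders}: {exc}") from exc
        params = res.params
        pos = 0
        b: list[np.ndarray] = []
        for _ in range(k):
            b.append(np.array([params[pos]]))
            pos += 1
        phi = params[pos : pos + n_a]; pos += n_a
        theta = params[pos : pos + n_c]; pos += n_c
        spec = ArmaxSpec(
            n_a, n_b, n_c, -np.asarray(phi), b=b, c=np.asarray(theta), k=k,
            noise_var=float(params[-1]),
        )
    spec.stable = bool(np.all(np.abs(spec.ar_roots) < 1.0)) if n_a else True
    return spec


def armax_forecast(spec: ArmaxSpec, context: np.ndarray, horizon: int) -> np.ndarray:
    """Recursive multi-step forecast with future disturbances at zero.

    In-sample residuals are reconstructed on the context by inverse
    filtering so the moving-average terms seed the first forecast steps.
    """
    y = np.asarray(context, dtype=np.float64).ravel()
    if horizon < 1:
        raise InvalidInputError(f"horizon must be >= 1, got {horizon}")
    if y.size < max(spec.n_a, 1):
        raise InvalidInputError(f"context of {y.size} samples shorter than AR order {spec.n_a}")
    e = np.zeros(y.size)
    if spec.n_c > 0:
        for t in range(y.size):
            acc = y[t]
            for j in range(1, spec.n_a + 1):
                if t - j >= 0:
                    acc += spec.a[j - 1] * y[t - j]
            for j in range(1, spec.n_c + 1):
                if t - j >= 0:
                    acc -= spec.c[j - 1] * e[t - j]
            e[t] = acc
    hist = np.concatenate([y, np.zeros(horizon)])
    err = np.concatenate([e, np.zeros(horizon)])
    n = y.size
    for t in range(n, n + horizon):
        acc = 0.0
        for j in range(1, spec.n_a + 1):
            acc -= spec.a[j - 1] * hist[t - j]
        for j in range(1, spec.n_c + 1):
            acc += spec.c[j - 1] * err[t - j]
        hist[t] = acc
    return hist[n:]


class ArmaxForecaster:
    """Forecasting-contract wrapper that refits the polynomials per context.

    Matches how the linear baseline is used in practice: every new context
    re-estimates the model (with ``orders="auto"`` by default), then the
    recursion produces ``output_len`` samples.
    """

    def __init__(self, input_len: int, output_len: int,
                 orders: tuple[int, int, int] | str = "auto"):
        self.input_len = int(input_len)
        self.output_len = int(output_len)
        self.orders = orders
        self.last_spec: ArmaxSpec | None = None
        self.trained = True

    def forecast(self, context: np.ndarray) -> np.ndarray:
        ctx = np.asarray(context, dtype=np.float64).ravel()
        if ctx.size != self.input_len:
            raise InvalidInputError(
                f"context of {ctx.size} samples, forecaster expects {self.input_len}"
            )
        self.last_spec = fit_armax(ctx, self.orders)
        return armax_forecast(self.last_spec, ctx, self.output_len)
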