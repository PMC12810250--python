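"""Calcification dose-response models on the TA-DIC predictor.

Two response shapes are supported, mirroring how positive calcification
responders to alkalinity enhancement are classified:

* **linear** — the rate rises proportionally with TA-DIC: ``y = a + b x``.
* **threshold** — the rate is flat above a critical TA-DIC and drops
  steeply below it, modelled as the exponential-plateau curve
  ``y = c - b exp(-k x)`` (plateau ``c`` approached from below as x grows).

Fits are ordinary / nonlinear least squares.  Model selection keeps the
fit with the lowest p-value and discards species for which neither model
is significant at p < 0.05.  Prediction intervals use the two-tailed
t-distribution at alpha = 0.1 (90 % intervals); for the nonlinear model
the interval is the delta-method analogue of the OLS formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalcificationDataset",
    "FitResult",
    "PredictionBand",
    "FitError",
    "fit_linear",
    "fit_threshold",
    "select_model",
    "predict_with_interval",
    "calcification_decline",
    "threshold_model",
]

SIGNIFICANCE_LEVEL = 0.05  # model selection cut
PREDICTION_ALPHA = 0.1  # 90 % prediction intervals


class FitError(RuntimeError):
    """Degenerate design or non-convergent fit."""


@dataclass(frozen=True)
class CalcificationDataset:
    """Per-species experimental points: TA-DIC (umol/kg) vs calcification rate."""

    species: str
    group: str
    rate_unit: str
    x: np.ndarray  # TA-DIC, umol/kg
    y: np.ndarray  # calcification rate, rate_unit

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite TA-DIC values")
        if not self.rate_unit:
            raise ValueError("rate_unit must be non-empty")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class FitResult:
    """A fitted response model with the residual statistics needed for
    prediction intervals (standard error of the estimate ``s``, design
    moments, and the covariance factor for the delta method)."""

    model_kind: Literal["linear", "threshold"]
    params: tuple  # linear: (a, b); threshold: (c, b, k)
    n: int
    dof: int
    sse: float
    rmse: float
    se_estimate: float
    p_value: float
    x_mean: float
    sxx: float
    cov_unscaled: np.ndarray | None = None  # (J'J)^-1 for the threshold model

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model_kind == "linear":
            a, b = self.params
            out = a + b * x
        else:
            c, b, k = self.params
            out = threshold_model(x, c, b, k)
        return out if out.ndim else float(out)

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class PredictionBand:
    """90 % (by default) prediction interval at a single point."""

    x_star: float
    y_hat: float
    lower: float
    upper: float
    alpha: float = PREDICTION_ALPHA

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0


def threshold_model(x, c, b, k):
    """Exponential-plateau response: plateau c at high TA-DIC, drop below."""
    return c - b * np.exp(-k * np.asarray(x, dtype=float))


def fit_linear(data: CalcificationDataset) -> FitResult:
    """Closed-form OLS of rate on TA-DIC; p-value is the two-sided t-test
    on the slope (equivalently the regression F-test)."""
    x, y = data.x, data.y
    n = x.size
    if n < 3:
        raise FitError(f"{data.species}: need >= 3 points for a linear fit, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FitError(f"{data.species}: all TA-DIC values identical")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    dof = n - 2
    s2 = sse / dof
    se_slope = np.sqrt(s2 / sxx)
    if se_slope == 0.0:
        p = 0.0
    else:
        t = slope / se_slope
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return FitResult(
        model_kind="linear",
        params=(intercept, slope),
        n=n,
        dof=dof,
        sse=sse,
        rmse=float(np.sqrt(sse / n)),
        se_estimate=float(np.sqrt(s2)),
        p_value=p,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


def _threshold_starts(x, y):
    """Deterministic multi-start values (c0, b0, k0-grid) for the plateau fit."""
    c0 = float(np.max(y)) * 1.001 + 1e-12
    b_span = float(np.max(y) - np.min(y))
    b0 = b_span if b_span > 0 else abs(c0) * 0.1 + 1e-12
    # log-linearisation: log(c0 - y) ~ log(b) - k x  on points below the plateau
    mask = (c0 - y) > 0
    k0 = np.nan
    if mask.sum() >= 2:
        slope = np.polyfit(x[mask], np.log(c0 - y[mask]), 1)[0]
        if slope < 0:
            k0 = -slope
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    if not np.isfinite(k0) or k0 <= 0.01 / span:
        k0 = 2.0 / span
    return c0, b0, [k0 * 0.5, k0, k0 * 2.0]


def fit_threshold(data: CalcificationDataset) -> FitResult:
    """Nonlinear least squares of the exponential-plateau model, multi-start
    over the decay-rate initial value; p-value from the F-test against the
    intercept-only (flat) model."""
    x, y = data.x, data.y
    n = x.size
    if n < 4:
        raise FitError(f"{data.species}: need >= 4 points for a threshold fit")
    c0, b0, k0s = _threshold_starts(x, y)
    best = None
    for k0 in k0s:
        try:
            popt, pcov = optimize.curve_fit(
                threshold_model, x, y, p0=[c0, b0, k0],
                bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - threshold_model(x, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitError(f"{data.species}: threshold fit did not converge")
    popt, sse = best
    # canonicalise the degenerate flat solution: with k -> 0 the curve is
    # the constant c - b, indistinguishable from b = 0 at the plateau mean
    c_, b_, k_ = popt
    spread = b_ * (np.exp(-k_ * np.min(x)) - np.exp(-k_ * np.max(x)))
    if abs(spread) < 1e-9 * max(float(np.max(np.abs(y))), 1e-300):
        popt = np.array([float(np.mean(y)), 0.0, k_])
        resid = y - popt[0]
        sse = float(resid @ resid)
    dof = n - 3
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= sse or sse == 0.0:
        # flat data (or an exact fit): compare against the null directly
        p = 1.0 if sst <= sse else 0.0
    else:
        f = ((sst - sse) / 2.0) / (sse / dof)
        p = float(stats.f.sf(f, 2, dof))
    # unscaled covariance (J'J)^-1 for delta-method prediction intervals
    jac = _threshold_jacobian(x, *popt)
    jtj = jac.T @ jac
    try:
        cov_unscaled = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_unscaled = np.linalg.pinv(jtj)
    s2 = sse / dof
    return FitResult(
        model_kind="threshold",
        params=tuple(float(v) for v in popt),
        n=n,
        dof=dof,
        sse=sse,
        rmse=float(np.sqrt(sse / n)),
        se_estimate=float(np.sqrt(s2)),
        p_value=p,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        cov_unscaled=cov_unscaled,
    )


def _threshold_jacobian(x, c, b, k):
    e = np.exp(-k * np.asarray(x, dtype=float))
    return np.column_stack([np.ones_like(e), -e, b * x * e])


def select_model(*fits: FitResult | None) -> FitResult | None:
    """Keep the significant fit (p < 0.05) with the lowest p-value; ``None``
    (species excluded) when neither model is significant.  Failed fits may
    be passed as ``None`` and count as p = 1."""
    candidates = [f for f in fits if f is not None and f.significant]
    if not candidates:
        return None
    return min(candidates, key=lambda f: f.p_value)


def predict_with_interval(fit: FitResult, x_star: float,
                          alpha: float = PREDICTION_ALPHA) -> PredictionBand:
    """Prediction interval for a new observation at ``x_star``.

    Linear: yhat +- t_{1-alpha/2,dof} * s * sqrt(1 + 1/n + (x*-xbar)^2/Sxx).
    Threshold: the delta-method analogue with the model gradient g(x*),
    half-width t * s * sqrt(1 + g' (J'J)^-1 g).
    """
    if fit.dof < 1:
        raise FitError("prediction interval undefined with dof < 1")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, fit.dof)
    y_hat = float(fit.predict(x_star))
    s = fit.se_estimate
    if fit.model_kind == "linear":
        lever = 1.0 + 1.0 / fit.n + (x_star - fit.x_mean) ** 2 / fit.sxx
    else:
        g = _threshold_jacobian(np.array([x_star]), *fit.params)[0]
        lever = 1.0 + float(g @ fit.cov_unscaled @ g)
    half = float(t_crit * s * np.sqrt(lever))
    return PredictionBand(x_star=float(x_star), y_hat=y_hat,
                          lower=y_hat - half, upper=y_hat + half, alpha=alpha)


def calcification_decline(fit: FitResult, x_current: float, x_pi: float) -> float:
    """Percent decline in calcification from the preindustrial TA-DIC
    ``x_pi`` to the current ``x_current``: 100 (1 - yhat(now)/yhat(PI)).

    Negative values (rates higher now than preindustrially) are reported
    as-is, not clamped.
    """
    y_pi = float(fit.predict(x_pi))
    if y_pi <= 0:
        raise FitError(
            f"predicted preindustrial rate {y_pi:.3g} <= 0; decline undefined"
        )
    y_now = float(fit.predict(x_current))
    return 100.0 * (1.0 - y_now / y_pi)
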