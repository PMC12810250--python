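"""Mitigation time of alkalinity enhancement on monthly chemistry series.

A continuous TA treatment offsets a declining carbonate-chemistry series;
the *mitigation time* is how many years of the ongoing acidification
trend that offset buys:

    mitigation time = mean(treated - unperturbed) / |trend slope of unperturbed|

computed on 12-month-smoothed series so the seasonal cycle cancels.  The
treatment is applied as an instantaneous equilibrated perturbation each
month (TA up by dTA, DIC up by f*eta*dTA), with pH and aragonite
saturation re-solved through the carbonate engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .carbonate import SeawaterConditions, compute_constants, solve_from_ta_dic
from .response import FitResult
from .scenarios import OAEScenario

__all__ = [
    "MonthlySeries",
    "MitigationResult",
    "smooth_12mo",
    "apply_oae_treatment",
    "trend_slope",
    "mitigation_time",
    "calcification_series",
]

MIN_SLOPE = 1e-6  # below this (units/yr) mitigation time is undefined


@dataclass
class MonthlySeries:
    """Monthly surface-chemistry series: decimal-year time, TA and DIC
    (umol/kg), and the physical conditions (shared by all months)."""

    time: np.ndarray
    ta: np.ndarray
    dic: np.ndarray
    conditions: SeawaterConditions = field(default_factory=SeawaterConditions)
    _derived: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ta = np.asarray(self.ta, dtype=float)
        self.dic = np.asarray(self.dic, dtype=float)
        if not (self.time.size == self.ta.size == self.dic.size):
            raise ValueError("time, ta, dic must have equal lengths")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def tadic(self) -> np.ndarray:
        return self.ta - self.dic

    def _solve_all(self) -> None:
        k = compute_constants(self.conditions)
        ph = np.empty(self.n)
        omega = np.empty(self.n)
        for i in range(self.n):
            st = solve_from_ta_dic(self.ta[i], self.dic[i], self.conditions,
                                   constants=k)
            ph[i] = st.ph_total
            omega[i] = st.omega_ar
        self._derived["ph"] = ph
        self._derived["omega_ar"] = omega

    @property
    def ph(self) -> np.ndarray:
        if "ph" not in self._derived:
            self._solve_all()
        return self._derived["ph"]

    @property
    def omega_ar(self) -> np.ndarray:
        if "omega_ar" not in self._derived:
            self._solve_all()
        return self._derived["omega_ar"]

    def variable(self, name: str) -> np.ndarray:
        if name == "tadic":
            return self.tadic
        if name == "ph":
            return self.ph
        if name == "omega_ar":
            return self.omega_ar
        raise KeyError(f"unknown series variable {name!r}")


@dataclass(frozen=True)
class MitigationResult:
    """Eq.-style mitigation statistic for one variable and treatment."""

    variable: str
    delta_ta: float
    mean_offset: float  # mean(treated - unperturbed), variable units
    slope: float  # unperturbed trend, variable units / yr
    years: float  # |mean_offset / slope|


def smooth_12mo(values: np.ndarray, time: np.ndarray | None = None):
    """Centered 12-month moving average (window [t-6, t+5]); the six
    months at each end that lack a full window are trimmed.

    Returns the smoothed values, or ``(time_trimmed, smoothed)`` when a
    time vector is supplied.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 24:
        raise ValueError(f"need >= 24 months to smooth, got {values.size}")
    kernel = np.full(12, 1.0 / 12.0)
    sm = np.convolve(values, kernel, mode="valid")  # length n - 11
    # valid window j covers values[j : j+12]; centering it at index j+6
    # realises the [t-6, t+5] window.  Trimmed index range: 6 .. n-6.
    if time is None:
        return sm
    time = np.asarray(time, dtype=float)
    return time[6:values.size - 5], sm


def apply_oae_treatment(series: MonthlySeries, delta_ta: float,
                        scenario: OAEScenario) -> MonthlySeries:
    """Continuously treated copy of the series: each month TA rises by
    ``delta_ta`` and DIC by ``f * eta * delta_ta`` (equilibrated CO2
    influx).  Only equilibrated scenarios are meaningful here."""
    if not scenario.equilibrated:
        raise ValueError("series treatment assumes an equilibrated scenario")
    if delta_ta < 0:
        raise ValueError("delta_ta must be >= 0")
    f, eta = scenario.cdr_efficiency, scenario.eta_max
    if scenario.reagent == "NaOH":
        dic_add = f * eta * delta_ta
    else:
        # dose in TA-equivalents: the reagent itself carries half a unit of
        # DIC per TA-equivalent; the air-sea influx closes the rest
        dic_add = (0.5 + f * (eta - 0.5)) * delta_ta
    return MonthlySeries(
        time=series.time.copy(),
        ta=series.ta + delta_ta,
        dic=series.dic + dic_add,
        conditions=series.conditions,
    )


def trend_slope(time: np.ndarray, values: np.ndarray):
    """OLS trend of a (smoothed) series vs decimal time.

    Returns ``(slope, p_value)`` in units/yr.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.size < 3 or np.ptp(time) == 0:
        raise ValueError("degenerate time vector")
    res = stats.linregress(time, values)
    return float(res.slope), float(res.pvalue)


def mitigation_time(treated: MonthlySeries, unperturbed: MonthlySeries,
                    variable: Literal["tadic", "ph", "omega_ar"] = "tadic",
                    delta_ta: float | None = None) -> MitigationResult:
    """Years of the unperturbed trend offset by the treatment.

    Both series are smoothed with the centered 12-month window; the mean
    treated-minus-unperturbed difference over the common months is divided
    by the magnitude of the unperturbed trend slope.  Positive offsets on
    a declining trend read as years of acidification undone.
    """
    if treated.n != unperturbed.n or not np.allclose(treated.time,
                                                     unperturbed.time):
        raise ValueError("series are not aligned in time")
    t_sm, base_sm = smooth_12mo(unperturbed.variable(variable),
                                unperturbed.time)
    treat_sm = smooth_12mo(treated.variable(variable))
    if delta_ta is None:
        delta_ta = float(np.mean(treated.ta - unperturbed.ta))
    return _assemble(variable, delta_ta, t_sm, base_sm, treat_sm)


def _assemble(variable: str, delta_ta: float, t_sm, base_sm,
              treat_sm) -> MitigationResult:
    slope, _ = trend_slope(t_sm, base_sm)
    offset = float(np.mean(treat_sm - base_sm))
    if abs(slope) < MIN_SLOPE:
        if abs(offset) < 1e-9:
            # untreated (or inert) variable on a flat trend: nothing to undo
            return MitigationResult(variable, float(delta_ta), offset, slope, 0.0)
        raise ValueError(
            f"unperturbed {variable} slope {slope:.2e}/yr below {MIN_SLOPE}; "
            "mitigation time undefined"
        )
    return MitigationResult(
        variable=variable,
        delta_ta=float(delta_ta),
        mean_offset=offset,
        slope=slope,
        years=abs(offset / slope),
    )


def mitigation_time_calcification(treated: MonthlySeries,
                                  unperturbed: MonthlySeries,
                                  fit: FitResult,
                                  delta_ta: float | None = None,
                                  ) -> MitigationResult:
    """Mitigation time of the calcification-rate series implied by a
    fitted response model applied to the TA-DIC series."""
    t_sm, base_sm = smooth_12mo(
        calcification_series(unperturbed, fit), unperturbed.time)
    treat_sm = smooth_12mo(calcification_series(treated, fit))
    if delta_ta is None:
        delta_ta = float(np.mean(treated.ta - unperturbed.ta))
    return _assemble("calcification", delta_ta, t_sm, base_sm, treat_sm)


def calcification_series(series: MonthlySeries, fit: FitResult) -> np.ndarray:
    """Per-month predicted calcification rate from the TA-DIC series."""
    return np.asarray(fit.predict(series.tadic), dtype=float)
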