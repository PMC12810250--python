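"""Synthetic inputs with known ground truth.

Three generators cover every input the analysis consumes:

* :func:`gen_experiment` — per-species dose-response experiments
  (TA-DIC design levels vs noisy calcification rates) with chemistry
  realized as solver-consistent (TA, DIC) pairs;
* :func:`gen_series` — a monthly surface-chemistry series with a secular
  TA-DIC decline, seasonal cycle and noise, emulating the shape of the
  observational 1982-2022 surface-ocean reconstructions;
* :func:`gen_grid` — a small lat-lon field with a latitudinal
  temperature gradient and coastal/polar masks for area-weighted
  efficiency means.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import xarray as xr

from .carbonate import SeawaterConditions, compute_constants, solve_from_ta_dic
from .mitigation import MonthlySeries
from .response import CalcificationDataset, threshold_model

__all__ = ["ExperimentSpec", "SeriesSpec", "gen_experiment", "gen_series",
           "gen_grid"]

# default experiment design: 6 TA-DIC levels x 3 replicates, the typical
# span of published OA perturbation experiments
DEFAULT_DESIGN = (120.0, 180.0, 240.0, 300.0, 360.0, 420.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """Ground truth for one synthetic calcification experiment."""

    response: Literal["linear", "threshold"] = "linear"
    # linear: (intercept, slope); threshold: (plateau c, amplitude b, rate k)
    true_params: tuple = (0.5, 0.01)
    design: Sequence[float] = DEFAULT_DESIGN
    replicates: int = 3
    noise_sd: float = 0.02  # fraction of the mean true rate
    noise_model: Literal["gaussian", "lognormal"] = "gaussian"
    seed: int = 0
    species: str = "synthetic sp."
    group: str = "synthetic"
    rate_unit: str = "mmol/g/h"
    ta: float = 2300.0  # umol/kg, fixed; DIC realizes each design TA-DIC
    conditions: SeawaterConditions = field(default_factory=SeawaterConditions)

    def __post_init__(self):
        d = np.asarray(self.design, dtype=float)
        if d.size < 2 or np.ptp(d) < 60.0:
            raise ValueError("design must span >= 60 umol/kg of TA-DIC")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def true_rate(self, x):
        x = np.asarray(x, dtype=float)
        if self.response == "linear":
            a, b = self.true_params
            return a + b * x
        c, b, k = self.true_params
        return threshold_model(x, c, b, k)


def gen_experiment(spec: ExperimentSpec) -> CalcificationDataset:
    """Noisy rates at each design TA-DIC level; each level's chemistry is
    checked solver-consistent (the (ta, ta - tadic) pair converges)."""
    rng = np.random.default_rng(spec.seed)
    k = compute_constants(spec.conditions)
    for tadic in spec.design:
        # raises if outside solver validity
        solve_from_ta_dic(spec.ta, spec.ta - tadic, spec.conditions, constants=k)
    x = np.repeat(np.asarray(spec.design, dtype=float), spec.replicates)
    mu = spec.true_rate(x)
    sd = spec.noise_sd * float(np.mean(np.abs(spec.true_rate(
        np.asarray(spec.design, dtype=float)))))
    if sd == 0.0:
        y = mu
    elif spec.noise_model == "gaussian":
        y = mu + rng.normal(0.0, sd, size=x.size)
    else:
        # multiplicative lognormal with the same coefficient of variation
        cv = sd / np.maximum(np.abs(mu), 1e-300)
        sigma = np.sqrt(np.log1p(cv**2))
        y = mu * rng.lognormal(-sigma**2 / 2.0, sigma, size=x.size)
    return CalcificationDataset(species=spec.species, group=spec.group,
                                rate_unit=spec.rate_unit, x=x, y=y)


@dataclass(frozen=True)
class SeriesSpec:
    """Ground truth for a synthetic monthly chemistry series.

    The default secular TA-DIC trend of -0.73 umol/kg/yr is of the
    magnitude observational surface-ocean reconstructions show for recent
    decades; seasonal amplitude and monthly noise defaults are typical
    open-ocean values.
    """

    start_year: int = 1982
    end_year: int = 2022
    ta0: float = 2300.0
    dic0: float = 2070.0  # TA-DIC starts at ta0 - dic0
    tadic_trend: float = -0.73  # umol/kg/yr, applied via rising DIC
    seasonal_amplitude: float = 8.0  # umol/kg
    noise_sd: float = 2.0  # umol/kg
    seed: int = 0
    conditions: SeawaterConditions = field(default_factory=SeawaterConditions)


def gen_series(spec: SeriesSpec) -> MonthlySeries:
    """Monthly series with tadic(t) = tadic0 + trend*t + seasonal + noise,
    decomposed as constant TA and DIC = TA - tadic (the secular signal is
    carried entirely by DIC, as over the industrial era)."""
    rng = np.random.default_rng(spec.seed)
    n_months = (spec.end_year - spec.start_year + 1) * 12
    t = spec.start_year + (np.arange(n_months) + 0.5) / 12.0
    elapsed = t - t[0]
    tadic0 = spec.ta0 - spec.dic0
    tadic = (
        tadic0
        + spec.tadic_trend * elapsed
        + spec.seasonal_amplitude * np.sin(2.0 * np.pi * (t - np.floor(t)))
        + (rng.normal(0.0, spec.noise_sd, size=n_months)
           if spec.noise_sd > 0 else 0.0)
    )
    ta = np.full(n_months, spec.ta0)
    return MonthlySeries(time=t, ta=ta, dic=ta - tadic,
                         conditions=spec.conditions)


def gen_grid(nlat: int = 9, nlon: int = 8, seed: int = 0) -> xr.Dataset:
    """Small cell-centered lat-lon surface field with TA, DIC, T, S,
    cos-lat weights and boolean coastal/polar masks.

    Temperature falls from a warm equator to cold poles; the coastal flag
    marks the two easternmost longitude columns (a synthetic shoreline);
    polar cells are those with |lat| >= 60 degrees.
    """
    if nlat < 2 or nlon < 2:
        raise ValueError("need nlat, nlon >= 2")
    rng = np.random.default_rng(seed)
    lat = np.linspace(-90.0, 90.0, nlat + 1)
    lat = (lat[:-1] + lat[1:]) / 2.0
    lon = np.linspace(0.0, 360.0, nlon + 1)
    lon = (lon[:-1] + lon[1:]) / 2.0
    lat2d = np.broadcast_to(lat[:, None], (nlat, nlon))
    temp = 28.0 - 26.0 * (np.abs(lat2d) / 90.0) ** 1.5
    temp = temp + rng.normal(0.0, 0.3, size=temp.shape)
    sal = 34.0 + 1.5 * np.cos(np.deg2rad(lat2d)) + rng.normal(
        0.0, 0.1, size=temp.shape)
    ta = 2300.0 + 60.0 * (sal - 35.0)
    dic = ta - (150.0 + 120.0 * np.cos(np.deg2rad(lat2d)) ** 2
                + rng.normal(0.0, 5.0, size=temp.shape))
    coastal = np.zeros((nlat, nlon), dtype=bool)
    coastal[:, -2:] = True
    polar = np.abs(lat2d) >= 60.0
    return xr.Dataset(
        {
            "ta": (("lat", "lon"), ta),
            "dic": (("lat", "lon"), dic),
            "temperature": (("lat", "lon"), temp),
            "salinity": (("lat", "lon"), sal),
            "coastal": (("lat", "lon"), coastal),
            "polar": (("lat", "lon"), polar),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"description": "synthetic surface carbonate-chemistry field"},
    )
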