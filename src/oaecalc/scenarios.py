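"""Alkalinity-enhancement scenarios: preindustrial targets, restoration
doses, and responsiveness of calcification to a fixed TA addition.

Scenario algebra
----------------
The working variable is TA-DIC.  Adding ``dTA`` umol/kg of alkalinity
changes it by ``factor * dTA``, where the factor depends on the reagent
stoichiometry and on whether the parcel re-equilibrates with the
atmosphere:

* NaOH adds TA only.  Unequilibrated: d(TA-DIC)/dTA = 1.  With
  equilibration, atmospheric CO2 influx adds ``f * eta`` of DIC per unit
  TA (``eta`` the maximum uptake efficiency, ``f`` the realized CDR
  efficiency), so the factor is ``1 - f*eta``.
* Na2CO3 supplies 2 TA-equivalents and 1 mole of DIC per mole, i.e. half
  a unit of DIC per unit of TA: unequilibrated factor 1/2; equilibrated
  ``1/2 - f*(eta - 1/2)``.

Defaults follow the study conditions: f = 0.8, regional eta of 0.832
(coastal) and 0.904 (polar), atmosphere-driven preindustrial offset of
142 uatm (420 current minus 278 preindustrial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .carbonate import (
    CarbonateState,
    SeawaterConditions,
    solve_from_ta_dic,
    solve_from_ta_pco2,
)
from .response import FitResult, predict_with_interval

__all__ = [
    "OAEScenario",
    "SpeciesControl",
    "RestorationResult",
    "SpeciesSummary",
    "ScenarioConfig",
    "DEFAULT_CONFIG",
    "preindustrial_state",
    "tadic_change_per_unit_ta",
    "required_ta_addition",
    "required_ta_exact_equilibrated",
    "calcification_responsiveness",
    "build_species_summary",
    "round_half_up",
]

CDR_EFFICIENCY_DEFAULT = 0.8
ETA_MAX_COASTAL = 0.832
ETA_MAX_POLAR = 0.904
TA_PROBE_DEFAULT = 50.0  # umol/kg, the fixed responsiveness dose


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition constants, overridable in one place."""

    atm_pco2_current: float = 420.0
    atm_pco2_preindustrial: float = 278.0
    cdr_efficiency: float = CDR_EFFICIENCY_DEFAULT
    eta_max_coastal: float = ETA_MAX_COASTAL
    eta_max_polar: float = ETA_MAX_POLAR
    ta_probe: float = TA_PROBE_DEFAULT
    alpha: float = 0.1

    @property
    def delta_pco2(self) -> float:
        return self.atm_pco2_current - self.atm_pco2_preindustrial

    def eta_for_region(self, region: str) -> float:
        if region == "polar":
            return self.eta_max_polar
        if region == "coastal":
            return self.eta_max_coastal
        raise ValueError(f"unknown region {region!r}; expected coastal|polar")


DEFAULT_CONFIG = ScenarioConfig()


@dataclass(frozen=True)
class OAEScenario:
    """Reagent + equilibration assumption + the efficiency parameters."""

    reagent: Literal["NaOH", "Na2CO3"]
    equilibrated: bool
    cdr_efficiency: float = CDR_EFFICIENCY_DEFAULT
    eta_max: float = ETA_MAX_COASTAL

    def __post_init__(self):
        if self.reagent not in ("NaOH", "Na2CO3"):
            raise ValueError(f"unknown reagent {self.reagent!r}")
        if not (0.0 <= self.cdr_efficiency <= 1.0):
            raise ValueError("cdr_efficiency must be in [0, 1]")
        if not (0.0 < self.eta_max < 1.2):
            raise ValueError("eta_max must be in (0, 1.2)")


@dataclass(frozen=True)
class SpeciesControl:
    """Experimental control chemistry defining a species' current baseline."""

    species: str
    region: Literal["coastal", "polar"]
    ta: float  # umol/kg
    dic: float  # umol/kg
    conditions: SeawaterConditions = field(default_factory=SeawaterConditions)

    def __post_init__(self):
        if self.ta <= self.dic:
            raise ValueError(
                f"{self.species}: control TA ({self.ta}) must exceed DIC "
                f"({self.dic}) for surface seawater"
            )


@dataclass(frozen=True)
class RestorationResult:
    """TA dose restoring a target TA-DIC under a given scenario."""

    delta_ta: float  # umol/kg of TA added
    scenario: OAEScenario
    current_tadic: float
    target_tadic: float


@dataclass(frozen=True)
class SpeciesSummary:
    """One species' full summary row: states, decline, doses, responsiveness."""

    species: str
    group: str
    rate_unit: str
    response: str
    region: str
    tadic_current: float
    rate_current: float
    rate_current_pi90: float
    tadic_preindustrial: float
    rate_preindustrial: float
    rate_preindustrial_pi90: float
    decline_pct: float
    dose_naoh_uneq: float
    dose_naoh_eq: float
    dose_na2co3_uneq: float
    dose_na2co3_eq: float
    resp_uneq_pct: float
    resp_eq_pct: float


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the table-formatting convention here),
    unlike banker's rounding of the builtin."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def preindustrial_state(control: SpeciesControl,
                        config: ScenarioConfig = DEFAULT_CONFIG,
                        ) -> CarbonateState:
    """Preindustrial chemistry for a species' control conditions.

    Solves the current state from (TA, DIC), then re-solves at the same TA
    (alkalinity assumed unchanged over the industrial era) with pCO2
    lowered by the atmospheric rise (142 uatm by default), holding
    temperature, salinity and nutrients fixed.  The preindustrial state
    has lower DIC and hence higher TA-DIC; with TA constant,
    d(TA-DIC) = -dDIC exactly.
    """
    current = solve_from_ta_dic(control.ta, control.dic, control.conditions)
    pi_pco2 = current.pco2 - config.delta_pco2
    if pi_pco2 <= 0:
        raise ValueError(
            f"{control.species}: current pCO2 {current.pco2:.1f} uatm minus "
            f"{config.delta_pco2:.0f} is non-positive; control is nonphysical"
        )
    return solve_from_ta_pco2(control.ta, pi_pco2, control.conditions,
                              constants=current.constants)


def tadic_change_per_unit_ta(scenario: OAEScenario) -> float:
    """d(TA-DIC)/d(TA added) for the scenario; must be positive for a
    restoration dose to exist."""
    if scenario.reagent == "NaOH":
        base, dic_per_ta = 1.0, 0.0
    else:  # Na2CO3: 2 TA-equivalents and 1 DIC per mole
        base, dic_per_ta = 0.5, 0.5
    factor = base
    if scenario.equilibrated:
        f, eta = scenario.cdr_efficiency, scenario.eta_max
        factor = base - f * (eta - dic_per_ta)
    if factor <= 0:
        raise ValueError(
            f"{scenario.reagent} {'eq' if scenario.equilibrated else 'uneq'}: "
            f"TA-DIC change per unit TA is {factor:.4f} <= 0; "
            "restoration by this scenario is impossible"
        )
    return factor


def required_ta_addition(current_tadic: float, target_tadic: float,
                         scenario: OAEScenario) -> RestorationResult:
    """TA dose such that current TA-DIC + factor * dose = target TA-DIC."""
    if target_tadic < current_tadic:
        raise ValueError(
            f"target TA-DIC {target_tadic} below current {current_tadic}; "
            "no alkalinity addition required"
        )
    factor = tadic_change_per_unit_ta(scenario)
    return RestorationResult(
        delta_ta=(target_tadic - current_tadic) / factor,
        scenario=scenario,
        current_tadic=float(current_tadic),
        target_tadic=float(target_tadic),
    )


def required_ta_exact_equilibrated(control: SpeciesControl, target_tadic: float,
                                   reagent: str = "NaOH") -> RestorationResult:
    """Exact nonlinear counterpart of the equilibrated dose at full
    equilibration (f = 1): root-find the TA addition whose fully
    re-equilibrated state (constant current pCO2) reaches the target
    TA-DIC.  For Na2CO3 every mole of reagent also delivers DIC, but at
    constant pCO2 the final DIC is set by the equilibrium, so the dose in
    TA-equivalents is reagent-independent; the result is reported in
    TA-equivalents added.
    """
    current = solve_from_ta_dic(control.ta, control.dic, control.conditions)
    scenario = OAEScenario(reagent=reagent, equilibrated=True,
                           cdr_efficiency=1.0)

    def gap(delta_ta: float) -> float:
        st = solve_from_ta_pco2(control.ta + delta_ta, current.pco2,
                                control.conditions, constants=current.constants)
        return st.tadic - target_tadic

    if target_tadic <= current.tadic:
        return RestorationResult(0.0, scenario, current.tadic, float(target_tadic))
    hi = 10.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("equilibrated dose root not bracketed")
    delta = brentq(gap, 0.0, hi, xtol=1e-10)
    return RestorationResult(float(delta), scenario, current.tadic,
                             float(target_tadic))


def calcification_responsiveness(fit: FitResult, x_current: float,
                                 scenario: OAEScenario,
                                 delta_ta: float = TA_PROBE_DEFAULT) -> float:
    """Percent calcification-rate gain for a fixed TA addition (default
    50 umol/kg) under the scenario's TA-DIC change factor."""
    y_now = float(fit.predict(x_current))
    if y_now <= 0:
        raise ValueError("responsiveness undefined for non-positive current rate")
    factor = tadic_change_per_unit_ta(scenario)
    y_enh = float(fit.predict(x_current + delta_ta * factor))
    return 100.0 * (y_enh - y_now) / y_now


def build_species_summary(control: SpeciesControl, fit: FitResult,
                          group: str = "", rate_unit: str = "",
                          config: ScenarioConfig = DEFAULT_CONFIG,
                          ) -> SpeciesSummary:
    """Assemble the full summary row for one species from its control
    chemistry and selected response model.

    TA-DIC values are rounded to integers, percentages to 2 decimals
    (half away from zero); rates and band half-widths are left unrounded
    (format at output time to 3 significant digits).
    """
    from .response import calcification_decline  # local to avoid cycle noise

    current = solve_from_ta_dic(control.ta, control.dic, control.conditions)
    pi = preindustrial_state(control, config)
    eta = config.eta_for_region(control.region)
    f = config.cdr_efficiency

    def scen(reagent, eq):
        return OAEScenario(reagent=reagent, equilibrated=eq,
                           cdr_efficiency=f, eta_max=eta)

    doses = {
        (r, e): required_ta_addition(current.tadic, pi.tadic, scen(r, e)).delta_ta
        for r in ("NaOH", "Na2CO3") for e in (False, True)
    }
    band_now = predict_with_interval(fit, current.tadic, alpha=config.alpha)
    band_pi = predict_with_interval(fit, pi.tadic, alpha=config.alpha)
    return SpeciesSummary(
        species=control.species,
        group=group,
        rate_unit=rate_unit,
        response=fit.model_kind,
        region=control.region,
        tadic_current=round_half_up(current.tadic),
        rate_current=band_now.y_hat,
        rate_current_pi90=band_now.half_width,
        tadic_preindustrial=round_half_up(pi.tadic),
        rate_preindustrial=band_pi.y_hat,
        rate_preindustrial_pi90=band_pi.half_width,
        decline_pct=round_half_up(
            calcification_decline(fit, current.tadic, pi.tadic), 2),
        dose_naoh_uneq=round_half_up(doses[("NaOH", False)]),
        dose_naoh_eq=round_half_up(doses[("NaOH", True)]),
        dose_na2co3_uneq=round_half_up(doses[("Na2CO3", False)]),
        dose_na2co3_eq=round_half_up(doses[("Na2CO3", True)]),
        resp_uneq_pct=round_half_up(
            calcification_responsiveness(fit, current.tadic, scen("NaOH", False),
                                         config.ta_probe), 2),
        resp_eq_pct=round_half_up(
            calcification_responsiveness(fit, current.tadic, scen("NaOH", True),
                                         config.ta_probe), 2),
    )
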