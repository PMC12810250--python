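"""Surface-seawater CO2-system equilibrium solver.

Solves the marine carbonate system from (TA, DIC) or (TA, pCO2) on the
total pH scale at surface pressure, with the constant set conventional for
open-ocean work: K1/K2 from Lueker et al. (2000), bisulfate from Dickson
(1990), total boron from Lee et al. (2010), K0 from Weiss (1974), borate
from Dickson (1990), water/phosphate/silicate from Millero-style fits as
used in standard CO2SYS, HF from Perez & Fraga (1987), and the aragonite
solubility product from Mucci (1983).  Also provides the maximum
alkalinity-enhancement uptake efficiency etamax (moles of DIC gained per
mole of TA added at constant pCO2) and its area-weighted regional mean.

Units: TA, DIC and all carbonate species in umol/kg unless stated;
internal thermodynamics in mol/kg.  pCO2 in uatm (fugacity-corrected,
i.e. fCO2 is computed internally and converted with the Weiss (1974)
virial coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SeawaterConditions",
    "EquilibriumConstants",
    "CarbonateState",
    "compute_constants",
    "alkalinity_residual",
    "solve_from_ta_dic",
    "solve_from_ta_pco2",
    "eta_max",
    "area_weighted_eta_max",
    "ConvergenceError",
    "ConstantDomainError",
]

# residual convergence contract, umol/kg
TA_RESIDUAL_TOL = 1e-3
# pH bracket for the root search
PH_MIN, PH_MAX = 2.0, 12.0

GAS_CONSTANT_ML_BAR = 83.14462618  # ml bar / (K mol)


class ConvergenceError(RuntimeError):
    """The equilibrium root search failed to bracket or converge."""


class ConstantDomainError(ValueError):
    """Conditions far outside the validity window of an empirical fit."""


@dataclass(frozen=True)
class SeawaterConditions:
    """Physical and nutrient state of a surface seawater parcel.

    temperature in degC, salinity practical, silicate and phosphate in
    umol/kg.  Nutrient defaults are the open-ocean reference values used
    throughout this package (Si(OH)4 = 50, PO4 = 0.5 umol/kg).
    """

    temperature: float = 16.0
    salinity: float = 34.68
    silicate: float = 50.0
    phosphate: float = 0.5

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ConstantDomainError(
                f"temperature {self.temperature} degC outside [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 45.0):
            raise ConstantDomainError(f"salinity {self.salinity} outside [0, 45]")
        if self.silicate < 0 or self.phosphate < 0:
            raise ConstantDomainError("nutrient concentrations must be >= 0")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric equilibrium constants on the total pH scale (mol/kg),
    plus salinity-derived total concentrations (mol/kg) and the CO2
    fugacity factor at 1 atm total pressure."""

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    ksi: float
    kp1: float
    kp2: float
    kp3: float
    kso4: float  # free scale, used with [H+]_free
    kf: float
    ksp_ar: float
    total_boron: float
    total_sulfate: float
    total_fluoride: float
    calcium: float
    fugacity_factor: float


@dataclass(frozen=True)
class CarbonateState:
    """A fully solved carbonate-system snapshot (concentrations in umol/kg)."""

    conditions: SeawaterConditions
    ta: float
    dic: float
    ph_total: float
    pco2: float
    co2aq: float
    hco3: float
    co3: float
    omega_ar: float
    constants: EquilibriumConstants = field(repr=False, compare=False, default=None)

    @property
    def tadic(self) -> float:
        """TA - DIC ('Alk*'), the carbonate-ion proxy used as predictor."""
        return self.ta - self.dic

    @property
    def h_total(self) -> float:
        """[H+] on the total scale, mol/kg."""
        return 10.0 ** (-self.ph_total)


def _check_window(name: str, value: float, lo: float, hi: float,
                  hard_lo: float, hard_hi: float) -> None:
    if not (hard_lo <= value <= hard_hi):
        raise ConstantDomainError(
            f"{name} = {value} outside usable range [{hard_lo}, {hard_hi}] "
            "for the carbonic-acid constants"
        )
    if not (lo <= value <= hi):
        warnings.warn(
            f"{name} = {value} outside the fitted validity window [{lo}, {hi}]; "
            "K1/K2 are extrapolated",
            stacklevel=3,
        )


def compute_constants(conditions: SeawaterConditions) -> EquilibriumConstants:
    """Evaluate the full constant set at the given conditions, surface pressure.

    Raises :class:`ConstantDomainError` when salinity or temperature is far
    outside the Lueker et al. (2000) fit domain (S 19-43, T 2-35 degC), and
    warns when moderately outside it.
    """
    t_c = conditions.temperature
    s = conditions.salinity
    # Lueker fit: 2-35 degC, S 19-43; tolerate modest extrapolation with a
    # warning, refuse brackish/fresh water outright.
    _check_window("salinity", s, 19.0, 43.0, 15.0, 45.0)
    _check_window("temperature", t_c, 2.0, 35.0, -2.0, 40.0)

    t_k = t_c + 273.15
    ln_t = np.log(t_k)
    sqrt_s = np.sqrt(s)

    # --- total concentrations from salinity (mol/kg) ---
    total_boron = 0.1336e-3 / 10.811 * s / 1.80655  # Lee et al. (2010)
    total_sulfate = 0.14 / 96.062 * s / 1.80655  # Morris & Riley (1966)
    total_fluoride = 0.000067 / 18.998 * s / 1.80655  # Riley (1965)
    calcium = 0.02128 / 40.087 * s / 1.80655  # Riley & Tongudai (1967)

    ionic_strength = 19.924 * s / (1000.0 - 1.005 * s)

    # --- K0, Weiss (1974), mol/kg/atm ---
    k0 = np.exp(
        -60.2409
        + 93.4517 * (100.0 / t_k)
        + 23.3585 * np.log(t_k / 100.0)
        + s * (0.023517 - 0.023656 * (t_k / 100.0) + 0.0047036 * (t_k / 100.0) ** 2)
    )

    # --- K1, K2, Lueker et al. (2000), total scale ---
    pk1 = 3633.86 / t_k - 61.2172 + 9.67770 * ln_t - 0.011555 * s + 0.0001152 * s**2
    pk2 = 471.78 / t_k + 25.9290 - 3.16967 * ln_t - 0.01781 * s + 0.0001122 * s**2
    k1 = 10.0**-pk1
    k2 = 10.0**-pk2

    # --- KSO4 (bisulfate), Dickson (1990a), free scale, mol/kg-sw ---
    ln_kso4 = (
        -4276.1 / t_k
        + 141.328
        - 23.093 * ln_t
        + (-13856.0 / t_k + 324.57 - 47.986 * ln_t) * np.sqrt(ionic_strength)
        + (35474.0 / t_k - 771.54 + 114.723 * ln_t) * ionic_strength
        - 2698.0 / t_k * ionic_strength**1.5
        + 1776.0 / t_k * ionic_strength**2
        + np.log(1.0 - 0.001005 * s)
    )
    kso4 = np.exp(ln_kso4)

    # --- KF (hydrogen fluoride), Perez & Fraga (1987), total scale ---
    kf = np.exp(874.0 / t_k - 9.68 + 0.111 * sqrt_s)

    # scale conversion factor for constants published on the seawater scale
    sws_to_total = (1.0 + total_sulfate / kso4) / (
        1.0 + total_sulfate / kso4 + total_fluoride / kf
    )

    # --- KB (boric acid), Dickson (1990b), total scale ---
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2)
        / t_k
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        - (24.4344 + 25.085 * sqrt_s + 0.2474 * s) * ln_t
        + 0.053105 * sqrt_s * t_k
    )
    kb = np.exp(ln_kb)

    # --- KW, Millero (1995), seawater scale -> total ---
    ln_kw = (
        148.9802
        - 13847.26 / t_k
        - 23.6521 * ln_t
        + (118.67 / t_k - 5.977 + 1.0495 * ln_t) * sqrt_s
        - 0.01615 * s
    )
    kw = np.exp(ln_kw) * sws_to_total

    # --- phosphoric acid, Yao & Millero (1995)/Millero (1995), SWS -> total ---
    ln_kp1 = (
        -4576.752 / t_k
        + 115.525
        - 18.453 * ln_t
        + (-106.736 / t_k + 0.69171) * sqrt_s
        + (-0.65643 / t_k - 0.01844) * s
    )
    ln_kp2 = (
        -8814.715 / t_k
        + 172.0883
        - 27.927 * ln_t
        + (-160.340 / t_k + 1.3566) * sqrt_s
        + (0.37335 / t_k - 0.05778) * s
    )
    ln_kp3 = (
        -3070.75 / t_k
        - 18.141
        + (17.27039 / t_k + 2.81197) * sqrt_s
        + (-44.99486 / t_k - 0.09984) * s
    )
    kp1 = np.exp(ln_kp1) * sws_to_total
    kp2 = np.exp(ln_kp2) * sws_to_total
    kp3 = np.exp(ln_kp3) * sws_to_total

    # --- silicic acid, Yao & Millero (1995), SWS, mol/kg-H2O -> mol/kg-sw ---
    ln_ksi = (
        -8904.2 / t_k
        + 117.385
        - 19.334 * ln_t
        + (-458.79 / t_k + 3.5913) * np.sqrt(ionic_strength)
        + (188.74 / t_k - 1.5998) * ionic_strength
        + (-12.1652 / t_k + 0.07871) * ionic_strength**2
        + np.log(1.0 - 0.001005 * s)
    )
    ksi = np.exp(ln_ksi) * sws_to_total

    # --- aragonite solubility, Mucci (1983), (mol/kg)^2 ---
    log_ksp_ar = (
        -171.945
        - 0.077993 * t_k
        + 2903.293 / t_k
        + 71.595 * np.log10(t_k)
        + (-0.068393 + 0.0017276 * t_k + 88.135 / t_k) * sqrt_s
        - 0.10018 * s
        + 0.0059415 * s**1.5
    )
    ksp_ar = 10.0**log_ksp_ar

    # --- fugacity factor, Weiss (1974) virial coefficients, 1 atm total P ---
    b_virial = (
        -1636.75 + 12.0408 * t_k - 0.0327957 * t_k**2 + 3.16528e-5 * t_k**3
    )  # cm3/mol
    delta_virial = 57.7 - 0.118 * t_k
    p_bar = 1.01325
    fugacity_factor = np.exp(
        (b_virial + 2.0 * delta_virial) * p_bar / (GAS_CONSTANT_ML_BAR * t_k)
    )

    return EquilibriumConstants(
        k0=float(k0), k1=float(k1), k2=float(k2), kb=float(kb), kw=float(kw),
        ksi=float(ksi), kp1=float(kp1), kp2=float(kp2), kp3=float(kp3),
        kso4=float(kso4), kf=float(kf), ksp_ar=float(ksp_ar),
        total_boron=float(total_boron), total_sulfate=float(total_sulfate),
        total_fluoride=float(total_fluoride), calcium=float(calcium),
        fugacity_factor=float(fugacity_factor),
    )


def _noncarbonate_alkalinity(h: float, conditions: SeawaterConditions,
                             k: EquilibriumConstants) -> float:
    """Alkalinity (mol/kg) carried by borate, water, phosphate, silicate,
    free H+, bisulfate and HF at total-scale [H+] = h."""
    tp = conditions.phosphate * 1e-6
    tsi = conditions.silicate * 1e-6
    b_alk = k.total_boron * k.kb / (k.kb + h)
    oh = k.kw / h
    h3 = h**3
    phos_denom = h3 + k.kp1 * h**2 + k.kp1 * k.kp2 * h + k.kp1 * k.kp2 * k.kp3
    p_alk = tp * (
        (k.kp1 * k.kp2 * h + 2.0 * k.kp1 * k.kp2 * k.kp3 - h3) / phos_denom
    )
    si_alk = tsi * k.ksi / (k.ksi + h)
    h_free = h / (1.0 + k.total_sulfate / k.kso4)
    hso4 = k.total_sulfate / (1.0 + k.kso4 / h_free)
    hf = k.total_fluoride / (1.0 + k.kf / h)
    return b_alk + oh + p_alk + si_alk - h_free - hso4 - hf


def alkalinity_residual(h: float, ta: float, dic: float,
                        constants: EquilibriumConstants,
                        conditions: SeawaterConditions | None = None) -> float:
    """TA implied by ([H+]=h total scale, DIC, minor acid-base systems)
    minus the input ta, in umol/kg.  Strictly decreasing in h.

    ta, dic in umol/kg; h in mol/kg.
    """
    if conditions is None:
        conditions = SeawaterConditions()
    k = constants
    dic_mol = dic * 1e-6
    denom = h**2 + k.k1 * h + k.k1 * k.k2
    c_alk = dic_mol * k.k1 * (h + 2.0 * k.k2) / denom
    ta_calc = c_alk + _noncarbonate_alkalinity(h, conditions, k)
    return (ta_calc - ta * 1e-6) * 1e6


def _solve_ph(residual, lo: float = PH_MIN, hi: float = PH_MAX) -> float:
    """Root of ``residual(h)`` in h, bracketed on pH in [lo, hi]."""
    h_hi, h_lo = 10.0**-lo, 10.0**-hi
    r_lo, r_hi = residual(h_lo), residual(h_hi)
    if not np.isfinite(r_lo) or not np.isfinite(r_hi):
        raise ConvergenceError("non-finite alkalinity residual at bracket ends")
    if r_lo * r_hi > 0:
        raise ConvergenceError(
            f"no sign change of the alkalinity residual on pH [{lo}, {hi}]: "
            f"residual({hi})={r_lo:.3g}, residual({lo})={r_hi:.3g} umol/kg"
        )
    h = brentq(residual, h_lo, h_hi, xtol=1e-20, rtol=8.882e-16, maxiter=200)
    return float(h)


def _finish_state(h: float, ta: float, dic: float,
                  conditions: SeawaterConditions,
                  k: EquilibriumConstants) -> CarbonateState:
    dic_mol = dic * 1e-6
    denom = h**2 + k.k1 * h + k.k1 * k.k2
    co2aq = dic_mol * h**2 / denom
    hco3 = dic_mol * k.k1 * h / denom
    co3 = dic_mol * k.k1 * k.k2 / denom
    fco2 = co2aq / k.k0  # atm
    pco2 = fco2 / k.fugacity_factor * 1e6  # uatm
    omega_ar = k.calcium * co3 / k.ksp_ar
    return CarbonateState(
        conditions=conditions,
        ta=float(ta),
        dic=float(dic),
        ph_total=float(-np.log10(h)),
        pco2=float(pco2),
        co2aq=float(co2aq * 1e6),
        hco3=float(hco3 * 1e6),
        co3=float(co3 * 1e6),
        omega_ar=float(omega_ar),
        constants=k,
    )


def solve_from_ta_dic(ta: float, dic: float,
                      conditions: SeawaterConditions | None = None,
                      constants: EquilibriumConstants | None = None,
                      ) -> CarbonateState:
    """Solve the system from total alkalinity and DIC (both umol/kg)."""
    if conditions is None:
        conditions = SeawaterConditions()
    if not (np.isfinite(ta) and np.isfinite(dic)):
        raise ValueError("ta and dic must be finite")
    if ta <= 0 or dic < 0:
        raise ValueError(f"require ta > 0 and dic >= 0, got ta={ta}, dic={dic}")
    k = constants if constants is not None else compute_constants(conditions)

    def residual(h: float) -> float:
        return alkalinity_residual(h, ta, dic, k, conditions)

    h = _solve_ph(residual)
    return _finish_state(h, ta, dic, conditions, k)


def solve_from_ta_pco2(ta: float, pco2: float,
                       conditions: SeawaterConditions | None = None,
                       constants: EquilibriumConstants | None = None,
                       ) -> CarbonateState:
    """Solve the system from total alkalinity (umol/kg) and pCO2 (uatm)."""
    if conditions is None:
        conditions = SeawaterConditions()
    if not (np.isfinite(ta) and np.isfinite(pco2)):
        raise ValueError("ta and pco2 must be finite")
    if ta <= 0 or pco2 <= 0:
        raise ValueError(f"require ta > 0 and pco2 > 0, got ta={ta}, pco2={pco2}")
    k = constants if constants is not None else compute_constants(conditions)
    co2aq = k.k0 * (pco2 * 1e-6) * k.fugacity_factor  # mol/kg

    def residual(h: float) -> float:
        c_alk = co2aq * (k.k1 / h + 2.0 * k.k1 * k.k2 / h**2)
        ta_calc = c_alk + _noncarbonate_alkalinity(h, conditions, k)
        return (ta_calc - ta * 1e-6) * 1e6

    h = _solve_ph(residual)
    dic = co2aq * (1.0 + k.k1 / h + k.k1 * k.k2 / h**2) * 1e6
    return _finish_state(h, ta, dic, conditions, k)


def eta_max(state: CarbonateState, delta_ta: float = 1.0) -> float:
    """Maximum uptake efficiency of alkalinity enhancement.

    The increase in DIC per unit increase in TA when the perturbed parcel
    re-equilibrates to the *same* pCO2 as the initial state (full air-sea
    equilibration, unchanged atmosphere):

        etamax = [DIC(TA + dTA; pCO2) - DIC(TA; pCO2)] / dTA

    The default probe dTA = 1 umol/kg approximates the derivative; 10 and
    100 umol/kg probes give the finite-dose efficiency.
    """
    if delta_ta <= 0:
        raise ValueError("delta_ta must be > 0")
    base = solve_from_ta_pco2(state.ta, state.pco2, state.conditions,
                              constants=state.constants)
    perturbed = solve_from_ta_pco2(state.ta + delta_ta, state.pco2,
                                   state.conditions, constants=state.constants)
    return (perturbed.dic - base.dic) / delta_ta


def area_weighted_eta_max(grid, mask=None, delta_ta: float = 1.0) -> float:
    """cos(latitude)-weighted mean etamax over the masked cells of a grid.

    ``grid`` is an xarray Dataset with ``lat``/``lon`` coordinates and
    variables ``ta``, ``dic``, ``temperature``, ``salinity`` (umol/kg, degC,
    practical salinity).  ``mask`` is an optional boolean DataArray on the
    same cells; by default all cells are used.
    """
    lat2d, _ = np.meshgrid(grid["lat"].values, grid["lon"].values, indexing="ij")
    weights = np.cos(np.deg2rad(lat2d))
    ta = grid["ta"].values
    dic = grid["dic"].values
    temp = grid["temperature"].values
    sal = grid["salinity"].values
    if mask is None:
        mask_arr = np.ones_like(ta, dtype=bool)
    else:
        mask_arr = np.asarray(mask.values if hasattr(mask, "values") else mask,
                              dtype=bool)
    if not mask_arr.any():
        raise ValueError("mask selects no grid cells")

    num = 0.0
    den = 0.0
    for i, j in zip(*np.nonzero(mask_arr)):
        conds = SeawaterConditions(temperature=float(temp[i, j]),
                                   salinity=float(sal[i, j]))
        state = solve_from_ta_dic(float(ta[i, j]), float(dic[i, j]), conds)
        num += weights[i, j] * eta_max(state, delta_ta)
        den += weights[i, j]
    return num / den
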