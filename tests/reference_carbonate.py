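"""Reference implementation of the surface CO2-system solve, written for
validation of the package's carbonate engine.

Deliberately a separate codepath: constants are retyped directly from
the primary literature (Weiss 1974; Lueker et al. 2000; Dickson 1990a,b;
Perez & Fraga 1987; Millero 1995; Yao & Millero 1995; Lee et al. 2010;
Mucci 1983; Morris & Riley 1966; Riley 1965; Riley & Tongudai 1967),
organised as per-constant functions, and the equilibrium is solved by
bisection in pH (not Brent in [H+]) on an explicitly assembled proton
condition.  Total pH scale, surface pressure, fugacity-corrected pCO2.
"""

from __future__ import annotations

from math import exp, log, log10, sqrt

from scipy.optimize import bisect

R_ML_BAR = 83.14462618


def totals(sal):
    """Salinity-proportional total concentrations, mol/kg-solution."""
    return {
        "BT": 0.1336e-3 * sal / (10.811 * 1.80655),   # Lee et al. 2010
        "ST": 0.14 * sal / (96.062 * 1.80655),        # Morris & Riley 1966
        "FT": 0.000067 * sal / (18.998 * 1.80655),    # Riley 1965
        "Ca": 0.02128 * sal / (40.087 * 1.80655),     # Riley & Tongudai 1967
    }


def k0_weiss(tk, sal):
    a = [-60.2409, 93.4517, 23.3585]
    b = [0.023517, -0.023656, 0.0047036]
    q = tk / 100.0
    return exp(a[0] + a[1] / q + a[2] * log(q)
               + sal * (b[0] + b[1] * q + b[2] * q * q))


def k1_k2_lueker(tk, sal):
    pk1 = 3633.86 / tk - 61.2172 + 9.6777 * log(tk) \
        - 0.011555 * sal + 0.0001152 * sal * sal
    pk2 = 471.78 / tk + 25.929 - 3.16967 * log(tk) \
        - 0.01781 * sal + 0.0001122 * sal * sal
    return 10.0 ** (-pk1), 10.0 ** (-pk2)


def ks_dickson(tk, sal):
    """Bisulfate, free scale, mol/kg-solution."""
    i = 19.924 * sal / (1000.0 - 1.005 * sal)
    lnk = (-4276.1 / tk + 141.328 - 23.093 * log(tk)
           + (-13856.0 / tk + 324.57 - 47.986 * log(tk)) * sqrt(i)
           + (35474.0 / tk - 771.54 + 114.723 * log(tk)) * i
           - (2698.0 / tk) * i ** 1.5 + (1776.0 / tk) * i * i)
    return exp(lnk) * (1.0 - 0.001005 * sal)


def kf_perez_fraga(tk, sal):
    return exp(874.0 / tk - 9.68 + 0.111 * sqrt(sal))


def kb_dickson(tk, sal):
    lnk = ((-8966.9 - 2890.53 * sqrt(sal) - 77.942 * sal
            + 1.728 * sal ** 1.5 - 0.0996 * sal * sal) / tk
           + 148.0248 + 137.1942 * sqrt(sal) + 1.62142 * sal
           + (-24.4344 - 25.085 * sqrt(sal) - 0.2474 * sal) * log(tk)
           + 0.053105 * sqrt(sal) * tk)
    return exp(lnk)


def kw_millero(tk, sal):
    """Water, seawater scale."""
    return exp(148.9802 - 13847.26 / tk - 23.6521 * log(tk)
               + (118.67 / tk - 5.977 + 1.0495 * log(tk)) * sqrt(sal)
               - 0.01615 * sal)


def kp_yao_millero(tk, sal):
    """Phosphoric acid K1-K3, seawater scale."""
    kp1 = exp(-4576.752 / tk + 115.525 - 18.453 * log(tk)
              + (-106.736 / tk + 0.69171) * sqrt(sal)
              + (-0.65643 / tk - 0.01844) * sal)
    kp2 = exp(-8814.715 / tk + 172.0883 - 27.927 * log(tk)
              + (-160.34 / tk + 1.3566) * sqrt(sal)
              + (0.37335 / tk - 0.05778) * sal)
    kp3 = exp(-3070.75 / tk - 18.141
              + (17.27039 / tk + 2.81197) * sqrt(sal)
              + (-44.99486 / tk - 0.09984) * sal)
    return kp1, kp2, kp3


def ksi_yao_millero(tk, sal):
    """Silicic acid, seawater scale, converted to mol/kg-solution."""
    i = 19.924 * sal / (1000.0 - 1.005 * sal)
    lnk = (-8904.2 / tk + 117.385 - 19.334 * log(tk)
           + (-458.79 / tk + 3.5913) * sqrt(i)
           + (188.74 / tk - 1.5998) * i
           + (-12.1652 / tk + 0.07871) * i * i)
    return exp(lnk) * (1.0 - 0.001005 * sal)


def kspar_mucci(tk, sal):
    logk = (-171.945 - 0.077993 * tk + 2903.293 / tk + 71.595 * log10(tk)
            + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqrt(sal)
            - 0.10018 * sal + 0.0059415 * sal ** 1.5)
    return 10.0 ** logk


def fugacity_factor(tk):
    b = -1636.75 + 12.0408 * tk - 0.0327957 * tk ** 2 + 3.16528e-5 * tk ** 3
    delta = 57.7 - 0.118 * tk
    return exp((b + 2.0 * delta) * 1.01325 / (R_ML_BAR * tk))


def constant_set(temp_c, sal):
    """All constants on the total scale (except KS, free scale)."""
    tk = temp_c + 273.15
    tot = totals(sal)
    ks = ks_dickson(tk, sal)
    kf = kf_perez_fraga(tk, sal)
    sws2tot = (1.0 + tot["ST"] / ks) / (1.0 + tot["ST"] / ks + tot["FT"] / kf)
    k1, k2 = k1_k2_lueker(tk, sal)
    kp1, kp2, kp3 = kp_yao_millero(tk, sal)
    return {
        "K0": k0_weiss(tk, sal), "K1": k1, "K2": k2,
        "KB": kb_dickson(tk, sal), "KW": kw_millero(tk, sal) * sws2tot,
        "KS": ks, "KF": kf,
        "KP1": kp1 * sws2tot, "KP2": kp2 * sws2tot, "KP3": kp3 * sws2tot,
        "KSi": ksi_yao_millero(tk, sal) * sws2tot,
        "KspAr": kspar_mucci(tk, sal),
        "FugFac": fugacity_factor(tk),
        **tot,
    }


def speciation(ph, dic_umol, k, si_umol=50.0, po4_umol=0.5):
    """All alkalinity contributions (mol/kg) at total-scale pH."""
    h = 10.0 ** (-ph)
    dic = dic_umol * 1e-6
    tsi, tp = si_umol * 1e-6, po4_umol * 1e-6
    gamma = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2 = dic * h * h / gamma
    hco3 = dic * k["K1"] * h / gamma
    co3 = dic * k["K1"] * k["K2"] / gamma
    borate = k["BT"] / (1.0 + h / k["KB"])
    oh = k["KW"] / h
    d = (h ** 3 + k["KP1"] * h * h + k["KP1"] * k["KP2"] * h
         + k["KP1"] * k["KP2"] * k["KP3"])
    h3po4 = tp * h ** 3 / d
    hpo4 = tp * k["KP1"] * k["KP2"] * h / d
    po4 = tp * k["KP1"] * k["KP2"] * k["KP3"] / d
    sioh3 = tsi / (1.0 + h / k["KSi"])
    hfree = h / (1.0 + k["ST"] / k["KS"])
    hso4 = k["ST"] * hfree / (hfree + k["KS"])
    hf = k["FT"] * h / (h + k["KF"])
    return {
        "co2": co2, "hco3": hco3, "co3": co3, "borate": borate, "oh": oh,
        "hpo4": hpo4, "po4": po4, "h3po4": h3po4, "sioh3": sioh3,
        "hfree": hfree, "hso4": hso4, "hf": hf,
    }


def alkalinity_of(ph, dic_umol, k, si_umol=50.0, po4_umol=0.5):
    """Total alkalinity (umol/kg) implied by (pH, DIC): proton acceptors
    minus donors relative to the zero level of protons."""
    s = speciation(ph, dic_umol, k, si_umol, po4_umol)
    ta = (s["hco3"] + 2.0 * s["co3"] + s["borate"] + s["oh"]
          + s["hpo4"] + 2.0 * s["po4"] - s["h3po4"] + s["sioh3"]
          - s["hfree"] - s["hso4"] - s["hf"])
    return ta * 1e6


def solve_ta_dic(ta_umol, dic_umol, temp_c, sal, si_umol=50.0, po4_umol=0.5):
    """Bisection in pH of the alkalinity mismatch; returns a result dict."""
    k = constant_set(temp_c, sal)

    def mismatch(ph):
        return alkalinity_of(ph, dic_umol, k, si_umol, po4_umol) - ta_umol

    ph = bisect(mismatch, 2.0, 12.0, xtol=1e-11)
    s = speciation(ph, dic_umol, k, si_umol, po4_umol)
    fco2 = s["co2"] / k["K0"]
    return {
        "ph": ph,
        "pco2": fco2 / k["FugFac"] * 1e6,
        "co3": s["co3"] * 1e6,
        "omega_ar": k["Ca"] * s["co3"] / k["KspAr"],
        "alk_terms": s,
        "constants": k,
    }


def solve_ta_pco2(ta_umol, pco2_uatm, temp_c, sal, si_umol=50.0, po4_umol=0.5):
    """Bisection in pH at fixed CO2(aq); returns DIC and the full result."""
    k = constant_set(temp_c, sal)
    co2 = k["K0"] * k["FugFac"] * pco2_uatm * 1e-6

    def dic_at(ph):
        h = 10.0 ** (-ph)
        return co2 * (1.0 + k["K1"] / h + k["K1"] * k["K2"] / (h * h)) * 1e6

    def mismatch(ph):
        return alkalinity_of(ph, dic_at(ph), k, si_umol, po4_umol) - ta_umol

    ph = bisect(mismatch, 2.0, 12.0, xtol=1e-11)
    dic = dic_at(ph)
    out = solve_ta_dic(ta_umol, dic, temp_c, sal, si_umol, po4_umol)
    out["dic"] = dic
    return out
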