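"""Scenario algebra, preindustrial targets, doses, responsiveness."""

import numpy as np
import pytest

from oaecalc.carbonate import SeawaterConditions, solve_from_ta_dic, solve_from_ta_pco2
from oaecalc.response import fit_linear, fit_threshold, CalcificationDataset, threshold_model
from oaecalc.scenarios import (
    DEFAULT_CONFIG,
    OAEScenario,
    ScenarioConfig,
    SpeciesControl,
    build_species_summary,
    calcification_responsiveness,
    preindustrial_state,
    required_ta_addition,
    required_ta_exact_equilibrated,
    round_half_up,
    tadic_change_per_unit_ta,
)

F, ETA_C, ETA_P = 0.8, 0.832, 0.904


def scen(reagent="NaOH", eq=False, f=F, eta=ETA_C):
    return OAEScenario(reagent, eq, f, eta)


class TestPreindustrialState:
    def test_direction_and_constant_ta(self):
        ctrl = SpeciesControl("sp", "coastal", 2300, 2100)
        cur = solve_from_ta_dic(2300, 2100)
        pi = preindustrial_state(ctrl)
        assert pi.ta == ctrl.ta  # alkalinity unchanged over the industrial era
        assert pi.tadic > cur.tadic
        assert pi.dic < cur.dic

    def test_tadic_change_equals_dic_change(self):
        ctrl = SpeciesControl("sp", "coastal", 2350, 2080)
        cur = solve_from_ta_dic(2350, 2080)
        pi = preindustrial_state(ctrl)
        assert pi.tadic - cur.tadic == pytest.approx(cur.dic - pi.dic, abs=1e-9)

    def test_nonphysical_control_rejected(self):
        # a control whose pCO2 is below the preindustrial offset
        ctrl = SpeciesControl("sp", "coastal", 2400, 1700)
        assert solve_from_ta_dic(2400, 1700).pco2 < 142
        with pytest.raises(ValueError, match="non-positive"):
            preindustrial_state(ctrl)

    def test_control_requires_supersaturated_surface_water(self):
        with pytest.raises(ValueError, match="exceed"):
            SpeciesControl("sp", "coastal", 2000, 2100)


class TestScenarioFactor:
    @pytest.mark.parametrize("reagent,eq,eta,expect", [
        ("NaOH", False, ETA_C, 1.0),
        ("NaOH", True, ETA_C, 1.0 - F * ETA_C),      # 0.3344
        ("Na2CO3", False, ETA_C, 0.5),
        ("Na2CO3", True, ETA_C, 0.5 - F * (ETA_C - 0.5)),  # 0.2344
        ("NaOH", True, ETA_P, 1.0 - F * ETA_P),
    ])
    def test_factor_values(self, reagent, eq, eta, expect):
        assert tadic_change_per_unit_ta(scen(reagent, eq, F, eta)) == pytest.approx(
            expect, abs=1e-12)

    def test_zero_cdr_efficiency_reduces_to_unequilibrated(self):
        for reagent in ("NaOH", "Na2CO3"):
            assert tadic_change_per_unit_ta(scen(reagent, True, 0.0)) == \
                tadic_change_per_unit_ta(scen(reagent, False))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            tadic_change_per_unit_ta(scen("NaOH", True, 1.0, 1.1))

    def test_unequilibrated_ignores_efficiencies(self):
        a = tadic_change_per_unit_ta(scen("NaOH", False, 0.2, 0.7))
        b = tadic_change_per_unit_ta(scen("NaOH", False, 1.0, 1.1))
        assert a == b == 1.0


class TestRequiredDose:
    def test_coral_unequilibrated_dose(self):
        res = required_ta_addition(486, 765, scen("NaOH", False))
        assert res.delta_ta == pytest.approx(279.0)

    def test_oyster_unequilibrated_dose(self):
        assert required_ta_addition(98, 120, scen("NaOH", False)).delta_ta == \
            pytest.approx(22.0)

    def test_equilibrated_dose_from_unequilibrated(self):
        # coralline-alga requirement: 93 unequilibrated -> 278 with
        # equilibration at f=0.8, coastal eta
        dose = 93.0 / tadic_change_per_unit_ta(scen("NaOH", True))
        assert round_half_up(dose) == 278.0

    def test_identity_and_ordering(self):
        assert required_ta_addition(300, 300, scen()).delta_ta == 0.0
        uneq = required_ta_addition(200, 280, scen("NaOH", False)).delta_ta
        eq = required_ta_addition(200, 280, scen("NaOH", True)).delta_ta
        assert eq > uneq
        with pytest.raises(ValueError, match="below current"):
            required_ta_addition(300, 200, scen())

    def test_na2co3_doubles_naoh(self):
        for gap in (22.0, 93.0, 279.0):
            naoh = required_ta_addition(300, 300 + gap, scen("NaOH", False))
            na2 = required_ta_addition(300, 300 + gap, scen("Na2CO3", False))
            assert na2.delta_ta == pytest.approx(2.0 * naoh.delta_ta, abs=1e-12)


class TestExactEquilibratedDose:
    def test_zero_gap(self):
        ctrl = SpeciesControl("sp", "coastal", 2300, 2100)
        cur = solve_from_ta_dic(2300, 2100)
        res = required_ta_exact_equilibrated(ctrl, cur.tadic)
        assert res.delta_ta == 0.0

    def test_small_dose_matches_linearisation(self):
        ctrl = SpeciesControl("sp", "coastal", 2300, 2100)
        cur = solve_from_ta_dic(2300, 2100)
        # eta evaluated at the control state, full equilibration (f=1)
        from oaecalc.carbonate import eta_max

        eta = eta_max(cur)
        target = cur.tadic + 15.0
        exact = required_ta_exact_equilibrated(ctrl, target).delta_ta
        linear = 15.0 / (1.0 - eta)
        assert exact == pytest.approx(linear, rel=0.02)

    def test_resulting_uptake_ratio_bounded(self):
        ctrl = SpeciesControl("sp", "coastal", 2300, 2100)
        cur = solve_from_ta_dic(2300, 2100)
        res = required_ta_exact_equilibrated(ctrl, cur.tadic + 30.0)
        after = solve_from_ta_pco2(2300 + res.delta_ta, cur.pco2)
        ratio = (after.dic - cur.dic) / res.delta_ta
        assert 0.0 < ratio < 1.0


class TestResponsiveness:
    def _gastropod_fit(self):
        # anchors (202, 1.49e-4) and (278, 2.67e-4) plus their midpoint
        x = np.array([202.0, 240.0, 278.0])
        y = np.array([1.49e-4, (1.49e-4 + 2.67e-4) / 2, 2.67e-4])
        return fit_linear(CalcificationDataset("sp", "g", "mmol/g/h", x, y))

    def test_unequilibrated_fifty_addition(self):
        fit = self._gastropod_fit()
        pct = calcification_responsiveness(fit, 202.0, scen("NaOH", False), 50.0)
        assert pct == pytest.approx(52.17, abs=0.1)

    def test_equilibrated_scales_by_factor(self):
        fit = self._gastropod_fit()
        uneq = calcification_responsiveness(fit, 202.0, scen("NaOH", False), 50.0)
        eq = calcification_responsiveness(fit, 202.0, scen("NaOH", True), 50.0)
        assert eq == pytest.approx(uneq * (1 - F * ETA_C), rel=1e-9)
        assert eq == pytest.approx(17.45, abs=0.1)

    def test_flat_plateau_zero_responsiveness(self):
        x = np.array([100.0, 250.0, 405.0, 480.0, 561.0])
        fit = fit_threshold(
            CalcificationDataset("sp", "g", "mmol/g/h", x, np.full(5, 1.9e-3)))
        pct = calcification_responsiveness(fit, 405.0, scen("NaOH", False), 50.0)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_negative_rate_rejected(self):
        x = np.array([100.0, 200.0, 300.0])
        fit = fit_linear(
            CalcificationDataset("sp", "g", "u", x, np.array([-2.0, -1.0, 0.0])))
        with pytest.raises(ValueError, match="undefined"):
            calcification_responsiveness(fit, 100.0, scen())


class TestSpeciesSummary:
    def _control_and_fits(self):
        ctrl = SpeciesControl("synthetic sp.", "coastal", 2300, 2100)
        cur = solve_from_ta_dic(2300, 2100)
        pi = preindustrial_state(ctrl)
        x = np.linspace(cur.tadic - 80, pi.tadic + 40, 8)
        rng = np.random.default_rng(0)
        lin = fit_linear(CalcificationDataset(
            "synthetic sp.", "g", "u", x, 0.5 + 0.01 * x + rng.normal(0, 0.05, 8)))
        thr = fit_threshold(CalcificationDataset(
            "synthetic sp.", "g", "u", x,
            threshold_model(x, 5.0, 40.0, 0.02) + rng.normal(0, 0.02, 8)))
        return ctrl, cur, pi, lin, thr

    def test_unequilibrated_dose_equals_tadic_gap(self):
        ctrl, cur, pi, lin, _ = self._control_and_fits()
        summ = build_species_summary(ctrl, lin, group="g", rate_unit="u")
        assert summ.dose_naoh_uneq == pytest.approx(
            round_half_up(pi.tadic - cur.tadic), abs=1.0)
        assert summ.dose_na2co3_uneq == pytest.approx(
            round_half_up(2 * (pi.tadic - cur.tadic)), abs=1.0)

    def test_linear_responsiveness_ratio_is_scenario_factor(self):
        ctrl, _, _, lin, _ = self._control_and_fits()
        summ = build_species_summary(ctrl, lin, group="g", rate_unit="u")
        assert summ.resp_eq_pct / summ.resp_uneq_pct == pytest.approx(
            1 - F * ETA_C, abs=0.01)

    def test_threshold_ratio_at_least_factor(self):
        ctrl, cur, _, _, thr = self._control_and_fits()
        for k in (0.005, 0.01, 0.03):
            x = np.linspace(cur.tadic - 80, cur.tadic + 150, 8)
            data = CalcificationDataset("sp", "g", "u", x,
                                        threshold_model(x, 5.0, 8.0, k))
            fit = fit_threshold(data)
            uneq = calcification_responsiveness(fit, cur.tadic,
                                                scen("NaOH", False), 50.0)
            eq = calcification_responsiveness(fit, cur.tadic,
                                              scen("NaOH", True), 50.0)
            assert eq / uneq >= (1 - F * ETA_C) - 1e-9

    def test_percent_rounding_two_decimals(self):
        ctrl, _, _, lin, _ = self._control_and_fits()
        summ = build_species_summary(ctrl, lin, group="g", rate_unit="u")
        for v in (summ.decline_pct, summ.resp_uneq_pct, summ.resp_eq_pct):
            assert v == round_half_up(v, 2)


class TestConfig:
    def test_delta_pco2_consistency(self):
        cfg = ScenarioConfig()
        assert cfg.delta_pco2 == 142.0
        assert cfg.eta_for_region("coastal") == ETA_C
        assert cfg.eta_for_region("polar") == ETA_P
        with pytest.raises(ValueError):
            cfg.eta_for_region("abyssal")

    def test_round_half_up_convention(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(1.5) == 2.0
        assert round_half_up(2.675, 2) == 2.68
        assert round_half_up(-0.5) == -1.0
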