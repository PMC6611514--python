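"""Scenario assembly, market-share linearity, ICER and sensitivity driver."""

import copy

import numpy as np
import pandas as pd
import pytest

import lygmodel as m
from lygmodel.scenarios import (default_sensitivity_scenarios, run_full_analysis,
                                run_scenario, run_sensitivity)


@pytest.fixture(scope="module")
def curves(base_analysis):
    return base_analysis["curves"]


def single_cohort(n=1000, year=2010):
    tab = pd.DataFrame({"total_bc_cases": [n], "target_n": [n]},
                       index=pd.Index([year], name="year"))
    return m.TargetCohorts(tab, {50: 0.5, 60: 0.5})


class TestShareModes:
    def test_zero_share_equals_ct_only(self, cohorts, curves, default_cfg):
        shares = {y: 0.0 for y in cohorts.years}
        rw = run_scenario(cohorts, curves, shares, default_cfg, "real_world")
        ct = run_scenario(cohorts, curves, shares, default_cfg, "ct_only")
        assert rw.total_ly == pytest.approx(ct.total_ly, rel=1e-12)
        assert rw.total_cost == pytest.approx(ct.total_cost, rel=1e-12)

    def test_full_share_equals_full_use(self, cohorts, curves, default_cfg):
        shares = {y: 1.0 for y in cohorts.years}
        rw = run_scenario(cohorts, curves, shares, default_cfg, "real_world")
        full = run_scenario(cohorts, curves, shares, default_cfg, "full_use")
        assert rw.total_ly == pytest.approx(full.total_ly, rel=1e-12)
        assert rw.total_cost == pytest.approx(full.total_cost, rel=1e-12)

    def test_real_world_is_convex_combination(self, curves, default_cfg):
        cohort = single_cohort()
        half = run_scenario(cohort, curves, {2010: 0.5}, default_cfg, "real_world")
        full = run_scenario(cohort, curves, {2010: 0.5}, default_cfg, "full_use")
        ct = run_scenario(cohort, curves, {2010: 0.5}, default_cfg, "ct_only")
        assert half.total_ly == pytest.approx(
            0.5 * full.total_ly + 0.5 * ct.total_ly, rel=1e-9)
        assert half.total_dfly == pytest.approx(
            0.5 * full.total_dfly + 0.5 * ct.total_dfly, rel=1e-9)
        assert half.total_cost == pytest.approx(
            0.5 * full.total_cost + 0.5 * ct.total_cost, rel=1e-9)

    def test_missing_share_year_raises(self, curves, default_cfg):
        with pytest.raises(KeyError, match="2010"):
            run_scenario(single_cohort(), curves, {}, default_cfg, "real_world")


class TestIcer:
    def test_published_cost_effect_cells(self):
        a = m.ScenarioResult("T+CT", 616_354.0, 534_907.0,
                             {"total": 1_581_553_536.0})
        b = m.ScenarioResult("CT", 564_137.0, 489_916.0,
                             {"total": 503_587_698.0})
        icer = m.compute_icer(a, b)
        assert icer.cost_per_lyg == 20_644
        assert icer.cost_per_dflyg == 23_960

    def test_identical_scenarios_flag_dominance(self):
        a = m.ScenarioResult("x", 100.0, 90.0, {"c": 10.0})
        icer = m.compute_icer(a, a)
        assert icer.dominance
        assert icer.cost_per_lyg is None
        assert icer.incremental_cost == 0.0


class TestSensitivity:
    def test_lyg_strictly_decreasing_in_discount_rate(self, cohorts, eff_inputs,
                                                      life_table, default_cfg):
        lygs = []
        for rate in (0.0, 0.03, 0.05):
            cfg = copy.deepcopy(default_cfg)
            cfg.discount_rate = rate
            lygs.append(run_full_analysis(cohorts, eff_inputs, life_table,
                                          cfg)["lyg"])
        assert lygs[0] > lygs[1] > lygs[2]

    def test_truncating_horizon_never_increases_lyg(self, cohorts, eff_inputs,
                                                    life_table, default_cfg):
        cfg = copy.deepcopy(default_cfg)
        cfg.horizon_year = 2030
        short = run_full_analysis(cohorts, eff_inputs, life_table, cfg)
        base = run_full_analysis(cohorts, eff_inputs, life_table, default_cfg)
        assert short["lyg"] <= base["lyg"]
        assert short["dflyg"] <= base["dflyg"]

    def test_cost_overrides_leave_effects_invariant(self, cohorts, eff_inputs,
                                                    life_table, default_cfg):
        scenarios = [s for s in default_sensitivity_scenarios(default_cfg)
                     if "recurrence cost" in s.name or "chemotherapy" in s.name
                     or s.name == "base case"]
        table = run_sensitivity(cohorts, eff_inputs, life_table, default_cfg,
                                scenarios).set_index("scenario")
        base = table.loc["base case"]
        for name in table.index.drop("base case"):
            assert table.loc[name, "lyg"] == pytest.approx(base["lyg"], rel=1e-12)
            assert table.loc[name, "dflyg"] == pytest.approx(base["dflyg"], rel=1e-12)
        # varying chemotherapy cost has no effect on incremental cost either
        for name in ("chemotherapy cost -25%", "chemotherapy cost +25%"):
            assert table.loc[name, "incremental_cost"] == pytest.approx(
                base["incremental_cost"], rel=1e-9)
        # recurrence cost endpoints do move the incremental cost
        assert (table.loc["recurrence cost lower", "incremental_cost"]
                != table.loc["recurrence cost upper", "incremental_cost"])

    def test_missing_alternative_efficacy_skipped_with_warning(
            self, cohorts, eff_inputs, life_table, default_cfg):
        scenarios = [s for s in default_sensitivity_scenarios(default_cfg)
                     if s.name == "efficacy HERA"]
        with pytest.warns(UserWarning, match="skipped"):
            table = run_sensitivity(cohorts, eff_inputs, life_table,
                                    default_cfg, scenarios)
        assert len(table) == 0

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ValueError, match="unknown override"):
            m.SensitivityScenario("bad", {"not_a_knob": 1})


class TestIncrementalSigns:
    def test_recurrence_category_savings_under_treatment(self, base_analysis):
        # dominating curves mean fewer relapses, hence lower recurrence cost
        full = base_analysis["full_use"]
        ct = base_analysis["ct_only"]
        assert full.costs["recurrence"] < ct.costs["recurrence"]

    def test_first_year_pharma_drives_incremental_cost(self, base_analysis):
        inc = base_analysis["full_use"] - base_analysis["ct_only"]
        assert inc.costs_by_category["first_year_pharma"] > 0
        assert inc.cost > 0
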