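"""Poisson incidence model, projection and target-population filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lygmodel as m
from lygmodel.incidence import IncidenceModel, round_half_up
from lygmodel.synthetic_data import SimulationSpec


def deterministic_table(rate=1e-3, n_bands=4, years=(2000, 2005), pop=50_000.0):
    """Counts set exactly to population x rate (no Poisson noise)."""
    rows = [(y, f"b{b}", "F", pop * rate, pop)
            for y in range(years[0], years[1] + 1) for b in range(n_bands)]
    return pd.DataFrame(rows, columns=["year", "age_band", "gender",
                                       "cases", "population"])


class TestFit:
    def test_recovers_year_slope_within_3_se(self):
        spec = SimulationSpec(seed=42, rate_year_slope=0.02)
        tab = m.simulate_incidence_table(spec)
        model = m.fit_incidence_model(tab)
        se = np.sqrt(model.cov[-1, -1])
        assert abs(model.year_effect - 0.02) < 3 * se

    def test_flat_rate_gives_zero_effects(self):
        model = m.fit_incidence_model(deterministic_table())
        assert model.year_effect == pytest.approx(0.0, abs=1e-8)
        assert all(abs(v) < 1e-8 for v in model.age_effects.values())

    def test_exposure_invariance(self):
        tab = deterministic_table()
        doubled = tab.assign(cases=tab.cases * 2, population=tab.population * 2)
        m1, m2 = m.fit_incidence_model(tab), m.fit_incidence_model(doubled)
        for band in m1.age_effects:
            assert m1.rate(band, 2003) == pytest.approx(m2.rate(band, 2003), rel=1e-9)

    def test_degenerate_design_raises(self):
        tab = deterministic_table(years=(2000, 2000))
        with pytest.raises(ValueError, match="2 distinct years"):
            m.fit_incidence_model(tab)
        tab = deterministic_table(n_bands=1)
        with pytest.raises(ValueError, match="2 age bands"):
            m.fit_incidence_model(tab)


class TestProjection:
    @staticmethod
    def _model(rate):
        return IncidenceModel(intercept=np.log(rate), age_effects={"b0": 0.0},
                              year_effect=0.0, year_center=2000.0, deviance=0.0)

    def test_single_band_rate_times_population(self):
        counts = m.project_new_cases(
            self._model(2e-3),
            pd.DataFrame({"year": [2001], "age_band": ["b0"],
                          "population": [10_000.0]}),
            range(2001, 2002))
        assert counts[2001] == pytest.approx(2e-3 * 10_000)

    def test_constant_model_constant_pyramid(self):
        pyr = pd.DataFrame({"year": [2001, 2002], "age_band": ["b0", "b0"],
                            "population": [5000.0, 5000.0]})
        counts = m.project_new_cases(self._model(1e-3), pyr, range(2001, 2003))
        assert counts[2001] == counts[2002]

    def test_matches_brute_force_cell_sum(self):
        tab = m.simulate_incidence_table(SimulationSpec(seed=3))
        model = m.fit_incidence_model(tab)
        pyr = tab[["year", "age_band", "gender", "population"]]
        years = range(2000, 2005)
        counts = m.project_new_cases(model, pyr, years)
        for year in years:
            expected = sum(model.rate(b, year) * p for b, p in
                           pyr[pyr.year == year][["age_band", "population"]].values)
            assert counts[year] == pytest.approx(expected, rel=1e-9)

    def test_missing_cell_named_in_error(self):
        pyr = pd.DataFrame({"year": [2001], "age_band": ["b0"],
                            "population": [5000.0]})
        with pytest.raises(KeyError, match="year=2002"):
            m.project_new_cases(self._model(1e-3), pyr, range(2001, 2003))


class TestTargetPopulation:
    def test_back_solved_prevalence_reproduces_cohort(self):
        # 21,132 diagnoses, 18% in-situ and 7% metastatic exclusions,
        # prevalence back-solved from the published 2006 cohort of 2,664
        out = m.select_target_population({2006: 21_132}, 0.18, 0.07,
                                         {2006: 0.16530})
        assert out.target_n(2006) == 2664
        assert out.target_n(2006) == round_half_up(21_132 * 0.82 * 0.93 * 0.16530)

    def test_no_filters_is_identity(self):
        out = m.select_target_population({2010: 1000}, 0.0, 0.0, {2010: 1.0})
        assert out.target_n(2010) == 1000

    def test_zero_prevalence_gives_empty_cohort(self):
        out = m.select_target_population({2010: 1000}, 0.18, 0.07, {2010: 0.0})
        assert out.target_n(2010) == 0

    def test_missing_prevalence_year_raises(self):
        with pytest.raises(KeyError, match="2011"):
            m.select_target_population({2011: 1000}, 0.1, 0.1, {2010: 0.2})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 1), d2=st.floats(0, 1), p=st.floats(0, 1))
    def test_monotone_in_exclusions_and_filter_order_free(self, d1, d2, p):
        n = 10_000
        base = m.select_target_population({2006: n}, d1, d2, {2006: p},
                                          rounding=False).target_n(2006)
        more = m.select_target_population({2006: n}, min(d1 + 0.1, 1), d2,
                                          {2006: p}, rounding=False).target_n(2006)
        assert more <= base + 1e-9
        swapped = m.select_target_population({2006: n}, d2, d1, {2006: p},
                                             rounding=False).target_n(2006)
        assert swapped == pytest.approx(base, abs=1e-9)

    def test_target_cannot_exceed_total(self):
        tab = pd.DataFrame({"total_bc_cases": [100], "target_n": [101]},
                           index=pd.Index([2006], name="year"))
        with pytest.raises(ValueError, match="exceeds total"):
            m.TargetCohorts(tab)
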