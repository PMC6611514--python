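"""Pseudo-IPD reconstruction, Weibull MLE, stitching and mortality adjustment."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter, WeibullFitter

import lygmodel as m
from lygmodel.survival import LifeTable, SurvivalCurve, weibull_loglik
from lygmodel.synthetic_data import digitize_km, make_life_table


class TestPseudoIPD:
    def test_complete_sample_recovered_exactly(self):
        # KM of a complete (uncensored) sample is the empirical survival:
        # ten unit drops must come back as ten events at the step times
        times = np.arange(1.0, 11.0)
        surv = 1.0 - times / 10.0
        ipd = m.reconstruct_pseudo_ipd(times, surv, 10)
        assert ipd.event.all()
        np.testing.assert_allclose(np.sort(ipd.time), times)

    def test_flat_curve_all_censored_at_cutoff(self):
        ipd = m.reconstruct_pseudo_ipd([5.0], [1.0], 100, censor_after=5.0)
        assert ipd.n == 100 and not ipd.event.any()
        assert (ipd.time == 5.0).all()

    def test_round_trip_sup_norm(self):
        data = m.simulate_km_dataset(m.WeibullParams(1.3, 12.0), 300,
                                     censor_rate=0.05, cutoff=10.0, seed=21)
        times, surv, at_risk = digitize_km(data, cutoff=10.0)
        ipd = m.reconstruct_pseudo_ipd(times, surv, data.n, at_risk,
                                       censor_after=10.0)
        assert ipd.n == data.n
        kmf = KaplanMeierFitter().fit(ipd.time, ipd.event)
        rec = kmf.survival_function_at_times(times).to_numpy()
        assert np.abs(rec - surv).max() <= 0.01

    def test_increasing_survival_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            m.reconstruct_pseudo_ipd([1.0, 2.0], [0.8, 0.9], 100)

    def test_inconsistent_at_risk_warns(self):
        times = np.arange(1.0, 6.0)
        surv = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        with pytest.warns(UserWarning, match="best-effort"):
            m.reconstruct_pseudo_ipd(times, surv, 100, at_risk=[(3.0, 95)])


class TestWeibullMLE:
    def test_exponential_closed_form(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        data = m.EventData(time, np.ones(4, dtype=bool))
        fit = m.fit_weibull_mle(data, fixed_shape=1.0)
        assert fit.params.scale == pytest.approx(time.sum() / 4, rel=1e-12)

    def test_parameter_recovery_within_3_se(self):
        data = m.simulate_km_dataset(m.WeibullParams(1.4, 9.0), 2000,
                                     censor_rate=0.03, cutoff=10.0, seed=7)
        fit = m.fit_weibull_mle(data)
        assert abs(fit.params.shape - 1.4) < 3 * fit.se_shape
        assert abs(fit.params.scale - 9.0) < 3 * fit.se_scale

    def test_optimum_beats_surrounding_grid(self):
        data = m.simulate_km_dataset(m.WeibullParams(1.2, 8.0), 400,
                                     censor_rate=0.05, cutoff=12.0, seed=3)
        fit = m.fit_weibull_mle(data)
        k, lam = fit.params.shape, fit.params.scale
        grid = [(k * fk, lam * fl)
                for fk in np.linspace(0.8, 1.2, 21) for fl in (0.9, 1.0, 1.1)]
        assert fit.loglik >= max(weibull_loglik(a, b, data) for a, b in grid) - 1e-9

    def test_loglik_agrees_with_naive_summation_oracle(self):
        rng = np.random.default_rng(5)
        data = m.EventData(rng.uniform(0.1, 10, 20), rng.uniform(size=20) < 0.7)
        k, lam = 1.3, 6.0
        naive = 0.0
        for t, e in zip(data.time, data.event):
            s = np.exp(-((t / lam) ** k))
            if e:
                h = (k / lam) * (t / lam) ** (k - 1)
                naive += np.log(h) + np.log(s)
            else:
                naive += np.log(s)
        assert weibull_loglik(k, lam, data) == pytest.approx(naive, abs=1e-8)

    def test_agrees_with_lifelines_weibull_fitter(self):
        data = m.simulate_km_dataset(m.WeibullParams(1.4, 9.0), 1000,
                                     censor_rate=0.03, cutoff=10.0, seed=13)
        fit = m.fit_weibull_mle(data)
        wf = WeibullFitter().fit(data.time, data.event)
        assert fit.params.scale == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.params.shape == pytest.approx(wf.rho_, rel=1e-4)

    def test_too_few_events_raises(self):
        data = m.EventData([1.0, 2.0], [True, False])
        with pytest.raises(ValueError, match="events"):
            m.fit_weibull_mle(data)


class TestSurvivalAt:
    @pytest.mark.parametrize("params, t, expected", [
        (m.WeibullParams(1.7, 3.0), 0.0, 1.0),
        (m.WeibullParams(1.0, 10.0), 10.0, np.exp(-1.0)),
        (m.WeibullParams(2.0, 10.0), 5.0, np.exp(-0.25)),
    ])
    def test_closed_forms(self, params, t, expected):
        assert m.survival_at(params, t) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            m.survival_at(m.WeibullParams(1.0, 1.0), -1.0)


class TestStitch:
    def setup_method(self):
        self.params = m.WeibullParams(1.3, 20.0)
        self.grid = np.arange(31.0)

    def test_switch_zero_is_pure_parametric(self):
        curve = m.stitch_curve(np.array([1.0]), self.params, 0, 30)
        np.testing.assert_allclose(curve.values, self.params.survival(self.grid))

    def test_km_equal_to_parametric_gives_identity(self):
        km = self.params.survival(np.arange(11.0))
        curve = m.stitch_curve(km, self.params, 10, 30)
        np.testing.assert_allclose(curve.values, self.params.survival(self.grid),
                                   rtol=1e-12)

    def test_continuity_at_switch(self):
        km = np.linspace(1.0, 0.7, 11)  # empirical curve unlike the Weibull
        curve = m.stitch_curve(km, self.params, 10, 30)
        assert curve.values[10] == pytest.approx(km[10], abs=0.0)
        np.testing.assert_allclose(curve.values[:11], km)
        assert np.all(np.diff(curve.values) <= 1e-12)

    def test_switch_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="switch_time"):
            m.stitch_curve(np.ones(11), self.params, 10, 5)


class TestBackgroundMortality:
    def _curve(self, values):
        return SurvivalCurve("OS", "T+CT", np.asarray(values, dtype=float))

    def test_negligible_background_leaves_curve_unchanged(self):
        lt = make_life_table(130, (1e-12, 0.0))
        curve = self._curve(m.WeibullParams(1.2, 20.0).survival(np.arange(11.0)))
        out = m.adjust_for_background_mortality(curve, lt, {50: 1.0})
        np.testing.assert_allclose(out.values, curve.values, rtol=1e-6)

    def test_flat_curve_decays_at_background_rate(self):
        lt = LifeTable(np.arange(0, 121), np.r_[np.full(120, 0.1), 1.0])
        out = m.adjust_for_background_mortality(self._curve(np.ones(11)), lt,
                                                {50: 1.0})
        np.testing.assert_allclose(out.values, 0.9 ** np.arange(11.0), rtol=1e-12)

    def test_adjusted_below_unadjusted_and_matches_stepwise_oracle(self):
        lt = make_life_table()
        values = m.WeibullParams(1.2, 25.0).survival(np.arange(30.0))
        weights = {55: 0.5, 70: 0.5}
        out = m.adjust_for_background_mortality(self._curve(values), lt, weights)
        assert np.all(out.values <= values + 1e-12)
        # brute-force year-by-year recomputation
        s = 1.0
        for t in range(1, 30):
            p_model = 1.0 - values[t] / values[t - 1]
            q = 0.5 * lt.q_at(55 + t - 1) + 0.5 * lt.q_at(70 + t - 1)
            s *= 1.0 - max(p_model, q)
            assert out.values[t] == pytest.approx(s, rel=1e-12)

    def test_requires_os_curve_and_coverage(self):
        lt = make_life_table(60)
        with pytest.raises(ValueError, match="OS"):
            m.adjust_for_background_mortality(
                SurvivalCurve("DFS", "CT", np.ones(5)), lt, {50: 1.0})
        with pytest.raises(KeyError, match="cover"):
            lt.q_at(-1)

    def test_dfs_capped_by_os_flags_grid_points(self):
        os_c = self._curve([1.0, 0.9, 0.8])
        dfs_c = SurvivalCurve("DFS", "T+CT", [1.0, 0.95, 0.75])
        capped = m.cap_dfs_by_os(os_c, dfs_c)
        assert capped.capped_at == (1,)
        assert np.all(capped.values <= os_c.values)


def test_parameter_recovery_median_error_across_replicates():
    """Median absolute relative error of (shape, scale) below 5% at n=1000."""
    errs = []
    for seed in range(20):
        data = m.simulate_km_dataset(m.WeibullParams(1.4, 9.0), 1000,
                                     censor_rate=0.03, cutoff=10.0, seed=seed)
        fit = m.fit_weibull_mle(data)
        errs.append(abs(fit.params.shape - 1.4) / 1.4)
        errs.append(abs(fit.params.scale - 9.0) / 9.0)
    assert np.median(errs) < 0.05
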