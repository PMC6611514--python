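"""Run the full pipeline: cohorts, scenarios, incremental effects and ICER.

Uses the published per-year target cohorts (2006-2017) and synthetic trial
efficacy, then compares the real-world scenario (market-share-weighted
trastuzumab use) with the chemotherapy-only counterfactual, and the full-use
scenario for the cost-effectiveness ratio.
"""

import numpy as np

import lygmodel as m
from lygmodel.reference import target_population_frame
from lygmodel.scenarios import EfficacyInputs, run_full_analysis
from lygmodel.synthetic_data import default_km_params, digitize_km, make_life_table

AGE_WEIGHTS = {42: 0.25, 52: 0.35, 62: 0.25, 72: 0.15}

km, params = {}, {}
for i, (key, true_p) in enumerate(sorted(default_km_params().items())):
    data = m.simulate_km_dataset(true_p, 1000, 0.03, 10.0, seed=100 + i)
    times, surv, at_risk = digitize_km(data, cutoff=10.0)
    ipd = m.reconstruct_pseudo_ipd(times, surv, data.n, at_risk, censor_after=10.0)
    km[key] = np.concatenate([[1.0], surv])
    params[key] = m.fit_weibull_mle(ipd).params
eff = EfficacyInputs(km, params, followup_years=10)

cohorts = m.TargetCohorts(target_population_frame(), AGE_WEIGHTS)
cfg = m.make_default_config()
out = run_full_analysis(cohorts, eff, make_life_table(), cfg)

print(f"cohorts 2006-2017: {cohorts.total_target:,.0f} women, follow-up to "
      f"{cfg.horizon_year}, discounted at {cfg.discount_rate:.0%} from "
      f"{cfg.reference_year}\n")
for name in ("real_world", "ct_only", "full_use"):
    r = out[name]
    print(f"{name:>10}: LY {r.total_ly:12,.0f}   DFLY {r.total_dfly:12,.0f}   "
          f"cost {r.total_cost / 1e6:8,.1f} M EUR")
print(f"\nlife years gained (real-world vs CT-only):      {out['lyg']:10,.0f}")
print(f"disease-free life years gained:                 {out['dflyg']:10,.0f}")
print(f"incremental direct cost:                        {out['incremental_cost'] / 1e6:10,.1f} M EUR")
icer = out["icer"]
print(f"ICER (full use vs CT-only): {icer.cost_per_lyg:,} EUR/LYG, "
      f"{icer.cost_per_dflyg:,} EUR/DFLYG")
print(f"life years still lost vs the general population: "
      f"{out['ly_lost_vs_general_population']:,.0f}")
print("\n-> effects come from the area between the scenario survival curves;\n"
      "   costs are dominated by first-year trastuzumab, partly offset by\n"
      "   avoided recurrences.")
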