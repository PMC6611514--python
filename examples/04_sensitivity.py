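"""Deterministic sensitivity battery: one full pipeline re-run per scenario.

Shows how the incremental effects and cost respond to the horizon, the
discount rate, the parametric switch, the progression method, the recurrence
window and the unit-cost ranges.  Effects must be untouched by pure cost
overrides, and chemotherapy cost must cancel out of the increment entirely.
"""

import warnings

import numpy as np

import lygmodel as m
from lygmodel.reference import target_population_frame
from lygmodel.scenarios import (EfficacyInputs, default_sensitivity_scenarios,
                                run_sensitivity)
from lygmodel.synthetic_data import default_km_params, digitize_km, make_life_table

km, params = {}, {}
for i, (key, true_p) in enumerate(sorted(default_km_params().items())):
    data = m.simulate_km_dataset(true_p, 1000, 0.03, 10.0, seed=100 + i)
    times, surv, at_risk = digitize_km(data, cutoff=10.0)
    ipd = m.reconstruct_pseudo_ipd(times, surv, data.n, at_risk, censor_after=10.0)
    km[key] = np.concatenate([[1.0], surv])
    params[key] = m.fit_weibull_mle(ipd).params
eff = EfficacyInputs(km, params, followup_years=10)

cohorts = m.TargetCohorts(target_population_frame(),
                          {42: 0.25, 52: 0.35, 62: 0.25, 72: 0.15})
cfg = m.make_default_config()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the alternative-efficacy slot is empty
    table = run_sensitivity(cohorts, eff, make_life_table(), cfg,
                            default_sensitivity_scenarios(cfg))

table["incremental_cost_meur"] = table.pop("incremental_cost") / 1e6
print(table.to_string(index=False, float_format=lambda x: f"{x:,.0f}"))
print("\n-> LYG falls with a shorter horizon or a higher discount rate; cost\n"
      "   overrides leave the effects untouched, and chemotherapy cost\n"
      "   cancels exactly because both scenarios administer it.")
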