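import numpy as np
import pytest

import lygmodel as m
from lygmodel.reference import target_population_frame
from lygmodel.scenarios import EfficacyInputs
from lygmodel.synthetic_data import default_km_params, digitize_km, make_life_table

# age-at-diagnosis weights used for background mortality and the comparator
AGE_WEIGHTS = {42: 0.25, 52: 0.35, 62: 0.25, 72: 0.15}


@pytest.fixture(scope="session")
def default_cfg():
    return m.make_default_config()


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def eff_inputs():
    """Synthetic trial efficacy: simulate each endpoint/arm from known Weibull
    parameters, digitize the KM curve, reconstruct pseudo-IPD and refit."""
    km, params = {}, {}
    for i, (key, true_p) in enumerate(sorted(default_km_params().items())):
        data = m.simulate_km_dataset(true_p, 1000, 0.03, 10.0, seed=100 + i)
        times, surv, at_risk = digitize_km(data, cutoff=10.0)
        ipd = m.reconstruct_pseudo_ipd(times, surv, data.n, at_risk,
                                       censor_after=10.0)
        fit = m.fit_weibull_mle(ipd)
        km[key] = np.concatenate([[1.0], surv])
        params[key] = fit.params
    return EfficacyInputs(km, params, followup_years=10)


@pytest.fixture(scope="session")
def cohorts():
    return m.TargetCohorts(target_population_frame(), dict(AGE_WEIGHTS))


@pytest.fixture(scope="session")
def base_analysis(cohorts, eff_inputs, life_table, default_cfg):
    from lygmodel.scenarios import run_full_analysis
    return run_full_analysis(cohorts, eff_inputs, life_table, default_cfg)
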