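"""Digitize a simulated trial curve, reconstruct pseudo-IPD, fit and stitch.

Mirrors the effectiveness stage: published KM curves are digitized, pseudo
individual-patient data are rebuilt from the step coordinates and numbers at
risk, a Weibull tail is fitted by maximum likelihood and stitched to the
empirical curve, and overall survival is floored by life-table mortality.
"""

import numpy as np

import lygmodel as m
from lygmodel.synthetic_data import digitize_km, make_life_table

true = m.WeibullParams(shape=1.2, scale=45.0)
data = m.simulate_km_dataset(true, n=1000, censor_rate=0.03, cutoff=10.0, seed=7)

times, surv, at_risk = digitize_km(data, cutoff=10.0)
ipd = m.reconstruct_pseudo_ipd(times, surv, data.n, at_risk, censor_after=10.0)
fit = m.fit_weibull_mle(ipd)
print(f"true parameters:   shape={true.shape:.3f}  scale={true.scale:.1f}")
print(f"fitted parameters: shape={fit.params.shape:.3f}  "
      f"scale={fit.params.scale:.1f}  (se {fit.se_shape:.3f} / {fit.se_scale:.1f})")
print("-> the fit recovers the generating parameters from nothing but the\n"
      "   digitized step coordinates and at-risk counts.\n")

km_annual = np.concatenate([[1.0], surv])
curve = m.stitch_curve(km_annual, fit.params, switch_time=10, horizon=29,
                       endpoint="OS", arm="T+CT")
adjusted = m.adjust_for_background_mortality(curve, make_life_table(),
                                             {42: 0.25, 52: 0.35, 62: 0.25, 72: 0.15})
print("year   empirical/stitched   mortality-adjusted")
for t in (5, 10, 20, 29):
    print(f"{t:4d}   {curve.values[t]:.4f}               {adjusted.values[t]:.4f}")
print("-> beyond the 10-year switch the Weibull tail extrapolates; the\n"
      "   adjustment only bites in the tail, where general-population\n"
      "   mortality at the attained ages overtakes the modelled hazard.")
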