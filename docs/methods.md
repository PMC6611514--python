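# Methods

## Model structure

The model is a deterministic expected-value cohort model, not a
microsimulation. Twelve annual incidence cohorts (2006–2017) of women newly
diagnosed with HER2+ early breast cancer are each followed in annual cycles
from their diagnosis year to the 2035 horizon (mean follow-up 23.5 years
across cohorts). Within each cohort two survival curves — overall survival
(OS) and disease-free survival (DFS) — fully determine the trace: expected
survivors are `n₀·OS(t)`, disease-free survivors `n₀·min(DFS, OS)(t)`, and
the progressed-state prevalence is their difference (partitioned-survival
logic). Scenario comparisons are differences of aggregated traces; because
every operation is linear in cohort size, the real-world scenario is exactly
the market-share-weighted convex combination of the full-use and
chemotherapy-only scenarios, a property the tests assert at 10⁻⁹.

## Survival inputs and extrapolation

Trial follow-up (10 years) is shorter than the horizon (up to 29 years), so
the curves are extrapolated:

1. **Pseudo-IPD reconstruction.** Digitized KM step coordinates plus numbers
   at risk are converted back to event/censoring records by interval
   allocation: within each at-risk interval a censor count is guessed, censor
   times spread uniformly, events at each step chosen so the running KM
   product matches the published value, and the censor count iterated until
   the next at-risk anchor is matched (best effort with a warning when the
   anchors are inconsistent). Without anchors, no censoring is assumed before
   the end of follow-up. The recomputed KM reproduces the input within one
   patient per step; on simulated 300-patient curves the round-trip sup-norm
   error is below 0.01.
2. **Weibull MLE.** `S(t) = exp(−(t/λ)^k)` is fitted by maximizing the
   right-censored log-likelihood (Nelder–Mead polish + BFGS on
   log-parameters; gradient-norm convergence check; standard errors from the
   finite-difference Hessian by the delta method). A `fixed_shape` path gives
   the closed-form conditional scale MLE (exponential when the shape is 1).
   This parameterization is fixed package-wide; rate-form parameters must be
   converted at the boundary.
3. **Stitching.** The curve equals the empirical KM on the annual grid up to
   `switch_time` (default 10, the trial follow-up; 0 in the
   parametric-from-the-start sensitivity mode, interpreted as t = 0 with a
   config override) and the Weibull tail after, rescaled by
   `km(switch)/S_param(switch)` for continuity.
4. **Background mortality.** Per annual step the applied death probability is
   `max(model-implied q, cohort-weighted life-table q at the attained age)`.
   The hazard-level maximum (rather than a minimum of survival functions)
   guarantees a proper, non-increasing survival curve and only affects the
   tail, where general-population mortality at ages 70+ overtakes the
   modelled hazard. Attained age is age at diagnosis plus elapsed years, with
   the age-at-diagnosis distribution supplied as weights; DFS is capped by
   the adjusted OS pointwise afterwards, and capped grid points are flagged.

## Cohort accounting and discounting

Person-years use the trapezoid (half-cycle) rule, `n₀·(S(t−1)+S(t))/2` per
annual interval; against a fine-grid integration of the same Weibull curve
the annual engine is within 1% over 29 years. The interval from t−1 to t is
booked to calendar year `cohort_year + t − 1`, so years lived in the
diagnosis year count from the start of that calendar year. Discounting at the
3% temporal preference rate divides amounts in calendar years after 2017 by
`1.03^(year−2017)`; calendar years up to 2017 are not discounted (the
analysis is referenced to the present), with `discount_past=True` available
for the conventional alternative. The general-population comparator rebuilds
survival for each cohort purely from the life table and accumulates and
discounts life years identically.

## Progressions

The Markov-cohort rule counts `n₀·[(DFS(t−1)−DFS(t)) − (OS(t−1)−OS(t))]` new
progressions per cycle; algebraically this equals the change in progressed
prevalence. The partitioned-survival rule (base case) adds the exits of
previously progressed patients: `new_t = prev_t − prev_{t−1}(1−m_t)` with the
progressed-state mortality `m_t` defaulting to the cohort OS hazard
(overridable, e.g. 0 reduces to pure prevalence increments). The two methods
therefore coincide exactly when nobody dies during the window and differ by
the progressed-state deaths otherwise — which is precisely what the
Markov-vs-PSM sensitivity row measures on the cost side. Negative raw
increments (digitization noise where the curves cross) are floored at zero
and the affected years flagged. Recurrences are assumed to occur only within
7 years of diagnosis (time since diagnosis and since initial treatment are
treated as the same clock); the cap is removable for sensitivity analysis.

## Costs

Only direct healthcare costs enter, in four categories. First-year pharmacy
expands each regimen into its administration calendar (trastuzumab IV:
loading plus 17 three-weekly maintenance doses, 18 administrations within 52
weeks; SC: 18 flat 600 mg doses; AC-T with weekly paclitaxel; TC), converts
per-kg/per-m² doses with the 66.4 kg / 1.73 m² reference patient, and prices
whole vials (`ceil(mg/vial)`), with exact-milligram pricing available for
sensitivity analysis. The statutory deduction of the cohort year applies to
trastuzumab only (IV: 0% through 2010, 7.5% 2011–2013, 15% from 2014; SC:
7.5% from 2014 — the boundary years are a package choice within the stated
ranges, consistent with the pinned 2008/2012/2016 multipliers). Chemotherapy
is priced at current prices for all cohorts. IV administrations incur the
€211.64 day-hospital fee per visit week (co-administered drugs share a
visit; SC doses generate none); trastuzumab-treated patients receive 4
echocardiograms (€133) in the treatment year and one per disease-free year
thereafter until the horizon. Both fees are CPI-adjustable per year; the
shipped CPI series is flat at 1.0 because the underlying index values are not
published at that granularity, and the fees are stated at 2017 level.
Recurrences carry a one-off €183,170 cost (midpoint of the €157,658–€208,682
weighted range, the range endpoints being the sensitivity bounds) charged
entirely in the progression year, equal for all cohorts. Because the
chemotherapy backbone is identical in both scenarios it cancels exactly from
every incremental result, which the sensitivity battery demonstrates.

## Synthetic data

The generators emulate the statistical structure of the four unpublished
inputs. Incidence: Poisson counts with log-rate linear in 5-year age band
(13 bands, 25–90) and calendar year; the defaults (baseline 18/100,000 in
the youngest band, age slope 0.25 per band, year slope 0.005, 1.5 M women
per band) put annual totals in the low twenty-thousands, the magnitude of the
Spanish registry estimates. Life table: Gompertz hazard
`α·exp(β·age)` with α = 2·10⁻⁵, β = 0.095 (q ≈ 0.001 at 40, ≈ 0.04 at 80),
closed at age 110. Trial data: Weibull event times with exponential plus
administrative censoring; the default parameters — OS (k 1.2, λ 45) vs
(1.2, 34), DFS (1.0, 34) vs (1.0, 26), 1,000 patients per arm, 3% annual
censoring, 10-year cutoff — give ten-year survival near the long-term trial
estimates for chemotherapy with and without adjuvant trastuzumab. The
digitizer emits yearly step coordinates and at-risk counts so the
reconstruction path is exercised end to end.

What the synthetic data do **not** emulate: real population pyramids and
their ageing (the pyramid is flat, so projected case growth comes from the
year slope only), age-dependent treatment effects, non-Weibull hazard shapes,
informative censoring, and real vial prices. Passing tests therefore
establish that the machinery is correct and internally consistent — parameter
recovery, conservation, monotonicity, convexity — not that the shipped
defaults reproduce the published Spanish totals, which rest on fitted
parameters and market shares that were never printed and are reproduced only
as arithmetic identities from their printed inputs.

## Numerical choices and edge cases

* Target-population sizes are rounded half-up per cohort year (published
  tables are integers); internal arithmetic is unrounded elsewhere, ICERs are
  rounded to the euro for display only.
* The Weibull fit requires at least two events and strictly positive event
  times; non-convergence raises with the final gradient norm.
* Pseudo-IPD censor-count iteration is capped at 40 rounds; the best
  allocation is kept and a warning issued if an anchor cannot be matched.
* Survival curves validate `S(0)=1`, monotonicity and range at construction;
  DFS>OS inputs to the progression functions are errors (cap first).
* Degenerate incidence designs (one year, one band) and missing pyramid
  cells, prices, CPI years, prevalence years or market shares raise errors
  naming the offending cell.
* Market shares default to a linear 0.40 (2006) → 1.00 (2014) ramp, held at
  1.0 thereafter, with a 50:50 IV/SC split from 2015 — configuration data, as
  the published year-by-year bars are not numeric.

## Problem sizes

Tests and the acceptance script run the full pipeline at the study scale
(12 cohorts, ~36,000 women, 29-year horizon) because the engine works on
expected values and is cheap; simulation-based validation uses 1,000-patient
trial arms and 50 replicates for parameter recovery. The whole suite runs in
a few seconds.
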