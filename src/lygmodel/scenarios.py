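"""Scenario assembly, incremental cost-effectiveness, and sensitivity analysis.

Three scenario modes are compared.  ``real_world`` splits each cohort by the
year's trastuzumab market share into a treated part (T+CT curves and costs)
and an untreated part (CT curves and costs); ``full_use`` treats everyone
(the comparison used for the ICER, so the incremental effect reflects the
drug and not its uptake); ``ct_only`` treats no one.  Results are additive
over the split, so the real-world scenario is the exact share-weighted convex
combination of the two pure scenarios.  The deterministic sensitivity driver
re-runs the full pipeline per scenario (horizon, discount rate, parametric
switch, progression method, recurrence cap and cost, unit-cost multipliers,
alternative efficacy curves).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_engine import (CohortTrace, ScenarioResult, aggregate,
                            build_cohort_trace, general_population_ly)
from .config import ModelConfig
from .costs import ancillary_costs, iv_visit_weeks, regimen_pharma_cost
from .incidence import TargetCohorts
from .progression import new_progressions_markov, new_progressions_psm
from .survival import (LifeTable, SurvivalCurve, WeibullParams,
                       adjust_for_background_mortality, cap_dfs_by_os,
                       stitch_curve)

__all__ = [
    "EfficacyInputs", "IcerResult", "SensitivityScenario", "build_curves",
    "run_scenario", "compute_icer", "run_full_analysis", "run_sensitivity",
    "default_sensitivity_scenarios", "curves_to_frame",
]

ARMS = ("T+CT", "CT")
ENDPOINTS = ("OS", "DFS")


@dataclass
class EfficacyInputs:
    """Empirical annual survival and fitted Weibull tails per endpoint/arm."""

    km: dict[tuple[str, str], np.ndarray]  # annual S on t = 0..followup_years
    params: dict[tuple[str, str], WeibullParams]
    followup_years: int

    def __post_init__(self) -> None:
        for key in [(e, a) for e in ENDPOINTS for a in ARMS]:
            if key not in self.km or key not in self.params:
                raise KeyError(f"efficacy inputs missing {key}")


def build_curves(eff: EfficacyInputs, switch_time: int, horizon: int,
                 life_table: LifeTable, age_weights: dict[int, float],
                 ) -> dict[tuple[str, str], SurvivalCurve]:
    """Stitch, mortality-adjust and order-cap the four scenario curves."""
    switch = int(min(switch_time, eff.followup_years))
    curves: dict[tuple[str, str], SurvivalCurve] = {}
    for arm in ARMS:
        os_c = stitch_curve(eff.km[("OS", arm)], eff.params[("OS", arm)],
                            switch, horizon, "OS", arm)
        os_c = adjust_for_background_mortality(os_c, life_table, age_weights)
        dfs_c = stitch_curve(eff.km[("DFS", arm)], eff.params[("DFS", arm)],
                             switch, horizon, "DFS", arm)
        curves[("OS", arm)] = os_c
        curves[("DFS", arm)] = cap_dfs_by_os(os_c, dfs_c)
    return curves


def curves_to_frame(curves: dict[tuple[str, str], SurvivalCurve]) -> pd.DataFrame:
    """Annual-grid curve table (year, OS_T+CT, OS_CT, DFS_T+CT, DFS_CT)."""
    out = pd.DataFrame({f"{e}_{a}": c.values for (e, a), c in sorted(curves.items())})
    out.insert(0, "year", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# per-cohort costing helpers
# ---------------------------------------------------------------------------

def _ct_backbone_cost(cfg: ModelConfig, year: int) -> float:
    """Mix-weighted chemotherapy cost per patient at current prices.

    Within each backbone the taxane alternative (regimen ``<name>-alt`` when
    shipped) is blended by the taxane split.
    """
    cost = 0.0
    for name, w in cfg.costs.regimen_mix.items():
        main = regimen_pharma_cost(cfg.regimens[name], cfg.costs, year)
        alt_name = f"{name}-alt"
        if alt_name in cfg.regimens:
            alt = regimen_pharma_cost(cfg.regimens[alt_name], cfg.costs, year)
            main = cfg.costs.taxane_split * main + (1 - cfg.costs.taxane_split) * alt
        cost += w * main
    return cost


def _ct_visits(cfg: ModelConfig) -> float:
    """Mix-weighted IV day-hospital visits per patient for chemotherapy alone."""
    return sum(
        w * len(iv_visit_weeks([cfg.regimens[name]], cfg.costs.patient_weight_kg,
                               cfg.costs.body_surface_m2))
        for name, w in cfg.costs.regimen_mix.items())


def _ct_with_trastuzumab_iv_visits(cfg: ModelConfig) -> float:
    """Visits when IV trastuzumab runs alongside the backbone (shared weeks)."""
    t_iv = cfg.regimens["trastuzumab_iv"]
    return sum(
        w * len(iv_visit_weeks([cfg.regimens[name], t_iv],
                               cfg.costs.patient_weight_kg,
                               cfg.costs.body_surface_m2))
        for name, w in cfg.costs.regimen_mix.items())


def _progression_series(os_c, dfs_c, n0, cfg: ModelConfig):
    if cfg.progression_method == "markov":
        return new_progressions_markov(os_c, dfs_c, n0, cfg.recurrence_cap_years)
    return new_progressions_psm(os_c, dfs_c, n0, cfg.recurrence_cap_years)


def _cohort_part(n0: float, arm: str, year: int, treated: bool,
                 curves, cfg: ModelConfig, ct_multiplier: float,
                 ) -> tuple[CohortTrace, pd.DataFrame]:
    """Trace plus undiscounted cost stream for one (cohort, arm) part."""
    os_c, dfs_c = curves[("OS", arm)], curves[("DFS", arm)]
    trace = build_cohort_trace(n0, os_c, dfs_c, year, cfg.horizon_year,
                               scenario=arm)
    prog = _progression_series(os_c, dfs_c, n0, cfg)

    ct_cost = _ct_backbone_cost(cfg, year) * ct_multiplier
    if treated:
        sc = cfg.sc_split.get(year, 0.0)
        pharma = ct_cost + (
            (1 - sc) * regimen_pharma_cost(cfg.regimens["trastuzumab_iv"], cfg.costs, year)
            + sc * regimen_pharma_cost(cfg.regimens["trastuzumab_sc"], cfg.costs, year))
        visits = (1 - sc) * _ct_with_trastuzumab_iv_visits(cfg) + sc * _ct_visits(cfg)
        treated_frac = 1.0
    else:
        pharma = ct_cost
        visits = _ct_visits(cfg)
        treated_frac = 0.0

    stream = ancillary_costs(trace, prog, cfg.costs, treated_frac,
                             n_iv_visits_per_patient=visits)
    pharma_row = pd.DataFrame([(year, year, "first_year_pharma", n0 * pharma)],
                              columns=["cohort_year", "calendar_year",
                                       "category", "amount"])
    return trace, pd.concat([pharma_row, stream], ignore_index=True)


def run_scenario(cohorts: TargetCohorts, curves, shares: dict[int, float],
                 cfg: ModelConfig, mode: str,
                 ct_multiplier: float = 1.0) -> ScenarioResult:
    """Run one scenario across all cohorts and aggregate.

    ``mode``: ``real_world`` (per-year market share), ``full_use`` (share 1,
    the ICER numerator scenario) or ``ct_only`` (share 0).
    """
    if mode not in ("real_world", "full_use", "ct_only"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    traces: list[CohortTrace] = []
    streams: list[pd.DataFrame] = []
    for year in cohorts.years:
        n0 = cohorts.target_n(year)
        if mode == "real_world":
            if year not in shares:
                raise KeyError(f"market share missing for cohort year {year}")
            share = shares[year]
        else:
            share = 1.0 if mode == "full_use" else 0.0
        for arm, part_n, treated in (("T+CT", n0 * share, True),
                                     ("CT", n0 * (1 - share), False)):
            if part_n <= 0:
                continue
            trace, stream = _cohort_part(part_n, arm, year, treated, curves,
                                         cfg, ct_multiplier)
            traces.append(trace)
            streams.append(stream)
    all_streams = (pd.concat(streams, ignore_index=True)
                   if streams else None)
    return aggregate(traces, all_streams, rate=cfg.discount_rate,
                     reference_year=cfg.reference_year,
                     discount_past=cfg.discount_past, scenario=mode)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

@dataclass
class IcerResult:
    incremental_cost: float
    incremental_ly: float
    incremental_dfly: float
    cost_per_lyg: float | None
    cost_per_dflyg: float | None
    dominance: bool = False


def compute_icer(a: ScenarioResult, b: ScenarioResult) -> IcerResult:
    """Incremental cost-effectiveness of scenario ``a`` versus ``b``.

    Ratios are computed from unrounded increments and rounded to the nearest
    euro for display; a non-positive incremental effect raises the dominance
    flag instead of reporting a ratio.
    """
    inc = a - b
    dominance = inc.lyg <= 0 or inc.dflyg <= 0
    per_lyg = round(inc.cost / inc.lyg) if inc.lyg > 0 else None
    per_dflyg = round(inc.cost / inc.dflyg) if inc.dflyg > 0 else None
    return IcerResult(inc.cost, inc.lyg, inc.dflyg, per_lyg, per_dflyg,
                      dominance)


# ---------------------------------------------------------------------------
# full pipeline and sensitivity battery
# ---------------------------------------------------------------------------

def run_full_analysis(cohorts: TargetCohorts, eff: EfficacyInputs,
                      life_table: LifeTable, cfg: ModelConfig,
                      ct_multiplier: float = 1.0) -> dict:
    """Base-case pipeline: build curves, run the three scenarios, derive
    incremental effects, incremental cost, ICERs and the general-population
    comparator."""
    horizon = cfg.horizon_year - min(cohorts.years)
    curves = build_curves(eff, cfg.switch_time, horizon, life_table,
                          cohorts.age_weights)
    real = run_scenario(cohorts, curves, cfg.market_shares, cfg, "real_world",
                        ct_multiplier)
    ct = run_scenario(cohorts, curves, cfg.market_shares, cfg, "ct_only",
                      ct_multiplier)
    full = run_scenario(cohorts, curves, cfg.market_shares, cfg, "full_use",
                        ct_multiplier)
    inc_real = real - ct
    gen_pop = general_population_ly(cohorts, life_table, cfg.horizon_year,
                                    cfg.discount_rate, cfg.reference_year,
                                    cfg.discount_past)
    return {
        "curves": curves,
        "real_world": real,
        "ct_only": ct,
        "full_use": full,
        "lyg": inc_real.lyg,
        "dflyg": inc_real.dflyg,
        "incremental_cost": inc_real.cost,
        "icer": compute_icer(full, ct),
        "general_population_ly": gen_pop,
        "ly_lost_vs_general_population": gen_pop - real.total_ly,
    }


_ALLOWED_OVERRIDES = {
    "horizon_year", "discount_rate", "switch_time", "progression_method",
    "recurrence_cap_years", "recurrence_cost", "admin_cost_multiplier",
    "echo_cost_multiplier", "ct_cost_multiplier", "efficacy",
}


@dataclass
class SensitivityScenario:
    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - _ALLOWED_OVERRIDES
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")


def default_sensitivity_scenarios(cfg: ModelConfig,
                                  hera_efficacy: EfficacyInputs | None = None,
                                  ) -> list[SensitivityScenario]:
    """The deterministic battery of the base analysis."""
    lo, hi = cfg.costs.recurrence_cost_range
    scenarios = [
        SensitivityScenario("base case", {}),
        SensitivityScenario("time horizon 2030", {"horizon_year": 2030}),
        SensitivityScenario("efficacy HERA", {"efficacy": hera_efficacy}),
        SensitivityScenario("parametric curves from the start", {"switch_time": 0}),
        SensitivityScenario("Markov progression estimation",
                            {"progression_method": "markov"}),
        SensitivityScenario("relapses beyond 7 years",
                            {"recurrence_cap_years": cfg.horizon_year - min(cfg.cohort_years)}),
        SensitivityScenario("discount rate 0%", {"discount_rate": 0.0}),
        SensitivityScenario("discount rate 5%", {"discount_rate": 0.05}),
        SensitivityScenario("administration cost -25%", {"admin_cost_multiplier": 0.75}),
        SensitivityScenario("administration cost +25%", {"admin_cost_multiplier": 1.25}),
        SensitivityScenario("echocardiogram cost -25%", {"echo_cost_multiplier": 0.75}),
        SensitivityScenario("echocardiogram cost +25%", {"echo_cost_multiplier": 1.25}),
        SensitivityScenario("chemotherapy cost -25%", {"ct_cost_multiplier": 0.75}),
        SensitivityScenario("chemotherapy cost +25%", {"ct_cost_multiplier": 1.25}),
        SensitivityScenario("recurrence cost lower", {"recurrence_cost": lo}),
        SensitivityScenario("recurrence cost upper", {"recurrence_cost": hi}),
    ]
    return scenarios


def run_sensitivity(cohorts: TargetCohorts, eff: EfficacyInputs,
                    life_table: LifeTable, cfg: ModelConfig,
                    scenarios: list[SensitivityScenario]) -> pd.DataFrame:
    """Re-run the full pipeline once per scenario.

    Returns a table of (scenario, lyg, dflyg, incremental_cost).  A scenario
    referencing an absent efficacy input is skipped with a warning.
    """
    rows = []
    for sc in scenarios:
        ov = dict(sc.overrides)
        eff_run = eff
        if "efficacy" in ov:
            eff_run = ov.pop("efficacy")
            if eff_run is None:
                warnings.warn(f"scenario {sc.name!r} skipped: efficacy input "
                              "not supplied", stacklevel=2)
                continue
        cfg_run = copy.deepcopy(cfg)
        if "recurrence_cost" in ov:
            cfg_run.costs.recurrence_cost = ov.pop("recurrence_cost")
        if "admin_cost_multiplier" in ov:
            cfg_run.costs.admin_visit_cost *= ov.pop("admin_cost_multiplier")
        if "echo_cost_multiplier" in ov:
            cfg_run.costs.echo_cost *= ov.pop("echo_cost_multiplier")
        ct_multiplier = ov.pop("ct_cost_multiplier", 1.0)
        cfg_run = replace(cfg_run, **ov)
        out = run_full_analysis(cohorts, eff_run, life_table, cfg_run,
                                ct_multiplier=ct_multiplier)
        rows.append((sc.name, out["lyg"], out["dflyg"], out["incremental_cost"]))
    return pd.DataFrame(rows, columns=["scenario", "lyg", "dflyg",
                                       "incremental_cost"])
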