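"""Annual-cycle cohort traces, discounting and cross-cohort aggregation.

Each incidence cohort is followed in annual cycles from its diagnosis year to
the horizon.  Expected survivors track the OS curve, disease-free survivors
the DFS curve, and person-years use the trapezoid (half-cycle) rule: the year
from t-1 to t contributes n0*(S(t-1)+S(t))/2 and is booked to calendar year
start_year + t - 1, so life years earned in the diagnosis year count from the
start of that calendar year.  Discounting divides amounts in calendar years
after the reference year by (1+rate)^(years past reference); earlier years
are left undiscounted (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .incidence import TargetCohorts
from .survival import LifeTable, SurvivalCurve, curve_from_life_table

__all__ = [
    "CohortTrace", "ScenarioResult", "Incremental", "build_cohort_trace",
    "discount", "discount_factors", "general_population_ly", "aggregate",
    "mean_followup_years",
]

COST_CATEGORIES = ("first_year_pharma", "administration", "monitoring", "recurrence")


@dataclass
class CohortTrace:
    """Per-calendar-year accounting for one cohort under one scenario."""

    cohort_year: int
    scenario: str
    n0: float
    frame: pd.DataFrame  # index calendar_year; alive, disease_free, ly, dfly

    @property
    def total_ly(self) -> float:
        return float(self.frame["ly"].sum())

    @property
    def total_dfly(self) -> float:
        return float(self.frame["dfly"].sum())

    def to_csv_rows(self) -> pd.DataFrame:
        out = self.frame.reset_index()
        out.insert(0, "scenario", self.scenario)
        out.insert(0, "cohort_year", self.cohort_year)
        return out


def build_cohort_trace(n0: float, os: SurvivalCurve, dfs: SurvivalCurve,
                       start_year: int, horizon_year: int,
                       scenario: str = "") -> CohortTrace:
    """Expected annual trace of one cohort from its OS/DFS curves.

    Covers calendar years start_year .. horizon_year - 1 (the cohort's
    follow-up is horizon_year - start_year years).  alive/disease_free are
    end-of-year expectations; ly/dfly use the trapezoid rule.
    """
    if horizon_year <= start_year:
        raise ValueError("horizon_year must be after start_year")
    if n0 < 0:
        raise ValueError("cohort size must be non-negative")
    duration = horizon_year - start_year
    if os.horizon < duration or dfs.horizon < duration:
        raise ValueError(
            f"curves must cover {duration} years (have {os.horizon}, {dfs.horizon})")

    years = np.arange(start_year, horizon_year)
    t = np.arange(1, duration + 1)
    os_v, dfs_v = os.values, dfs.values
    frame = pd.DataFrame({
        "alive": n0 * os_v[t],
        "disease_free": n0 * np.minimum(dfs_v[t], os_v[t]),
        "ly": n0 * (os_v[t - 1] + os_v[t]) / 2.0,
        "dfly": n0 * (dfs_v[t - 1] + dfs_v[t]) / 2.0,
    }, index=pd.Index(years, name="calendar_year"))
    return CohortTrace(start_year, scenario, n0, frame)


def discount_factors(years: pd.Index | np.ndarray, rate: float,
                     reference_year: int, discount_past: bool = False) -> np.ndarray:
    years = np.asarray(years, dtype=float)
    delta = years - reference_year
    if not discount_past:
        delta = np.maximum(delta, 0.0)
    return (1.0 + rate) ** (-delta)


def discount(values_by_calendar_year: pd.Series, rate: float,
             reference_year: int, discount_past: bool = False) -> pd.Series:
    """Temporal-preference discounting referenced to ``reference_year``.

    Values in years at or before the reference year are unchanged; later
    values are divided by (1+rate)^(year - reference_year).
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    f = discount_factors(values_by_calendar_year.index, rate, reference_year,
                         discount_past)
    return values_by_calendar_year * f


@dataclass
class ScenarioResult:
    """Totals across cohorts for one scenario (discounted unless noted)."""

    scenario: str
    total_ly: float
    total_dfly: float
    costs: dict[str, float] = field(default_factory=dict)
    total_ly_undiscounted: float | None = None
    total_dfly_undiscounted: float | None = None
    cohort_breakdown: pd.DataFrame | None = None

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    def __sub__(self, other: "ScenarioResult") -> "Incremental":
        cats = set(self.costs) | set(other.costs)
        return Incremental(
            lyg=self.total_ly - other.total_ly,
            dflyg=self.total_dfly - other.total_dfly,
            cost=self.total_cost - other.total_cost,
            costs_by_category={c: self.costs.get(c, 0.0) - other.costs.get(c, 0.0)
                               for c in sorted(cats)},
        )


@dataclass
class Incremental:
    """Differences between two scenario results."""

    lyg: float
    dflyg: float
    cost: float
    costs_by_category: dict[str, float] = field(default_factory=dict)


def aggregate(traces: list[CohortTrace],
              cost_streams: pd.DataFrame | None = None,
              rate: float = 0.0, reference_year: int = 2017,
              discount_past: bool = False,
              scenario: str = "") -> ScenarioResult:
    """Sum (discounted) life years and costs over cohort traces.

    ``cost_streams`` rows carry (cohort_year, calendar_year, category,
    amount); discounting is applied here with the same convention as for
    effects, so totals always equal the sum of the per-cohort parts.
    An empty trace list yields zero totals.
    """
    horizons = {int(t.frame.index.max()) for t in traces}
    if len(horizons) > 1:
        raise ValueError(f"traces have mismatched horizons: {sorted(horizons)}")

    rows = []
    for t in traces:
        f = discount_factors(t.frame.index, rate, reference_year, discount_past)
        rows.append({
            "cohort_year": t.cohort_year,
            "ly": float((t.frame["ly"] * f).sum()),
            "dfly": float((t.frame["dfly"] * f).sum()),
            "ly_undisc": t.total_ly,
            "dfly_undisc": t.total_dfly,
        })
    breakdown = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["cohort_year", "ly", "dfly", "ly_undisc", "dfly_undisc"])

    costs = {c: 0.0 for c in COST_CATEGORIES}
    if cost_streams is not None and len(cost_streams):
        cs = cost_streams.copy()
        cs["factor"] = discount_factors(cs["calendar_year"].to_numpy(), rate,
                                        reference_year, discount_past)
        cs["disc"] = cs["amount"] * cs["factor"]
        for cat, amount in cs.groupby("category")["disc"].sum().items():
            costs[str(cat)] = costs.get(str(cat), 0.0) + float(amount)

    return ScenarioResult(
        scenario=scenario,
        total_ly=float(breakdown["ly"].sum()) if len(breakdown) else 0.0,
        total_dfly=float(breakdown["dfly"].sum()) if len(breakdown) else 0.0,
        costs=costs,
        total_ly_undiscounted=float(breakdown["ly_undisc"].sum()) if len(breakdown) else 0.0,
        total_dfly_undiscounted=float(breakdown["dfly_undisc"].sum()) if len(breakdown) else 0.0,
        cohort_breakdown=breakdown,
    )


def general_population_ly(cohorts: TargetCohorts, life_table: LifeTable,
                          horizon_year: int, rate: float = 0.03,
                          reference_year: int = 2017,
                          discount_past: bool = False) -> float:
    """Life years the target cohorts would generate free of disease.

    Survival is built purely from life-table death probabilities at the
    cohort's attained ages, then accumulated and discounted exactly like the
    disease traces.
    """
    if not cohorts.age_weights:
        raise ValueError("TargetCohorts.age_weights required for the comparator")
    traces = []
    for year in cohorts.years:
        duration = horizon_year - year
        curve = curve_from_life_table(life_table, cohorts.age_weights, duration)
        traces.append(build_cohort_trace(cohorts.target_n(year), curve, curve,
                                         year, horizon_year, "general_population"))
    total = 0.0
    for t in traces:
        f = discount_factors(t.frame.index, rate, reference_year, discount_past)
        total += float((t.frame["ly"] * f).sum())
    return total


def mean_followup_years(cohort_years, horizon_year: int) -> float:
    """Average follow-up across cohorts, (sum of horizon - cohort year) / n."""
    years = list(cohort_years)
    return float(np.mean([horizon_year - y for y in years]))
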