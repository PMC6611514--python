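"""Incidence projection and target-population selection.

A Poisson log-linear model (age band + calendar year, population exposure) is
fitted to registry-style counts, projected onto population pyramids to give
annual new breast-cancer diagnoses, and filtered to the HER2+ early-disease
target population: in-situ ductal carcinomas and de-novo metastatic cases are
removed as fixed fractions and the HER2+ prevalence of the cohort year is
applied (all patients are assumed tested, so no uptake factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IncidenceModel", "TargetCohorts", "fit_incidence_model",
    "project_new_cases", "select_target_population", "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class IncidenceModel:
    """Fitted Poisson log-linear incidence model.

    ``rate(age_band, year)`` returns cases per person-year.  Coefficients:
    intercept, one effect per non-reference age band, and a linear calendar
    year effect, with log population as exposure.
    """

    intercept: float
    age_effects: dict[str, float]  # per band label, reference band effect 0
    year_effect: float
    year_center: float
    deviance: float
    cov: np.ndarray | None = None

    def rate(self, age_band: str, year: float) -> float:
        if age_band not in self.age_effects:
            raise KeyError(f"unknown age band {age_band!r}")
        eta = (self.intercept + self.age_effects[age_band]
               + self.year_effect * (year - self.year_center))
        return float(np.exp(eta))


def fit_incidence_model(data: pd.DataFrame) -> IncidenceModel:
    """Fit the Poisson model by maximum likelihood with population exposure.

    Requires at least two distinct years and two age bands with positive
    population.  Degenerate designs raise ``ValueError`` naming the problem.
    """
    df = data.copy()
    required = {"year", "age_band", "cases", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    df = df[df["population"] > 0]
    if df["year"].nunique() < 2:
        raise ValueError("need >= 2 distinct years with non-zero population to fit")
    if df["age_band"].nunique() < 2:
        raise ValueError("need >= 2 age bands with non-zero population to fit")
    if (df["cases"] < 0).any():
        raise ValueError("cases must be non-negative")

    bands = sorted(df["age_band"].unique())
    year_center = float(df["year"].mean())
    dummies = pd.get_dummies(df["age_band"], dtype=float)[bands].iloc[:, 1:]
    X = sm.add_constant(
        pd.concat([dummies, (df["year"] - year_center).rename("year_c")], axis=1),
        has_constant="add")
    try:
        res = sm.GLM(df["cases"].to_numpy(dtype=float), X.to_numpy(),
                     family=sm.families.Poisson(),
                     exposure=df["population"].to_numpy(dtype=float)).fit()
    except Exception as exc:  # separation / singular design
        raise ValueError(
            f"Poisson incidence fit failed ({exc}); check the design for "
            "empty cells or collinear age bands") from exc
    if not np.all(np.isfinite(res.params)):
        raise ValueError("Poisson incidence fit diverged (non-finite coefficients)")

    params = np.asarray(res.params, dtype=float)
    age_effects = {bands[0]: 0.0}
    for j, band in enumerate(bands[1:]):
        age_effects[band] = float(params[1 + j])
    return IncidenceModel(
        intercept=float(params[0]),
        age_effects=age_effects,
        year_effect=float(params[-1]),
        year_center=year_center,
        deviance=float(res.deviance),
        cov=np.asarray(res.cov_params(), dtype=float),
    )


def project_new_cases(model: IncidenceModel, pyramid: pd.DataFrame,
                      years: range) -> pd.Series:
    """Projected annual counts: sum over bands of rate x population.

    Raises ``KeyError`` naming the first missing (year, age_band) pyramid cell.
    """
    pyr = pyramid.set_index(["year", "age_band"])["population"]
    counts = {}
    bands = sorted(model.age_effects)
    for year in years:
        total = 0.0
        for band in bands:
            if (year, band) not in pyr.index:
                raise KeyError(f"pyramid cell missing: year={year}, age_band={band!r}")
            total += model.rate(band, year) * float(pyr.loc[(year, band)])
        counts[year] = total
    return pd.Series(counts, name="new_cases")


@dataclass
class TargetCohorts:
    """Annual HER2+ early-disease cohorts eligible for adjuvant treatment."""

    table: pd.DataFrame  # index cohort year, columns total_bc_cases, target_n
    age_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.table[self.table["target_n"] > self.table["total_bc_cases"]]
        if len(bad):
            raise ValueError("target_n exceeds total cases for years "
                             f"{list(bad.index)}")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.table.index]

    def target_n(self, year: int) -> float:
        return float(self.table.loc[year, "target_n"])

    @property
    def total_target(self) -> float:
        """Sum of target-population sizes across cohorts (conservation check)."""
        return float(self.table["target_n"].sum())


def select_target_population(
    cases_by_year: pd.Series | dict[int, float],
    dcis_frac: float,
    metastatic_frac: float,
    her2_prev_by_year: dict[int, float],
    age_weights: dict[int, float] | None = None,
    rounding: bool = True,
) -> TargetCohorts:
    """Filter total diagnoses to the HER2+ early-disease target population.

    target_n(y) = cases(y) x (1 - dcis) x (1 - metastatic) x her2_prev(y),
    rounded half-up to an integer (the filters commute, pure multiplication).
    """
    for name, frac in (("dcis_frac", dcis_frac), ("metastatic_frac", metastatic_frac)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {frac}")
    cases = pd.Series(cases_by_year).sort_index()
    rows = []
    for year, n in cases.items():
        year = int(year)
        if year not in her2_prev_by_year:
            raise KeyError(f"HER2+ prevalence missing for cohort year {year}")
        prev = her2_prev_by_year[year]
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"HER2 prevalence out of [0,1] for {year}: {prev}")
        target = n * (1.0 - dcis_frac) * (1.0 - metastatic_frac) * prev
        rows.append((year, float(n), round_half_up(target) if rounding else target))
    table = pd.DataFrame(rows, columns=["year", "total_bc_cases", "target_n"]
                         ).set_index("year")
    return TargetCohorts(table, age_weights or {})
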