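"""Model configuration: cohorts, filters, regimens, prices, schedules.

The default configuration encodes the Spanish adjuvant-trastuzumab setting:
annual incidence cohorts 2006-2017 followed to 2035, a 3% temporal preference
rate referenced to 2017, exclusion of in-situ ductal carcinoma (18%) and
de-novo metastatic disease (7%), HER2+ prevalence 16.7% for years without a
reported figure, and the statutory RDL 8/2010 price deductions by year and
formulation.  Drug vial prices and some chemotherapy component doses are not
public at that granularity; the shipped values for those fields are synthetic
placeholders (flagged below) and every incremental-effect quantity is
independent of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import yaml

DoseRule = Literal["per_kg", "per_m2", "flat"]
Route = Literal["IV", "SC"]


@dataclass(frozen=True)
class DrugDose:
    """One component of a regimen: repeated administrations of one drug."""

    drug: str
    dose_rule: DoseRule
    dose_value: float  # mg/kg, mg/m2 or mg depending on rule
    cycle_weeks: int   # spacing between administrations
    n_cycles: int
    start_week: int = 0

    def __post_init__(self) -> None:
        if self.dose_value <= 0:
            raise ValueError(f"dose_value must be positive, got {self.dose_value}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")


@dataclass(frozen=True)
class RegimenSpec:
    name: str
    components: tuple[DrugDose, ...]
    route: Route = "IV"


@dataclass
class DeductionSchedule:
    """Statutory price deduction by calendar year and formulation.

    IV trastuzumab: none through 2010, 7.5% 2011-2013, 15% from 2014.
    SC trastuzumab: 7.5% from its marketing (2014 onwards).
    """

    iv_75_from: int = 2011
    iv_150_from: int = 2014
    sc_75_from: int = 2014

    def rate(self, year: int, formulation: Route) -> float:
        if formulation == "SC":
            return 0.075 if year >= self.sc_75_from else 0.0
        if year >= self.iv_150_from:
            return 0.15
        if year >= self.iv_75_from:
            return 0.075
        return 0.0


@dataclass
class CostConfig:
    """Unit prices, dosing constants and cost schedules.

    Prices are euros per vial.  ``placeholder_prices`` lists the drugs whose
    vial prices are synthetic stand-ins for unpublished hospital dispensation
    (PTR) prices.
    """

    # (vial size mg, price per vial EUR)
    prices: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "trastuzumab_iv": (150.0, 560.0),
        "trastuzumab_sc": (600.0, 1650.0),
        "paclitaxel": (100.0, 18.0),
        "docetaxel": (80.0, 35.0),
        "doxorubicin": (50.0, 12.0),
        "cyclophosphamide": (1000.0, 11.0),
        "carboplatin": (450.0, 25.0),
    })
    placeholder_prices: tuple[str, ...] = (
        "trastuzumab_iv", "trastuzumab_sc", "paclitaxel", "docetaxel",
        "doxorubicin", "cyclophosphamide", "carboplatin",
    )
    deductions: DeductionSchedule = field(default_factory=DeductionSchedule)
    admin_visit_cost: float = 211.64     # day-hospital visit, EUR (2017)
    echo_cost: float = 133.0             # echocardiogram, EUR (2017)
    echos_treatment_year: int = 4        # 3-4 during the trastuzumab year
    echos_followup_per_year: float = 1.0
    cpi: dict[int, float] = field(default_factory=dict)  # year -> multiplier vs base
    recurrence_cost: float = 183_170.0   # one-off, EUR
    recurrence_cost_range: tuple[float, float] = (157_658.0, 208_682.0)
    patient_weight_kg: float = 66.4
    body_surface_m2: float = 1.73
    regimen_mix: dict[str, float] = field(default_factory=lambda: {"AC-T": 0.75, "TC": 0.25})
    # taxane within each backbone: paclitaxel in AC-T, docetaxel in TC, 75:25
    taxane_split: float = 0.75
    vial_policy: Literal["whole_vials", "exact_mg"] = "whole_vials"

    def cpi_multiplier(self, year: int) -> float:
        if not self.cpi:
            return 1.0
        if year not in self.cpi:
            raise KeyError(f"CPI multiplier missing for year {year}")
        return self.cpi[year]


def default_regimens() -> dict[str, RegimenSpec]:
    """Regimens of the base case.

    Trastuzumab IV: 8 mg/kg loading then 6 mg/kg every 3 weeks for one year
    (18 administrations in weeks 0, 3, ..., 51).  Trastuzumab SC: 600 mg flat
    on the same 3-weekly clock.  AC-T: doxorubicin 60 mg/m2 x4 +
    cyclophosphamide 600 mg/m2 x6 + weekly paclitaxel 80 mg/m2 x12.  TC
    component doses (docetaxel, carboplatin) are placeholder values.
    """
    return {
        "trastuzumab_iv": RegimenSpec("trastuzumab_iv", (
            DrugDose("trastuzumab_iv", "per_kg", 8.0, 52, 1, start_week=0),
            DrugDose("trastuzumab_iv", "per_kg", 6.0, 3, 17, start_week=3),
        ), route="IV"),
        "trastuzumab_sc": RegimenSpec("trastuzumab_sc", (
            DrugDose("trastuzumab_sc", "flat", 600.0, 3, 18, start_week=0),
        ), route="SC"),
        "AC-T": RegimenSpec("AC-T", (
            DrugDose("doxorubicin", "per_m2", 60.0, 3, 4, start_week=0),
            DrugDose("cyclophosphamide", "per_m2", 600.0, 3, 6, start_week=0),
            DrugDose("paclitaxel", "per_m2", 80.0, 1, 12, start_week=18),
        ), route="IV"),
        "TC": RegimenSpec("TC", (  # placeholder doses, SA-varied; cancels in increments
            DrugDose("docetaxel", "per_m2", 75.0, 3, 4, start_week=0),
            DrugDose("carboplatin", "flat", 600.0, 3, 4, start_week=0),
        ), route="IV"),
    }


def default_market_shares() -> dict[int, float]:
    """Adjuvant trastuzumab uptake among eligible patients.

    40% at introduction in 2006, rising linearly to full uptake by 2014 and
    held thereafter.  The year-by-year published bars are not available at
    numeric precision, so the trajectory is configuration data.
    """
    shares = {}
    for year in range(2006, 2018):
        if year >= 2014:
            shares[year] = 1.0
        else:
            shares[year] = round(0.40 + (1.0 - 0.40) * (year - 2006) / (2014 - 2006), 4)
    return shares


def default_sc_split() -> dict[int, float]:
    """Fraction of treated patients on the SC formulation (0 before 2015)."""
    split = {year: 0.0 for year in range(2006, 2015)}
    for year in range(2015, 2018):
        split[year] = 0.5  # placeholder; the published split is not numeric
    return split


@dataclass
class ModelConfig:
    """Full model configuration for one analysis run."""

    cohort_years: tuple[int, ...] = tuple(range(2006, 2018))
    horizon_year: int = 2035
    reference_year: int = 2017
    discount_rate: float = 0.03
    discount_past: bool = False  # years before reference_year left undiscounted
    dcis_frac: float = 0.18
    metastatic_frac: float = 0.07
    her2_prevalence: dict[int, float] = field(
        default_factory=lambda: {y: 0.167 for y in range(2006, 2018)})
    recurrence_cap_years: int = 7
    progression_method: Literal["psm", "markov"] = "psm"
    switch_time: int = 10  # years of empirical KM before parametric tail
    market_shares: dict[int, float] = field(default_factory=default_market_shares)
    sc_split: dict[int, float] = field(default_factory=default_sc_split)
    regimens: dict[str, RegimenSpec] = field(default_factory=default_regimens)
    costs: CostConfig = field(default_factory=CostConfig)

    def __post_init__(self) -> None:
        for name, frac in (("dcis_frac", self.dcis_frac),
                           ("metastatic_frac", self.metastatic_frac),
                           ("discount_rate", self.discount_rate)):
            if frac < 0 or (name != "discount_rate" and frac > 1):
                raise ValueError(f"{name} out of range: {frac}")
        if abs(sum(self.costs.regimen_mix.values()) - 1.0) > 1e-9:
            raise ValueError("regimen_mix must sum to 1")
        for year, share in self.market_shares.items():
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"market share for {year} out of [0,1]: {share}")
        for year, frac in self.sc_split.items():
            if year < 2015 and frac != 0.0:
                raise ValueError("SC share must be 0 before 2015")


def to_yaml(cfg: ModelConfig, path: str) -> None:
    """Write the configuration as a nested key-value text file."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
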