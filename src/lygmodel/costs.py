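"""Direct healthcare costs: first-year regimens, administration, monitoring,
and one-off recurrence costs.

First-year pharmacy is built from the dosing calendars of the regimens
(per-kg and per-m2 doses use the reference 66.4 kg / 1.73 m2 patient), priced
per whole vial by default, with the statutory trastuzumab deduction of the
cohort year applied.  Intravenous day-hospital visits carry an administration
fee and trastuzumab-treated patients receive echocardiographic monitoring (4
in the treatment year, then 1 per disease-free year).  Administration and
monitoring fees are CPI-adjusted to the cohort's calendar year.  Recurrences
are charged entirely in the year of progression (one-off cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrace
from .config import CostConfig, DeductionSchedule, RegimenSpec, Route
from .progression import ProgressionSeries

__all__ = [
    "Administration", "doses_in_first_year", "iv_visit_weeks", "drug_cost",
    "apply_deduction", "regimen_pharma_cost", "ancillary_costs",
]


@dataclass(frozen=True)
class Administration:
    week: int
    drug: str
    mg: float


def doses_in_first_year(regimen: RegimenSpec, weight_kg: float = 66.4,
                        body_surface_m2: float = 1.73) -> list[Administration]:
    """Expand a regimen into its first-year administration calendar.

    Each component contributes ``n_cycles`` administrations at
    ``start_week + i*cycle_weeks``; per-kg and per-m2 doses are converted to
    mg with the reference patient.  Administrations beyond week 51 are not
    scheduled (one treatment year).
    """
    doses: list[Administration] = []
    for comp in regimen.components:
        if comp.dose_rule == "per_kg":
            mg = comp.dose_value * weight_kg
        elif comp.dose_rule == "per_m2":
            mg = comp.dose_value * body_surface_m2
        else:
            mg = comp.dose_value
        for i in range(comp.n_cycles):
            week = comp.start_week + i * comp.cycle_weeks
            if week > 51:
                break
            doses.append(Administration(week, comp.drug, mg))
    return sorted(doses, key=lambda d: (d.week, d.drug))


def iv_visit_weeks(regimens: list[RegimenSpec], weight_kg: float = 66.4,
                   body_surface_m2: float = 1.73) -> set[int]:
    """Distinct day-hospital visit weeks across IV regimens.

    Drugs co-administered in the same week share a single visit; SC
    administrations generate no day-hospital visit.
    """
    weeks: set[int] = set()
    for reg in regimens:
        if reg.route != "IV":
            continue
        weeks |= {d.week for d in doses_in_first_year(reg, weight_kg, body_surface_m2)}
    return weeks


def drug_cost(doses: list[Administration], prices: dict[str, tuple[float, float]],
              vial_policy: str = "whole_vials") -> float:
    """Price an administration calendar.

    ``whole_vials`` charges ceil(mg / vial size) vials per administration
    (vials are not shared); ``exact_mg`` prices the exact milligrams.
    """
    total = 0.0
    for dose in doses:
        if dose.drug not in prices:
            raise KeyError(f"no price for drug {dose.drug!r}")
        vial_mg, vial_price = prices[dose.drug]
        if vial_policy == "whole_vials":
            total += math.ceil(dose.mg / vial_mg - 1e-9) * vial_price
        elif vial_policy == "exact_mg":
            total += dose.mg / vial_mg * vial_price
        else:
            raise ValueError(f"unknown vial policy {vial_policy!r}")
    return total


def apply_deduction(cost: float, year: int, formulation: Route,
                    schedule: DeductionSchedule) -> float:
    """Apply the statutory price deduction of the cohort year."""
    return cost * (1.0 - schedule.rate(year, formulation))


def regimen_pharma_cost(regimen: RegimenSpec, cfg: CostConfig, year: int,
                        deduct: bool = True) -> float:
    """First-year drug cost of one regimen for one patient, after deduction.

    The statutory deduction applies to trastuzumab only; chemotherapy is
    priced at current prices for all cohorts.
    """
    doses = doses_in_first_year(regimen, cfg.patient_weight_kg, cfg.body_surface_m2)
    trastu = [d for d in doses if d.drug.startswith("trastuzumab")]
    other = [d for d in doses if not d.drug.startswith("trastuzumab")]
    cost = drug_cost(other, cfg.prices, cfg.vial_policy)
    if trastu:
        t_cost = drug_cost(trastu, cfg.prices, cfg.vial_policy)
        if deduct:
            t_cost = apply_deduction(t_cost, year, regimen.route, cfg.deductions)
        cost += t_cost
    return cost


def ancillary_costs(trace: CohortTrace, progression: ProgressionSeries,
                    cfg: CostConfig, treated_with_T: float,
                    n_iv_visits_per_patient: float = 0.0) -> pd.DataFrame:
    """Administration, monitoring and recurrence cost stream for one trace.

    Returns rows (cohort_year, calendar_year, category, amount), undiscounted.
    Administration: IV day-hospital visits x fee x CPI of the cohort year.
    Monitoring (trastuzumab-treated only): treatment-year echocardiograms for
    the cohort, then one echo per disease-free survivor per year.
    Recurrence: new progressions x one-off cost in the progression year.
    """
    if not 0.0 <= treated_with_T <= 1.0:
        raise ValueError("treated_with_T must lie in [0,1]")
    cohort_year = trace.cohort_year
    years = trace.frame.index.to_numpy()
    n0 = trace.n0
    rows: list[tuple[int, int, str, float]] = []

    cpi0 = cfg.cpi_multiplier(cohort_year)
    if n_iv_visits_per_patient > 0:
        rows.append((cohort_year, cohort_year, "administration",
                     n0 * n_iv_visits_per_patient * cfg.admin_visit_cost * cpi0))

    if treated_with_T > 0:
        rows.append((cohort_year, cohort_year, "monitoring",
                     n0 * treated_with_T * cfg.echos_treatment_year
                     * cfg.echo_cost * cpi0))
        for year in years[1:]:
            survivors = float(trace.frame.loc[year, "disease_free"])
            rows.append((cohort_year, int(year), "monitoring",
                         treated_with_T * survivors * cfg.echos_followup_per_year
                         * cfg.echo_cost * cfg.cpi_multiplier(int(year))))

    for t, new_p in enumerate(progression.new_progressions, start=1):
        if new_p <= 0:
            continue
        year = cohort_year + t - 1
        if year > years[-1]:
            break
        rows.append((cohort_year, int(year), "recurrence",
                     new_p * cfg.recurrence_cost))

    return pd.DataFrame(rows, columns=["cohort_year", "calendar_year",
                                       "category", "amount"])
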