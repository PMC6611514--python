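"""Published summary figures of the Spanish adjuvant-trastuzumab analysis.

These are the reported national base-case figures (cohorts 2006-2017,
follow-up to 2035, 3% discounting): per-year target-population sizes, the
scenario life-year totals, the cost-effect table under full trastuzumab use,
and the general-population comparator.  They are used as *inputs* to the
aggregation, incremental and ICER operations for arithmetic-identity checks;
the underlying fitted survival parameters and year-by-year market shares were
never published, so the absolute totals cannot be recomputed from raw data
and are not treated as recoverable.
"""

from __future__ import annotations

import pandas as pd

# per-cohort HER2+ early-disease target population (women), 2006-2017
TARGET_POPULATION_BY_YEAR: dict[int, int] = {
    2006: 2664, 2007: 2724, 2008: 2787, 2009: 2841, 2010: 2891, 2011: 2937,
    2012: 2982, 2013: 3018, 2014: 3249, 2015: 3377, 2016: 3173, 2017: 3208,
}

# total breast-cancer diagnoses (women 25-90) per year
TOTAL_BC_BY_YEAR: dict[int, int] = {
    2006: 21132, 2007: 21608, 2008: 22101, 2009: 22533, 2010: 22925,
    2011: 23291, 2012: 23651, 2013: 23936, 2014: 24175, 2015: 24442,
    2016: 24724, 2017: 24994,
}

# real-world scenario totals (market-share weighted T+CT vs CT)
REAL_WORLD_LY = {"T+CT": 605_358.0, "CT": 564_137.0}
REAL_WORLD_DFLY = {"T+CT": 525_964.0, "CT": 489_916.0}

# cost-effect table under full trastuzumab use
FULL_USE_COSTS = {"T+CT": 1_581_553_536.0, "CT": 503_587_698.0}
FULL_USE_LY = {"T+CT": 616_354.0, "CT": 564_137.0}
FULL_USE_DFLY = {"T+CT": 534_907.0, "CT": 489_916.0}

GENERAL_POPULATION_LY = 704_331.0
REAL_WORLD_INCREMENTAL_COST_EUR = 880.43e6
CT_TOTAL_COST_EUR = 503.59e6


def target_population_frame() -> pd.DataFrame:
    """The per-year cohort table as a TargetCohorts-shaped frame."""
    return pd.DataFrame({
        "total_bc_cases": pd.Series(TOTAL_BC_BY_YEAR),
        "target_n": pd.Series(TARGET_POPULATION_BY_YEAR),
    }).rename_axis("year")
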