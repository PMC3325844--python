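"""Published steady-state measurements for the KT2442 decanoate chemostat.

The study ran *Pseudomonas putida* KT2442 in aerobic chemostats at
D = 0.1 h^-1 with NH4Cl fixed at 1 g/l and decanoate varied to impose
carbon-, dual- (carbon-nitrogen) and nitrogen-limited growth.  This
module carries the published per-condition measurements (feed molar
C/N ratio, yield coefficients, residual nutrients, CDW, PHA content and
monomer composition) as the canonical worked-example input; the
analysis functions recompute the derived quantities from them.

Residuals reported below the assay detection limit are stored as NaN
and interpreted as zero consumption offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import physiology
from .physiology import FeedMedium, SteadyStateRecord, StudyConfig

__all__ = [
    "DILUTION_RATE",
    "NH4CL_FEED",
    "chemostat_table",
    "feed_media",
    "steady_state_records",
]

#: Dilution rate of every published condition, h^-1.
DILUTION_RATE = 0.1

#: NH4Cl feed concentration common to all conditions, g/l.
NH4CL_FEED = 1.0

_ROWS = [
    # condition, c0_n0, y_xc, y_xn, border, resid_C, resid_N, cdw, cdw_sd,
    # pha_pct, pha_sd, C6, C8, C10
    ("carbon", 5.83, 1.11, 9.80, 10.40, np.nan, 0.112, 1.46, 0.04,
     25.78, 0.97, 3.3, 53.4, 43.3),
    ("dual", 16.56, 1.16, 16.67, np.nan, np.nan, np.nan, 4.35, 0.13,
     61.94, 4.95, 4.8, 42.8, 52.4),
    ("nitrogen", 26.97, 1.01, 17.74, 20.50, 1.53, np.nan, 4.63, 0.14,
     80.58, 0.24, 4.3, 40.2, 55.5),
]

_COLUMNS = [
    "condition", "c0_n0", "y_xc", "y_xn", "border",
    "resid_C_g_per_l", "resid_N_g_per_l", "cdw_g_per_l", "cdw_sd",
    "pha_pct_cdw", "pha_sd", "molpct_C6", "molpct_C8", "molpct_C10",
]


def chemostat_table() -> pd.DataFrame:
    """The published steady-state table, one row per condition.

    Residuals below detection are NaN.  The feed molar ratio, yields and
    regime borders are the published values; everything else in the
    pipeline is recomputed from the measured columns.
    """
    return pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("condition")


def feed_media() -> dict[str, FeedMedium]:
    """Feed media reconstructed from the published molar C/N ratios.

    The decanoate concentration (acid equivalents) is back-calculated
    from each condition's feed ratio at the fixed 1 g/l NH4Cl.
    """
    table = chemostat_table()
    return {
        cond: physiology.feed_for_ratio(
            row["c0_n0"], NH4CL_FEED, condition=cond
        )
        for cond, row in table.iterrows()
    }


def steady_state_records() -> dict[str, SteadyStateRecord]:
    """Published measurements as validated steady-state records."""
    table = chemostat_table()
    records = {}
    for cond, row in table.iterrows():
        resid_c = row["resid_C_g_per_l"]
        resid_n = row["resid_N_g_per_l"]
        records[cond] = SteadyStateRecord(
            condition=cond,
            dilution_rate=DILUTION_RATE,
            cdw=row["cdw_g_per_l"],
            cdw_sd=row["cdw_sd"],
            pha_fraction=row["pha_pct_cdw"] / 100.0,
            pha_sd=row["pha_sd"] / 100.0,
            residual_carbon=0.0 if np.isnan(resid_c) else float(resid_c),
            residual_nitrogen=0.0 if np.isnan(resid_n) else float(resid_n),
            residual_carbon_below_detection=bool(np.isnan(resid_c)),
            residual_nitrogen_below_detection=bool(np.isnan(resid_n)),
            monomer_molpercent={
                "C6": row["molpct_C6"],
                "C8": row["molpct_C8"],
                "C10": row["molpct_C10"],
            },
        )
    return records
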