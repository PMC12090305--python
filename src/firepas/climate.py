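"""Climatic predisposition from an annual water-balance drought index.

The drought index contrasts actual evapotranspiration (supply, E_m) with
evaporative demand from the soil (D_m) over the growing season, defined as
the months with mean temperature >= 5.5 °C:

    FCDI = 1 − (Σ E_m) / (Σ D_m)   over m with T_m >= 5.5 °C

FCDI = 0 means supply meets demand (no drought); values above 0.5 represent
extremely dry conditions, uncommon in European forests — hence the score
map pf.clim = clamp(2·FCDI, 0, 1) saturating at FCDI = 0.5. The index may
also be supplied precomputed per stand (e.g. by a forest gap model), in
which case only the score map applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROWING_SEASON_TEMP = 5.5  # deg C


@dataclass(frozen=True)
class MonthlyClimateRecord:
    month: int
    mean_temp: float   # deg C
    evapotranspiration: float  # mm, supply E_m
    demand: float      # mm, demand D_m

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError("month must be 1-12")
        if self.demand < 0 or self.evapotranspiration < 0:
            raise ValueError("E_m and D_m must be >= 0")
        if self.evapotranspiration > self.demand + 1e-12:
            raise ValueError("supply E_m cannot exceed demand D_m")


def fcdi(records: list[MonthlyClimateRecord]) -> float:
    """Annual drought index from 12 monthly records (ratio-of-sums form)."""
    if len(records) != 12:
        raise ValueError("need exactly 12 monthly records")
    growing = [r for r in records if r.mean_temp >= GROWING_SEASON_TEMP]
    if not growing:
        raise ValueError(
            "no month with mean temperature >= 5.5 degC: drought index undefined")
    total_demand = sum(r.demand for r in growing)
    if total_demand <= 0:
        raise ValueError("total evaporative demand is zero: index undefined")
    total_supply = sum(r.evapotranspiration for r in growing)
    return float(np.clip(1.0 - total_supply / total_demand, 0.0, 1.0))


def score_climate(fcdi_value):
    """pf.clim = clamp(2 * FCDI, 0, 1): linear positive between FCDI = 0
    and the extreme-drought threshold FCDI = 0.5."""
    arr = np.asarray(fcdi_value, dtype=float)
    if np.ndim(fcdi_value) == 0 and not np.isfinite(arr):
        raise ValueError("non-finite FCDI")
    out = np.clip(2.0 * arr, 0.0, 1.0)
    return float(out) if np.ndim(fcdi_value) == 0 else out


def fcdi_from_monthly_table(table: pd.DataFrame) -> pd.DataFrame:
    """Annual FCDI per (stand_id, year) from a tidy monthly table with
    columns stand_id, year, month, mean_temp, evapotranspiration, demand."""
    out = []
    for (sid, year), grp in table.groupby(["stand_id", "year"]):
        recs = [MonthlyClimateRecord(int(r.month), r.mean_temp,
                                     r.evapotranspiration, r.demand)
                for r in grp.itertuples()]
        out.append({"stand_id": sid, "year": year, "fcdi": fcdi(recs)})
    return pd.DataFrame(out)
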