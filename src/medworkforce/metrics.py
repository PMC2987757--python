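"""Gap metrics: deficit/surplus, ratios per 100 000, pyramid summaries.

The deficit convention is (supply - need) / supply: negative values are
shortages.  Using supply (not need) as the divisor is what makes a supply
of 152 160 against a need of 173 918 a 14.3% deficit rather than 12.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .supply import SEXES, SpecialtyStock, SupplyTrajectory

__all__ = [
    "deficit_fraction",
    "ratio_per_100k",
    "pyramid_summaries",
    "rank_specialties",
    "ScenarioResult",
]


def deficit_fraction(supply: float, need: float) -> float:
    """(supply - need) / supply; negative = deficit, positive = surplus."""
    if supply <= 0:
        raise ValueError(f"supply must be > 0, got {supply}")
    return (supply - need) / supply


def ratio_per_100k(supply: float, population: float) -> float:
    """Specialists per 100 000 inhabitants."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return supply * 100_000.0 / population


def pyramid_summaries(
    stock: SpecialtyStock, specialty_id: int | None = None
) -> tuple[float, float, pd.DataFrame]:
    """(pct_women, pct_under_51, pyramid table) for one specialty or all.

    "Under 51" means attained age <= 50.  An empty stock raises rather than
    silently reporting 0 (the fractions are undefined).
    """
    if specialty_id is None:
        counts = stock.counts.sum(axis=0)  # (2, A)
    else:
        pos = np.flatnonzero(stock.specialty_ids == specialty_id)
        if len(pos) == 0:
            raise KeyError(f"specialty {specialty_id} not in stock")
        counts = stock.counts[int(pos[0])]
    total = counts.sum()
    if total <= 0:
        raise ValueError(
            f"empty stock for specialty {specialty_id!r}: pyramid fractions undefined"
        )
    pct_women = float(counts[0].sum() / total)
    under = stock.ages <= 50
    pct_under_51 = float(counts[:, under].sum() / total)
    sex_idx, age_idx = np.meshgrid(np.arange(2), stock.ages, indexing="ij")
    table = pd.DataFrame(
        {
            "sex": np.array(SEXES)[sex_idx.ravel()],
            "age": age_idx.ravel(),
            "count": counts.ravel(),
        }
    )
    return pct_women, pct_under_51, table


@dataclass
class ScenarioResult:
    """Outputs of one scenario run.

    ``by_specialty``: tidy frame per (specialty_id, year) with supply_head,
    supply_fte, need, deficit_head, deficit_pct, ratio_per_100k, pct_women,
    pct_under_51.  ``aggregate``: the same metrics summed/recomputed over
    all specialties per year, plus population.  ``trajectory`` keeps the
    full age-sex stocks so pyramids remain recoverable for any
    (specialty, year).
    """

    name: str
    by_specialty: pd.DataFrame
    aggregate: pd.DataFrame
    trajectory: SupplyTrajectory | None = None
    config_digest: str | None = None

    def years(self) -> list[int]:
        return sorted(self.aggregate["year"].unique().tolist())

    def pyramid(self, specialty_id: int, year: int) -> pd.DataFrame:
        if self.trajectory is None:
            raise ValueError("trajectory not retained on this result")
        return self.trajectory.pyramid(specialty_id, year)

    def summary(self, years: Sequence[int] = (2008, 2015, 2025)) -> pd.DataFrame:
        """Compact aggregate table (rows = metrics, columns = years)."""
        years = [y for y in years if y in set(self.aggregate["year"])]
        agg = self.aggregate.set_index("year")
        rows = {
            "inhabitants": [agg.loc[y, "population"] for y in years],
            "supply_head": [agg.loc[y, "supply_head"] for y in years],
            "supply_fte": [agg.loc[y, "supply_fte"] for y in years],
            "need": [agg.loc[y, "need"] for y in years],
            "deficit_head": [agg.loc[y, "deficit_head"] for y in years],
            "deficit_pct": [100 * agg.loc[y, "deficit_pct"] for y in years],
            "ratio_per_100k": [agg.loc[y, "ratio_per_100k"] for y in years],
            "pct_women": [100 * agg.loc[y, "pct_women"] for y in years],
            "pct_under_51": [100 * agg.loc[y, "pct_under_51"] for y in years],
        }
        return pd.DataFrame(rows, index=pd.Index(years, name="year")).T


def rank_specialties(result: ScenarioResult, year: int) -> pd.DataFrame:
    """Specialties ordered by deficit_pct ascending (worst shortage first).

    Ties broken by specialty id (stable, lower id first).
    """
    df = result.by_specialty
    sub = df[df["year"] == year]
    if sub.empty:
        raise KeyError(f"year {year} not present in result")
    return (
        sub.sort_values(["deficit_pct", "specialty_id"], kind="stable")
        .reset_index(drop=True)
    )
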