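"""Demand/need submodel.

Need for each specialty is a normative ratio of specialists per 100 000
inhabitants in a base year, compounded geometrically at a demand-group
growth rate and scaled by a population projection:

    Need_s(t) = base_ratio_s * (1 + g_s)^(t - t0) * P(t) / 100_000

The four demand groups and their default annual per-capita growth rates
(sharply increasing 1.3%, stable/increasing 0.6%, stable 0%, decreasing
-0.6%) follow the planning-standard rates used by the US Department of
Health and Human Services; both the standards and the rates are scenario
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEMAND_GROUPS",
    "DEFAULT_GROUP_RATES",
    "NeedStandard",
    "PopulationScenario",
    "MODERATE_POPULATION_ANCHORS",
    "cumulative_growth",
    "need_trajectory",
    "total_need",
    "spain_population",
]

DEMAND_GROUPS = ("sharply_increasing", "stable_increasing", "stable", "decreasing")

DEFAULT_GROUP_RATES: dict[str, float] = {
    "sharply_increasing": 0.013,
    "stable_increasing": 0.006,
    "stable": 0.0,
    "decreasing": -0.006,
}

#: Moderate-growth population anchors for Spain (inhabitants).
MODERATE_POPULATION_ANCHORS = {2008: 44_366_332, 2015: 46_333_661, 2025: 48_018_184}


def cumulative_growth(annual_rate: float, n_years: int) -> float:
    """Cumulative growth over ``n_years`` of geometric compounding.

    Returns (1 + annual_rate)**n_years - 1; e.g. an annual 0.6% compounds
    to 10.7% over the 17 years spanning 2008-2025.
    """
    if annual_rate <= -1.0:
        raise ValueError("annual_rate must be > -1")
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    return (1.0 + annual_rate) ** n_years - 1.0


@dataclass
class NeedStandard:
    """Per-specialty need standard: base ratio per 100 000 plus demand group."""

    specialty: int
    base_ratio: float
    group: str = "stable"
    rate_override: float | None = None

    def __post_init__(self) -> None:
        if self.base_ratio <= 0:
            raise ValueError(f"base_ratio must be > 0 (specialty {self.specialty})")
        if self.group not in DEMAND_GROUPS:
            raise ValueError(
                f"unknown demand group {self.group!r}; expected one of {DEMAND_GROUPS}"
            )

    def growth_rate(self, group_rates: Mapping[str, float] | None = None) -> float:
        if self.rate_override is not None:
            return self.rate_override
        rates = dict(DEFAULT_GROUP_RATES)
        if group_rates:
            rates.update(group_rates)
        return rates[self.group]


@dataclass
class PopulationScenario:
    """Inhabitants per year under a named growth hypothesis."""

    label: str
    population: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.population.values()):
            raise ValueError("population must be > 0 for all years")

    def at(self, year: int) -> float:
        try:
            return float(self.population[year])
        except KeyError:
            raise KeyError(
                f"population scenario {self.label!r} has no value for year {year}"
            ) from None

    @classmethod
    def from_anchors(
        cls, label: str, anchors: Mapping[int, float], years: Sequence[int]
    ) -> "PopulationScenario":
        """Geometric interpolation between anchor years; anchors reproduced
        exactly, intermediate years filled with a constant within-segment
        growth rate (smooth and order-preserving)."""
        ys = sorted(anchors)
        pop: dict[int, float] = {}
        for year in years:
            if year in anchors:
                pop[year] = float(anchors[year])
                continue
            lo = max((y for y in ys if y < year), default=None)
            hi = min((y for y in ys if y > year), default=None)
            if lo is None or hi is None:
                raise ValueError(
                    f"year {year} outside anchor range {ys[0]}..{ys[-1]}"
                )
            frac = (year - lo) / (hi - lo)
            pop[year] = float(
                anchors[lo] * (anchors[hi] / anchors[lo]) ** frac
            )
        return cls(label, pop)

    @classmethod
    def from_growth_rate(
        cls, label: str, base_year: int, base_population: float,
        annual_rate: float, years: Sequence[int],
    ) -> "PopulationScenario":
        return cls(
            label,
            {y: base_population * (1.0 + annual_rate) ** (y - base_year) for y in years},
        )


def spain_population(
    label: str = "moderate", years: Sequence[int] = range(2008, 2026)
) -> PopulationScenario:
    """Built-in Spain-like population paths.

    ``moderate`` interpolates the printed 2008/2015/2025 anchors
    geometrically; ``rapid`` (1.2%/yr) and ``slow`` (0.25%/yr) compound
    from the same 2008 base and bracket the moderate path's implied
    ~0.47%/yr.
    """
    base = MODERATE_POPULATION_ANCHORS[2008]
    if label == "moderate":
        return PopulationScenario.from_anchors(
            "moderate", MODERATE_POPULATION_ANCHORS, years
        )
    if label == "rapid":
        return PopulationScenario.from_growth_rate("rapid", 2008, base, 0.012, years)
    if label == "slow":
        return PopulationScenario.from_growth_rate("slow", 2008, base, 0.0025, years)
    raise ValueError(f"unknown population scenario {label!r}; expected slow/moderate/rapid")


def need_trajectory(
    standard: NeedStandard,
    scenario: PopulationScenario,
    base_year: int,
    horizon: Sequence[int],
    group_rates: Mapping[str, float] | None = None,
) -> pd.Series:
    """Need headcount per year for one specialty.

    Need(t) = base_ratio * (1+g)^(t-base_year) * P(t) / 100 000; equals
    base_ratio * P(base_year)/100 000 exactly at the base year.
    """
    horizon = list(horizon)
    if base_year not in horizon:
        raise ValueError(f"base_year {base_year} not in horizon")
    g = standard.growth_rate(group_rates)
    values = [
        standard.base_ratio
        * (1.0 + g) ** (t - base_year)
        * scenario.at(t)
        / 100_000.0
        for t in horizon
    ]
    return pd.Series(values, index=pd.Index(horizon, name="year"), name=standard.specialty)


def total_need(
    standards: Sequence[NeedStandard],
    scenario: PopulationScenario,
    year: int,
    base_year: int | None = None,
    group_rates: Mapping[str, float] | None = None,
) -> float:
    """Aggregate need over specialties for one year (simple sum)."""
    standards = list(standards)
    if not standards:
        raise ValueError("standards list is empty")
    if base_year is None:
        base_year = min(scenario.population)
    return float(
        sum(
            need_trajectory(s, scenario, base_year, [base_year, year] if year != base_year else [base_year], group_rates).loc[year]
            for s in standards
        )
    )


def need_table(
    standards: Sequence[NeedStandard],
    scenario: PopulationScenario,
    base_year: int,
    horizon: Sequence[int],
    group_rates: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Need per (specialty, year) as a wide DataFrame (years x specialties)."""
    if not standards:
        raise ValueError("standards list is empty")
    cols = {
        s.specialty: need_trajectory(s, scenario, base_year, horizon, group_rates)
        for s in standards
    }
    df = pd.DataFrame(cols)
    df.columns.name = "specialty_id"
    return df
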