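"""Scenario engine: bind supply, need and metrics into named runs.

A :class:`Scenario` packages an initial stock, rate tables, per-year policy
schedules, need standards and a population path.  ``run_scenario`` executes
it deterministically over the horizon; ``compare_scenarios`` and
``sweep_parameter`` support what-if analysis.

Schedules use carry-forward semantics: a parameter value set in year y
holds until overridden, matching the baseline convention that controllable
parameters remain at their current values unless the planner changes them.
Policy feedback (adjusting admissions in response to projected shortage) is
deliberately not modelled; policies are inputs, not endogenous.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import demand as dm
from . import metrics as mx
from . import supply as sp

__all__ = [
    "SCHEDULABLE_PARAMETERS",
    "ScheduleError",
    "ParameterSchedule",
    "Scenario",
    "run_scenario",
    "compare_scenarios",
    "sweep_parameter",
]

#: Parameters a planner can reset in any year (carry-forward applies).
SCHEDULABLE_PARAMETERS = (
    "numerus_clausus",
    "entrant_female_fraction",
    "residency_positions",
    "retirement_age",
    "fte_ratio",
    "immigration_net",
)


class ScheduleError(ValueError):
    """A schedule does not cover the simulation horizon."""

    def __init__(self, missing: list[tuple[str, int]]):
        self.missing = missing
        super().__init__(
            "schedule gaps: "
            + ", ".join(f"({p}, {y})" for p, y in missing)
        )


@dataclass
class ParameterSchedule:
    """Per-year values of every policy-controllable parameter.

    Each field maps year -> value.  ``residency_positions`` and
    ``immigration_net`` values may be scalars (applied to every specialty)
    or (S,) arrays; ``fte_ratio`` values may be scalars or (2, A) arrays.
    With ``carry_forward`` (default) a value persists until overridden;
    without it every simulated year must be explicit.
    """

    numerus_clausus: dict[int, float] = field(default_factory=dict)
    entrant_female_fraction: dict[int, float] = field(default_factory=dict)
    residency_positions: dict[int, Any] = field(default_factory=dict)
    retirement_age: dict[int, int] = field(default_factory=dict)
    fte_ratio: dict[int, Any] = field(default_factory=dict)
    immigration_net: dict[int, Any] = field(default_factory=dict)
    carry_forward: bool = True

    def table(self, name: str) -> dict[int, Any]:
        if name not in SCHEDULABLE_PARAMETERS:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: "
                + ", ".join(SCHEDULABLE_PARAMETERS)
            )
        return getattr(self, name)

    def value_for(self, name: str, year: int, *, carry_back: bool = False) -> Any:
        """Resolve a parameter for one year.

        With carry-forward, the most recent value at or before ``year`` is
        used; ``carry_back`` additionally allows warm-up years before the
        first scheduled value to borrow the earliest value (used only for
        pipeline history).
        """
        tab = self.table(name)
        if not tab:
            raise ScheduleError([(name, year)])
        if year in tab:
            return tab[year]
        if self.carry_forward:
            prior = [y for y in tab if y < year]
            if prior:
                return tab[max(prior)]
        if carry_back:
            return tab[min(tab)]
        raise ScheduleError([(name, year)])

    def validate(self, years: Sequence[int]) -> list[tuple[str, int]]:
        """Return the (parameter, year) pairs the horizon is missing."""
        missing: list[tuple[str, int]] = []
        for name in SCHEDULABLE_PARAMETERS:
            tab = self.table(name)
            for year in years:
                if year in tab:
                    continue
                if self.carry_forward and any(y < year for y in tab):
                    continue
                missing.append((name, year))
        return missing


@dataclass
class Scenario:
    """A fully specified, deterministic what-if run.

    ``seed`` records how synthetic fixture inputs were generated; the
    simulation itself contains no randomness.
    """

    name: str
    horizon: tuple[int, int]
    initial_stock: sp.SpecialtyStock
    mortality: np.ndarray
    dropout: np.ndarray
    schedule: ParameterSchedule
    standards: list[dm.NeedStandard]
    population: dm.PopulationScenario
    early_retirement: np.ndarray | None = None
    d_med: int = 6
    d_res: np.ndarray | None = None  # per-specialty residency years, default 4
    exam_pass_fraction: float = 1.0
    completion_fraction: np.ndarray | float = 1.0
    entry_age_distribution: np.ndarray | None = None
    immigration_sex_split: float = 0.5
    immigration_age_distribution: np.ndarray | None = None
    group_rates: dict[str, float] = field(default_factory=dict)
    specialty_names: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d_res is None:
            self.d_res = np.full(self.initial_stock.n_specialties, 4, dtype=int)
        else:
            self.d_res = np.asarray(self.d_res, dtype=int)

    @property
    def years(self) -> list[int]:
        return list(range(self.horizon[0], self.horizon[1] + 1))

    def validate(self) -> None:
        years = self.years
        missing = self.schedule.validate(years)
        if missing:
            raise ScheduleError(missing)
        missing_pop = [y for y in years if y not in self.population.population]
        if missing_pop:
            raise ValueError(
                f"population scenario {self.population.label!r} missing years "
                f"{missing_pop}"
            )
        if not self.standards:
            raise ValueError("scenario has no need standards")
        S = self.initial_stock.n_specialties
        if len(self.d_res) != S:
            raise ValueError("d_res length must match number of specialties")
        if self.dropout.shape[0] != S:
            raise ValueError("dropout table must cover every specialty")


def _as_specialty_vector(value: Any, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    return np.broadcast_to(arr, (n,)).copy()


def _build_pipeline(scn: Scenario) -> sp.TrainingPipeline:
    """Resolve admissions / positions over horizon plus warm-up history.

    History before the first scheduled year borrows the earliest scheduled
    value (warm-up cohorts held constant).
    """
    t0, t1 = scn.horizon
    S = scn.initial_stock.n_specialties
    max_dres = int(scn.d_res.max())
    adm_years = range(t0 - scn.d_med - max_dres, t1 + 1)
    admissions = {
        y: float(scn.schedule.value_for("numerus_clausus", y, carry_back=True))
        for y in adm_years
    }
    female = {
        y: float(
            scn.schedule.value_for("entrant_female_fraction", y, carry_back=True)
        )
        for y in adm_years
    }
    pos_years = range(t0 - max_dres, t1 + 1)
    positions = {
        y: _as_specialty_vector(
            scn.schedule.value_for("residency_positions", y, carry_back=True), S
        )
        for y in pos_years
    }
    return sp.TrainingPipeline(
        admissions=admissions,
        positions=positions,
        d_res=scn.d_res,
        d_med=scn.d_med,
        exam_pass_fraction=scn.exam_pass_fraction,
        completion_fraction=scn.completion_fraction,
        female_fraction=female,
        entry_age_distribution=scn.entry_age_distribution,
    )


def run_scenario(scenario: Scenario, keep_trajectory: bool = True) -> mx.ScenarioResult:
    """Execute one scenario over its horizon; fully deterministic."""
    scn = scenario
    scn.validate()
    years = scn.years
    S = scn.initial_stock.n_specialties
    A = scn.initial_stock.counts.shape[2]

    exits = sp.ExitRates(
        mortality=scn.mortality,
        dropout=scn.dropout,
        retirement_age={
            y: int(scn.schedule.value_for("retirement_age", y)) for y in years
        },
        early_retirement=scn.early_retirement,
    )
    pipeline = _build_pipeline(scn)
    immigration = sp.ImmigrationFlow(
        net_entrants={
            y: _as_specialty_vector(
                scn.schedule.value_for("immigration_net", y), S
            )
            for y in years
        },
        sex_split=scn.immigration_sex_split,
        age_distribution=scn.immigration_age_distribution,
    )

    traj = sp.simulate_supply(scn.initial_stock, exits, pipeline, immigration, years)
    base_year = years[0]
    needs = dm.need_table(scn.standards, scn.population, base_year, years, scn.group_rates)
    std_order = [s.specialty for s in scn.standards]

    spec_rows: list[dict[str, Any]] = []
    agg_rows: list[dict[str, Any]] = []
    ids = scn.initial_stock.specialty_ids
    for year in years:
        stock = traj.stock_at(year)
        fte = sp.FteRatio(scn.schedule.value_for("fte_ratio", year))
        head = stock.total_by_specialty()
        fte_by_spec = sp.fte_supply(stock, fte)
        pop = scn.population.at(year)
        need_row = needs.loc[year]
        for i, sid in enumerate(ids):
            need_i = float(need_row[sid]) if sid in need_row.index else np.nan
            supply_i = float(head[i])
            counts = stock.counts[i]
            tot = counts.sum()
            spec_rows.append(
                {
                    "specialty_id": int(sid),
                    "specialty_name": scn.specialty_names.get(int(sid), str(sid)),
                    "year": year,
                    "supply_head": supply_i,
                    "supply_fte": float(fte_by_spec[i]),
                    "need": need_i,
                    "deficit_head": supply_i - need_i,
                    "deficit_pct": (
                        mx.deficit_fraction(supply_i, need_i) if supply_i > 0 else np.nan
                    ),
                    "ratio_per_100k": mx.ratio_per_100k(supply_i, pop),
                    "pct_women": (
                        float(counts[0].sum() / tot) if tot > 0 else np.nan
                    ),
                    "pct_under_51": (
                        float(counts[:, stock.ages <= 50].sum() / tot)
                        if tot > 0
                        else np.nan
                    ),
                }
            )
        total_supply = float(head.sum())
        total_need = float(need_row[std_order].sum())
        pw, pu, _ = mx.pyramid_summaries(stock)
        agg_rows.append(
            {
                "year": year,
                "population": pop,
                "supply_head": total_supply,
                "supply_fte": float(fte_by_spec.sum()),
                "need": total_need,
                "deficit_head": total_supply - total_need,
                "deficit_pct": mx.deficit_fraction(total_supply, total_need),
                "ratio_per_100k": mx.ratio_per_100k(total_supply, pop),
                "pct_women": pw,
                "pct_under_51": pu,
            }
        )

    return mx.ScenarioResult(
        name=scn.name,
        by_specialty=pd.DataFrame(spec_rows),
        aggregate=pd.DataFrame(agg_rows),
        trajectory=traj if keep_trajectory else None,
    )


_AGG_METRICS = (
    "supply_head",
    "supply_fte",
    "need",
    "deficit_head",
    "deficit_pct",
    "ratio_per_100k",
)


def compare_scenarios(scenarios: Sequence[Scenario]) -> pd.DataFrame:
    """Aggregate-metric differences of each scenario vs the first (reference).

    Returns a long frame (metric, year, scenario, value, reference_value,
    difference).  Scenarios must share the same horizon.
    """
    scenarios = list(scenarios)
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    horizons = {s.horizon for s in scenarios}
    if len(horizons) != 1:
        raise ValueError(f"mismatched horizons: {sorted(horizons)}")
    results = [run_scenario(s, keep_trajectory=False) for s in scenarios]
    ref = results[0].aggregate.set_index("year")
    rows = []
    for scn, res in zip(scenarios[1:], results[1:]):
        agg = res.aggregate.set_index("year")
        for metric in _AGG_METRICS:
            for year in agg.index:
                rows.append(
                    {
                        "metric": metric,
                        "year": int(year),
                        "scenario": scn.name,
                        "value": float(agg.loc[year, metric]),
                        "reference_value": float(ref.loc[year, metric]),
                        "difference": float(agg.loc[year, metric] - ref.loc[year, metric]),
                    }
                )
    return pd.DataFrame(rows)


def sweep_parameter(
    scenario: Scenario, parameter: str, values: Sequence[Any]
) -> dict[Any, mx.ScenarioResult]:
    """Run one independent scenario per value of a schedulable parameter.

    The parameter is set from the horizon start (constant, carry-forward);
    the input scenario is never modified.  Demand-group growth rates are
    sweepable as ``"group_rate.<group>"`` (e.g. ``group_rate.stable``).
    """
    group = None
    if parameter.startswith("group_rate."):
        group = parameter.split(".", 1)[1]
        if group not in dm.DEMAND_GROUPS:
            raise KeyError(
                f"unknown demand group {group!r}; valid groups: "
                + ", ".join(dm.DEMAND_GROUPS)
            )
    elif parameter not in SCHEDULABLE_PARAMETERS:
        raise KeyError(
            f"unknown parameter {parameter!r}; valid names: "
            + ", ".join(SCHEDULABLE_PARAMETERS)
            + ", group_rate.<group>"
        )
    out: dict[Any, mx.ScenarioResult] = {}
    for value in values:
        scn = copy.deepcopy(scenario)
        scn.name = f"{scenario.name}[{parameter}={value}]"
        if group is not None:
            scn.group_rates = {**scn.group_rates, group: float(value)}
        else:
            setattr(scn.schedule, parameter, {scn.horizon[0]: value})
        out[value] = run_scenario(scn, keep_trajectory=False)
    return out
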