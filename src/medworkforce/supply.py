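"""Supply submodel: annual stock-and-flow update of the specialist workforce.

The workforce is a stock indexed by (specialty, sex, single-year age).  Each
simulated year the stock is advanced by the discrete balance

    Stock(t+1) = Stock(t) + Inflow(t) - Outflow(t)

with a fixed within-year operation order: mandatory retirement, then
multiplicative exits (mortality, drop-out, optional early retirement), then
aging by one year, then training completions, then net immigration.  Every
flow is recorded in a :class:`FlowLedger` so conservation can be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AGE_MIN = 30
AGE_MAX = 65
N_AGES = AGE_MAX - AGE_MIN + 1  # 36 single-year age groups
SEXES = ("female", "male")
FEMALE, MALE = 0, 1

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "N_AGES",
    "SEXES",
    "SpecialtyStock",
    "ExitRates",
    "TrainingPipeline",
    "ImmigrationFlow",
    "FteRatio",
    "FlowLedger",
    "SupplyTrajectory",
    "step_year",
    "training_inflow",
    "residency_intake",
    "simulate_supply",
    "fte_supply",
]


def _ages(age_min: int, age_max: int) -> np.ndarray:
    return np.arange(age_min, age_max + 1)


@dataclass
class SpecialtyStock:
    """Headcounts per (specialty, sex, age).

    ``counts`` has shape ``(S, 2, A)`` with sex axis ordered (female, male)
    and the age axis covering ``age_min..age_max`` in single years.  Counts
    are continuous non-negative reals (fractional people are allowed; the
    model is deterministic).
    """

    counts: np.ndarray
    specialty_ids: np.ndarray | None = None
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[1] != 2:
            raise ValueError(
                f"counts must have shape (S, 2, A); got {self.counts.shape}"
            )
        n_ages = self.age_max - self.age_min + 1
        if self.counts.shape[2] != n_ages:
            raise ValueError(
                f"age axis has {self.counts.shape[2]} groups; "
                f"ages {self.age_min}..{self.age_max} require {n_ages}"
            )
        if self.specialty_ids is None:
            self.specialty_ids = np.arange(1, self.counts.shape[0] + 1)
        else:
            self.specialty_ids = np.asarray(self.specialty_ids, dtype=int)
            if len(self.specialty_ids) != self.counts.shape[0]:
                raise ValueError("specialty_ids length must match counts axis 0")
        if np.any(self.counts < 0):
            s, x, a = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at specialty={self.specialty_ids[s]}, "
                f"sex={SEXES[x]}, age={self.age_min + a}"
            )

    @property
    def n_specialties(self) -> int:
        return self.counts.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return _ages(self.age_min, self.age_max)

    def total(self) -> float:
        return float(self.counts.sum())

    def total_by_specialty(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def copy(self) -> "SpecialtyStock":
        return SpecialtyStock(
            self.counts.copy(), self.specialty_ids.copy(), self.age_min, self.age_max
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns specialty_id, sex, age, count."""
        s, x, a = np.meshgrid(
            self.specialty_ids, np.arange(2), self.ages, indexing="ij"
        )
        return pd.DataFrame(
            {
                "specialty_id": s.ravel(),
                "sex": np.array(SEXES)[x.ravel()],
                "age": a.ravel(),
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, age_min: int = AGE_MIN, age_max: int = AGE_MAX
    ) -> "SpecialtyStock":
        ids = np.sort(df["specialty_id"].unique())
        n_ages = age_max - age_min + 1
        counts = np.zeros((len(ids), 2, n_ages))
        id_pos = {sid: i for i, sid in enumerate(ids)}
        sex_pos = {s: i for i, s in enumerate(SEXES)}
        for row in df.itertuples(index=False):
            age = int(row.age)
            if not age_min <= age <= age_max:
                raise ValueError(f"age {age} outside {age_min}..{age_max}")
            counts[id_pos[row.specialty_id], sex_pos[row.sex], age - age_min] += row.count
        return cls(counts, ids, age_min, age_max)


@dataclass
class ExitRates:
    """Exit-flow rates: mortality, drop-out, mandatory and early retirement.

    ``mortality`` is (2, A) per (sex, age); ``dropout`` is (S, 2, A);
    ``retirement_age`` is the mandatory retirement age, either a constant or
    a year-keyed schedule resolved with carry-forward.  ``early_retirement``
    is an optional (2, A) rate applied like the other multiplicative exits.
    """

    mortality: np.ndarray
    dropout: np.ndarray
    retirement_age: int | Mapping[int, int] = AGE_MAX
    early_retirement: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.dropout = np.asarray(self.dropout, dtype=float)
        if self.early_retirement is not None:
            self.early_retirement = np.asarray(self.early_retirement, dtype=float)
        for name, arr in (
            ("mortality", self.mortality),
            ("dropout", self.dropout),
            ("early_retirement", self.early_retirement),
        ):
            if arr is not None and (np.any(arr < 0) or np.any(arr > 1)):
                raise ValueError(f"{name} rates must lie in [0, 1]")

    def retirement_age_for(self, year: int) -> int:
        if isinstance(self.retirement_age, Mapping):
            keys = [y for y in self.retirement_age if y <= year]
            if not keys:
                raise KeyError(
                    f"retirement_age schedule has no value at or before {year}"
                )
            return int(self.retirement_age[max(keys)])
        return int(self.retirement_age)


@dataclass
class TrainingPipeline:
    """Lagged training cohorts: medical school then residency.

    A cohort admitted in year y graduates after ``d_med`` years, sits the
    national examination (``exam_pass_fraction``), is allocated to residency
    positions, and enters the specialist stock ``d_res`` years later, scaled
    by the per-specialty ``completion_fraction``.  The sex split is fixed at
    admission (``female_fraction``) and preserved through the pipeline.

    ``admissions`` maps admission year -> total admitted; ``positions`` maps
    residency start year -> (S,) available positions.  Both must cover the
    full lag history of any simulated year (warm-up cohorts); values do not
    carry forward implicitly here — the scenario layer pre-resolves them.
    """

    admissions: Mapping[int, float]
    positions: Mapping[int, np.ndarray]
    d_res: np.ndarray  # (S,) residency duration per specialty, 4 or 5 years
    d_med: int = 6
    exam_pass_fraction: float = 1.0
    completion_fraction: np.ndarray | float = 1.0
    female_fraction: float | Mapping[int, float] = 2.0 / 3.0
    entry_age_distribution: np.ndarray | None = None  # (A,), default point mass at age_min

    def __post_init__(self) -> None:
        self.d_res = np.asarray(self.d_res, dtype=int)
        if not np.all((self.d_res >= 1)):
            raise ValueError("residency durations must be >= 1 year")
        if not 0.0 <= self.exam_pass_fraction <= 1.0:
            raise ValueError("exam_pass_fraction must lie in [0, 1]")
        self.completion_fraction = np.broadcast_to(
            np.asarray(self.completion_fraction, dtype=float), self.d_res.shape
        ).copy()
        if np.any(self.completion_fraction < 0) or np.any(self.completion_fraction > 1):
            raise ValueError("completion_fraction must lie in [0, 1]")
        if self.entry_age_distribution is not None:
            d = np.asarray(self.entry_age_distribution, dtype=float)
            if abs(d.sum() - 1.0) > 1e-9 or np.any(d < 0):
                raise ValueError("entry_age_distribution must be a probability vector")
            self.entry_age_distribution = d

    @property
    def n_specialties(self) -> int:
        return len(self.d_res)

    def _admissions_for(self, year: int) -> float:
        try:
            return float(self.admissions[year])
        except KeyError:
            raise KeyError(
                f"pipeline has no admission cohort for year {year}; supply "
                "warm-up cohorts back to year - (d_med + max d_res)"
            ) from None

    def _female_fraction_for(self, year: int) -> float:
        if isinstance(self.female_fraction, Mapping):
            keys = [y for y in self.female_fraction if y <= year]
            if not keys:
                raise KeyError(f"female_fraction has no value at or before {year}")
            return float(self.female_fraction[max(keys)])
        return float(self.female_fraction)


def residency_intake(pipeline: TrainingPipeline, start_year: int) -> np.ndarray:
    """Residency entrants per (specialty, sex) for one national-exam year.

    Graduates of the cohort admitted ``d_med`` years earlier who pass the
    exam are allocated to specialties in proportion to available positions,
    and each specialty's intake is capped by its positions:
    intake_s = positions_s * min(1, graduates / total positions).
    """
    admitted = pipeline._admissions_for(start_year - pipeline.d_med)
    ffrac = pipeline._female_fraction_for(start_year - pipeline.d_med)
    graduates = admitted * pipeline.exam_pass_fraction
    try:
        positions = np.asarray(pipeline.positions[start_year], dtype=float)
    except KeyError:
        raise KeyError(
            f"pipeline has no residency positions for start year {start_year}; "
            "supply warm-up positions back to year - max d_res"
        ) from None
    total_positions = positions.sum()
    fill = min(1.0, graduates / total_positions) if total_positions > 0 else 0.0
    intake = positions * fill  # (S,)
    return np.stack([intake * ffrac, intake * (1.0 - ffrac)], axis=1)  # (S, 2)


def training_inflow(pipeline: TrainingPipeline, year: int) -> np.ndarray:
    """New specialists per (specialty, sex) completing residency in ``year``.

    Specialty s receives the intake of the residency cohort that started in
    ``year - d_res[s]``, scaled by its completion fraction.
    """
    inflow = np.zeros((pipeline.n_specialties, 2))
    for dur in np.unique(pipeline.d_res):
        mask = pipeline.d_res == dur
        intake = residency_intake(pipeline, year - int(dur))
        inflow[mask] = intake[mask] * pipeline.completion_fraction[mask, None]
    return inflow


@dataclass
class ImmigrationFlow:
    """Net international migration of specialists.

    ``net_entrants`` maps year -> (S,) net entrants per specialty (negative
    = net emigration); ``sex_split`` is the fraction female;
    ``age_distribution`` spreads entrants over the age axis (sums to 1).
    """

    net_entrants: Mapping[int, np.ndarray] | np.ndarray
    sex_split: float = 0.5
    age_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_split <= 1.0:
            raise ValueError("sex_split must lie in [0, 1]")
        if self.age_distribution is not None:
            d = np.asarray(self.age_distribution, dtype=float)
            if abs(d.sum() - 1.0) > 1e-9 or np.any(d < 0):
                raise ValueError("age_distribution must be a probability vector")
            self.age_distribution = d

    def net_for(self, year: int, n_specialties: int) -> np.ndarray:
        if isinstance(self.net_entrants, Mapping):
            keys = [y for y in self.net_entrants if y <= year]
            if not keys:
                return np.zeros(n_specialties)
            net = np.asarray(self.net_entrants[max(keys)], dtype=float)
        else:
            net = np.asarray(self.net_entrants, dtype=float)
        return np.broadcast_to(net, (n_specialties,)).copy()


def default_immigration_age_distribution(
    age_min: int = AGE_MIN, age_max: int = AGE_MAX, upper: int = 40
) -> np.ndarray:
    """Uniform over ages age_min..upper (default 30-40), zero above."""
    n_ages = age_max - age_min + 1
    d = np.zeros(n_ages)
    k = upper - age_min + 1
    d[:k] = 1.0 / k
    return d


@dataclass
class FteRatio:
    """Headcount-to-FTE conversion: FTE = headcount * ratio, per (sex, age)."""

    ratio: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratio, dtype=float)
        if np.any(arr <= 0) or np.any(arr > 1.5):
            raise ValueError("FTE ratios must lie in (0, 1.5]")
        self.ratio = arr

    def grid(self, n_ages: int) -> np.ndarray:
        return np.broadcast_to(self.ratio, (2, n_ages))


@dataclass
class FlowLedger:
    """Per-step record of every flow, per (specialty, sex).

    Outflows are positive magnitudes.  ``conservation_residual`` returns
    total(t+1) - total(t) - (inflows - outflows), which is ~0 up to float
    rounding for every step.
    """

    year: int
    retirements: np.ndarray
    deaths: np.ndarray
    dropouts: np.ndarray
    early_retirements: np.ndarray
    aged_out: np.ndarray
    training_in: np.ndarray
    immigration_net: np.ndarray

    OUTFLOWS = ("retirements", "deaths", "dropouts", "early_retirements", "aged_out")
    INFLOWS = ("training_in", "immigration_net")

    def total_outflow(self) -> float:
        return float(sum(getattr(self, f).sum() for f in self.OUTFLOWS))

    def total_inflow(self) -> float:
        return float(sum(getattr(self, f).sum() for f in self.INFLOWS))

    def conservation_residual(
        self, before: SpecialtyStock, after: SpecialtyStock
    ) -> float:
        return (after.total() - before.total()) - (
            self.total_inflow() - self.total_outflow()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.OUTFLOWS + self.INFLOWS:
            arr = getattr(self, name)
            for s in range(arr.shape[0]):
                for x in range(2):
                    rows.append(
                        {
                            "year": self.year,
                            "flow": name,
                            "specialty_index": s,
                            "sex": SEXES[x],
                            "value": arr[s, x],
                        }
                    )
        return pd.DataFrame(rows)


def step_year(
    stock: SpecialtyStock,
    exits: ExitRates,
    pipeline: TrainingPipeline | None,
    immigration: ImmigrationFlow | None,
    year: int,
) -> tuple[SpecialtyStock, FlowLedger]:
    """Advance the stock one year; ``year`` labels the *returned* stock.

    ``stock`` describes year - 1; the result describes ``year`` after that
    year's retirements, exits, aging, training completions and migration.
    A cohort admitted to medical school in year y therefore first appears
    in the stock of year y + d_med + d_res.

    Operation order (fixed; it changes results at the third decimal):
    1. remove everyone at age >= retirement_age (mandatory retirement);
    2. apply mortality, drop-out and early retirement multiplicatively,
       in that order, to the survivors;
    3. age every cohort one year (anyone pushed past age_max exits as
       ``aged_out`` — only possible when retirement_age > age_max);
    4. add training completions of ``year`` at the entry-age distribution;
    5. add net immigration.

    Raises ValueError if net emigration would drive a cell negative, naming
    the cell.
    """
    S, _, A = stock.counts.shape
    c = stock.counts.copy()
    ages = stock.ages

    # 1. mandatory retirement
    ret_age = exits.retirement_age_for(year)
    ret_mask = ages >= ret_age
    retirements = c[:, :, ret_mask].sum(axis=2)
    c[:, :, ret_mask] = 0.0

    # 2. multiplicative exits on survivors
    mort = np.broadcast_to(exits.mortality, (2, A))
    deaths_cells = c * mort[None, :, :]
    c = c - deaths_cells
    drop = np.broadcast_to(exits.dropout, (S, 2, A))
    drop_cells = c * drop
    c = c - drop_cells
    if exits.early_retirement is not None:
        early = np.broadcast_to(exits.early_retirement, (2, A))
        early_cells = c * early[None, :, :]
        c = c - early_cells
    else:
        early_cells = np.zeros_like(c)

    # 3. aging: shift the age axis up by one
    aged_out = c[:, :, -1].copy()
    c = np.concatenate([np.zeros((S, 2, 1)), c[:, :, :-1]], axis=2)

    # 4. training completions
    if pipeline is not None:
        inflow = training_inflow(pipeline, year)  # (S, 2)
        entry = pipeline.entry_age_distribution
        if entry is None:
            entry = np.zeros(A)
            entry[0] = 1.0  # point mass at age_min
        c = c + inflow[:, :, None] * entry[None, None, :]
        training_in = inflow
    else:
        training_in = np.zeros((S, 2))

    # 5. net immigration
    if immigration is not None:
        net = immigration.net_for(year, S)  # (S,)
        sex_w = np.array([immigration.sex_split, 1.0 - immigration.sex_split])
        age_w = immigration.age_distribution
        if age_w is None:
            age_w = default_immigration_age_distribution(stock.age_min, stock.age_max)
        delta = net[:, None, None] * sex_w[None, :, None] * age_w[None, None, :]
        c = c + delta
        if np.any(c < -1e-9):
            s, x, a = np.argwhere(c < -1e-9)[0]
            raise ValueError(
                "net emigration exceeds stock at cell "
                f"(specialty={stock.specialty_ids[s]}, sex={SEXES[x]}, "
                f"age={stock.age_min + a})"
            )
        c = np.maximum(c, 0.0)
        immigration_net = net[:, None] * sex_w[None, :]
    else:
        immigration_net = np.zeros((S, 2))

    ledger = FlowLedger(
        year=year,
        retirements=retirements,
        deaths=deaths_cells.sum(axis=2),
        dropouts=drop_cells.sum(axis=2),
        early_retirements=early_cells.sum(axis=2),
        aged_out=aged_out,
        training_in=training_in,
        immigration_net=immigration_net,
    )
    new_stock = SpecialtyStock(c, stock.specialty_ids.copy(), stock.age_min, stock.age_max)
    return new_stock, ledger


@dataclass
class SupplyTrajectory:
    """Stocks for every year of a simulation horizon, plus the flow ledgers."""

    years: list[int]
    stocks: list[SpecialtyStock]
    ledgers: list[FlowLedger] = field(default_factory=list)

    def stock_at(self, year: int) -> SpecialtyStock:
        try:
            return self.stocks[self.years.index(year)]
        except ValueError:
            raise KeyError(f"year {year} not in trajectory {self.years[0]}..{self.years[-1]}") from None

    def counts_array(self) -> np.ndarray:
        """(T, S, 2, A) array over the horizon."""
        return np.stack([s.counts for s in self.stocks])

    def totals(self) -> pd.Series:
        return pd.Series(
            [s.total() for s in self.stocks], index=pd.Index(self.years, name="year")
        )

    def pyramid(self, specialty_id: int, year: int) -> pd.DataFrame:
        stock = self.stock_at(year)
        idx = int(np.flatnonzero(stock.specialty_ids == specialty_id)[0])
        df = stock.to_frame()
        return df[df["specialty_id"] == stock.specialty_ids[idx]].reset_index(drop=True)


def simulate_supply(
    initial: SpecialtyStock,
    exits: ExitRates,
    pipeline: TrainingPipeline | None,
    immigration: ImmigrationFlow | None,
    years: Sequence[int],
) -> SupplyTrajectory:
    """Run the annual update over ``years`` (inclusive of both ends).

    The returned trajectory holds the stock at 1 January of every year in
    the horizon; ``years[0]`` carries the initial stock unchanged.  The run
    is fully deterministic.
    """
    years = list(years)
    if years != sorted(years) or len(set(years)) != len(years):
        raise ValueError("years must be strictly increasing")
    stocks = [initial.copy()]
    ledgers: list[FlowLedger] = []
    current = initial
    for year in years[1:]:
        current, ledger = step_year(current, exits, pipeline, immigration, year)
        stocks.append(current)
        ledgers.append(ledger)
    return SupplyTrajectory(years=years, stocks=stocks, ledgers=ledgers)


def fte_supply(stock: SpecialtyStock, fte: FteRatio) -> np.ndarray:
    """Full-time-equivalent supply per specialty: sum of counts x ratio."""
    grid = fte.grid(stock.counts.shape[2])  # (2, A)
    return (stock.counts * grid[None, :, :]).sum(axis=(1, 2))
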