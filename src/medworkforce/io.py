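"""Configuration IO: strict YAML scenario files, CSV tables, result files.

A scenario on disk is one YAML file plus a set of CSV tables it points to.
The YAML schema is strict — unknown keys are errors, so a typo in a policy
parameter name fails validation instead of being silently ignored.  Files
use "." as the decimal separator and no thousands separators.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import demand as dm
from . import metrics as mx
from . import scenario as se
from . import supply as sp

__all__ = [
    "ValidationReport",
    "ScenarioValidationError",
    "load_scenario",
    "save_scenario",
    "validate_scenario",
    "write_results",
    "read_results_long",
    "scenario_digest",
]


@dataclass
class ValidationReport:
    """Severity-tagged findings from scenario validation."""

    items: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, severity: str, location: str, message: str) -> None:
        self.items.append((severity, location, message))

    @property
    def errors(self) -> list[tuple[str, str, str]]:
        return [i for i in self.items if i[0] == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        return "\n".join(f"[{s}] {loc}: {msg}" for s, loc, msg in self.items) or "ok"


class ScenarioValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


# ---------------------------------------------------------------- YAML schema


class _Meta(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    seed: int | None = None


class _Horizon(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: int
    end: int


class _SupplyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_med: int = 6
    exam_pass_fraction: float = 1.0
    completion_fraction: float = 1.0
    entry_age: int | None = None  # point mass; None = age 30
    immigration_sex_split: float = 0.5
    immigration_age_max: int = 40
    numerus_clausus: dict[int, float]
    entrant_female_fraction: dict[int, float] = {}
    retirement_age: dict[int, int]
    carry_forward: bool = True


class _DemandParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population_scenario: Literal["slow", "moderate", "rapid", "file"] = "moderate"
    group_rates: dict[str, float] = {}


class _Files(BaseModel):
    model_config = ConfigDict(extra="forbid")
    initial_stock: str
    mortality: str
    dropout: str
    standards: str
    specialties: str
    positions: str
    fte: str
    immigration: str
    population: str | None = None


class _ScenarioFile(BaseModel):
    model_config = ConfigDict(extra="forbid")
    meta: _Meta
    horizon: _Horizon
    supply_params: _SupplyParams
    demand_params: _DemandParams
    files: _Files


# ------------------------------------------------------------------- loading


def _read_csv(path: Path, report: ValidationReport, required: list[str]) -> pd.DataFrame | None:
    if not path.exists():
        report.add("error", str(path), "file not found")
        return None
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.add("error", str(path), f"missing columns {missing}")
        return None
    return df


def _sex_age_table(df: pd.DataFrame, value_col: str) -> np.ndarray:
    arr = np.zeros((2, sp.N_AGES))
    seen = np.zeros((2, sp.N_AGES), dtype=bool)
    sex_pos = {s: i for i, s in enumerate(sp.SEXES)}
    for row in df.itertuples(index=False):
        arr[sex_pos[row.sex], int(row.age) - sp.AGE_MIN] = getattr(row, value_col)
        seen[sex_pos[row.sex], int(row.age) - sp.AGE_MIN] = True
    if not seen.all():
        sx, ax = np.argwhere(~seen)[0]
        raise ValueError(f"missing rate cell (sex={sp.SEXES[sx]}, age={sp.AGE_MIN + ax})")
    return arr


def _year_specialty_schedule(df: pd.DataFrame, ids: np.ndarray, value_col: str) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    id_pos = {int(s): i for i, s in enumerate(ids)}
    for year, grp in df.groupby("year"):
        vec = np.zeros(len(ids))
        for row in grp.itertuples(index=False):
            vec[id_pos[int(row.specialty_id)]] = getattr(row, value_col)
        out[int(year)] = vec
    return out


def validate_scenario(path: str | Path) -> ValidationReport:
    """Validate without constructing; returns the full report."""
    try:
        load_scenario(path)
        return ValidationReport()
    except ScenarioValidationError as exc:
        return exc.report


def load_scenario(path: str | Path) -> se.Scenario:
    """Load and cross-validate a scenario directory's YAML entry point.

    Raises :class:`ScenarioValidationError` carrying a report if the
    schema, a referenced file, or a cross-reference is invalid; a scenario
    with any error never reaches ``run_scenario``.
    """
    path = Path(path)
    report = ValidationReport()
    if not path.exists():
        report.add("error", str(path), "scenario file not found")
        raise ScenarioValidationError(report)
    raw = yaml.safe_load(path.read_text())
    try:
        cfg = _ScenarioFile.model_validate(raw)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            report.add("error", f"{path}:{loc}", err["msg"])
        raise ScenarioValidationError(report) from None

    base = path.parent
    stock_df = _read_csv(base / cfg.files.initial_stock, report,
                         ["specialty_id", "sex", "age", "count"])
    mort_df = _read_csv(base / cfg.files.mortality, report, ["sex", "age", "rate"])
    drop_df = _read_csv(base / cfg.files.dropout, report,
                        ["specialty_id", "sex", "age", "rate"])
    std_df = _read_csv(base / cfg.files.standards, report,
                       ["specialty_id", "base_ratio_per_100k", "demand_group"])
    spc_df = _read_csv(base / cfg.files.specialties, report,
                       ["specialty_id", "specialty_name", "d_res"])
    pos_df = _read_csv(base / cfg.files.positions, report,
                       ["year", "specialty_id", "positions"])
    fte_df = _read_csv(base / cfg.files.fte, report, ["year", "sex", "age", "ratio"])
    imm_df = _read_csv(base / cfg.files.immigration, report,
                       ["year", "specialty_id", "net_entrants"])
    if not report.ok:
        raise ScenarioValidationError(report)

    stock = sp.SpecialtyStock.from_frame(stock_df)
    ids = stock.specialty_ids
    id_set = set(int(i) for i in ids)
    for name, df in (("dropout", drop_df), ("standards", std_df),
                     ("specialties", spc_df), ("positions", pos_df),
                     ("immigration", imm_df)):
        extra = set(df["specialty_id"].astype(int)) - id_set
        lacking = id_set - set(df["specialty_id"].astype(int))
        if extra:
            report.add("error", name, f"unknown specialty ids {sorted(extra)}")
        if lacking:
            report.add("error", name, f"specialty ids without rows: {sorted(lacking)}")
    if not report.ok:
        raise ScenarioValidationError(report)

    try:
        mortality = _sex_age_table(mort_df, "rate")
        dropout = np.zeros((len(ids), 2, sp.N_AGES))
        for sid, grp in drop_df.groupby("specialty_id"):
            i = int(np.flatnonzero(ids == sid)[0])
            dropout[i] = _sex_age_table(grp, "rate")
    except ValueError as exc:
        report.add("error", "rate tables", str(exc))
        raise ScenarioValidationError(report) from None

    spc_df = spc_df.sort_values("specialty_id")
    d_res = spc_df["d_res"].to_numpy(dtype=int)
    names = dict(zip(spc_df["specialty_id"].astype(int), spc_df["specialty_name"]))

    standards = [
        dm.NeedStandard(
            specialty=int(r.specialty_id),
            base_ratio=float(r.base_ratio_per_100k),
            group=str(r.demand_group),
        )
        for r in std_df.sort_values("specialty_id").itertuples(index=False)
    ]

    years = range(cfg.horizon.start, cfg.horizon.end + 1)
    if cfg.demand_params.population_scenario == "file":
        if cfg.files.population is None:
            report.add("error", "files.population",
                       "population_scenario is 'file' but no population file given")
            raise ScenarioValidationError(report)
        pop_df = _read_csv(base / cfg.files.population, report,
                           ["scenario", "year", "population"])
        if pop_df is None:
            raise ScenarioValidationError(report)
        label = str(pop_df["scenario"].iloc[0])
        population = dm.PopulationScenario(
            label,
            {int(r.year): float(r.population)
             for r in pop_df.itertuples(index=False) if r.scenario == label},
        )
    else:
        population = dm.spain_population(cfg.demand_params.population_scenario, years)

    fte_sched = {
        int(year): _sex_age_table(grp, "ratio")
        for year, grp in fte_df.groupby("year")
    }
    entry = None
    if cfg.supply_params.entry_age is not None:
        entry = np.zeros(sp.N_AGES)
        entry[cfg.supply_params.entry_age - sp.AGE_MIN] = 1.0

    schedule = se.ParameterSchedule(
        numerus_clausus={int(k): float(v) for k, v in cfg.supply_params.numerus_clausus.items()},
        entrant_female_fraction=(
            {int(k): float(v) for k, v in cfg.supply_params.entrant_female_fraction.items()}
            or {cfg.horizon.start: 2.0 / 3.0}
        ),
        residency_positions=_year_specialty_schedule(pos_df, ids, "positions"),
        retirement_age={int(k): int(v) for k, v in cfg.supply_params.retirement_age.items()},
        fte_ratio=fte_sched,
        immigration_net=_year_specialty_schedule(imm_df, ids, "net_entrants"),
        carry_forward=cfg.supply_params.carry_forward,
    )

    scn = se.Scenario(
        name=cfg.meta.name,
        horizon=(cfg.horizon.start, cfg.horizon.end),
        initial_stock=stock,
        mortality=mortality,
        dropout=dropout,
        schedule=schedule,
        standards=standards,
        population=population,
        d_med=cfg.supply_params.d_med,
        d_res=d_res,
        exam_pass_fraction=cfg.supply_params.exam_pass_fraction,
        completion_fraction=cfg.supply_params.completion_fraction,
        entry_age_distribution=entry,
        immigration_sex_split=cfg.supply_params.immigration_sex_split,
        immigration_age_distribution=sp.default_immigration_age_distribution(
            upper=cfg.supply_params.immigration_age_max
        ),
        group_rates=dict(cfg.demand_params.group_rates),
        specialty_names=names,
        seed=cfg.meta.seed,
    )
    missing = scn.schedule.validate(scn.years)
    for p, y in missing:
        report.add("error", "schedule", f"missing value for ({p}, {y})")
    if not report.ok:
        raise ScenarioValidationError(report)
    return scn


# -------------------------------------------------------------------- saving


def _schedule_to_yaml(tab: dict[int, Any]) -> dict[int, Any]:
    return {int(k): (float(v) if np.isscalar(v) else v) for k, v in tab.items()}


def save_scenario(scn: se.Scenario, out_dir: str | Path) -> Path:
    """Write the YAML + CSV file set for a scenario; returns the YAML path.

    ``load_scenario(save_scenario(s))`` reproduces an equivalent scenario
    (round-trip identity on all simulated quantities).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = scn.initial_stock.specialty_ids
    S = len(ids)

    scn.initial_stock.to_frame().assign(
        specialty_name=lambda d: d["specialty_id"].map(
            lambda i: scn.specialty_names.get(int(i), str(i))
        )
    ).to_csv(out / "initial_stock.csv", index=False, float_format="%.17g")

    ages = np.arange(sp.AGE_MIN, sp.AGE_MAX + 1)
    mort = np.broadcast_to(scn.mortality, (2, sp.N_AGES))
    pd.DataFrame(
        {
            "sex": np.repeat(sp.SEXES, sp.N_AGES),
            "age": np.tile(ages, 2),
            "rate": mort.ravel(),
        }
    ).to_csv(out / "mortality.csv", index=False, float_format="%.17g")

    drop = np.broadcast_to(scn.dropout, (S, 2, sp.N_AGES))
    sidx, xidx, aidx = np.meshgrid(ids, np.arange(2), ages, indexing="ij")
    pd.DataFrame(
        {
            "specialty_id": sidx.ravel(),
            "sex": np.array(sp.SEXES)[xidx.ravel()],
            "age": aidx.ravel(),
            "rate": drop.ravel(),
        }
    ).to_csv(out / "dropout.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {
            "specialty_id": [s.specialty for s in scn.standards],
            "base_ratio_per_100k": [s.base_ratio for s in scn.standards],
            "demand_group": [s.group for s in scn.standards],
        }
    ).to_csv(out / "standards.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {
            "specialty_id": ids,
            "specialty_name": [scn.specialty_names.get(int(i), str(i)) for i in ids],
            "d_res": scn.d_res,
        }
    ).to_csv(out / "specialties.csv", index=False, float_format="%.17g")

    pos_rows = []
    for year, val in sorted(scn.schedule.residency_positions.items()):
        vec = np.broadcast_to(np.asarray(val, dtype=float), (S,))
        pos_rows += [
            {"year": year, "specialty_id": int(i), "positions": float(v)}
            for i, v in zip(ids, vec)
        ]
    pd.DataFrame(pos_rows).to_csv(out / "positions.csv", index=False, float_format="%.17g")

    fte_rows = []
    for year, val in sorted(scn.schedule.fte_ratio.items()):
        grid = np.broadcast_to(np.asarray(val, dtype=float), (2, sp.N_AGES))
        for x, sex in enumerate(sp.SEXES):
            fte_rows += [
                {"year": year, "sex": sex, "age": int(a), "ratio": float(r)}
                for a, r in zip(ages, grid[x])
            ]
    pd.DataFrame(fte_rows).to_csv(out / "fte.csv", index=False, float_format="%.17g")

    imm_rows = []
    for year, val in sorted(scn.schedule.immigration_net.items()):
        vec = np.broadcast_to(np.asarray(val, dtype=float), (S,))
        imm_rows += [
            {"year": year, "specialty_id": int(i), "net_entrants": float(v)}
            for i, v in zip(ids, vec)
        ]
    pd.DataFrame(imm_rows).to_csv(out / "immigration.csv", index=False, float_format="%.17g")

    pop_label = scn.population.label
    files: dict[str, Any] = {
        "initial_stock": "initial_stock.csv",
        "mortality": "mortality.csv",
        "dropout": "dropout.csv",
        "standards": "standards.csv",
        "specialties": "specialties.csv",
        "positions": "positions.csv",
        "fte": "fte.csv",
        "immigration": "immigration.csv",
    }
    if pop_label in ("slow", "moderate", "rapid"):
        pop_scenario = pop_label
    else:
        pop_scenario = "file"
        files["population"] = "population.csv"
        pd.DataFrame(
            {
                "scenario": pop_label,
                "year": sorted(scn.population.population),
                "population": [
                    scn.population.population[y]
                    for y in sorted(scn.population.population)
                ],
            }
        ).to_csv(out / "population.csv", index=False, float_format="%.17g")

    entry_age = None
    if scn.entry_age_distribution is not None:
        entry_age = int(sp.AGE_MIN + int(np.argmax(scn.entry_age_distribution)))
    imm_dist = scn.immigration_age_distribution
    imm_age_max = 40
    if imm_dist is not None:
        imm_age_max = int(sp.AGE_MIN + int(np.flatnonzero(imm_dist > 0)[-1]))

    doc = {
        "meta": {"name": scn.name, "seed": scn.seed},
        "horizon": {"start": scn.horizon[0], "end": scn.horizon[1]},
        "supply_params": {
            "d_med": int(scn.d_med),
            "exam_pass_fraction": float(scn.exam_pass_fraction),
            "completion_fraction": float(np.asarray(scn.completion_fraction).ravel()[0]),
            "entry_age": entry_age,
            "immigration_sex_split": float(scn.immigration_sex_split),
            "immigration_age_max": imm_age_max,
            "numerus_clausus": _schedule_to_yaml(scn.schedule.numerus_clausus),
            "entrant_female_fraction": _schedule_to_yaml(
                scn.schedule.entrant_female_fraction
            ),
            "retirement_age": {
                int(k): int(v) for k, v in scn.schedule.retirement_age.items()
            },
            "carry_forward": scn.schedule.carry_forward,
        },
        "demand_params": {
            "population_scenario": pop_scenario,
            "group_rates": {k: float(v) for k, v in scn.group_rates.items()},
        },
        "files": files,
    }
    yaml_path = out / "scenario.yaml"
    yaml_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return yaml_path


# ------------------------------------------------------------------- results


def scenario_digest(scn: se.Scenario) -> str:
    """SHA-256 over a canonical serialization of every scenario input."""

    def enc(obj: Any) -> Any:
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    payload = {
        "name": scn.name,
        "horizon": list(scn.horizon),
        "stock": scn.initial_stock.counts,
        "mortality": scn.mortality,
        "dropout": scn.dropout,
        "early_retirement": scn.early_retirement,
        "schedule": {
            p: scn.schedule.table(p) for p in se.SCHEDULABLE_PARAMETERS
        },
        "carry_forward": scn.schedule.carry_forward,
        "standards": [
            [s.specialty, s.base_ratio, s.group, s.rate_override]
            for s in scn.standards
        ],
        "population": scn.population.population,
        "d_med": scn.d_med,
        "d_res": scn.d_res,
        "exam_pass_fraction": scn.exam_pass_fraction,
        "completion_fraction": scn.completion_fraction,
        "entry_age_distribution": scn.entry_age_distribution,
        "immigration_sex_split": scn.immigration_sex_split,
        "immigration_age_distribution": scn.immigration_age_distribution,
        "group_rates": scn.group_rates,
    }
    blob = json.dumps(enc(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(
    result: mx.ScenarioResult,
    out_dir: str | Path,
    scenario: se.Scenario | None = None,
    pyramids: str = "combined",
) -> dict[str, Path]:
    """Serialize a run: tidy long CSV, summary table, pyramids, manifest.

    ``pyramids``: "combined" writes one pyramids.csv; "per_specialty"
    writes one CSV per (specialty, year) under pyramids/; "none" skips.
    Numbers are written at full double precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    long_df = result.by_specialty.melt(
        id_vars=["specialty_id", "specialty_name", "year"],
        var_name="metric",
        value_name="value",
    )
    long_df.insert(0, "scenario", result.name)
    p = out / "results_long.csv"
    long_df.to_csv(p, index=False, float_format="%.17g")
    written["long"] = p

    p = out / "aggregate.csv"
    result.aggregate.assign(scenario=result.name).to_csv(
        p, index=False, float_format="%.17g"
    )
    written["aggregate"] = p

    p = out / "summary.csv"
    result.summary().to_csv(p, float_format="%.17g")
    written["summary"] = p

    if result.trajectory is not None and pyramids != "none":
        frames = []
        for year in result.years():
            stock = result.trajectory.stock_at(year)
            df = stock.to_frame()
            df.insert(0, "year", year)
            frames.append(df)
        pyr = pd.concat(frames, ignore_index=True)
        if pyramids == "combined":
            p = out / "pyramids.csv"
            pyr.to_csv(p, index=False, float_format="%.17g")
            written["pyramids"] = p
        elif pyramids == "per_specialty":
            pdir = out / "pyramids"
            pdir.mkdir(exist_ok=True)
            for (sid, year), grp in pyr.groupby(["specialty_id", "year"]):
                grp.to_csv(
                    pdir / f"specialty_{int(sid):02d}_{int(year)}.csv",
                    index=False,
                    float_format="%.17g",
                )
            written["pyramids"] = pdir
        else:
            raise ValueError(f"unknown pyramids mode {pyramids!r}")

    manifest = {
        "scenario": result.name,
        "config_sha256": scenario_digest(scenario) if scenario is not None else None,
        "package_version": _package_version(),
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "years": result.years(),
        "n_specialties": int(result.by_specialty["specialty_id"].nunique()),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = p
    return written


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("medworkforce")
    except PackageNotFoundError:
        return "unknown"


def read_results_long(path: str | Path) -> pd.DataFrame:
    """Read back a tidy long results CSV (lossless at double precision)."""
    return pd.read_csv(path, float_precision="round_trip")
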