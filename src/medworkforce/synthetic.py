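"""Synthetic, internally consistent input fixtures.

Real per-specialty registries of specialists by sex and age are rarely
public; this module generates Spain-like stand-ins: 43 specialties x 2
sexes x 36 single-year ages, with configurable pyramid shapes (old-heavy
"traditional" specialties with few women vs young, strongly feminized
ones), Gompertz-like mortality, and aggregate calibration targets.  All
outputs are deterministic given the seed, and every generated object is
marked synthetic — per-specialty values emulate structure, not real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import demand as dm
from . import scenario as se
from . import supply as sp

__all__ = [
    "PYRAMID_SHAPES",
    "FixtureSpec",
    "generate_initial_stock",
    "generate_rate_tables",
    "generate_spain_like_scenario",
]

PYRAMID_SHAPES = ("old_heavy", "uniform", "young_feminized")

# (beta_a, beta_b, female_share): age density Beta(a, b) stretched over the
# age axis. old_heavy peaks near 55 with few women; young_feminized peaks
# near 40 with a female majority.
_SHAPE_PARAMS = {
    "old_heavy": (5.0, 2.0, 0.25),
    "uniform": (1.0, 1.0, 0.45),
    "young_feminized": (2.0, 5.0, 0.65),
}


def _beta_age_density(a: float, b: float, n_ages: int) -> np.ndarray:
    """Beta(a, b) density discretized at cell midpoints, normalized to 1."""
    x = (np.arange(n_ages) + 0.5) / n_ages
    pdf = x ** (a - 1.0) * (1.0 - x) ** (b - 1.0)
    return pdf / pdf.sum()


@dataclass
class FixtureSpec:
    """Recipe for one synthetic input set.

    ``shapes`` assigns a pyramid shape per specialty (default: cycle
    through old_heavy / uniform / young_feminized).  Calibration targets
    are aggregate 2008 supply and need headcounts; generated totals hit
    them to well within 0.1%.
    """

    n_specialties: int = 43
    shapes: Sequence[str] | None = None
    entrant_female_fraction: float = 2.0 / 3.0
    supply_target: float = 141_579.0
    need_target: float = 144_410.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specialties < 1:
            raise ValueError("n_specialties must be >= 1")
        if self.supply_target <= 0 or self.need_target <= 0:
            raise ValueError(
                "calibration targets must be > 0 for a non-empty fixture"
            )
        if self.shapes is None:
            self.shapes = [
                PYRAMID_SHAPES[i % 3] for i in range(self.n_specialties)
            ]
        self.shapes = list(self.shapes)
        if len(self.shapes) != self.n_specialties:
            raise ValueError("shapes must list one shape per specialty")
        unknown = set(self.shapes) - set(PYRAMID_SHAPES)
        if unknown:
            raise ValueError(f"unknown pyramid shapes: {sorted(unknown)}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _specialty_sizes(spec: FixtureSpec) -> np.ndarray:
    """Seeded lognormal size weights normalized to the supply target."""
    rng = spec.rng(1)
    w = rng.lognormal(mean=0.0, sigma=0.6, size=spec.n_specialties)
    return w / w.sum() * spec.supply_target


def generate_initial_stock(spec: FixtureSpec) -> sp.SpecialtyStock:
    """Synthetic base-year stock with per-shape pyramid contracts.

    old_heavy specialties have mean age >= 50; young_feminized have mean
    age <= 42 and female share >= 0.55; the aggregate headcount matches
    ``supply_target`` exactly up to float rounding.
    """
    rng = spec.rng(2)
    sizes = _specialty_sizes(spec)
    n_ages = sp.N_AGES
    counts = np.zeros((spec.n_specialties, 2, n_ages))
    for i, shape in enumerate(spec.shapes):
        a, b, female_share = _SHAPE_PARAMS[shape]
        # mild seeded jitter keeps specialties distinct without breaking
        # the shape contracts
        a_j = a * rng.uniform(0.95, 1.05)
        b_j = b * rng.uniform(0.95, 1.05)
        dens = _beta_age_density(a_j, b_j, n_ages)
        f = np.clip(female_share + rng.uniform(-0.03, 0.03), 0.0, 1.0)
        counts[i, 0] = sizes[i] * f * dens
        counts[i, 1] = sizes[i] * (1.0 - f) * dens
    return sp.SpecialtyStock(counts)


def generate_rate_tables(
    spec: FixtureSpec,
    m0: float = 5e-4,
    beta: float = 0.09,
    female_mortality_factor: float = 0.6,
    dropout_female: float = 0.004,
    dropout_male: float = 0.002,
    fte_female: float = 0.85,
    fte_male: float = 1.0,
    immigration_total: float = 1000.0,
) -> tuple[sp.ExitRates, sp.FteRatio, sp.ImmigrationFlow]:
    """Smooth synthetic rate tables.

    Mortality is Gompertz-like, m(age) = m0 * exp(beta * (age - 30)), with
    female mortality a constant fraction of male at every age.  Drop-out is
    constant by sex (higher for women, reflecting higher exit rates).  FTE
    ratios are scalar per sex.  Immigration is split across specialties in
    proportion to stock size, half female, uniform over ages 30-40.
    """
    ages = np.arange(sp.AGE_MIN, sp.AGE_MAX + 1)
    male_mort = m0 * np.exp(beta * (ages - sp.AGE_MIN))
    if np.any(male_mort > 1.0):
        raise ValueError("mortality parameters produce rates > 1")
    mortality = np.stack([female_mortality_factor * male_mort, male_mort])
    dropout = np.zeros((spec.n_specialties, 2, sp.N_AGES))
    dropout[:, 0, :] = dropout_female
    dropout[:, 1, :] = dropout_male
    exits = sp.ExitRates(mortality=mortality, dropout=dropout, retirement_age=65)
    fte = sp.FteRatio(
        np.stack(
            [np.full(sp.N_AGES, fte_female), np.full(sp.N_AGES, fte_male)]
        )
    )
    sizes = _specialty_sizes(spec)
    net = immigration_total * sizes / sizes.sum()
    immigration = sp.ImmigrationFlow(
        net_entrants=net,
        sex_split=0.5,
        age_distribution=sp.default_immigration_age_distribution(),
    )
    return exits, fte, immigration


def _solve_group_shares(
    horizon_years: int,
    need_growth_target: float,
    population_growth: float,
    stable_share: float = 0.2,
    decreasing_share: float = 0.1,
) -> dict[str, float]:
    """Need-weighted demand-group shares reproducing an aggregate need path.

    Solves for the sharply-increasing vs stable-increasing split such that
    sum_g w_g (1+g_g)^T equals the target aggregate need growth net of
    population growth.  Raises if the four default rates cannot bracket the
    target with the fixed stable/decreasing shares.
    """
    f = {
        g: (1.0 + r) ** horizon_years for g, r in dm.DEFAULT_GROUP_RATES.items()
    }
    target = need_growth_target / population_growth
    rest = 1.0 - stable_share - decreasing_share
    a = (
        target
        - stable_share * f["stable"]
        - decreasing_share * f["decreasing"]
        - rest * f["stable_increasing"]
    ) / (f["sharply_increasing"] - f["stable_increasing"])
    if not 0.0 <= a <= rest:
        raise ValueError(
            "aggregate need growth target not reachable with default group rates"
        )
    return {
        "sharply_increasing": a,
        "stable_increasing": rest - a,
        "stable": stable_share,
        "decreasing": decreasing_share,
    }


def _generate_standards(spec: FixtureSpec, base_population: float,
                        need_growth_target: float,
                        population_growth: float,
                        horizon_years: int) -> list[dm.NeedStandard]:
    rng = spec.rng(3)
    total_ratio = spec.need_target * 100_000.0 / base_population
    shares = _solve_group_shares(horizon_years, need_growth_target, population_growth)
    groups = [dm.DEMAND_GROUPS[i % 4] for i in range(spec.n_specialties)]
    standards: list[dm.NeedStandard] = []
    jitter = rng.lognormal(0.0, 0.4, size=spec.n_specialties)
    for g in dm.DEMAND_GROUPS:
        idx = [i for i, gi in enumerate(groups) if gi == g]
        if not idx:
            continue
        w = jitter[idx] / jitter[idx].sum()
        group_ratio = shares[g] * total_ratio
        for i, wi in zip(idx, w):
            standards.append(
                dm.NeedStandard(specialty=i + 1, base_ratio=group_ratio * wi, group=g)
            )
    standards.sort(key=lambda s: s.specialty)
    return standards


def generate_spain_like_scenario(
    seed: int = 0,
    population_label: str = "moderate",
    need_2025_target: float = 173_918.0,
) -> se.Scenario:
    """A complete synthetic baseline scenario calibrated to Spain-like
    aggregates: 2008 supply ~141 579 and need ~144 410 (a 2% deficit, 319
    specialists per 100 000), with the demand-group mix solved so aggregate
    need reaches ~173 918 by 2025 under moderate population growth.

    Baseline policies are held constant over 2008-2025: 4 500 medical-school
    admissions per year (the numerus-clausus level of the cohorts feeding
    this horizon's residency completions; two thirds women), 7 000 residency
    positions split in proportion to need, mandatory retirement at 65, and a
    small positive net immigration.  Every per-specialty number is synthetic.
    """
    spec = FixtureSpec(seed=seed)
    horizon = (2008, 2025)
    years = range(horizon[0], horizon[1] + 1)
    population = dm.spain_population(population_label, years)
    pop_moderate = dm.spain_population("moderate", years)
    stock = generate_initial_stock(spec)
    exits, fte, immigration = generate_rate_tables(spec)
    standards = _generate_standards(
        spec,
        base_population=pop_moderate.at(2008),
        need_growth_target=need_2025_target / spec.need_target,
        population_growth=pop_moderate.at(2025) / pop_moderate.at(2008),
        horizon_years=horizon[1] - horizon[0],
    )
    need_share = np.array([s.base_ratio for s in standards])
    need_share = need_share / need_share.sum()
    d_res = np.array([5 if i % 3 == 2 else 4 for i in range(spec.n_specialties)])
    schedule = se.ParameterSchedule(
        numerus_clausus={2008: 4500.0},
        entrant_female_fraction={2008: spec.entrant_female_fraction},
        residency_positions={2008: 7000.0 * need_share},
        retirement_age={2008: 65},
        fte_ratio={2008: np.asarray(fte.ratio)},
        immigration_net={2008: immigration.net_for(2008, spec.n_specialties)},
    )
    return se.Scenario(
        name=f"spain-like-baseline-{population_label}",
        horizon=horizon,
        initial_stock=stock,
        mortality=exits.mortality,
        dropout=exits.dropout,
        schedule=schedule,
        standards=standards,
        population=population,
        d_res=d_res,
        entry_age_distribution=None,
        immigration_sex_split=immigration.sex_split,
        immigration_age_distribution=immigration.age_distribution,
        specialty_names={
            i + 1: f"synthetic_specialty_{i + 1:02d}" for i in range(spec.n_specialties)
        },
        seed=seed,
    )
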