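"""Shared fixtures and a pure-Python per-cell reference implementation.

The oracle walks every (specialty, sex, age) cell with scalar loops and
applies the documented within-year order (retire, mortality, drop-out,
early retirement, age, train-in, immigrate).  It shares no code with the
vectorized update it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from medworkforce.supply import AGE_MIN, N_AGES, SpecialtyStock


def oracle_step(
    counts,
    mortality,
    dropout,
    early,
    retirement_age,
    training,
    entry_dist,
    net,
    sex_split,
    age_dist,
):
    """Scalar reference for one annual step.

    counts: (S,2,A) nested lists or array; mortality (2,A); dropout (S,2,A);
    early (2,A) or None; training (S,2) inflow; entry_dist (A,); net (S,)
    net immigration; age_dist (A,).  Returns (new_counts, flows dict).
    """
    counts = np.asarray(counts, dtype=float)
    S, _, A = counts.shape
    new = [[[0.0] * A for _ in range(2)] for _ in range(S)]
    flows = {
        "retirements": 0.0,
        "deaths": 0.0,
        "dropouts": 0.0,
        "early_retirements": 0.0,
        "aged_out": 0.0,
        "training_in": 0.0,
        "immigration_net": 0.0,
    }
    for s in range(S):
        for x in range(2):
            for a in range(A):
                v = counts[s][x][a]
                age = AGE_MIN + a
                if age >= retirement_age:
                    flows["retirements"] += v
                    continue
                d = v * mortality[x][a]
                flows["deaths"] += d
                v -= d
                d = v * dropout[s][x][a]
                flows["dropouts"] += d
                v -= d
                if early is not None:
                    d = v * early[x][a]
                    flows["early_retirements"] += d
                    v -= d
                if a + 1 >= A:
                    flows["aged_out"] += v
                else:
                    new[s][x][a + 1] += v
    for s in range(S):
        for x in range(2):
            t = training[s][x]
            flows["training_in"] += t
            for a in range(A):
                new[s][x][a] += t * entry_dist[a]
    for s in range(S):
        for x in range(2):
            m = net[s] * (sex_split if x == 0 else 1.0 - sex_split)
            flows["immigration_net"] += m
            for a in range(A):
                new[s][x][a] += m * age_dist[a]
    return np.array(new), flows


def random_stock(rng: np.random.Generator, n_specialties: int = 3) -> SpecialtyStock:
    return SpecialtyStock(rng.uniform(0.0, 50.0, size=(n_specialties, 2, N_AGES)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20081)


@pytest.fixture
def small_stock(rng) -> SpecialtyStock:
    return random_stock(rng, 3)
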