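"""Supply submodel: stock-flow update, pipeline delays, FTE conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medworkforce.supply import (
    AGE_MAX,
    AGE_MIN,
    N_AGES,
    ExitRates,
    FteRatio,
    ImmigrationFlow,
    SpecialtyStock,
    TrainingPipeline,
    default_immigration_age_distribution,
    fte_supply,
    simulate_supply,
    step_year,
    training_inflow,
)

from conftest import oracle_step, random_stock


def zero_exits(n_spec: int, retirement_age=AGE_MAX + 2) -> ExitRates:
    return ExitRates(
        mortality=np.zeros((2, N_AGES)),
        dropout=np.zeros((n_spec, 2, N_AGES)),
        retirement_age=retirement_age,
    )


def single_person_stock(age: int, n_spec: int = 1) -> SpecialtyStock:
    counts = np.zeros((n_spec, 2, N_AGES))
    counts[0, 1, age - AGE_MIN] = 1.0
    return SpecialtyStock(counts)


class TestStepYear:
    def test_pure_aging_is_index_shift(self, small_stock):
        """Zero flows and retirement beyond the age range: the update is an
        exact one-year index shift."""
        stock = small_stock
        stock.counts[:, :, -1] = 0.0  # keep the top cell empty
        new, ledger = step_year(stock, zero_exits(3), None, None, 2009)
        assert np.array_equal(new.counts[:, :, 1:], stock.counts[:, :, :-1])
        assert np.all(new.counts[:, :, 0] == 0.0)
        assert ledger.total_inflow() == 0.0
        assert ledger.total_outflow() == 0.0

    def test_boundary_drain_at_retirement_age(self):
        """One 64-year-old with retirement at 65 leaves after two steps,
        recorded as exactly one retirement exit."""
        stock = single_person_stock(64)
        exits = zero_exits(1, retirement_age=65)
        s1, l1 = step_year(stock, exits, None, None, 2009)
        assert l1.retirements.sum() == 0.0
        assert s1.counts[0, 1, 65 - AGE_MIN] == 1.0
        s2, l2 = step_year(s1, exits, None, None, 2010)
        assert s2.total() == 0.0
        assert l2.retirements.sum() == pytest.approx(1.0)
        assert l2.total_outflow() == pytest.approx(1.0)

    def test_matches_scalar_oracle_over_five_steps(self, rng):
        """Vectorized update equals the per-cell scalar loop to 1e-9."""
        n_spec = 3
        stock = random_stock(rng, n_spec)
        mortality = rng.uniform(0.0, 0.05, (2, N_AGES))
        dropout = rng.uniform(0.0, 0.03, (n_spec, 2, N_AGES))
        early = rng.uniform(0.0, 0.02, (2, N_AGES))
        exits = ExitRates(mortality, dropout, retirement_age=65, early_retirement=early)
        entry = np.zeros(N_AGES)
        entry[0] = 1.0
        training = rng.uniform(0.0, 20.0, (n_spec, 2))
        pipeline = TrainingPipeline(
            admissions={y: float(training.sum()) for y in range(1990, 2030)},
            positions={y: training.sum(axis=1) for y in range(1990, 2030)},
            d_res=np.full(n_spec, 4),
            female_fraction=float(training[:, 0].sum() / training.sum()),
        )
        net = rng.uniform(-1.0, 5.0, n_spec)
        imm = ImmigrationFlow(
            net_entrants=net,
            sex_split=0.4,
            age_distribution=default_immigration_age_distribution(),
        )
        expected = stock.counts.copy()
        got = stock
        for year in range(2009, 2014):
            inflow = training_inflow(pipeline, year)
            expected, _ = oracle_step(
                expected, mortality, dropout, early, 65, inflow, entry,
                net, 0.4, default_immigration_age_distribution(),
            )
            got, _ = step_year(got, exits, pipeline, imm, year)
            np.testing.assert_allclose(got.counts, expected, atol=1e-9)

    def test_emigration_exceeding_stock_names_cell(self):
        stock = single_person_stock(35)
        imm = ImmigrationFlow(
            net_entrants=np.array([-100.0]),
            sex_split=1.0,
            age_distribution=np.eye(N_AGES)[35 - AGE_MIN],
        )
        with pytest.raises(ValueError, match="age=35"):
            step_year(stock, zero_exits(1), None, imm, 2009)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_exact_conservation_per_step(self, seed):
        """total(t+1) - total(t) equals recorded inflows - outflows (1e-9),
        for random stocks, rates and flows."""
        r = np.random.default_rng(seed)
        n_spec = int(r.integers(1, 5))
        stock = random_stock(r, n_spec)
        exits = ExitRates(
            mortality=r.uniform(0, 0.1, (2, N_AGES)),
            dropout=r.uniform(0, 0.05, (n_spec, 2, N_AGES)),
            retirement_age=int(r.integers(60, 67)),
            early_retirement=r.uniform(0, 0.02, (2, N_AGES)),
        )
        pipeline = TrainingPipeline(
            admissions={y: 100.0 for y in range(1995, 2012)},
            positions={y: np.full(n_spec, 40.0) for y in range(1995, 2012)},
            d_res=r.integers(4, 6, n_spec),
            exam_pass_fraction=float(r.uniform(0.5, 1.0)),
            completion_fraction=r.uniform(0.8, 1.0, n_spec),
        )
        imm = ImmigrationFlow(net_entrants=r.uniform(0, 10, n_spec), sex_split=0.5)
        new, ledger = step_year(stock, exits, pipeline, imm, 2009)
        assert abs(ledger.conservation_residual(stock, new)) < 1e-9


class TestTrainingPipeline:
    def test_single_cohort_arrives_one_decade_later(self):
        """7000 admitted in year y with d_med=6, d_res=4 and ample positions
        produce an inflow of 7000 in year y+10 and nothing else: policy
        effects lag by a decade."""
        y = 1999
        pipeline = TrainingPipeline(
            admissions={yy: (7000.0 if yy == y else 0.0) for yy in range(1990, 2020)},
            positions={yy: np.array([8000.0]) for yy in range(1990, 2020)},
            d_res=np.array([4]),
        )
        for year in range(2005, 2016):
            total = training_inflow(pipeline, year).sum()
            assert total == pytest.approx(7000.0 if year == y + 10 else 0.0)

    def test_positions_cap_intake(self):
        pipeline = TrainingPipeline(
            admissions={y: 250.0 for y in range(1990, 2020)},
            positions={y: np.array([100.0]) for y in range(1990, 2020)},
            d_res=np.array([4]),
        )
        assert training_inflow(pipeline, 2010).sum() == pytest.approx(100.0)

    def test_steady_state_inflow_product(self):
        """6000 admissions/yr, pass 0.9, completion 0.95, d_res=5 settle to
        6000*0.9*0.95 = 5130 new specialists per year."""
        pipeline = TrainingPipeline(
            admissions={y: 6000.0 for y in range(1980, 2030)},
            positions={y: np.array([10000.0]) for y in range(1980, 2030)},
            d_res=np.array([5]),
            exam_pass_fraction=0.9,
            completion_fraction=0.95,
        )
        for year in range(2000, 2020):
            assert training_inflow(pipeline, year).sum() == pytest.approx(5130.0)

    def test_sex_split_fixed_at_admission(self):
        pipeline = TrainingPipeline(
            admissions={y: 900.0 for y in range(1990, 2020)},
            positions={y: np.array([1000.0]) for y in range(1990, 2020)},
            d_res=np.array([4]),
            female_fraction=2.0 / 3.0,
        )
        inflow = training_inflow(pipeline, 2010)
        assert inflow[0, 0] == pytest.approx(600.0)
        assert inflow[0, 1] == pytest.approx(300.0)

    def test_missing_history_instructs_warmup(self):
        pipeline = TrainingPipeline(
            admissions={2005: 100.0},
            positions={y: np.array([100.0]) for y in range(2000, 2020)},
            d_res=np.array([4]),
        )
        with pytest.raises(KeyError, match="warm-up"):
            training_inflow(pipeline, 2009)

    def test_proportional_allocation_under_scarcity(self):
        """Fewer graduates than positions fill every specialty at the same
        fractional rate."""
        pipeline = TrainingPipeline(
            admissions={y: 300.0 for y in range(1990, 2020)},
            positions={y: np.array([100.0, 300.0]) for y in range(1990, 2020)},
            d_res=np.array([4, 4]),
        )
        inflow = training_inflow(pipeline, 2010).sum(axis=1)
        np.testing.assert_allclose(inflow, [75.0, 225.0])


class TestSimulateSupply:
    def test_closed_form_drain_with_zero_flows(self, rng):
        """With no inflows and retirement at 65, the 2025 total equals the
        initial cohort mass that has not yet aged past retirement."""
        stock = random_stock(rng, 2)
        exits = zero_exits(2, retirement_age=65)
        years = list(range(2008, 2026))
        traj = simulate_supply(stock, exits, None, None, years)
        # a person initially aged a survives all k steps iff a + k - 1 < 65
        k = len(years) - 1
        expected = stock.counts[:, :, : (66 - k) - AGE_MIN].sum()
        assert traj.stock_at(2025).total() == pytest.approx(expected, abs=1e-9)

    def test_old_pyramid_declines_faster(self):
        """Under identical rates an old-heavy pyramid loses supply faster
        than a young one."""
        counts = np.zeros((2, 2, N_AGES))
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        counts[0, :, :] = np.exp(-0.5 * ((ages - 58) / 5.0) ** 2)  # old-heavy
        counts[1, :, :] = np.exp(-0.5 * ((ages - 40) / 5.0) ** 2)  # young
        counts *= 1000.0 / counts.sum(axis=(1, 2), keepdims=True)
        stock = SpecialtyStock(counts)
        exits = ExitRates(
            mortality=np.full((2, N_AGES), 0.002),
            dropout=np.zeros((2, 2, N_AGES)),
            retirement_age=65,
        )
        traj = simulate_supply(stock, exits, None, None, range(2008, 2016))
        final = traj.stock_at(2015).total_by_specialty()
        assert final[0] < final[1]

    def test_full_size_run_matches_oracle(self, rng):
        """43x2x36 run over the full 18-year horizon equals the scalar
        reference end-to-end."""
        n_spec = 43
        stock = random_stock(rng, n_spec)
        mortality = rng.uniform(0, 0.02, (2, N_AGES))
        dropout = rng.uniform(0, 0.01, (n_spec, 2, N_AGES))
        exits = ExitRates(mortality, dropout, retirement_age=65)
        years = list(range(2008, 2026))
        pipeline = TrainingPipeline(
            admissions={y: 5000.0 for y in range(1990, 2026)},
            positions={y: np.full(n_spec, 7000.0 / n_spec) for y in range(1990, 2026)},
            d_res=np.array([5 if i % 3 == 0 else 4 for i in range(n_spec)]),
        )
        net = rng.uniform(0, 5, n_spec)
        age_dist = default_immigration_age_distribution()
        imm = ImmigrationFlow(net_entrants=net, sex_split=0.5, age_distribution=age_dist)
        traj = simulate_supply(stock, exits, pipeline, imm, years)
        entry = np.zeros(N_AGES)
        entry[0] = 1.0
        expected = stock.counts.copy()
        for year in years[1:]:
            inflow = training_inflow(pipeline, year)
            expected, _ = oracle_step(
                expected, mortality, dropout, None, 65, inflow, entry, net, 0.5, age_dist
            )
        np.testing.assert_allclose(traj.stock_at(2025).counts, expected, atol=1e-9)

    def test_admission_shock_respects_pipeline_delay(self):
        """Perturbing admissions in year y leaves every stock cell bitwise
        unchanged before y + d_med + min d_res."""
        n_spec = 2
        stock = SpecialtyStock(np.full((n_spec, 2, N_AGES), 10.0))
        exits = zero_exits(n_spec, retirement_age=65)
        d_res = np.array([4, 5])

        def run(extra):
            adm = {y: 1000.0 for y in range(1990, 2026)}
            adm[2010] += extra
            pipeline = TrainingPipeline(
                admissions=adm,
                positions={y: np.full(n_spec, 2000.0) for y in range(1990, 2026)},
                d_res=d_res,
            )
            return simulate_supply(stock, exits, pipeline, None, range(2008, 2026))

        base, shocked = run(0.0), run(500.0)
        first_effect = 2010 + 6 + 4
        for year in range(2008, first_effect):
            assert np.array_equal(
                base.stock_at(year).counts, shocked.stock_at(year).counts
            )
        assert shocked.stock_at(first_effect).total() > base.stock_at(first_effect).total()

    @pytest.mark.parametrize(
        "mutate",
        [
            # 63 -> 65: strict effect requires staying below the age cap,
            # since anyone reaching 66 leaves the modelled range anyway
            lambda e, p, i: setattr(e, "retirement_age", 65),
            lambda e, p, i: p.admissions.update({y: 6000.0 for y in p.admissions}),
            lambda e, p, i: setattr(
                i, "net_entrants", np.asarray(i.net_entrants) + 5.0
            ),
        ],
        ids=["retirement_age", "admissions", "immigration"],
    )
    def test_supply_monotone_in_policy_levers(self, rng, mutate):
        """Raising retirement age, admissions or immigration never lowers
        supply in any year."""
        n_spec = 3
        stock = random_stock(rng, n_spec)
        years = list(range(2008, 2026))

        def build():
            exits = ExitRates(
                mortality=np.full((2, N_AGES), 0.003),
                dropout=np.full((n_spec, 2, N_AGES), 0.002),
                retirement_age=63,
            )
            pipeline = TrainingPipeline(
                admissions={y: 3000.0 for y in range(1990, 2026)},
                positions={y: np.full(n_spec, 2000.0) for y in range(1990, 2026)},
                d_res=np.full(n_spec, 4),
            )
            imm = ImmigrationFlow(net_entrants=np.full(n_spec, 2.0), sex_split=0.5)
            return exits, pipeline, imm

        exits, pipeline, imm = build()
        base = simulate_supply(stock, exits, pipeline, imm, years).totals()
        exits, pipeline, imm = build()
        mutate(exits, pipeline, imm)
        raised = simulate_supply(stock, exits, pipeline, imm, years).totals()
        assert (raised >= base - 1e-9).all()
        assert raised.iloc[-1] > base.iloc[-1]


class TestFte:
    def test_unit_ratio_is_identity(self, small_stock):
        np.testing.assert_allclose(
            fte_supply(small_stock, FteRatio(1.0)),
            small_stock.total_by_specialty(),
        )

    def test_weighted_sum_by_sex(self):
        counts = np.zeros((1, 2, N_AGES))
        counts[0, 0, 5] = 100.0  # women
        counts[0, 1, 7] = 100.0  # men
        stock = SpecialtyStock(counts)
        ratio = np.stack([np.full(N_AGES, 0.8), np.full(N_AGES, 1.0)])
        assert fte_supply(stock, FteRatio(ratio))[0] == pytest.approx(180.0)

    def test_matches_scalar_loop(self, rng):
        stock = random_stock(rng, 4)
        ratio = rng.uniform(0.5, 1.2, (2, N_AGES))
        expected = [
            sum(
                stock.counts[s, x, a] * ratio[x, a]
                for x in range(2)
                for a in range(N_AGES)
            )
            for s in range(4)
        ]
        np.testing.assert_allclose(fte_supply(stock, FteRatio(ratio)), expected, atol=1e-9)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            FteRatio(0.0)


class TestValidation:
    def test_negative_counts_rejected_with_cell(self):
        counts = np.zeros((2, 2, N_AGES))
        counts[1, 0, 3] = -1.0
        with pytest.raises(ValueError, match="specialty=2"):
            SpecialtyStock(counts)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="mortality"):
            ExitRates(
                mortality=np.full((2, N_AGES), 1.5),
                dropout=np.zeros((1, 2, N_AGES)),
            )

    def test_stock_frame_round_trip(self, small_stock):
        again = SpecialtyStock.from_frame(small_stock.to_frame())
        np.testing.assert_allclose(again.counts, small_stock.counts)
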