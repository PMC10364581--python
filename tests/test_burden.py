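import numpy as np
import pandas as pd
import pytest

from diabem import DrawSet, LifeTable, make_grid
from diabem.burden import (
    Sequela,
    StandardPopulation,
    age_standardise,
    build_standard_population,
    compute_daly,
    compute_yld,
    compute_yll,
    comorbidity_share,
    rate_per_100k,
    representative_age,
)


def _life_table():
    ages = np.arange(0.0, 111.0)
    return LifeTable(ages=ages, ex=np.maximum(80.0 - ages, 2.0))


def _index(age_groups, location="A"):
    rows = [(location, a0, a1, "female", 2021) for a0, a1 in age_groups]
    return pd.DataFrame(rows, columns=["location", "age_start", "age_end", "sex", "year"])


class TestComputeYll:
    def test_one_death_yields_remaining_life_expectancy(self):
        lt = _life_table()
        idx = _index([(47.5, 52.5)])  # representative age 50 -> 30 years left
        deaths = DrawSet.constant(idx, np.array([1.0]), 3)
        yll = compute_yll(deaths, lt)
        assert np.allclose(yll.draws, 30.0)

    def test_hand_arithmetic_total(self):
        lt = _life_table()
        idx = _index([(37.5, 42.5), (57.5, 62.5)])  # LE 40 and 20
        deaths = DrawSet.constant(idx, np.array([10.0, 5.0]), 2)
        yll = compute_yll(deaths, lt)
        assert np.allclose(yll.total(), 500.0)

    def test_zero_deaths_zero_ylls(self):
        idx = _index([(0.0, 5.0)])
        yll = compute_yll(DrawSet.constant(idx, np.array([0.0]), 2), _life_table())
        assert np.all(yll.draws == 0.0)

    def test_age_outside_life_table_is_an_error(self):
        lt = LifeTable(ages=np.arange(0.0, 50.0), ex=np.linspace(60, 10, 50))
        idx = _index([(80.0, 85.0)])
        with pytest.raises(ValueError, match="life table"):
            compute_yll(DrawSet.constant(idx, np.array([1.0]), 2), lt)

    def test_open_ended_top_group_uses_start_plus_2_5(self):
        assert representative_age(np.array([95.0]), np.array([np.inf]))[0] == 97.5


class TestComputeYld:
    def test_single_sequela_product(self):
        idx = _index([(40.0, 45.0)])
        prev = DrawSet.constant(idx, np.array([0.1]), 4)
        pop = idx.copy()
        pop["value"] = 1000.0
        seq = [Sequela("neuropathy", 0.2, 1.0)]
        yld = compute_yld(prev, seq, pop, background_ylds_per_capita=0.0)
        assert np.allclose(yld.draws, 20.0)

    def test_multiplicative_comorbidity_formula(self):
        # two independent states with weights 0.2 and 0.3 combine to
        # 1 - 0.8*0.7 = 0.44; the first keeps 0.44 * 0.2/0.5 = 0.176
        assert comorbidity_share(0.2, 0.3) == pytest.approx(0.176)

    def test_no_background_comorbidity_is_identity(self):
        assert comorbidity_share(0.2, 0.0) == 0.2

    def test_correction_never_increases_ylds(self):
        idx = _index([(40.0, 45.0)])
        prev = DrawSet.constant(idx, np.array([0.1]), 2)
        pop = idx.copy()
        pop["value"] = 1000.0
        seq = [Sequela("neuropathy", 0.2, 0.5)]
        raw = compute_yld(prev, seq, pop, background_ylds_per_capita=0.0)
        corrected = compute_yld(prev, seq, pop, background_ylds_per_capita=0.15)
        assert np.all(corrected.draws < raw.draws)

    def test_invalid_disability_weight_rejected(self):
        with pytest.raises(ValueError, match="disability weight"):
            Sequela("neuropathy", 1.2, 0.5)


class TestComputeDaly:
    def test_sum_of_yll_and_yld(self):
        idx = _index([(40.0, 45.0)])
        yll = DrawSet.constant(idx, np.array([437.4]), 3)
        yld = DrawSet.constant(idx, np.array([477.6]), 3)
        daly = compute_daly(yll, yld)
        assert np.allclose(daly.draws, 915.0)

    def test_zero_yld_reduces_to_yll(self):
        idx = _index([(40.0, 45.0)])
        yll = DrawSet.constant(idx, np.array([123.0]), 2)
        yld = DrawSet.constant(idx, np.array([0.0]), 2)
        assert np.allclose(compute_daly(yll, yld).draws, yll.draws)

    def test_additivity_survives_aggregation(self):
        rng = np.random.default_rng(1)
        idx = make_grid(["A", "B"], np.arange(0.0, 101.0, 20.0))
        yll = DrawSet(idx, rng.uniform(0, 100, (len(idx), 10)))
        yld = DrawSet(idx, rng.uniform(0, 100, (len(idx), 10)))
        daly = compute_daly(yll, yld)
        over = ["age_start", "age_end", "sex", "year"]
        lhs = daly.aggregate(over=over).draws
        rhs = yll.aggregate(over=over).draws + yld.aggregate(over=over).draws
        assert np.allclose(lhs, rhs, rtol=1e-9)


class TestStandardPopulation:
    def _pop(self, spec):
        rows = [(loc, a, v) for loc, dist in spec.items() for a, v in dist.items()]
        return pd.DataFrame(rows, columns=["location", "age_start", "value"])

    def test_single_qualifying_location_is_its_own_standard(self):
        pop = self._pop({"A": {0.0: 6e6, 50.0: 2e6}})
        std = build_standard_population(pop)
        assert np.allclose(std.weights, [0.75, 0.25])

    def test_hand_mean_of_two_distributions(self):
        pop = self._pop({
            "A": {0.0: 6e6, 50.0: 4e6},    # distribution (0.6, 0.4)
            "B": {0.0: 2e6, 50.0: 8e6},    # distribution (0.2, 0.8)
        })
        std = build_standard_population(pop)
        assert np.allclose(std.weights, [0.4, 0.6])

    def test_threshold_is_strict(self):
        pop = self._pop({
            "A": {0.0: 6e6, 50.0: 4e6},
            "small": {0.0: 4_999_999.0},
        })
        std = build_standard_population(pop)
        assert np.allclose(std.weights, [0.6, 0.4])  # 'small' excluded

    def test_no_qualifying_location_is_an_error(self):
        pop = self._pop({"A": {0.0: 1e6}})
        with pytest.raises(ValueError, match="threshold"):
            build_standard_population(pop)

    def test_weights_sum_to_one(self, small_world):
        pop = small_world.population
        pop19 = pop[pop["year"] == 2019]
        std = build_standard_population(
            pop19.groupby(["location", "age_start"], as_index=False)["value"].sum()
        )
        assert std.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestAgeStandardise:
    def _rates(self, values, ages=(0.0, 50.0)):
        idx = pd.DataFrame({
            "age_start": ages, "age_end": [a + 50 for a in ages],
        })
        return DrawSet.constant(idx, np.asarray(values, dtype=float), 3)

    def test_uniform_rates_pass_through(self):
        std = StandardPopulation(np.array([0.0, 50.0]), np.array([0.3, 0.7]))
        out = age_standardise(self._rates([200.0, 200.0]), std)
        assert np.allclose(out.draws, 200.0)

    def test_hand_weighted_mean(self):
        std = StandardPopulation(np.array([0.0, 50.0]), np.array([0.5, 0.5]))
        out = age_standardise(self._rates([100.0, 300.0]), std)
        assert np.allclose(out.draws, 200.0)

    def test_order_invariance(self):
        std = StandardPopulation(np.array([0.0, 50.0]), np.array([0.25, 0.75]))
        a = age_standardise(self._rates([100.0, 300.0], ages=(0.0, 50.0)), std)
        b = age_standardise(self._rates([300.0, 100.0], ages=(50.0, 0.0)), std)
        assert np.allclose(a.draws, b.draws)

    def test_result_bounded_by_age_specific_rates(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            w = rng.dirichlet(np.ones(5))
            rates = rng.uniform(10, 1000, 5)
            std = StandardPopulation(np.arange(5) * 10.0, w)
            out = age_standardise(self._rates(rates, ages=np.arange(5) * 10.0), std)
            assert rates.min() - 1e-9 <= out.draws[0, 0] <= rates.max() + 1e-9

    def test_coverage_gap_is_an_error(self):
        std = StandardPopulation(np.array([0.0, 50.0, 80.0]), np.array([0.3, 0.3, 0.4]))
        with pytest.raises(ValueError, match="missing"):
            age_standardise(self._rates([1.0, 2.0]), std)


class TestRatePer100k:
    def _counts(self, values, n_draws=2):
        idx = _index([(40.0, 45.0)] * len(values))
        idx["age_start"] = idx["age_start"] + np.arange(len(values)) * 5
        return DrawSet.constant(idx, np.asarray(values, dtype=float), n_draws)

    def test_basic_rate(self):
        counts = self._counts([50.0])
        pop = counts.index.copy()
        pop["value"] = 1_000_000.0
        out = rate_per_100k(counts, pop)
        assert np.allclose(out.draws, 5.0)

    def test_zero_events(self):
        counts = self._counts([0.0])
        pop = counts.index.copy()
        pop["value"] = 1000.0
        assert np.all(rate_per_100k(counts, pop).draws == 0.0)

    def test_doubling_population_halves_rate(self):
        counts = self._counts([42.0])
        pop = counts.index.copy()
        pop["value"] = 10_000.0
        pop2 = pop.copy()
        pop2["value"] = 20_000.0
        assert np.allclose(rate_per_100k(counts, pop).draws,
                           2 * rate_per_100k(counts, pop2).draws)

    def test_zero_population_with_events_is_an_error(self):
        counts = self._counts([5.0])
        pop = counts.index.copy()
        pop["value"] = 0.0
        with pytest.raises(ValueError, match="population"):
            rate_per_100k(counts, pop)
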