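"""Neutral colonization simulator, schedules and the closed-form oracle."""

import numpy as np
import pytest

from alien_accrual import colonization_sim as cs
from alien_accrual import studies


class TestMainland:
    def test_zero_sdlog_gives_equal_abundances(self):
        com = cs.build_mainland(20, 2.0, 0.0, 0)
        assert len(set(com.abundances.tolist())) == 1

    def test_log_abundance_mean_matches_meanlog(self):
        meanlog, sdlog, m = 5.0, 0.5, 10_000
        com = cs.build_mainland(m, meanlog, sdlog, 1)
        logs = np.log(com.abundances)
        se = logs.std(ddof=1) / np.sqrt(m)
        # ceiling of the draws biases the mean up slightly; stay within
        # 3 SE plus that small bias allowance
        assert abs(logs.mean() - meanlog) < 3 * se + 0.01

    def test_community_sizes_span_full_range(self):
        for m in (100, 100_000):
            com = cs.build_mainland(m, 2.0, 1.0, 0)
            assert com.m_species == m
            assert com.total_propagules >= m


class TestSchedule:
    def test_constant_budget(self):
        sch = cs.make_schedule("constant", 1000, 100)
        np.testing.assert_allclose(sch.p, 0.1)

    def test_exponential_ratio_constant_before_clipping(self):
        sch = cs.make_schedule("exponential", 500, 10, growth_rate=0.01)
        ratios = sch.p[1:] / sch.p[:-1]
        np.testing.assert_allclose(ratios, np.exp(0.01), rtol=1e-9)

    def test_clipping_preserves_budget(self):
        sch = cs.make_schedule("exponential", 100, 95, growth_rate=0.2)
        assert np.all(sch.p <= 1.0 + 1e-12)
        assert sch.p.sum() == pytest.approx(95, abs=1e-9)

    def test_budget_above_steps_rejected(self):
        with pytest.raises(ValueError):
            cs.make_schedule("constant", 10, 11)

    def test_proportional_follows_driver(self):
        driver = np.array([1.0, 2.0, 4.0, 8.0])
        sch = cs.make_schedule("proportional", 4, 1.0, driver=driver)
        np.testing.assert_allclose(sch.p / sch.p[0], driver)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            cs.make_schedule("quadratic", 10, 1)

    def test_equal_budgets_give_equal_expected_arrivals(self):
        # standardization rule: different shapes, same expected total
        budget, n = 100, 1000
        shapes = [
            cs.make_schedule("constant", n, budget),
            cs.make_schedule("exponential", n, budget),
        ]
        rng = np.random.default_rng(0)
        for sch in shapes:
            assert sch.p.sum() == pytest.approx(budget, abs=1e-9)
            arrivals = [
                int((rng.random(n) < sch.p).sum()) for _ in range(100)
            ]
            assert abs(np.mean(arrivals) - budget) < 3 * np.sqrt(budget)


class TestSimulate:
    def test_zero_pressure_zero_richness(self):
        com = cs.build_mainland(10, 2.0, 1.0, 0)
        sch = cs.Schedule(np.zeros(50), "constant", 0.0)
        res = cs.simulate(com, sch, cs.SimConfig(seed=1, n_replicates=3))
        assert np.all(res.richness == 0)

    def test_certain_arrival_single_species(self):
        com = cs.MainlandCommunity(np.array([7]))
        sch = cs.make_schedule("constant", 10, 10)  # P = 1 each step
        res = cs.simulate(com, sch, cs.SimConfig(seed=1, n_replicates=2))
        assert np.all(res.richness == 1)
        assert all(est == {0: 0} for est in res.establishment_steps)

    def test_richness_nondecreasing_and_bounded(self):
        com = cs.build_mainland(30, 2.0, 1.0, 2)
        sch = cs.make_schedule("linear", 500, 100)
        res = cs.simulate(com, sch, cs.SimConfig(seed=3, n_replicates=5))
        assert np.all(np.diff(res.richness, axis=1) >= 0)
        assert res.richness.max() <= 30

    def test_mean_richness_matches_closed_form(self):
        out = studies.simulator_oracle_study(seed=11, n_replicates=200)
        assert out["max_abs_z"] < 3.0

    def test_allee_zero_is_bitwise_basic_model(self):
        com = cs.build_mainland(30, 2.0, 1.0, 2)
        sch = cs.make_schedule("constant", 300, 60)
        res_a = cs.simulate(
            com, sch, cs.SimConfig(seed=5, n_replicates=4, allee_threshold=0, window=1)
        )
        res_b = cs.simulate(
            com, sch, cs.SimConfig(seed=5, n_replicates=4, allee_threshold=0, window=1000)
        )
        assert np.array_equal(res_a.richness, res_b.richness)
        assert res_a.establishment_steps == res_b.establishment_steps

    def test_allee_delays_at_every_step(self):
        out = studies.allee_monotonicity_study(seed=7, n_replicates=10, n_steps=2000)
        assert out["monotone_fraction"] == 1.0

    def test_increasing_threshold_delays_each_species(self):
        # under the same seed the arrival stream is identical, so raising
        # the threshold can only postpone (or prevent) every establishment
        com = cs.build_mainland(20, 3.0, 1.5, 4)
        sch = cs.make_schedule("constant", 3000, 1500)
        runs = [
            cs.simulate(
                com,
                sch,
                cs.SimConfig(seed=9, n_replicates=10, allee_threshold=a, window=500),
            )
            for a in (0, 5, 10)
        ]
        for lo, hi in zip(runs, runs[1:]):
            for est_lo, est_hi in zip(lo.establishment_steps, hi.establishment_steps):
                assert set(est_hi) <= set(est_lo)
                for sp, t in est_hi.items():
                    assert t >= est_lo[sp]

    def test_allee_window_counts_need_threshold_exceeded(self):
        # arrivals at steps 0..a-1: exactly a arrivals never exceed a
        steps = np.arange(5)
        species = np.zeros(5, dtype=int)
        est = cs._establishments(steps, species, allee_threshold=5, window=100)
        assert est == {}
        est = cs._establishments(steps, species, allee_threshold=4, window=100)
        assert est == {0: 4}
        # same arrivals, but too slow for the window
        est = cs._establishments(steps * 50, species, allee_threshold=4, window=100)
        assert est == {}

    def test_first_record_rate_bins_establishments(self):
        com = cs.MainlandCommunity(np.array([1, 1]))
        sch = cs.make_schedule("constant", 4, 4)
        res = cs.simulate(com, sch, cs.SimConfig(seed=2, n_replicates=1))
        series = res.first_record_rate(2)
        assert series.counts.sum() == res.richness[0, -1]


class TestOracle:
    def test_single_species_geometric(self):
        com = cs.MainlandCommunity(np.array([5]))
        p = 0.2
        sch = cs.make_schedule("constant", 20, p * 20)
        oracle = cs.expected_richness_oracle(com, sch)
        t = np.arange(1, 21)
        np.testing.assert_allclose(oracle, 1 - (1 - p) ** t, rtol=1e-12)

    def test_saturates_to_species_pool(self):
        com = cs.build_mainland(8, 1.0, 0.5, 0)
        sch = cs.make_schedule("constant", 5000, 2500)
        oracle = cs.expected_richness_oracle(com, sch)
        assert oracle[-1] == pytest.approx(8.0, abs=1e-6)

    def test_matches_exhaustive_enumeration(self):
        assert studies.enumeration_check() < 1e-12

    def test_rejects_allee_threshold(self):
        com = cs.MainlandCommunity(np.array([1]))
        sch = cs.make_schedule("constant", 5, 1)
        with pytest.raises(ValueError):
            cs.expected_richness_oracle(com, sch, allee_threshold=3)
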