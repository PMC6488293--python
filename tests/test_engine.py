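"""Engine operations against closed-form and distributional oracles."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, norm

from mmcds.engine import (
    CellPool,
    ExtinctionError,
    SimulationConfig,
    apply_mutations,
    attempt_divisions,
    cell_fitness,
    compete,
    replicate_seeds,
    run_replicates,
    run_simulation,
    step,
)
from mmcds.experiments import apply_overrides, standard_mmc_config
from mmcds.schedules import DivisionSchedule, GrowthSchedule, SelectionSchedule


def flat_config(pool=10_000, interval=20.0, s=0.0, mr=0.0, lifespan=100):
    """Age-independent config: constant capacity, interval and selection."""
    return SimulationConfig(
        lifespan=lifespan,
        growth=GrowthSchedule(initial_pool_size=pool, adult_pool_size=pool,
                              proportional_start=False),
        division=DivisionSchedule(profile="stable", stable_interval=interval),
        selection=SelectionSchedule(model="MMC", fixed_advantage=s),
        mutation_rate=mr,
    )


class TestCellFitness:
    def test_zero_drivers_is_neutral(self):
        assert cell_fitness(0, 0.3) == 1.0

    def test_matches_repeated_multiplication(self):
        # oracle: explicit repeated multiplication of (1 + s)
        expected = 1.0
        for _ in range(4):
            expected *= 1.01
        assert cell_fitness(4, 0.01) == pytest.approx(expected, rel=1e-15)
        assert cell_fitness(4, 0.01) == pytest.approx(1.04060401, rel=1e-12)

    def test_single_driver(self):
        assert cell_fitness(1, 0.01) == pytest.approx(1.01)

    def test_negative_selection(self):
        assert cell_fitness(2, -0.005) == pytest.approx(0.995 * 0.995, rel=1e-15)

    def test_vectorized_over_driver_counts(self):
        f = cell_fitness(np.array([0, 1, 2]), 0.01)
        np.testing.assert_allclose(f, [1.0, 1.01, 1.0201])

    def test_lethal_coefficient_rejected(self):
        with pytest.raises(ValueError):
            cell_fitness(1, -1.0)


class TestAttemptDivisions:
    """Normal-CDF oracles: P(divide) = Phi((timer - mean)/(mean/8))."""

    N = 10_000

    def _pool(self, timer):
        return CellPool(drivers=np.zeros(self.N, dtype=np.int64),
                        timers=np.full(self.N, float(timer)))

    def test_fresh_cells_never_divide(self):
        # timer 0 at interval 20: P = Phi(-8) ~ 6e-16 per cell
        cfg = flat_config(interval=20.0)
        rng = np.random.default_rng(0)
        new_pool, n_new = attempt_divisions(self._pool(0.0), 50, cfg, rng)
        assert n_new == 0
        assert new_pool.size == self.N
        np.testing.assert_array_equal(new_pool.timers, 1.0)

    def test_overdue_cells_always_divide(self):
        # timer = 2 x interval: P = Phi(8) ~ 1 per cell
        cfg = flat_config(interval=20.0)
        rng = np.random.default_rng(0)
        new_pool, n_new = attempt_divisions(self._pool(40.0), 50, cfg, rng)
        assert n_new == 2 * self.N
        assert new_pool.size == 2 * self.N
        np.testing.assert_array_equal(new_pool.timers, 0.0)

    def test_cells_at_mean_divide_half_the_time(self):
        cfg = flat_config(interval=20.0)
        rng = np.random.default_rng(1)
        _, n_new = attempt_divisions(self._pool(20.0), 50, cfg, rng)
        n_div = n_new // 2
        sigma = np.sqrt(self.N * 0.25)
        assert abs(n_div - self.N / 2) < 3 * sigma

    def test_intermediate_timer_matches_cdf(self):
        cfg = flat_config(interval=20.0)
        rng = np.random.default_rng(2)
        timer = 22.0
        p = norm.cdf((timer - 20.0) / 2.5)
        _, n_new = attempt_divisions(self._pool(timer), 50, cfg, rng)
        n_div = n_new / 2
        sigma = np.sqrt(self.N * p * (1 - p))
        assert abs(n_div - self.N * p) < 4 * sigma

    def test_daughters_inherit_driver_count(self):
        cfg = flat_config(interval=20.0)
        pool = CellPool(drivers=np.array([3] * 10, dtype=np.int64),
                        timers=np.full(10, 40.0))
        new_pool, n_new = attempt_divisions(pool, 50, cfg, np.random.default_rng(0))
        assert n_new == 20
        np.testing.assert_array_equal(new_pool.drivers, 3)


class TestApplyMutations:
    def test_rate_zero_changes_nothing(self):
        d = np.arange(100, dtype=np.int64)
        out = apply_mutations(d, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, d)

    def test_rate_one_adds_exactly_one_driver_each(self):
        d = np.zeros(1000, dtype=np.int64)
        out = apply_mutations(d, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, 1)

    def test_mutant_count_matches_binomial(self):
        n, rate = 100_000, 1e-3
        out = apply_mutations(np.zeros(n, dtype=np.int64), rate,
                              np.random.default_rng(3))
        mutants = int(out.sum())
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(mutants - n * rate) < 3 * sigma

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_mutations(np.zeros(3, dtype=np.int64), 1.5,
                            np.random.default_rng(0))


class TestCompete:
    def test_at_capacity_equal_fitness_pool_unchanged(self):
        cfg = flat_config(pool=5000)
        pool = CellPool(drivers=np.zeros(5000, dtype=np.int64),
                        timers=np.zeros(5000))
        out = compete(pool, 50, cfg, np.random.default_rng(0))
        assert out.size == 5000

    def test_double_capacity_halves_pool(self):
        K = 5000
        cfg = flat_config(pool=K)
        pool = CellPool(drivers=np.zeros(2 * K, dtype=np.int64),
                        timers=np.zeros(2 * K))
        out = compete(pool, 50, cfg, np.random.default_rng(1))
        sigma = np.sqrt(2 * K * 0.25)
        assert abs(out.size - K) < 3 * sigma

    def test_high_fitness_cell_survives_certainly(self):
        # fitness (1.01)^92 ~ 2.5; with N = 2K and pool mean ~1 the survival
        # probability min(1, 0.5 * 2.5) caps at 1
        K = 500
        cfg = flat_config(pool=K, s=0.01)
        drivers = np.zeros(2 * K, dtype=np.int64)
        drivers[0] = 92
        for trial in range(200):
            pool = CellPool(drivers=drivers.copy(), timers=np.zeros(2 * K))
            out = compete(pool, 50, cfg, np.random.default_rng(trial))
            assert 92 in out.drivers

    def test_empty_pool_signals_extinction(self):
        cfg = flat_config(pool=100)
        empty = CellPool(drivers=np.zeros(0, dtype=np.int64), timers=np.zeros(0))
        with pytest.raises(ExtinctionError):
            compete(empty, 10, cfg, np.random.default_rng(0))

    def test_neutral_selection_is_fitness_blind(self):
        # s = 0: mutants and non-mutants must survive at the same rate
        # (>= 1e5 cell-trials in total)
        K = 5000
        cfg = flat_config(pool=K, s=0.0)
        rng = np.random.default_rng(7)
        surv_mut = surv_wt = tot_mut = tot_wt = 0
        for _ in range(15):
            drivers = np.zeros(2 * K, dtype=np.int64)
            drivers[:K] = 1  # half mutants
            pool = CellPool(drivers=drivers, timers=np.zeros(2 * K))
            out = compete(pool, 50, cfg, rng)
            surv_mut += int((out.drivers == 1).sum())
            surv_wt += int((out.drivers == 0).sum())
            tot_mut += K
            tot_wt += K
        assert tot_mut + tot_wt >= 100_000
        p_mut, p_wt = surv_mut / tot_mut, surv_wt / tot_wt
        se = np.sqrt(0.5 * 0.5 * (1 / tot_mut + 1 / tot_wt))
        assert abs(p_mut - p_wt) < 4 * se


class TestStepAndRun:
    def test_step_composes_and_preserves_invariants(self):
        cfg = flat_config(pool=2000, interval=5.0, s=0.01, mr=0.05)
        rng = np.random.default_rng(0)
        pool = CellPool.initial(cfg, rng)
        for week in range(30):
            pool = step(pool, week, cfg, rng)
        assert pool.size > 0
        assert pool.drivers.min() >= 0

    def test_no_mutation_no_selection_stays_driver_free(self):
        cfg = flat_config(pool=1000, interval=10.0, s=0.0, mr=0.0, lifespan=300)
        ts = run_simulation(cfg, seed=5)
        assert int(ts.counts.sum()) == 0
        assert len(ts) == 300

    def test_default_run_has_full_lifespan(self):
        ts = run_simulation(SimulationConfig(), seed=11)
        assert len(ts) == 5200
        assert not ts.extinct

    def test_seeded_runs_bit_identical(self, tiny_config):
        a = run_simulation(tiny_config, seed=42)
        b = run_simulation(tiny_config, seed=42)
        np.testing.assert_array_equal(a.pool_size, b.pool_size)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_clone_class_nesting(self, tiny_config):
        cfg = tiny_config.with_overrides(mutation_rate=2e-2)
        ts = run_simulation(cfg, seed=3)
        c = ts.counts
        assert np.all(c[:, 0] >= c[:, 1])
        assert np.all(c[:, 1] >= c[:, 2])
        assert np.all(c[:, 2] >= c[:, 3])
        assert np.all(c[:, 0] <= ts.pool_size)
        assert c[:, 0].max() > 0  # mutations actually happened

    def test_numpy_backend_agrees_with_kernel(self, tiny_config):
        """Statistical equivalence of the fused kernel and the composed ops."""
        n = 40
        seeds = replicate_seeds(99, n)
        final_k = [run_simulation(tiny_config, int(s), backend="kernel").count_ge(1)[-1]
                   for s in seeds]
        final_p = [run_simulation(tiny_config, int(s), backend="numpy").count_ge(1)[-1]
                   for s in seeds]
        # same distribution of end-of-run mutant burden
        res = mannwhitneyu(final_k, final_p)
        assert res.pvalue > 1e-3
        # same mean pool size trajectory
        pool_k = np.mean([run_simulation(tiny_config, int(s)).pool_size[-50:].mean()
                          for s in seeds[:10]])
        pool_p = np.mean([run_simulation(tiny_config, int(s), backend="numpy")
                          .pool_size[-50:].mean() for s in seeds[:10]])
        assert abs(pool_k - pool_p) / pool_k < 0.02


class TestReplicates:
    def test_single_run_mean_equals_run(self, tiny_config):
        rs = run_replicates(tiny_config, n=1, base_seed=8)
        np.testing.assert_allclose(rs.mean_frame()["ge1"],
                                   rs.runs[0].count_ge(1))

    def test_seeds_distinct_and_deterministic(self):
        s1 = replicate_seeds(123, 50)
        s2 = replicate_seeds(123, 50)
        np.testing.assert_array_equal(s1, s2)
        assert len(np.unique(s1)) == 50
        assert np.all(s1 >= 0) and np.all(s1 < 2 ** 31)

    def test_same_base_seed_reproduces_mean(self, tiny_config):
        a = run_replicates(tiny_config, n=4, base_seed=21)
        b = run_replicates(tiny_config, n=4, base_seed=21)
        np.testing.assert_array_equal(a.mean_frame().to_numpy(),
                                      b.mean_frame().to_numpy())

    def test_results_independent_of_worker_count(self, tiny_config):
        seq = run_replicates(tiny_config, n=4, base_seed=33, n_jobs=1)
        par = run_replicates(tiny_config, n=4, base_seed=33, n_jobs=2)
        for a, b in zip(seq.runs, par.runs):
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_mean_series_bounded_by_run_envelope(self, tiny_config):
        rs = run_replicates(tiny_config, n=5, base_seed=4)
        mat = rs.count_matrix(1)
        mean = rs.mean_frame()["ge1"].to_numpy()
        assert np.all(mean >= mat.min(axis=0) - 1e-9)
        assert np.all(mean <= mat.max(axis=0) + 1e-9)


class TestCapacityTracking:
    def test_neutral_pool_tracks_capacity(self):
        """Mean pool size stays on the capacity curve after the growth phase."""
        cfg = apply_overrides(
            standard_mmc_config(),
            {"lifespan": 1200, "growth.adult_pool_size": 1000,
             "mutation_rate": 0.0, "selection.fixed_advantage": 0.0})
        rs = run_replicates(cfg, n=40, base_seed=17)
        cap = cfg.growth.capacity(np.arange(1200, dtype=float))
        pools = rs.pool_matrix().astype(float)
        mature = np.arange(1200) >= cfg.growth.maturity_age
        mean = pools.mean(axis=0)[mature]
        se = pools.std(axis=0, ddof=1)[mature] / np.sqrt(rs.n)
        z = (mean - cap[mature]) / np.maximum(se, 1e-9)
        # pointwise 3-SE band with an allowance for the ~200 correlated weeks
        assert np.mean(np.abs(z) <= 3.0) >= 0.95
        assert np.abs(z).max() < 6.0
        # no systematic bias beyond half a percent of capacity
        assert abs(mean.mean() - cap[mature].mean()) / cap[mature].mean() < 0.005
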