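"""Shared fixtures: small fast configs plus the session-scoped sweep bundles.

The sweep fixtures reproduce the published experimental conditions (50
replicates per level at the standard pool and lifespan) and are shared
across the acceptance tests so each expensive condition is simulated once.
The common standard-MMC condition is reused wherever a sweep contains it,
with one fixed base seed so matched-seed comparisons are meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mmcds.engine import SimulationConfig, run_replicates, run_simulation, replicate_seeds
from mmcds.experiments import apply_overrides, standard_mmc_config, standard_mmcds_config
from mmcds.schedules import WEEKS_PER_YEAR

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: One base seed for every sweep fixture: levels share per-replicate seeds,
#: which is what makes between-condition comparisons matched-seed.
BASE_SEED = 1234

SWEEP_REPLICATES = 50
POOL_REPLICATES = 8
FIG5_RUNS = 1000

NEVER = 10 ** 9  # sentinel for "never took over" when taking medians


def kruskal_oracle(samples) -> tuple[float, float]:
    """Brute-force Kruskal-Wallis H and chi-square p, from first principles.

    Ranks are computed by explicit sorting with average ranks for ties, the
    H statistic from group rank sums, and the standard tie correction
    1 - sum(t^3 - t)/(N^3 - N).  Independent of scipy.stats.kruskal.
    """
    from scipy.stats import chi2

    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    N = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    i = 0
    sorted_vals = pooled[order]
    while i < N:
        j = i
        while j + 1 < N and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average rank, 1-based
        i = j + 1

    h = 0.0
    start = 0
    for s in samples:
        n_i = len(s)
        r_i = ranks[start:start + n_i].sum()
        h += r_i ** 2 / n_i
        start += n_i
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)

    tie = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    for t in counts:
        tie += t ** 3 - t
    correction = 1.0 - tie / (N ** 3 - N)
    if correction == 0.0:
        return 0.0, 1.0
    h /= correction
    return h, float(chi2.sf(h, df=len(samples) - 1))


def takeover_median(runs, clone_class=1, fraction=0.5) -> float:
    """Median first-takeover week over runs, never-events counted as late."""
    from mmcds.stats import takeover_week

    weeks = [takeover_week(r, clone_class, fraction) for r in runs]
    return float(np.median([NEVER if np.isnan(w) else w for w in weeks]))


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A seconds-scale config for functional tests: small pool, short life."""
    cfg = standard_mmc_config()
    return apply_overrides(cfg, {
        "lifespan": 400,
        "growth.adult_pool_size": 800,
        "mutation_rate": 5e-3,
    })


@pytest.fixture(scope="session")
def standard_mmc_50():
    """50 replicates of the standard fixed-selection condition."""
    return run_replicates(standard_mmc_config(), n=SWEEP_REPLICATES,
                          base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def stable_mmc_50():
    cfg = apply_overrides(standard_mmc_config(), {"division.profile": "stable"})
    return run_replicates(cfg, n=SWEEP_REPLICATES, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def mr_sweep(standard_mmc_50):
    """Mutation-rate sweep 1e-2..1e-5 (MMC baseline), 50 replicates per level."""
    out = {}
    for mr in (1e-2, 1e-3, 1e-4, 1e-5):
        if mr == 1e-3:
            out[mr] = standard_mmc_50
        else:
            cfg = standard_mmc_config().with_overrides(mutation_rate=mr)
            out[mr] = run_replicates(cfg, n=SWEEP_REPLICATES, base_seed=BASE_SEED)
    return out


@pytest.fixture(scope="session")
def fa_sweep(standard_mmc_50):
    """Fitness-advantage sweep +0.1%..+1% (MMC), 50 replicates per level."""
    out = {}
    for fa in (0.001, 0.0025, 0.005, 0.01):
        if fa == 0.005:
            out[fa] = standard_mmc_50
        else:
            cfg = apply_overrides(standard_mmc_config(),
                                  {"selection.fixed_advantage": fa})
            out[fa] = run_replicates(cfg, n=SWEEP_REPLICATES, base_seed=BASE_SEED)
    return out


@pytest.fixture(scope="session")
def switch_sweep():
    """MMC-DS selection sign-switch age sweep: 10/30/50/70 years."""
    out = {}
    for years in (10, 30, 50, 70):
        cfg = apply_overrides(standard_mmcds_config(),
                              {"selection.switch_age": float(years * WEEKS_PER_YEAR)})
        out[years] = run_replicates(cfg, n=SWEEP_REPLICATES, base_seed=BASE_SEED)
    return out


@pytest.fixture(scope="session")
def pool_sweep():
    """Adult pool sweep 10k..100k under both models, fixed 300-cell start."""
    out = {}
    for model_name, base in (("MMC", standard_mmc_config()),
                             ("MMC_DS", standard_mmcds_config())):
        for ap in (10_000, 25_000, 50_000, 100_000):
            cfg = apply_overrides(base, {"growth.adult_pool_size": ap,
                                         "growth.proportional_start": False})
            out[(model_name, ap)] = run_replicates(cfg, n=POOL_REPLICATES,
                                                   base_seed=BASE_SEED)
    return out


@pytest.fixture(scope="session")
def fig5_runs():
    """Large samples of individual runs for the early-life transient.

    Scaled study: adult pool 2,500 cells (drift-dominated early phase is the
    object of interest and depends on the small early pool), horizon 1,560
    weeks (the transient statistic only involves ages 0-30).
    """
    overrides = {"growth.adult_pool_size": 2_500, "lifespan": 1_560}
    out = {}
    for name, base in (("MMC", standard_mmc_config()),
                       ("MMC_DS", standard_mmcds_config())):
        cfg = apply_overrides(base, overrides)
        seeds = replicate_seeds(BASE_SEED, FIG5_RUNS)
        out[name] = [run_simulation(cfg, int(s)) for s in seeds]
    return out
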