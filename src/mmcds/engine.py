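"""Weekly Monte Carlo update loop over an explicit stem-cell population.

One simulated week, per cell:

1. *Division*: the cell's time since its last division is compared against a
   threshold drawn fresh from Normal(mean = current division interval,
   sd = mean/8); if the timer has reached the threshold the cell is replaced
   by two daughters with timers reset to 0, otherwise its timer advances by
   one week.
2. *Mutation*: each new daughter independently acquires one driver mutation
   with probability ``mutation_rate`` (at most one driver per daughter per
   division).
3. *Competition*: every cell survives a binomial trial with probability
   min(1, (K/N) · f_i / f̄), where K is the pool capacity at the current age,
   N the post-division cell count, f_i = (1+s)^drivers the cell's somatic
   fitness at the current age's selection coefficient s, and f̄ the pool mean
   fitness.  This form keeps the expected pool size at K under neutrality
   while making survival odds proportional to relative fitness.

The public operations (:func:`attempt_divisions`, :func:`apply_mutations`,
:func:`compete`, :func:`step`) are plain numpy and define the reference
semantics.  :func:`run_simulation` defaults to a numba-compiled kernel that
fuses the three stages for speed; ``backend="numpy"`` runs the composed
reference operations instead (different random streams, identical
distribution — checked by the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .schedules import DivisionSchedule, GrowthSchedule, SelectionSchedule

__all__ = [
    "SimulationConfig",
    "CellPool",
    "ClonalTimeSeries",
    "ReplicateSet",
    "ExtinctionError",
    "cell_fitness",
    "attempt_divisions",
    "apply_mutations",
    "compete",
    "step",
    "run_simulation",
    "run_replicates",
    "replicate_seeds",
]

#: Division-threshold dispersion: sd of the threshold draw is mean / THRESHOLD_SD_DIVISOR.
THRESHOLD_SD_DIVISOR = 8.0


class ExtinctionError(RuntimeError):
    """Raised when an operation requiring a non-empty pool receives an empty one."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulated lifespan.

    Defaults describe the standard human scenario: 5200 weekly updates
    (100 years), a pool growing from 300 to 10,000 cells by maturity, the
    dynamic division slowdown 3→40 weeks, and a phenotypic mutation rate of
    1e-3 per division.
    """

    lifespan: int = 5200
    growth: GrowthSchedule = field(default_factory=GrowthSchedule)
    division: DivisionSchedule = field(default_factory=DivisionSchedule)
    selection: SelectionSchedule = field(default_factory=SelectionSchedule)
    mutation_rate: float = 1e-3
    max_tracked_drivers: int = 4
    rng_seed: int = 0
    replicates: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be a probability in [0, 1]")
        if self.lifespan < 1:
            raise ValueError("lifespan must be >= 1 week")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_tracked_drivers < 1:
            raise ValueError("max_tracked_drivers must be >= 1")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)

    def schedule_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate all three schedules on the weekly grid 0..lifespan-1."""
        weeks = np.arange(self.lifespan, dtype=float)
        cap = np.asarray(self.growth.capacity(weeks), dtype=np.int64)
        interval = np.asarray(self.division.interval(weeks), dtype=np.float64)
        sel = np.asarray(self.selection.coefficient(weeks), dtype=np.float64)
        return cap, interval, sel


@dataclass
class CellPool:
    """Per-cell state at one timepoint: driver count and weeks since division."""

    drivers: np.ndarray
    timers: np.ndarray

    def __post_init__(self) -> None:
        self.drivers = np.asarray(self.drivers, dtype=np.int64)
        self.timers = np.asarray(self.timers, dtype=np.float64)
        if self.drivers.shape != self.timers.shape or self.drivers.ndim != 1:
            raise ValueError("drivers and timers must be 1-D arrays of equal length")
        if self.size and (self.drivers.min() < 0 or self.timers.min() < 0):
            raise ValueError("driver counts and timers must be non-negative")

    @property
    def size(self) -> int:
        return self.drivers.shape[0]

    @classmethod
    def initial(cls, config: SimulationConfig, rng: np.random.Generator) -> "CellPool":
        """Founder pool: capacity(0) driver-free cells with desynchronized timers."""
        n = config.growth.capacity(0)
        interval0 = config.division.interval(0)
        return cls(drivers=np.zeros(n, dtype=np.int64),
                   timers=rng.uniform(0.0, interval0, size=n))


@dataclass
class ClonalTimeSeries:
    """Weekly pool size and cumulative clone-class counts for a single run.

    ``counts[w, k-1]`` is the number of cells carrying >= k drivers at week w
    (clone classes 1+ .. max_tracked+; cells in deeper classes are nested in
    the shallower ones).
    """

    pool_size: np.ndarray
    counts: np.ndarray
    extinct: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pool_size = np.asarray(self.pool_size, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape[0] != self.pool_size.shape[0]:
            raise ValueError("counts and pool_size must cover the same weeks")

    def __len__(self) -> int:
        return self.pool_size.shape[0]

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    def count_ge(self, k: int) -> np.ndarray:
        """Cells carrying at least ``k`` drivers, per week."""
        if not (1 <= k <= self.counts.shape[1]):
            raise ValueError(f"clone class must be in 1..{self.counts.shape[1]}")
        return self.counts[:, k - 1]

    def to_frame(self) -> pd.DataFrame:
        data = {"week": self.weeks, "pool_size": self.pool_size}
        for k in range(1, self.counts.shape[1] + 1):
            data[f"ge{k}"] = self.counts[:, k - 1]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, extinct: bool = False,
                   seed: int | None = None) -> "ClonalTimeSeries":
        ks = sorted(int(c[2:]) for c in df.columns if c.startswith("ge"))
        counts = np.column_stack([df[f"ge{k}"].to_numpy(np.int64) for k in ks])
        return cls(pool_size=df["pool_size"].to_numpy(np.int64), counts=counts,
                   extinct=extinct, seed=seed)


@dataclass
class ReplicateSet:
    """Independent runs of one configuration plus their pointwise mean."""

    config: SimulationConfig
    runs: list[ClonalTimeSeries]
    base_seed: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.runs}
        if len(lengths) > 1:
            raise ValueError("all runs in a ReplicateSet must have equal length "
                             "(an extinct, truncated run cannot be averaged)")

    @property
    def n(self) -> int:
        return len(self.runs)

    def count_matrix(self, k: int) -> np.ndarray:
        """(n_runs, T) matrix of the >=k clone-class counts."""
        return np.stack([r.count_ge(k) for r in self.runs])

    def pool_matrix(self) -> np.ndarray:
        return np.stack([r.pool_size for r in self.runs])

    def mean_frame(self) -> pd.DataFrame:
        """Pointwise arithmetic mean over runs (float-valued)."""
        data = {"week": self.runs[0].weeks,
                "pool_size": self.pool_matrix().mean(axis=0)}
        for k in range(1, self.runs[0].counts.shape[1] + 1):
            data[f"ge{k}"] = self.count_matrix(k).mean(axis=0)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Reference operations (numpy)
# ---------------------------------------------------------------------------

def cell_fitness(driver_count, s):
    """Somatic fitness (1 + s)^driver_count; driver-free cells have fitness 1."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= -1.0):
        raise ValueError("selection coefficient must be > -1 "
                         "(fitness must stay positive)")
    k = np.asarray(driver_count)
    if np.any(k < 0):
        raise ValueError("driver_count must be non-negative")
    out = (1.0 + s_arr) ** k
    if np.ndim(driver_count) == 0 and np.ndim(s) == 0:
        return float(out)
    return out


def attempt_divisions(pool: CellPool, age: float, config: SimulationConfig,
                      rng: np.random.Generator) -> tuple[CellPool, int]:
    """Advance division timers one week and split the cells whose timers expire.

    Each cell draws its own threshold T ~ Normal(interval(age), interval/8),
    truncated at 0, and divides iff its timer has reached T.  A dividing cell
    is replaced by two timer-0 daughters (appended after the surviving
    non-dividers); non-dividers age by one week.  Returns the new pool and the
    number of daughters (= 2 x number of divisions).
    """
    mean = config.division.interval(age)
    sd = mean / THRESHOLD_SD_DIVISOR
    n = pool.size
    thresholds = np.maximum(rng.normal(mean, sd, size=n), 0.0)
    divides = pool.timers >= thresholds

    keep_drivers = pool.drivers[~divides]
    keep_timers = pool.timers[~divides] + 1.0
    daughters = np.repeat(pool.drivers[divides], 2)
    new_pool = CellPool(
        drivers=np.concatenate([keep_drivers, daughters]),
        timers=np.concatenate([keep_timers, np.zeros(daughters.size)]),
    )
    return new_pool, int(daughters.size)


def apply_mutations(daughter_drivers: np.ndarray, mutation_rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Each daughter independently gains exactly one driver with probability MR."""
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be a probability in [0, 1]")
    hits = rng.random(daughter_drivers.shape[0]) < mutation_rate
    return daughter_drivers + hits.astype(np.int64)


def compete(pool: CellPool, age: float, config: SimulationConfig,
            rng: np.random.Generator) -> CellPool:
    """Capacity-constrained binomial survival with fitness-weighted odds.

    Survival probability per cell: min(1, (K/N) * f_i / mean(f)).
    """
    if pool.size == 0:
        raise ExtinctionError("cannot run competition on an empty pool")
    K = config.growth.capacity(age)
    s = config.selection.coefficient(age)
    f = cell_fitness(pool.drivers, s)
    p = np.minimum(1.0, (K / pool.size) * f / f.mean())
    survives = rng.random(pool.size) < p
    return CellPool(drivers=pool.drivers[survives], timers=pool.timers[survives])


def step(pool: CellPool, week: int, config: SimulationConfig,
         rng: np.random.Generator) -> CellPool:
    """One weekly update: divisions, then daughter mutations, then competition."""
    pool, n_new = attempt_divisions(pool, week, config, rng)
    if n_new and config.mutation_rate > 0:
        mutated = apply_mutations(pool.drivers[-n_new:], config.mutation_rate, rng)
        pool.drivers[-n_new:] = mutated
    return compete(pool, week, config, rng)


# ---------------------------------------------------------------------------
# Fused kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _division_prob(timer, mean, sd):  # pragma: no cover
    # P(timer >= T) for T ~ Normal(mean, sd) truncated at 0; equals the
    # normal CDF at the timer (truncation only re-routes the negative tail,
    # which a non-negative timer always clears).
    z = (timer - mean) / sd
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


@njit(cache=True)
def _select_k(idx, start, c, k):  # pragma: no cover
    # Partial Fisher-Yates: move a uniform k-subset of idx[start:start+c]
    # to the front of the slice.
    for j in range(k):
        r = j + np.random.randint(0, c - j)
        tmp = idx[start + j]
        idx[start + j] = idx[start + r]
        idx[start + r] = tmp


@njit(cache=True)
def _run_kernel(seed, lifespan, capacity, interval, sel, mutation_rate,
                max_tracked, buf_size):  # pragma: no cover - exercised via run_simulation
    # Per-cell Bernoulli trials (division, survival) are sampled group-wise:
    # cells sharing the same success probability get a Binomial count of
    # successes and a uniformly chosen subset — identical in distribution to
    # independent per-cell draws, at a fraction of the RNG cost.
    np.random.seed(seed)
    drivers = np.zeros(buf_size, dtype=np.int64)
    timers = np.zeros(buf_size, dtype=np.float64)
    flag = np.zeros(buf_size, dtype=np.uint8)
    idx = np.zeros(buf_size, dtype=np.int64)
    n = int(capacity[0])
    interval0 = interval[0]
    for i in range(n):
        timers[i] = np.random.uniform(0.0, interval0)

    pool_size = np.zeros(lifespan, dtype=np.int64)
    counts = np.zeros((lifespan, max_tracked), dtype=np.int64)
    extinct_week = -1

    for w in range(lifespan):
        mean = interval[w]
        sd = mean / THRESHOLD_SD_DIVISOR
        K = float(capacity[w])
        s = sel[w]

        # Division probability by integer timer value.  Drawing a fresh
        # Normal(mean, sd) threshold per cell and comparing is, in
        # distribution, a Bernoulli with p = Phi((timer - mean)/sd); timers
        # are integers for every cell that has divided at least once, so the
        # CDF is tabulated once per week (founder cells with fractional
        # timers are decided cell-by-cell until their first division).
        # Timers at or past mean + 8 sd (= 2 mean) divide with certainty.
        tmax = int(2.0 * mean) + 2
        pdiv = np.empty(tmax + 1, dtype=np.float64)
        for t in range(tmax):
            pdiv[t] = _division_prob(float(t), mean, sd)
        pdiv[tmax] = 1.0

        # --- divisions: bucket integer-timer cells by timer value ---------
        m = n
        bcount = np.zeros(tmax + 1, dtype=np.int64)
        for i in range(m):
            ti = timers[i]
            tint = int(ti)
            if ti == tint:
                b = tint if tint < tmax else tmax
                bcount[b] += 1
                flag[i] = 0
            else:
                flag[i] = 1 if np.random.random() < _division_prob(ti, mean, sd) else 0
        boff = np.zeros(tmax + 2, dtype=np.int64)
        for b in range(tmax + 1):
            boff[b + 1] = boff[b] + bcount[b]
        fill = boff[:-1].copy()
        for i in range(m):
            ti = timers[i]
            tint = int(ti)
            if ti == tint:
                b = tint if tint < tmax else tmax
                idx[fill[b]] = i
                fill[b] += 1
        for b in range(tmax + 1):
            c = bcount[b]
            if c == 0:
                continue
            p = pdiv[b]
            if p >= 1.0:
                ndiv = c
            elif p <= 0.0:
                ndiv = 0
            else:
                ndiv = np.random.binomial(c, p)
            if ndiv > 0:
                if ndiv < c:
                    _select_k(idx, boff[b], c, ndiv)
                for j in range(ndiv):
                    flag[idx[boff[b] + j]] = 1

        # --- apply divisions + daughter mutations -------------------------
        for i in range(m):
            if flag[i]:
                d = drivers[i]
                timers[i] = 0.0
                if np.random.random() < mutation_rate:
                    drivers[i] = d + 1
                if n >= buf_size:
                    raise RuntimeError("cell buffer overflow")
                d2 = d
                if np.random.random() < mutation_rate:
                    d2 = d + 1
                drivers[n] = d2
                timers[n] = 0.0
                n += 1
            else:
                timers[i] += 1.0

        # --- competition: bucket by driver count --------------------------
        dmax = 0
        for i in range(n):
            if drivers[i] > dmax:
                dmax = drivers[i]
        table = np.empty(dmax + 1, dtype=np.float64)
        table[0] = 1.0
        base = 1.0 + s
        for k in range(1, dmax + 1):
            table[k] = table[k - 1] * base
        dcount = np.zeros(dmax + 1, dtype=np.int64)
        for i in range(n):
            dcount[drivers[i]] += 1
        fsum = 0.0
        for d in range(dmax + 1):
            fsum += dcount[d] * table[d]
        ratio = K / fsum  # (K/N) / fbar = K / (N * fbar) = K / fsum
        doff = np.zeros(dmax + 2, dtype=np.int64)
        for d in range(dmax + 1):
            doff[d + 1] = doff[d] + dcount[d]
        dfill = doff[:-1].copy()
        for i in range(n):
            d = drivers[i]
            idx[dfill[d]] = i
            dfill[d] += 1
            flag[i] = 0  # 0 = survive
        for d in range(dmax + 1):
            c = dcount[d]
            if c == 0:
                continue
            p = table[d] * ratio
            if p >= 1.0:
                continue  # certain survival
            nkill = np.random.binomial(c, 1.0 - p)
            if nkill > 0:
                if nkill < c:
                    _select_k(idx, doff[d], c, nkill)
                for j in range(nkill):
                    flag[idx[doff[d] + j]] = 1

        j = 0
        for i in range(n):
            if flag[i] == 0:
                drivers[j] = drivers[i]
                timers[j] = timers[i]
                j += 1
        n = j

        pool_size[w] = n
        for i in range(n):
            c = drivers[i]
            kk = c if c < max_tracked else max_tracked
            for k in range(kk):
                counts[w, k] += 1
        if n == 0:
            extinct_week = w
            break

    return pool_size, counts, extinct_week


def _buffer_size(config: SimulationConfig) -> int:
    max_k = config.growth.adult_pool_size
    return 2 * max_k + 8 * int(np.sqrt(max_k)) + 64


def run_simulation(config: SimulationConfig, seed: int | None = None,
                   backend: str = "kernel") -> ClonalTimeSeries:
    """Simulate one lifespan and return its weekly clonal time series.

    The series has exactly ``config.lifespan`` records unless the pool went
    extinct, in which case it is truncated at the extinction week and flagged.
    Identical config + seed gives bit-identical output (per backend).
    """
    if seed is None:
        seed = config.rng_seed
    seed = int(seed) % (2 ** 31)
    cap, interval, sel = config.schedule_arrays()

    if backend == "kernel":
        pool_size, counts, extinct_week = _run_kernel(
            seed, config.lifespan, cap, interval, sel,
            float(config.mutation_rate), config.max_tracked_drivers,
            _buffer_size(config))
    elif backend == "numpy":
        pool_size, counts, extinct_week = _run_numpy(config, seed)
    else:
        raise ValueError(f"unknown backend {backend!r}; expected 'kernel' or 'numpy'")

    extinct = extinct_week >= 0
    if extinct:
        end = extinct_week + 1
        pool_size, counts = pool_size[:end], counts[:end]
    return ClonalTimeSeries(pool_size=pool_size, counts=counts,
                            extinct=extinct, seed=seed)


def _run_numpy(config: SimulationConfig, seed: int):
    """Reference backend: the composed public operations, week by week."""
    rng = np.random.default_rng(seed)
    pool = CellPool.initial(config, rng)
    T = config.lifespan
    mt = config.max_tracked_drivers
    pool_size = np.zeros(T, dtype=np.int64)
    counts = np.zeros((T, mt), dtype=np.int64)
    extinct_week = -1
    for w in range(T):
        try:
            pool = step(pool, w, config, rng)
        except ExtinctionError:
            extinct_week = w
            break
        pool_size[w] = pool.size
        for k in range(1, mt + 1):
            counts[w, k - 1] = int(np.count_nonzero(pool.drivers >= k))
        if pool.size == 0:
            extinct_week = w
            break
    return pool_size, counts, extinct_week


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic, distinct per-replicate seeds derived from ``base_seed``."""
    ss = np.random.SeedSequence(int(base_seed))
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_replicates(config: SimulationConfig, n: int | None = None,
                   base_seed: int | None = None, n_jobs: int = 1,
                   backend: str = "kernel") -> ReplicateSet:
    """Run ``n`` independent replicates with seeds derived from ``base_seed``.

    Results are independent of ``n_jobs`` (each replicate's stream depends
    only on ``base_seed`` and its index).
    """
    if n is None:
        n = config.replicates
    if base_seed is None:
        base_seed = config.rng_seed
    if n < 1:
        raise ValueError("need at least one replicate")
    seeds = replicate_seeds(base_seed, n)
    if n_jobs == 1:
        runs = [run_simulation(config, int(s), backend=backend) for s in seeds]
    else:
        from joblib import Parallel, delayed
        runs = Parallel(n_jobs=n_jobs)(
            delayed(run_simulation)(config, int(s), backend=backend) for s in seeds)
    return ReplicateSet(config=config, runs=runs, base_seed=int(base_seed))
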