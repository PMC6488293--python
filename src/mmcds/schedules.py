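"""Age-dependent deterministic schedules: pool capacity, division interval, selection.

All three curves are two-plateau sigmoids over simulated age (in weeks).  The
growth and division curves are *anchored*: a logistic is renormalized so the
curve equals its configured endpoint values exactly at week 0 and at
``maturity_age``, and is held constant afterwards.  The selection curve of the
MMC-DS model is a *pure* logistic, so that its zero crossing sits exactly at
``switch_age`` and shifting ``switch_age`` translates the whole curve rigidly;
its plateaus are asymptotic (the residual is <1e-9 at the default parameters).

Ages are measured in weeks from birth; one simulated year is 52 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WEEKS_PER_YEAR",
    "DEFAULT_MATURITY_AGE",
    "GrowthSchedule",
    "DivisionSchedule",
    "SelectionSchedule",
    "pool_capacity",
    "division_interval",
    "selection_coefficient",
]

WEEKS_PER_YEAR = 52

#: End of the body-growth / division-slowdown transition: 19 simulated years.
DEFAULT_MATURITY_AGE = 19 * WEEKS_PER_YEAR  # 988 weeks


def _as_week_array(age) -> np.ndarray:
    """Validate and broadcast an age (scalar or array) to a float array."""
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age must be non-negative (weeks since birth)")
    return arr


def _anchored_sigmoid(age: np.ndarray, maturity: float, midpoint: float,
                      steepness: float) -> np.ndarray:
    """Logistic ramp renormalized to hit 0 at week 0 and 1 at ``maturity``.

    Clamped to 1 for all ages past maturity, so the plateau is exact.
    """
    lo = 1.0 / (1.0 + math.exp(midpoint / steepness))
    hi = 1.0 / (1.0 + math.exp(-(maturity - midpoint) / steepness))
    raw = 1.0 / (1.0 + np.exp(-(age - midpoint) / steepness))
    frac = (raw - lo) / (hi - lo)
    return np.clip(frac, 0.0, 1.0)


@dataclass(frozen=True)
class GrowthSchedule:
    """Stem-cell pool capacity over age: small at birth, adult-sized by maturity.

    The pool starts at ``initial_pool_size`` cells and grows sigmoidally to
    ``adult_pool_size`` by ``maturity_age``, emulating compartment expansion
    during body growth.  With ``proportional_start`` (the default), the
    starting pool scales with the adult pool so that the 300:10,000 ratio is
    preserved in simulations of larger compartments; with it off, the starting
    pool is always ``initial_pool_size`` cells regardless of adult size.
    """

    initial_pool_size: int = 300
    adult_pool_size: int = 10_000
    maturity_age: float = DEFAULT_MATURITY_AGE
    midpoint: float = field(default=DEFAULT_MATURITY_AGE / 2)
    steepness: float = field(default=DEFAULT_MATURITY_AGE / 12)
    proportional_start: bool = True

    _REFERENCE_INITIAL = 300
    _REFERENCE_ADULT = 10_000

    def __post_init__(self) -> None:
        if self.initial_pool_size < 1:
            raise ValueError("initial_pool_size must be >= 1")
        if self.adult_pool_size < self.initial_pool_size:
            raise ValueError("adult_pool_size must be >= initial_pool_size")
        if self.maturity_age <= 0 or self.steepness <= 0:
            raise ValueError("maturity_age and steepness must be positive")

    @property
    def start_size(self) -> int:
        """Pool size at week 0, after applying ``proportional_start`` scaling."""
        if self.proportional_start:
            scaled = self.initial_pool_size * self.adult_pool_size / self._REFERENCE_ADULT
            return max(1, int(round(scaled)))
        return self.initial_pool_size

    def capacity(self, age) -> np.ndarray | int:
        """Pool capacity (integer cell count) at the given age in weeks."""
        arr = _as_week_array(age)
        frac = _anchored_sigmoid(arr, self.maturity_age, self.midpoint, self.steepness)
        start = self.start_size
        cap = np.rint(start + (self.adult_pool_size - start) * frac).astype(np.int64)
        if np.ndim(age) == 0:
            return int(cap)
        return cap


@dataclass(frozen=True)
class DivisionSchedule:
    """Mean cell-division interval over age, in weeks.

    ``stable`` keeps one division per ``stable_interval`` weeks for life (the
    classical multistage-model assumption of a constant division rate).
    ``dynamic`` reflects the measured slowdown of stem-cell cycling: roughly
    one division per 3 weeks at birth, decelerating to one per 40 weeks
    (sweepable up to 70) by maturity.
    """

    profile: str = "dynamic"
    stable_interval: float = 20.0
    initial_interval: float = 3.0
    adult_interval: float = 40.0
    maturity_age: float = DEFAULT_MATURITY_AGE
    midpoint: float = field(default=DEFAULT_MATURITY_AGE / 2)
    steepness: float = field(default=DEFAULT_MATURITY_AGE / 12)

    def __post_init__(self) -> None:
        if self.profile not in ("stable", "dynamic"):
            raise ValueError(f"unknown division profile {self.profile!r}; "
                             "expected 'stable' or 'dynamic'")
        for name in ("stable_interval", "initial_interval", "adult_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.adult_interval < self.initial_interval:
            raise ValueError("adult_interval must be >= initial_interval "
                             "(division slows with age)")
        if self.maturity_age <= 0 or self.steepness <= 0:
            raise ValueError("maturity_age and steepness must be positive")

    def interval(self, age) -> np.ndarray | float:
        """Mean weeks between divisions at the given age."""
        arr = _as_week_array(age)
        if self.profile == "stable":
            out = np.full_like(arr, self.stable_interval)
        else:
            frac = _anchored_sigmoid(arr, self.maturity_age, self.midpoint,
                                     self.steepness)
            out = self.initial_interval + (self.adult_interval - self.initial_interval) * frac
        if np.ndim(age) == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class SelectionSchedule:
    """Per-driver selection coefficient s(age).

    ``MMC``: s is the age-independent ``fixed_advantage`` (classical model,
    every driver confers the same constant advantage).

    ``MMC_DS``: s follows a rising logistic from a plateau of ``-neg_max``
    early in life to ``+pos_max`` late in life, crossing zero exactly at
    ``switch_age`` (whenever ``neg_max > 0``; with no early negative
    selection the curve starts at 0 and the nominal switch age marks the
    transition midpoint).  ``transition_width`` is the logistic scale in
    weeks; ~90% of the swing occurs within ±3 widths of the crossing.
    """

    model: str = "MMC"
    fixed_advantage: float = 0.005
    neg_max: float = 0.005
    pos_max: float = 0.005
    switch_age: float = 50 * WEEKS_PER_YEAR
    transition_width: float = 150.0

    def __post_init__(self) -> None:
        if self.model not in ("MMC", "MMC_DS"):
            raise ValueError(f"unknown selection model {self.model!r}; "
                             "expected 'MMC' or 'MMC_DS'")
        if self.fixed_advantage <= -1:
            raise ValueError("fixed_advantage must be > -1 (fitness must stay positive)")
        if self.neg_max < 0 or self.neg_max >= 1:
            raise ValueError("neg_max is a magnitude in [0, 1)")
        if self.pos_max < 0:
            raise ValueError("pos_max must be non-negative")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.switch_age < 0:
            raise ValueError("switch_age must be non-negative")

    @property
    def _center(self) -> float:
        """Logistic center t0 such that s(switch_age) = 0 exactly.

        Solving -neg + (neg+pos) * sigma((switch - t0)/w) = 0 gives
        t0 = switch - w * logit(neg / (neg + pos)).  For neg == 0 (or a
        degenerate all-zero curve) the center defaults to switch_age itself.
        """
        total = self.neg_max + self.pos_max
        if self.neg_max == 0 or self.pos_max == 0 or total == 0:
            # no true sign change; the nominal switch age marks the midpoint
            return self.switch_age
        q = self.neg_max / total
        return self.switch_age - self.transition_width * math.log(q / (1.0 - q))

    def coefficient(self, age) -> np.ndarray | float:
        """Selection coefficient at the given age in weeks."""
        arr = _as_week_array(age)
        if self.model == "MMC":
            out = np.full_like(arr, self.fixed_advantage)
        else:
            sig = 1.0 / (1.0 + np.exp(-(arr - self._center) / self.transition_width))
            out = -self.neg_max + (self.neg_max + self.pos_max) * sig
        if np.ndim(age) == 0:
            return float(out)
        return out


def pool_capacity(age, schedule: GrowthSchedule):
    """Pool capacity (cells) at ``age`` weeks under ``schedule``."""
    return schedule.capacity(age)


def division_interval(age, schedule: DivisionSchedule):
    """Mean division interval (weeks) at ``age`` weeks under ``schedule``."""
    return schedule.interval(age)


def selection_coefficient(age, schedule: SelectionSchedule):
    """Per-driver selection coefficient at ``age`` weeks under ``schedule``."""
    return schedule.coefficient(age)
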