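"""Replicate-comparison statistics and summary measures for clonal dynamics.

The headline comparison is nonparametric and pointwise: at every simulated
week the clone-class counts of two (or more) conditions — each condition a
sample of independent runs — are compared with the Kruskal–Wallis rank test,
yielding a p-value curve over the lifespan.  The curve is summarized by its
normalized area (mean p-value): 1 means the conditions' clonal behavior is
indistinguishable throughout life, values near 0 mean it differs almost
everywhere.  No multiple-testing correction is applied across timepoints:
the area ratio is a descriptive magnitude, not an inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .engine import ClonalTimeSeries, ReplicateSet

__all__ = [
    "ComparisonResult",
    "pointwise_rank_test",
    "pvalue_auc_ratio",
    "compare_replicate_sets",
    "normalize_series",
    "takeover_week",
    "early_peak_and_decline",
]


@dataclass(frozen=True)
class ComparisonResult:
    """A per-week p-value curve between conditions and its area summary."""

    p_values: np.ndarray
    clone_class: int
    labels: tuple[str, ...] = ()

    @property
    def auc_ratio(self) -> float:
        """Mean p-value = area under the curve / (1 x number of weeks)."""
        return pvalue_auc_ratio(self.p_values)


def _as_matrix(group, clone_class: int) -> np.ndarray:
    """Coerce a condition's sample of runs into an (n_runs, T) count matrix."""
    if isinstance(group, ReplicateSet):
        return group.count_matrix(clone_class)
    if isinstance(group, (list, tuple)) and group and isinstance(group[0], ClonalTimeSeries):
        return np.stack([r.count_ge(clone_class) for r in group])
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 2:
        raise ValueError("each group must be a ReplicateSet, a list of runs, "
                         "or a 2-D (runs x weeks) array")
    return arr


def pointwise_rank_test(groups: Sequence, clone_class: int = 1) -> np.ndarray:
    """Kruskal–Wallis p-value at every week across >=2 groups of runs.

    Uses average ranks with the standard tie correction and the chi-square
    approximation (df = number of groups - 1).  Weeks where every run in
    every group has the identical value are degenerate (zero rank variance);
    they are reported as p = 1, i.e. identical behavior.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    mats = [_as_matrix(g, clone_class) for g in groups]
    T = mats[0].shape[1]
    if any(m.shape[1] != T for m in mats):
        raise ValueError("all groups must cover the same number of weeks")
    if any(m.shape[0] < 2 for m in mats):
        raise ValueError("each group needs at least 2 runs")

    p = np.ones(T)
    for t in range(T):
        samples = [m[:, t] for m in mats]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            continue  # degenerate week: identical behavior, p = 1
        p[t] = sps.kruskal(*samples).pvalue
    return p


def pvalue_auc_ratio(p_values) -> float:
    """Area under a p-value curve divided by the total chart area (1 x T)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("p-value series must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(p.mean())


def compare_replicate_sets(a: ReplicateSet, b: ReplicateSet, clone_class: int = 1,
                           labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Convenience wrapper: pointwise rank test between two replicate sets."""
    p = pointwise_rank_test([a, b], clone_class=clone_class)
    return ComparisonResult(p_values=p, clone_class=clone_class, labels=tuple(labels))


def normalize_series(values) -> np.ndarray:
    """Scale a non-negative incidence series by its maximum (shape-preserving).

    The maximum maps to exactly 1; useful for overlaying incidence curves of
    cancers with very different absolute rates.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("series must be non-empty")
    if np.any(v < 0):
        raise ValueError("incidence values must be non-negative")
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("series must contain at least one positive value")
    return v / vmax


def takeover_week(series: ClonalTimeSeries, clone_class: int = 1,
                  fraction: float = 0.5) -> float:
    """First week the >=k clone class exceeds ``fraction`` of the pool size.

    Returns NaN when the class never reaches that share within the series.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    counts = series.count_ge(clone_class)
    hit = counts > fraction * series.pool_size
    idx = np.flatnonzero(hit)
    return float(idx[0]) if idx.size else float("nan")


def early_peak_and_decline(series: ClonalTimeSeries, clone_class: int = 1,
                           peak_before: int = 520, decline_by: int = 1560,
                           decline_fraction: float = 0.5,
                           min_peak: int = 2) -> bool:
    """Detect a childhood clonal transient: an early peak later mostly erased.

    True when the >=k clone count reaches a maximum of at least ``min_peak``
    cells before week ``peak_before`` (default age 10) and has dropped by at
    least ``decline_fraction`` of that peak at some week up to ``decline_by``
    (default age 30).
    """
    counts = series.count_ge(clone_class)
    if len(counts) < decline_by:
        raise ValueError("series too short for the requested decline window")
    early = counts[:peak_before]
    peak_val = int(early.max())
    if peak_val < min_peak:
        return False
    peak_at = int(np.argmax(early))
    later_min = counts[peak_at:decline_by].min()
    return later_min <= (1.0 - decline_fraction) * peak_val
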