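"""Scenario registry: the published parameter sweeps, ready to rerun.

Each scenario is a baseline configuration plus an ordered list of
single-parameter (or paired-parameter) overrides — the color-coded levels of
the corresponding figure.  The baseline is a *reconstructed* standard
parameter set (the original supplementary tables are not distributed with
this package): adult pool 10,000 cells, dynamic division profile 3→40 weeks,
phenotypic mutation rate 1e-3, MMC fitness advantage +0.5% per driver, and
for MMC-DS a symmetric ±0.5% swing switching sign at age 50.  Every value is
overridable through the config file or the API.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Any, Callable

from .engine import ReplicateSet, SimulationConfig, run_replicates
from .schedules import WEEKS_PER_YEAR, DivisionSchedule, GrowthSchedule, SelectionSchedule
from .stats import ComparisonResult, pointwise_rank_test

__all__ = [
    "Scenario",
    "ScenarioResult",
    "SCENARIO_NAMES",
    "standard_mmc_config",
    "standard_mmcds_config",
    "apply_overrides",
    "build_scenario",
    "run_scenario",
]


def standard_mmc_config() -> SimulationConfig:
    """Reconstructed standard parameter set, fixed-selection (MMC) variant."""
    return SimulationConfig(
        selection=SelectionSchedule(model="MMC", fixed_advantage=0.005))


def standard_mmcds_config() -> SimulationConfig:
    """Reconstructed standard parameter set, differential-selection variant."""
    return SimulationConfig(
        selection=SelectionSchedule(model="MMC_DS", neg_max=0.005, pos_max=0.005,
                                    switch_age=50 * WEEKS_PER_YEAR))


def apply_overrides(config: SimulationConfig, overrides: dict[str, Any]) -> SimulationConfig:
    """Replace fields addressed by dotted paths, e.g. ``selection.pos_max``."""
    for path, value in overrides.items():
        parts = path.split(".")
        config = _replace_path(config, parts, value)
    return config


def _replace_path(obj, parts: list[str], value):
    name = parts[0]
    if not hasattr(obj, name):
        raise KeyError(f"unknown config field {name!r} on {type(obj).__name__}")
    if len(parts) == 1:
        return dataclasses.replace(obj, **{name: value})
    inner = _replace_path(getattr(obj, name), parts[1:], value)
    return dataclasses.replace(obj, **{name: inner})


@dataclass(frozen=True)
class Scenario:
    """A named sweep: baseline config + ordered override levels."""

    name: str
    description: str
    baseline: SimulationConfig
    levels: tuple[tuple[str, tuple[tuple[str, Any], ...]], ...]
    replicates: int = 50
    #: Fig 5-style scenarios examine individual runs, never the mean.
    individual_runs: bool = False

    def level_config(self, label: str) -> SimulationConfig:
        for lab, overrides in self.levels:
            if lab == label:
                return apply_overrides(self.baseline, dict(overrides))
        raise KeyError(f"no level {label!r} in scenario {self.name!r}")

    def level_labels(self) -> list[str]:
        return [lab for lab, _ in self.levels]

    def with_baseline(self, baseline: SimulationConfig) -> "Scenario":
        return dataclasses.replace(self, baseline=baseline)


def _levels(pairs) -> tuple:
    return tuple((label, tuple(overrides.items())) for label, overrides in pairs)


def _fig3a() -> Scenario:
    return Scenario(
        name="fig3A_division_profile",
        description="Stable (1 division/~20 wk for life) vs dynamic (3→40 wk) "
                    "cell division profile, fixed-selection baseline.",
        baseline=standard_mmc_config(),
        levels=_levels([
            ("stable", {"division.profile": "stable"}),
            ("dynamic", {"division.profile": "dynamic"}),
        ]))


def _fig3b() -> Scenario:
    return Scenario(
        name="fig3B_adult_rate",
        description="Adult division interval sweep under the dynamic profile: "
                    "one division per ~70/60/50/40 weeks.",
        baseline=standard_mmc_config(),
        levels=_levels([
            (f"adult_{w}wk", {"division.adult_interval": float(w)})
            for w in (70, 60, 50, 40)
        ]))


def _fig3c() -> Scenario:
    return Scenario(
        name="fig3C_mutation_rate",
        description="Phenotypic mutation rate sweep 1e-2 .. 1e-5.",
        baseline=standard_mmc_config(),
        levels=_levels([
            (f"MR_{mr:g}", {"mutation_rate": mr})
            for mr in (1e-2, 1e-3, 1e-4, 1e-5)
        ]))


def _fig4a_mmc() -> Scenario:
    return Scenario(
        name="fig4A_fitness_MMC",
        description="Fixed per-driver fitness advantage sweep "
                    "+0.1% / +0.25% / +0.5% / +1%.",
        baseline=standard_mmc_config(),
        levels=_levels([
            (f"FA_{fa:g}", {"selection.fixed_advantage": fa})
            for fa in (0.001, 0.0025, 0.005, 0.01)
        ]))


def _fig4a_ds_a() -> Scenario:
    return Scenario(
        name="fig4A_MMC_DS_a",
        description="Differential selection, general strength sweep: "
                    "symmetric ±Fmax of 0.05% / 0.125% / 0.25% / 0.5%.",
        baseline=standard_mmcds_config(),
        levels=_levels([
            (f"Fmax_{f:g}", {"selection.neg_max": f, "selection.pos_max": f})
            for f in (0.0005, 0.00125, 0.0025, 0.005)
        ]))


def _fig4a_ds_b() -> Scenario:
    pairs = [(0.005, 0.005), (0.003, 0.007), (0.001, 0.009), (0.0, 0.01)]
    return Scenario(
        name="fig4A_MMC_DS_b",
        description="Differential selection, early/late strength ratio sweep: "
                    "-Fmax/+Fmax of -0.5/+0.5, -0.3/+0.7, -0.1/+0.9, 0/+1 (%).",
        baseline=standard_mmcds_config(),
        levels=_levels([
            (f"neg{n:g}_pos{p:g}", {"selection.neg_max": n, "selection.pos_max": p})
            for n, p in pairs
        ]))


def _fig4b() -> Scenario:
    return Scenario(
        name="fig4B_pool_size",
        description="Adult pool size sweep 10k / 25k / 50k / 100k cells; the "
                    "starting pool is 300 cells in every condition, and clone "
                    "sizes are read as percent of the adult pool.",
        baseline=apply_overrides(standard_mmcds_config(),
                                 {"growth.proportional_start": False}),
        levels=_levels([
            (f"AP_{ap}", {"growth.adult_pool_size": ap})
            for ap in (10_000, 25_000, 50_000, 100_000)
        ]))


def _fig4c() -> Scenario:
    return Scenario(
        name="fig4C_aging_curve",
        description="Selection sign-switch age sweep (aging profile): "
                    "10 / 30 / 50 / 70 years.",
        baseline=standard_mmcds_config(),
        levels=_levels([
            (f"switch_{y}y", {"selection.switch_age": float(y * WEEKS_PER_YEAR)})
            for y in (10, 30, 50, 70)
        ]))


def _fig5() -> Scenario:
    return Scenario(
        name="fig5_early_life",
        description="Early-life clonal transients: large samples of individual "
                    "(non-averaged) runs under MMC vs MMC-DS.",
        baseline=standard_mmc_config(),
        levels=_levels([
            ("MMC", {"selection": SelectionSchedule(model="MMC",
                                                    fixed_advantage=0.005)}),
            ("MMC_DS", {"selection": SelectionSchedule(model="MMC_DS",
                                                       neg_max=0.005,
                                                       pos_max=0.005)}),
        ]),
        replicates=1000,
        individual_runs=True)


_REGISTRY: dict[str, Callable[[], Scenario]] = {
    s().name: s for s in (_fig3a, _fig3b, _fig3c, _fig4a_mmc, _fig4a_ds_a,
                          _fig4a_ds_b, _fig4b, _fig4c, _fig5)
}

SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def build_scenario(name: str) -> Scenario:
    """Look up a scenario by name; error lists the available names."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{', '.join(SCENARIO_NAMES)}") from None


@dataclass
class ScenarioResult:
    """Per-level replicate sets and the pairwise comparison matrix."""

    scenario: Scenario
    base_seed: int
    level_results: dict[str, ReplicateSet]
    comparisons: dict[tuple[int, str, str], ComparisonResult] = field(default_factory=dict)


def run_scenario(scenario: Scenario, base_seed: int, replicates: int | None = None,
                 n_jobs: int = 1, compare: bool = True,
                 clone_classes: tuple[int, ...] = (1, 2, 3, 4),
                 progress: Callable[[str], None] | None = None) -> ScenarioResult:
    """Run every sweep level and, optionally, all pairwise comparisons.

    Every level uses the same ``base_seed``, hence matched per-replicate
    seeds across levels; rerunning with the same seed reproduces all outputs
    bit-identically.  Fig 5-style individual-run scenarios skip comparisons
    unless asked (their interest is per-run shape, not group means).
    """
    n = replicates if replicates is not None else scenario.replicates
    results: dict[str, ReplicateSet] = {}
    for label in scenario.level_labels():
        cfg = scenario.level_config(label)
        results[label] = run_replicates(cfg, n=n, base_seed=base_seed, n_jobs=n_jobs)
        if progress is not None:
            progress(f"level {label}: {n} runs done")

    out = ScenarioResult(scenario=scenario, base_seed=base_seed, level_results=results)
    if compare and not scenario.individual_runs:
        labels = scenario.level_labels()
        for k in clone_classes:
            for a, b in itertools.combinations(labels, 2):
                p = pointwise_rank_test([results[a], results[b]], clone_class=k)
                out.comparisons[(k, a, b)] = ComparisonResult(
                    p_values=p, clone_class=k, labels=(a, b))
                if progress is not None:
                    progress(f"compared {a} vs {b} (clone class >= {k})")
    return out
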