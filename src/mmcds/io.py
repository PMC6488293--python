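"""Config loading, result serialization, and run manifests.

Configs are YAML mappings mirroring :class:`~mmcds.engine.SimulationConfig`
(top-level scalars plus ``growth`` / ``division`` / ``selection`` sections).
Unknown keys are rejected with their full path.  Time series are written as
tab-separated text (``week  pool_size  ge1..ge4``), one file per run, with a
JSON manifest holding the resolved config, its hash, and the per-run seeds —
enough to reproduce every output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import ClonalTimeSeries, ReplicateSet, SimulationConfig
from .schedules import DivisionSchedule, GrowthSchedule, SelectionSchedule

__all__ = [
    "ConfigError",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
    "RunManifest",
    "write_run",
    "read_run",
    "write_replicates",
    "read_replicates",
]

_SECTIONS = {
    "growth": GrowthSchedule,
    "division": DivisionSchedule,
    "selection": SelectionSchedule,
}
_SCALARS = ("lifespan", "mutation_rate", "max_tracked_drivers", "rng_seed",
            "replicates")


class ConfigError(ValueError):
    """A config file failed to parse or violated a parameter constraint."""


def _build_section(cls, mapping: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls) if f.init}
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key '{path}.{key}'")
    try:
        return cls(**mapping)
    except ValueError as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated config from a plain mapping, defaults filled in."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key in _SCALARS:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown key '{key}'")
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Load a YAML config file; an empty file yields the full default config."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(config: SimulationConfig) -> dict:
    """Resolved parameters as a plain nested mapping (full precision)."""
    out = {name: getattr(config, name) for name in _SCALARS}
    for name, cls in _SECTIONS.items():
        section = getattr(config, name)
        out[name] = {f.name: getattr(section, f.name)
                     for f in dataclasses.fields(cls) if f.init}
    return out


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a replicate set bit-identically."""

    config: dict
    config_hash: str
    base_seed: int | None
    run_seeds: list[int]
    version: str
    created: str
    status: str = "complete"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_run(series: ClonalTimeSeries, path) -> None:
    """One run as TSV: week, pool_size, ge1..geN (integer counts)."""
    series.to_frame().to_csv(path, sep="\t", index=False)


def read_run(path) -> ClonalTimeSeries:
    return ClonalTimeSeries.from_frame(pd.read_csv(path, sep="\t"))


def write_replicates(repset: ReplicateSet, out_dir, overwrite: bool = True) -> Path:
    """Write run_NNN.tsv per run, mean.tsv, and manifest.json into a directory."""
    out = Path(out_dir)
    if out.exists() and not overwrite and any(out.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty {out} "
                              "(overwrite disabled)")
    out.mkdir(parents=True, exist_ok=True)
    for i, run in enumerate(repset.runs):
        write_run(run, out / f"run_{i:03d}.tsv")
    repset.mean_frame().to_csv(out / "mean.tsv", sep="\t", index=False)
    manifest = RunManifest(
        config=config_to_dict(repset.config),
        config_hash=config_hash(repset.config),
        base_seed=repset.base_seed,
        run_seeds=[int(r.seed) for r in repset.runs],
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return out


def read_replicates(run_dir) -> tuple[ReplicateSet, RunManifest]:
    """Round-trip a directory written by :func:`write_replicates`."""
    run_dir = Path(run_dir)
    manifest = RunManifest.from_json((run_dir / "manifest.json").read_text())
    config = config_from_dict(manifest.config)
    runs = []
    for i, path in enumerate(sorted(run_dir.glob("run_*.tsv"))):
        run = read_run(path)
        run.seed = manifest.run_seeds[i] if i < len(manifest.run_seeds) else None
        runs.append(run)
    repset = ReplicateSet(config=config, runs=runs, base_seed=manifest.base_seed)
    return repset, manifest
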