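"""Configuration parsing, dataset I/O and run manifests.

Configurations are JSON or YAML mappings.  Parsing is strict: unknown keys
are rejected, defaults are filled in explicitly, and the resulting
:class:`RunConfig` round-trips through ``to_dict`` unchanged.  Datasets
travel as wide CSV with the exact header ``y1,y2,y3,group``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_fit import (
    InverseGammaPrior,
    NormalPrior,
    PriorSpec,
    SamplerConfig,
    default_priors,
)
from .exceptions import ConfigError, InputError
from .growth_model import (
    LongitudinalDataset,
    ParameterSet,
    STRUCTURAL_NAMES,
    VARIANCE_NAMES,
)
from .mc_study import BETA_PRIOR_VARIANCE_GRID
from .synthetic_data import SimulationDesign, default_population

_COMMANDS = ("simulate", "fit-ml", "fit-bayes", "mc-study", "sensitivity", "diagnose")


def _require_mapping(obj: Any, where: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{where} must be a mapping")
    return obj


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_population(obj: Any) -> ParameterSet:
    mapping = _require_mapping(obj, "population")
    if not mapping:
        return default_population()
    try:
        return ParameterSet.from_dict(mapping)
    except InputError as exc:
        raise ConfigError(f"population: {exc}") from exc


def _parse_design(obj: Any) -> SimulationDesign:
    mapping = _require_mapping(obj, "design")
    _reject_unknown(
        mapping, {"population", "n", "group_allocation", "n_reps", "seed"}, "design"
    )
    try:
        return SimulationDesign(
            population=_parse_population(mapping.get("population")),
            n=int(mapping.get("n", 8)),
            group_allocation=float(mapping.get("group_allocation", 0.5)),
            n_reps=int(mapping.get("n_reps", 1000)),
            seed=int(mapping.get("seed", 0)),
        )
    except InputError as exc:
        raise ConfigError(f"design: {exc}") from exc


def _parse_priors(obj: Any) -> PriorSpec:
    mapping = _require_mapping(obj, "priors")
    _reject_unknown(mapping, {"structural", "variances"}, "priors")
    spec = default_priors()
    structural = dict(spec.structural)
    for name, sub in _require_mapping(
        mapping.get("structural"), "priors.structural"
    ).items():
        if name not in STRUCTURAL_NAMES:
            raise ConfigError(f"priors.structural: unknown parameter {name!r}")
        sub = _require_mapping(sub, f"priors.structural.{name}")
        _reject_unknown(sub, {"mean", "variance"}, f"priors.structural.{name}")
        try:
            structural[name] = NormalPrior(
                mean=float(sub.get("mean", 0.0)),
                variance=float(sub.get("variance", 1e10)),
            )
        except InputError as exc:
            raise ConfigError(f"priors.structural.{name}: {exc}") from exc
    variances = dict(spec.variances)
    for name, sub in _require_mapping(
        mapping.get("variances"), "priors.variances"
    ).items():
        if name not in VARIANCE_NAMES:
            raise ConfigError(f"priors.variances: unknown parameter {name!r}")
        sub = _require_mapping(sub, f"priors.variances.{name}")
        _reject_unknown(sub, {"shape", "scale"}, f"priors.variances.{name}")
        try:
            variances[name] = InverseGammaPrior(
                shape=float(sub.get("shape", -1.0)),
                scale=float(sub.get("scale", 0.0)),
            )
        except InputError as exc:
            raise ConfigError(f"priors.variances.{name}: {exc}") from exc
    return PriorSpec(structural=structural, variances=variances)


def _parse_sampler(obj: Any) -> SamplerConfig:
    mapping = _require_mapping(obj, "sampler")
    _reject_unknown(
        mapping,
        {"n_iterations", "burn_in_fraction", "seed", "point_estimate_rule"},
        "sampler",
    )
    try:
        return SamplerConfig(
            n_iterations=int(mapping.get("n_iterations", 10_000)),
            burn_in_fraction=float(mapping.get("burn_in_fraction", 0.5)),
            seed=int(mapping.get("seed", 0)),
            point_estimate_rule=str(mapping.get("point_estimate_rule", "median")),
        )
    except InputError as exc:
        raise ConfigError(f"sampler: {exc}") from exc


def _priors_to_dict(priors: PriorSpec) -> dict:
    return {
        "structural": {
            name: {"mean": p.mean, "variance": p.variance}
            for name, p in priors.structural.items()
        },
        "variances": {
            name: {"shape": p.shape, "scale": p.scale}
            for name, p in priors.variances.items()
        },
    }


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings for one command, defaults included."""

    command: str
    design: SimulationDesign | None = None
    priors: PriorSpec | None = None
    sampler: SamplerConfig | None = None
    mu0_grid: tuple[float, ...] = ()
    var0_grid: tuple[float, ...] = ()
    estimator: str = "ml"
    threshold_multiplier: float = 50.0

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"command": self.command}
        if self.design is not None:
            out["design"] = {
                "population": self.design.population.as_dict(),
                "n": self.design.n,
                "group_allocation": self.design.group_allocation,
                "n_reps": self.design.n_reps,
                "seed": self.design.seed,
            }
        if self.priors is not None:
            out["priors"] = _priors_to_dict(self.priors)
        if self.sampler is not None:
            out["sampler"] = dataclasses.asdict(self.sampler)
        if self.command == "sensitivity":
            out["mu0_grid"] = list(self.mu0_grid)
            out["var0_grid"] = list(self.var0_grid)
        if self.command == "mc-study":
            out["estimator"] = self.estimator
        if self.command == "diagnose":
            out["threshold_multiplier"] = self.threshold_multiplier
        return out


def parse_config(text: str, command: str) -> RunConfig:
    """Parse a JSON/YAML document into a validated :class:`RunConfig`."""
    if command not in _COMMANDS:
        raise ConfigError(f"unknown command {command!r}")
    try:
        raw = yaml.safe_load(text) if text.strip() else {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration document: {exc}") from exc
    raw = dict(_require_mapping(raw, "configuration"))
    if "command" in raw:
        if raw.pop("command") != command:
            raise ConfigError("configuration 'command' does not match")

    if command == "simulate":
        _reject_unknown(raw, {"design"}, "configuration")
        return RunConfig(command=command, design=_parse_design(raw.get("design")))
    if command == "fit-ml":
        _reject_unknown(raw, set(), "configuration")
        return RunConfig(command=command)
    if command == "fit-bayes":
        _reject_unknown(raw, {"priors", "sampler"}, "configuration")
        return RunConfig(
            command=command,
            priors=_parse_priors(raw.get("priors")),
            sampler=_parse_sampler(raw.get("sampler")),
        )
    if command == "mc-study":
        _reject_unknown(raw, {"design", "estimator", "priors", "sampler"},
                        "configuration")
        estimator = str(raw.get("estimator", "ml"))
        if estimator not in ("ml", "bayes"):
            raise ConfigError("estimator must be 'ml' or 'bayes'")
        return RunConfig(
            command=command,
            design=_parse_design(raw.get("design")),
            estimator=estimator,
            priors=_parse_priors(raw.get("priors")),
            sampler=_parse_sampler(raw.get("sampler")),
        )
    if command == "sensitivity":
        _reject_unknown(
            raw, {"mu0_grid", "var0_grid", "priors", "sampler"}, "configuration"
        )
        mu0_grid = tuple(float(v) for v in raw.get("mu0_grid", [10.0, 5.0, 0.0, -5.0, -10.0]))
        var0_grid = tuple(
            float(v) for v in raw.get("var0_grid", list(BETA_PRIOR_VARIANCE_GRID))
        )
        if not mu0_grid or not var0_grid:
            raise ConfigError("sensitivity grids must be non-empty")
        return RunConfig(
            command=command,
            mu0_grid=mu0_grid,
            var0_grid=var0_grid,
            priors=_parse_priors(raw.get("priors")),
            sampler=_parse_sampler(raw.get("sampler")),
        )
    # diagnose
    _reject_unknown(raw, {"threshold_multiplier"}, "configuration")
    mult = float(raw.get("threshold_multiplier", 50.0))
    if mult <= 1.0:
        raise ConfigError("threshold_multiplier must exceed 1")
    return RunConfig(command=command, threshold_multiplier=mult)


DATASET_COLUMNS = ("y1", "y2", "y3", "group")


def read_dataset_csv(path: str) -> LongitudinalDataset:
    """Read a wide dataset CSV with the exact header ``y1,y2,y3,group``."""
    frame = pd.read_csv(path)
    if tuple(frame.columns) != DATASET_COLUMNS:
        raise InputError(
            f"dataset header must be {','.join(DATASET_COLUMNS)}; "
            f"found {','.join(map(str, frame.columns))}"
        )
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise InputError(f"missing value in dataset row {row}")
    group = frame["group"]
    if not np.all(np.isin(group.to_numpy(), (0, 1))):
        raise InputError("group column must contain only 0 and 1")
    return LongitudinalDataset(
        outcomes=frame[["y1", "y2", "y3"]].to_numpy(dtype=float),
        group=group.to_numpy(dtype=np.int64),
    )


def write_dataset_csv(data: LongitudinalDataset, path: str) -> None:
    frame = pd.DataFrame(data.outcomes, columns=["y1", "y2", "y3"])
    frame["group"] = data.group
    frame.to_csv(path, index=False)


def write_manifest(
    path: str, config: RunConfig, seed: int | None, timings: dict[str, float]
) -> None:
    """Record enough (config echo, seed, version) to re-execute the run."""
    manifest = {
        "package": "bayesrma",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict(),
        "timings_seconds": timings,
    }
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2)
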