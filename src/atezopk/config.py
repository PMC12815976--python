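"""Run configuration: one YAML file drives the whole pipeline.

A fully worked default is shipped with the package (``atezopk/data/
default.yaml``); its PK parameter block is transcribed from the published
atezolizumab population-PK model and annotated as externally sourced.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import yaml

from .dosing import DEFAULT_INFUSION_DAYS, Regimen, builtin_regimens
from .engine import DEFAULT_GRID_RESOLUTION
from .pkmodel import CovariateEffect, IIVSpec, ModelConfig, StructuralParams
from .population import PopulationSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config", "config_from_dict"]


class ConfigError(ValueError):
    """The configuration file is missing, unreadable, or invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end run."""

    population: PopulationSpec
    model: ModelConfig
    regimens: tuple
    resolution: float = DEFAULT_GRID_RESOLUTION
    infusion_duration: float = DEFAULT_INFUSION_DAYS
    seed: int = 0
    mec: float = 6.0
    output_dir: str = "output"

    def __post_init__(self) -> None:
        if self.mec <= 0:
            raise ConfigError(f"mec must be > 0, got {self.mec}")
        if self.resolution <= 0:
            raise ConfigError(f"grid resolution must be > 0, got {self.resolution}")
        if not self.regimens:
            raise ConfigError("at least one regimen is required")
        object.__setattr__(self, "regimens", tuple(self.regimens))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed),
                       population=replace(self.population, seed=int(seed)))


def _parse_regimen(entry) -> Regimen:
    builtins = builtin_regimens()
    if isinstance(entry, str):
        if entry not in builtins:
            raise ConfigError(f"unknown regimen {entry!r}; built-ins: {sorted(builtins)}")
        return builtins[entry]
    try:
        return Regimen(name=entry["name"], blocks=tuple(tuple(b) for b in entry["blocks"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid regimen definition {entry!r}: {exc}") from exc


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a parsed YAML mapping."""
    try:
        seed = int(raw.get("seed", 0))
        pop_raw = dict(raw.get("population", {}))
        pop_raw.setdefault("seed", seed)  # population inherits the master seed
        pop = PopulationSpec.from_dict(pop_raw)
        m = raw.get("model", {})
        structural = StructuralParams(**m["structural"])
        effects = tuple(CovariateEffect(**e) for e in m.get("covariates", []))
        iiv_raw = m.get("iiv", {})
        iiv = IIVSpec(omega_sq=dict(iiv_raw.get("omega_sq", {})),
                      correlation=iiv_raw.get("correlation"))
        model = ModelConfig(structural=structural, effects=effects, iiv=iiv)
        regimens = tuple(_parse_regimen(r) for r in raw.get("regimens", []))
        return RunConfig(
            population=pop,
            model=model,
            regimens=regimens,
            resolution=float(raw.get("grid", {}).get("resolution", DEFAULT_GRID_RESOLUTION)),
            infusion_duration=float(m.get("infusion_duration_days", DEFAULT_INFUSION_DAYS)),
            seed=seed,
            mec=float(raw.get("mec", 6.0)),
            output_dir=str(raw.get("output_dir", "output")),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path=None) -> RunConfig:
    """Load a YAML run configuration (the shipped default when path is None)."""
    if path is None:
        text = importlib.resources.files("atezopk").joinpath("data/default.yaml").read_text()
    else:
        try:
            with open(path) as fh:
                text = fh.read()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path or 'default config'}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def default_config() -> RunConfig:
    """The shipped study configuration."""
    return load_config(None)
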