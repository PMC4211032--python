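"""Configuration loading, validation and defaults.

A run is fully described by one YAML (or JSON) mapping with sections
``arms``, ``econ_params``, ``psa`` and ``cohort`` plus top-level ``seed``
and ``strict_accounting``.  The packaged default configuration reproduces
the published cost ledger verbatim; a user file only needs to state what it
overrides — it is deep-merged over the defaults.  Unknown keys are rejected.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cohort import CohortParams
from .costs import ArmModel, EconParams
from .sensitivity import PsaSpec

__all__ = [
    "ArmsConfig",
    "RunConfig",
    "ConfigError",
    "default_config_dict",
    "default_config",
    "load_config",
]

REQUIRED_SECTIONS = ("arms", "econ_params", "psa", "cohort")


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or validated."""


class ArmsConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    mobile: ArmModel
    in_person: ArmModel


class RunConfig(BaseModel):
    """Validated model configuration for one run."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    arms: ArmsConfig
    econ_params: EconParams
    psa: PsaSpec
    cohort: CohortParams
    seed: int = Field(default=0, ge=0)
    strict_accounting: bool = False

    def with_seed(self, seed: int) -> "RunConfig":
        """Copy of this config with every stochastic seed replaced."""
        data = self.model_dump(mode="python")
        data["seed"] = seed
        data["psa"]["seed"] = seed
        data["cohort"]["seed"] = seed
        return RunConfig.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def default_config_dict() -> dict:
    """The packaged default configuration as a plain mapping."""
    text = resources.files("ambucea").joinpath("data/default.yaml").read_text()
    return yaml.safe_load(text)


def default_config() -> RunConfig:
    """The packaged default configuration, validated."""
    return RunConfig.model_validate(default_config_dict())


def _deep_merge(base: dict, override: Mapping[str, Any]) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path, fill_defaults: bool = True) -> RunConfig:
    """Load and validate a configuration file.

    The file must contain a non-empty mapping; with ``fill_defaults`` (the
    default) it is deep-merged over the packaged defaults, so partial
    configurations are valid.  An empty document is an error naming the
    required sections.  Validation failures are re-raised as
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigError(
            f"{path} is empty; required sections: {', '.join(REQUIRED_SECTIONS)}"
        )
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path} must contain a mapping at top level")

    data = _deep_merge(default_config_dict(), raw) if fill_defaults else dict(raw)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration in {path} at: {locs}\n{exc}") from exc
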