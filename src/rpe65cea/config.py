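"""Scenario configuration: defaults, YAML loading, strict validation.

Every model parameter lives in one :class:`ScenarioConfig` tree whose
defaults are the published base case, so an empty configuration file
reproduces the base-case setup.  Loading is strict: unknown keys and
invariant violations raise :class:`~rpe65cea.errors.ConfigError` naming
the offending key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, is_dataclass

import yaml

from .costing import (DirectCostSchedule, DiscountParams, IndirectCostTable)
from .disease import (EffectScenario, ProgressionParams, TrialEffects,
                      UtilityParams)
from .errors import ConfigError
from .mortality import GompertzMakehamParams
from .population import CohortSpec


@dataclass(frozen=True)
class MortalityConfig:
    """Life-table source: a CSV path, or the synthetic generator params."""

    life_table_path: str | None = None
    gompertz_makeham: GompertzMakehamParams = field(
        default_factory=GompertzMakehamParams
    )
    sex_ratio_adjust: float = 1.6

    def __post_init__(self) -> None:
        if self.sex_ratio_adjust <= 0:
            raise ConfigError("sex_ratio_adjust must be > 0")


@dataclass(frozen=True)
class CostParams:
    """Direct schedule, indirect band table, discounting, and switches."""

    direct: DirectCostSchedule = field(default_factory=DirectCostSchedule)
    indirect: IndirectCostTable = field(default_factory=IndirectCostTable)
    discount: DiscountParams = field(default_factory=DiscountParams)
    include_indirect: bool = True
    indirect_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.indirect_mode not in ("mean", "sampled"):
            raise ConfigError(
                f"indirect_mode must be 'mean' or 'sampled', got {self.indirect_mode!r}"
            )


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterisation of one simulation scenario."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    progression: ProgressionParams = field(default_factory=ProgressionParams)
    effects: TrialEffects = field(default_factory=TrialEffects)
    scenario: EffectScenario = field(default_factory=EffectScenario)
    utility: UtilityParams = field(default_factory=UtilityParams)
    costs: CostParams = field(default_factory=CostParams)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    n_sims: int = 1000
    master_seed: int = 20_200_810
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigError(f"n_sims must be >= 1, got {self.n_sims}")
        if self.max_age < 1:
            raise ConfigError(f"max_age must be >= 1, got {self.max_age}")


def default_config() -> ScenarioConfig:
    """The base-case configuration (all published defaults)."""
    return ScenarioConfig()


_TUPLE_FIELDS = {"age_range", "onset_window", "bcva_bounds"}


def _build(cls, data, loc: str):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{loc}: expected a mapping, got {type(data).__name__}")
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(field_map))
    if unknown:
        raise ConfigError(f"{loc}: unknown key(s) {unknown}")
    kwargs = {}
    for name, value in data.items():
        f = field_map[name]
        default = _field_default(f)
        if is_dataclass(default):
            kwargs[name] = _build(type(default), value, f"{loc}.{name}")
        elif name in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"{loc}.{name}: expected a 2-element list")
            kwargs[name] = (float(value[0]), float(value[1]))
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except ConfigError as exc:
        raise ConfigError(f"{loc}: {exc}") from None
    except TypeError as exc:
        raise ConfigError(f"{loc}: {exc}") from None


def _field_default(f: dataclasses.Field):
    if f.default is not dataclasses.MISSING:
        return f.default
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        return f.default_factory()  # type: ignore[misc]
    return None


def config_from_mapping(data: dict | None) -> ScenarioConfig:
    """Build a validated config from a (possibly partial) nested mapping."""
    return _build(ScenarioConfig, data, "config")


def load_config(path) -> ScenarioConfig:
    """Load a YAML (or JSON, a YAML subset) configuration file.

    An empty file yields the full default configuration.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_mapping(data)


def config_to_mapping(config: ScenarioConfig) -> dict:
    """Fully-resolved configuration as plain nested dicts/lists."""
    return json.loads(json.dumps(dataclasses.asdict(config)))


def dump_config(config: ScenarioConfig, path) -> None:
    """Write the fully-resolved configuration as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_mapping(config), fh, sort_keys=True)


def config_fingerprint(config: ScenarioConfig) -> str:
    """Stable hash of the fully-resolved configuration."""
    payload = json.dumps(config_to_mapping(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
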