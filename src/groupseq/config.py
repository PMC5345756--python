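"""YAML/JSON serialization for designs, rules and scenarios.

Configurations are plain mappings, e.g.::

    label: larger/freq_seq
    schedule:
      cumulative_n_per_group: [18, 36]
    rule:
      kind: freq_seq
      stage_alphas: [0.0065, 0.0525]
      futility_alpha: 0.5

and for effect-size scenarios::

    label: pessimistic
    support: [0.0, 0.5, 1.0]
    weights: [0.8, 0.15, 0.05]

Validation errors name the offending key.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import DesignSpec
from .rules import StoppingRule
from .schedule import StageSchedule
from .synthetic import EffectSizeScenario

__all__ = [
    "ConfigError",
    "rule_to_dict",
    "rule_from_dict",
    "design_to_dict",
    "design_from_dict",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_design",
    "dump_design",
    "load_scenario",
]

_RULE_FIELDS = (
    "kind",
    "alpha",
    "stage_alphas",
    "futility_alpha",
    "bf_success",
    "bf_futility",
    "bf_prior_scale",
    "cri_levels",
    "cri_futility_level",
)


class ConfigError(ValueError):
    """Malformed configuration mapping."""


def rule_to_dict(rule: StoppingRule) -> dict:
    out = {}
    for name in _RULE_FIELDS:
        value = getattr(rule, name)
        if value is None:
            continue
        out[name] = list(value) if isinstance(value, tuple) else value
    return out


def rule_from_dict(data: dict) -> StoppingRule:
    if not isinstance(data, dict) or "kind" not in data:
        raise ConfigError("rule must be a mapping with a 'kind' key")
    unknown = set(data) - set(_RULE_FIELDS)
    if unknown:
        raise ConfigError(f"unknown rule keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("stage_alphas", "cri_levels"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return StoppingRule(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid rule: {err}") from err


def design_to_dict(design: DesignSpec) -> dict:
    return {
        "label": design.label,
        "schedule": {
            "cumulative_n_per_group": list(design.schedule.cumulative_n_per_group)
        },
        "rule": rule_to_dict(design.rule),
    }


def design_from_dict(data: dict) -> DesignSpec:
    if not isinstance(data, dict):
        raise ConfigError("design must be a mapping")
    for key in ("schedule", "rule"):
        if key not in data:
            raise ConfigError(f"design is missing the {key!r} key")
    sched = data["schedule"]
    if not isinstance(sched, dict) or "cumulative_n_per_group" not in sched:
        raise ConfigError("schedule must be a mapping with 'cumulative_n_per_group'")
    try:
        schedule = StageSchedule(tuple(sched["cumulative_n_per_group"]))
    except ValueError as err:
        raise ConfigError(f"invalid schedule: {err}") from err
    rule = rule_from_dict(data["rule"])
    try:
        return DesignSpec(schedule=schedule, rule=rule, label=data.get("label", ""))
    except ValueError as err:
        raise ConfigError(f"incompatible design: {err}") from err


def scenario_to_dict(scenario: EffectSizeScenario) -> dict:
    return {
        "label": scenario.label,
        "support": list(scenario.support),
        "weights": list(scenario.weights),
    }


def scenario_from_dict(data: dict) -> EffectSizeScenario:
    if not isinstance(data, dict):
        raise ConfigError("scenario must be a mapping")
    for key in ("support", "weights"):
        if key not in data:
            raise ConfigError(f"scenario is missing the {key!r} key")
    try:
        return EffectSizeScenario(
            support=tuple(data["support"]),
            weights=tuple(data["weights"]),
            label=data.get("label", "custom"),
        )
    except ValueError as err:
        raise ConfigError(f"invalid scenario: {err}") from err


def load_design(path: str | Path) -> DesignSpec:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def dump_design(design: DesignSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_scenario(path: str | Path) -> EffectSizeScenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
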