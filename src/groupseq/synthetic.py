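"""Synthetic staged two-group data and effect-size prior scenarios.

The simulation setting mirrors a typical small-animal two-group experiment:
outcomes are normal with common unit standard deviation, group A centred at
0 and group B shifted by ``true_d * sd`` (so ``true_d`` is Cohen's d), and
observations arrive in preplanned per-stage batches.  Effect-size scenarios
are discrete priors over the true d, used for the predictive-value analysis.

Stage data are incremental: the data available at stage k+1 extend — never
modify — the data at stage k, and the whole stream is reproducible from the
scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np

from .schedule import StageSchedule

__all__ = [
    "SimulationScenario",
    "StageDataset",
    "EffectSizeScenario",
    "generate_trial_data",
    "sample_true_effect",
    "OPTIMISTIC_SCENARIO",
    "PESSIMISTIC_SCENARIO",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class SimulationScenario:
    """One simulated experiment's data-generating configuration."""

    true_d: float
    schedule: StageSchedule
    sd: float = 1.0
    seed: SeedLike = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.true_d):
            raise ValueError("true_d must be finite")
        if not self.sd > 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class StageDataset:
    """Cumulative data available at one analysis stage (1-based index)."""

    stage_index: int
    group_a: np.ndarray
    group_b: np.ndarray


def generate_trial_data(scenario: SimulationScenario) -> Iterator[StageDataset]:
    """Yield the cumulative dataset at each stage of one trial.

    Group A is drawn from Normal(0, sd), group B from Normal(true_d * sd, sd),
    in batches sized by the schedule.  Deterministic given ``scenario.seed``.
    """
    rng = (
        scenario.seed
        if isinstance(scenario.seed, np.random.Generator)
        else np.random.default_rng(scenario.seed)
    )
    sd = scenario.sd
    shift = scenario.true_d * sd
    a_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    for k, batch in enumerate(scenario.schedule.stage_batch_sizes(), start=1):
        a_parts.append(rng.normal(0.0, sd, size=batch))
        b_parts.append(rng.normal(shift, sd, size=batch))
        yield StageDataset(
            stage_index=k,
            group_a=np.concatenate(a_parts),
            group_b=np.concatenate(b_parts),
        )


@dataclass(frozen=True)
class EffectSizeScenario:
    """Discrete prior over the true standardized effect size.

    The preset weights below are placeholders for a field's effect-size
    landscape ("optimistic": larger effects common; "pessimistic": mostly
    null effects); they are not canonical and are meant to be overridden
    with field-specific distributions.
    """

    support: tuple[float, ...]
    weights: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(self.support) == 0:
            raise ValueError("scenario support must be non-empty")
        if len(self.support) != len(self.weights):
            raise ValueError("support and weights must have equal length")
        s = np.asarray(self.support, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if np.any(s < 0):
            raise ValueError("support values must be nonnegative effect sizes")
        if len(np.unique(s)) != len(s) or np.any(np.diff(s) <= 0):
            raise ValueError("support values must be distinct and sorted")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "support", tuple(float(v) for v in s))
        object.__setattr__(self, "weights", tuple(float(v) for v in w))


OPTIMISTIC_SCENARIO = EffectSizeScenario(
    support=(0.0, 0.5, 1.0), weights=(0.3, 0.3, 0.4), label="optimistic"
)
PESSIMISTIC_SCENARIO = EffectSizeScenario(
    support=(0.0, 0.5, 1.0), weights=(0.8, 0.15, 0.05), label="pessimistic"
)


def sample_true_effect(
    scenario: EffectSizeScenario, seed: SeedLike, size: int | None = None
):
    """Draw true effect size(s) from a discrete scenario distribution."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.choice(scenario.support, size=size, p=scenario.weights)
    return float(draws) if size is None else draws
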