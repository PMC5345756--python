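"""Run one staged experiment under a design (schedule + stopping rule)."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .rules import Action, StoppingRule, two_sample_t
from .schedule import StageSchedule
from .synthetic import SimulationScenario, generate_trial_data

__all__ = ["DesignSpec", "TrialOutcome", "run_trial"]


@dataclass(frozen=True)
class DesignSpec:
    """A stage schedule paired with a stopping rule."""

    schedule: StageSchedule
    rule: StoppingRule
    label: str = ""

    def __post_init__(self) -> None:
        required = self.rule.n_stages_required
        if required is not None and required != self.schedule.n_stages:
            raise ValueError(
                f"rule defines thresholds for {required} stages but the "
                f"schedule has {self.schedule.n_stages}"
            )


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one simulated staged experiment.

    ``d_est`` is the Cohen's d estimate from the analysis at the stopping
    stage (not re-estimated on later data), so selection effects on the
    estimate are visible.  ``animals_used`` is twice the cumulative
    per-group sample size at the stopping stage.
    """

    decision: str  # {"significant", "futile", "nonsignificant"}
    stop_stage: int
    animals_used: int
    d_est: float
    seed: int = 0


_DECISION_OF_ACTION = {
    Action.STOP_EFFICACY: "significant",
    Action.STOP_FUTILITY: "futile",
    Action.FINAL_NONSIGNIFICANT: "nonsignificant",
}


def run_trial(
    design: DesignSpec, scenario: SimulationScenario, trial_index: int = 0
) -> TrialOutcome:
    """Simulate one trial: accumulate stage data, analyse, apply the rule.

    Stops at the first stop decision; the final stage never continues.
    """
    if scenario.schedule != design.schedule:
        raise ValueError("design and scenario schedules differ")
    n_stages = design.schedule.n_stages
    for stage_data in generate_trial_data(scenario):
        k = stage_data.stage_index
        stats = two_sample_t(stage_data.group_a, stage_data.group_b)
        decision = design.rule.decide(stats, k, n_stages)
        if decision.action is not Action.CONTINUE:
            return TrialOutcome(
                decision=_DECISION_OF_ACTION[decision.action],
                stop_stage=k,
                animals_used=design.schedule.animals_used(k),
                d_est=stats.d_hat,
                seed=trial_index,
            )
    raise AssertionError("rule continued past the final stage")  # pragma: no cover


def with_schedule(design: DesignSpec, schedule: StageSchedule) -> DesignSpec:
    """Convenience: the same rule on a different schedule."""
    return replace(design, schedule=schedule)
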