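"""Predictive value of a significant result under effect-size prior scenarios.

In practice the true effect size behind an experiment is unknown; what a
field controls is its distribution of true effects across the experiments it
runs.  Given such a discrete prior, this module estimates, for a design:

* P(significant) — the marginal probability of a significant result,
* PPV(d != 0)    — the probability that a significant result corresponds to
                   a truly nonzero effect,
* PPV(d >= 0.5)  — likewise for an effect of at least 0.5,
* their products — the overall probability of obtaining a significant result
                   that truly represents an effect.

Classification uses the *true* drawn effect, not the estimate.  Alongside
the direct Monte-Carlo estimates, a semi-analytic composition
sum_d w_d * power(d) from per-effect Monte-Carlo power estimates is returned
as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import DesignSpec, run_trial
from .mc import estimate_operating_characteristics
from .synthetic import EffectSizeScenario, SimulationScenario, sample_true_effect

__all__ = ["PpvResult", "ppv_analysis"]


@dataclass(frozen=True)
class PpvResult:
    design_label: str
    scenario_label: str
    n_reps: int
    n_significant: int
    p_significant: float
    ppv_any: float
    ppv_ge_half: float
    p_detect_any: float
    p_detect_ge_half: float
    per_d_power: dict[float, float]
    p_significant_composed: float

    def as_dict(self) -> dict:
        return {
            "design": self.design_label,
            "scenario": self.scenario_label,
            "n_reps": self.n_reps,
            "n_significant": self.n_significant,
            "p_significant": self.p_significant,
            "ppv_any": self.ppv_any,
            "ppv_ge_half": self.ppv_ge_half,
            "p_detect_any": self.p_detect_any,
            "p_detect_ge_half": self.p_detect_ge_half,
            "per_d_power": {str(k): v for k, v in self.per_d_power.items()},
            "p_significant_composed": self.p_significant_composed,
        }


def ppv_analysis(
    design: DesignSpec,
    scenario: EffectSizeScenario,
    n_reps: int,
    seed: int,
    power_reps: int | None = None,
) -> PpvResult:
    """Estimate P(significant) and positive predictive values by simulation.

    Each replicate draws a true effect size from the scenario, runs one trial
    under the design, and records the (true d, decision) pair.  When no trial
    is significant the PPVs are undefined and returned as NaN, with
    ``n_significant`` making the condition explicit.

    ``power_reps`` controls the independent per-effect power runs used for
    the semi-analytic composition (defaults to ``n_reps``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.SeedSequence(seed)
    d_rng = np.random.default_rng(master.spawn(1)[0])
    true_ds = sample_true_effect(scenario, d_rng, size=n_reps)
    children = master.spawn(n_reps)
    significant = np.empty(n_reps, dtype=bool)
    for i, (d_i, child) in enumerate(zip(true_ds, children)):
        sim = SimulationScenario(
            true_d=float(d_i), schedule=design.schedule, seed=child
        )
        outcome = run_trial(design, sim, trial_index=i)
        significant[i] = outcome.decision == "significant"

    n_sig = int(significant.sum())
    p_sig = n_sig / n_reps
    if n_sig > 0:
        ppv_any = float(np.mean(true_ds[significant] != 0.0))
        ppv_ge_half = float(np.mean(true_ds[significant] >= 0.5))
    else:
        ppv_any = ppv_ge_half = float("nan")

    power_reps = n_reps if power_reps is None else power_reps
    per_d_power: dict[float, float] = {}
    power_seeds = master.generate_state(len(scenario.support)) % (2**31)
    for d_val, pseed in zip(scenario.support, power_seeds):
        oc = estimate_operating_characteristics(
            design, true_d=d_val, n_reps=power_reps, seed=int(pseed)
        )
        per_d_power[d_val] = oc.overall_significant_pct / 100.0
    composed = float(
        sum(w * per_d_power[d] for d, w in zip(scenario.support, scenario.weights))
    )

    return PpvResult(
        design_label=design.label,
        scenario_label=scenario.label,
        n_reps=n_reps,
        n_significant=n_sig,
        p_significant=p_sig,
        ppv_any=ppv_any,
        ppv_ge_half=ppv_ge_half,
        p_detect_any=p_sig * ppv_any if n_sig > 0 else float("nan"),
        p_detect_ge_half=p_sig * ppv_ge_half if n_sig > 0 else float("nan"),
        per_d_power=per_d_power,
        p_significant_composed=composed,
    )
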