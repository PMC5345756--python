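"""Simulation-based calibration of stopping thresholds to a target type I error.

A single free threshold parameter of a design is tuned so that the
Monte-Carlo type I error (the probability of a significant result at d = 0)
hits a target, by monotone bisection on a *fixed* stream of simulated trials
(common random numbers).  On a fixed stream the achieved rate is a monotone
step function of the threshold, so bisection terminates either inside the
tolerance or when the parameter interval has collapsed onto a step.

Supported free parameters:

* ``"alpha"``      — the single significance level of a fixed (one-look)
                     design; the achieved rate is increasing in alpha.
* ``"bf_success"`` — the Bayes-factor efficacy threshold applied at every
                     stage; the achieved rate is decreasing in the threshold.
* ``"cri_level"``  — the credible level of all looks after the first (the
                     first-look level stays at its configured value); the
                     achieved rate is decreasing in the level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import DesignSpec
from .mc import StageStatArrays, apply_rule_matrix, bf_matrix_for, simulate_stage_statistics
from .rules import StoppingRule

__all__ = ["CalibrationSpec", "CalibrationResult", "CalibrationError", "calibrate"]


class CalibrationError(RuntimeError):
    """Target type I error not attainable on the search interval."""


@dataclass(frozen=True)
class CalibrationSpec:
    design: DesignSpec
    free_parameter: str  # {"alpha", "bf_success", "cri_level"}
    bounds: tuple[float, float]
    target_alpha: float = 0.05
    tolerance: float = 0.0025
    n_reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.free_parameter not in ("alpha", "bf_success", "cri_level"):
            raise ValueError(f"unknown free parameter {self.free_parameter!r}")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy lo < hi")
        if not 0 < self.target_alpha < 1:
            raise ValueError("target_alpha must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    rule: StoppingRule
    parameter_value: float
    achieved_alpha: float
    monte_carlo_se: float
    target_alpha: float
    n_reps: int
    n_evaluations: int


def _rule_with(rule: StoppingRule, free: str, value: float) -> StoppingRule:
    if free == "alpha":
        return replace(rule, alpha=value)
    if free == "bf_success":
        return replace(rule, bf_success=value)
    levels = (rule.cri_levels[0],) + (value,) * (len(rule.cri_levels) - 1)
    return replace(rule, cri_levels=levels)


def achieved_type_one_error(
    design: DesignSpec, arrs: StageStatArrays, bf_matrix=None
) -> float:
    """Fraction of significant trials on a precomputed null statistic stream."""
    significant, _ = apply_rule_matrix(design.rule, arrs, bf_matrix=bf_matrix)
    return float(np.mean(significant))


def calibrate(spec: CalibrationSpec) -> CalibrationResult:
    """Tune the free threshold so the achieved type I error hits the target."""
    design = spec.design
    rule = design.rule
    arrs = simulate_stage_statistics(
        design.schedule, true_d=0.0, n_reps=spec.n_reps, seed=spec.seed
    )
    bf = (
        bf_matrix_for(arrs, rule.bf_prior_scale)
        if rule.kind == "bayes_factor"
        else None
    )

    n_eval = 0

    def achieved(value: float) -> float:
        nonlocal n_eval
        n_eval += 1
        candidate = _rule_with(rule, spec.free_parameter, value)
        sig, _ = apply_rule_matrix(candidate, arrs, bf_matrix=bf)
        return float(np.mean(sig))

    increasing = spec.free_parameter == "alpha"
    lo, hi = spec.bounds
    a_lo, a_hi = achieved(lo), achieved(hi)
    if not increasing:
        a_lo, a_hi = a_hi, a_lo  # rates at the loose/strict ends
    # a_lo is now the rate at the permissive end ordering: ensure bracketing
    lo_rate = min(a_lo, a_hi)
    hi_rate = max(a_lo, a_hi)
    if not lo_rate <= spec.target_alpha <= hi_rate:
        raise CalibrationError(
            f"target {spec.target_alpha} outside achieved range "
            f"[{lo_rate:.4f}, {hi_rate:.4f}] on bounds {spec.bounds}"
        )

    best_value, best_rate = None, None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = achieved(mid)
        if best_rate is None or abs(rate - spec.target_alpha) < abs(
            best_rate - spec.target_alpha
        ):
            best_value, best_rate = mid, rate
        if abs(rate - spec.target_alpha) <= spec.tolerance:
            best_value, best_rate = mid, rate
            break
        too_liberal = rate > spec.target_alpha
        if too_liberal == increasing:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9 * (spec.bounds[1] - spec.bounds[0]):
            break

    final_rule = _rule_with(rule, spec.free_parameter, best_value)
    se = float(np.sqrt(best_rate * (1 - best_rate) / spec.n_reps))
    return CalibrationResult(
        rule=final_rule,
        parameter_value=float(best_value),
        achieved_alpha=float(best_rate),
        monte_carlo_se=se,
        target_alpha=spec.target_alpha,
        n_reps=spec.n_reps,
        n_evaluations=n_eval,
    )
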