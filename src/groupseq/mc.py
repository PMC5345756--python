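"""Monte-Carlo operating characteristics and analytic power cross-checks.

``estimate_operating_characteristics`` runs independent trials through the
trial engine and aggregates them into the usual design summary: cumulative
per-stage stop-for-significance percentages, per-stage futility percentages,
overall power (or type I error at d = 0), mean animal cost, and the median
effect-size estimate among significant trials (the winner's-curse summary).

``simulate_stage_statistics`` is a vectorized generator of per-stage pooled-t
statistics for many trials at once; it is the common-random-number stream
used by threshold calibration, where only thresholds change between
candidate rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import nct
from scipy.stats import t as t_dist

from .bayes import bf10_from_t
from .engine import DesignSpec, TrialOutcome, run_trial
from .rules import StoppingRule
from .schedule import StageSchedule
from .synthetic import SimulationScenario

__all__ = [
    "OperatingCharacteristics",
    "estimate_operating_characteristics",
    "analytic_fixed_power",
    "winners_curse_summary",
    "StageStatArrays",
    "simulate_stage_statistics",
    "apply_rule_matrix",
    "run_table1",
]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated Monte-Carlo summary of one design under one true effect."""

    design_label: str
    true_d: float
    n_reps: int
    cumulative_significant_pct: tuple[float, ...]  # per stage, nondecreasing
    futility_pct: tuple[float, ...]  # per stage (non-cumulative)
    overall_significant_pct: float
    mean_cost: float
    median_d_est_significant: float | None
    monte_carlo_se_pct: float
    outcomes: tuple[TrialOutcome, ...] = field(
        default=(), repr=False, compare=False
    )


def winners_curse_summary(outcomes) -> float | None:
    """Median Cohen's d estimate among significant trials; None when empty."""
    d = [o.d_est for o in outcomes if o.decision == "significant"]
    if not d:
        return None
    return float(np.median(d))


def estimate_operating_characteristics(
    design: DesignSpec,
    true_d: float,
    n_reps: int,
    seed: int,
    sd: float = 1.0,
    keep_outcomes: bool = False,
) -> OperatingCharacteristics:
    """Run ``n_reps`` independent trials and aggregate.

    Per-trial seeds are spawned deterministically from the master seed, so
    every trial is individually reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    K = design.schedule.n_stages
    outcomes = []
    for i, child in enumerate(children):
        scenario = SimulationScenario(
            true_d=true_d, schedule=design.schedule, sd=sd, seed=child
        )
        outcomes.append(run_trial(design, scenario, trial_index=i))

    sig_stage = np.array(
        [o.stop_stage if o.decision == "significant" else 0 for o in outcomes]
    )
    fut_stage = np.array(
        [o.stop_stage if o.decision == "futile" else 0 for o in outcomes]
    )
    cum_sig = tuple(
        100.0 * np.mean((sig_stage > 0) & (sig_stage <= k)) for k in range(1, K + 1)
    )
    fut = tuple(100.0 * np.mean(fut_stage == k) for k in range(1, K + 1))
    overall = cum_sig[-1]
    p = overall / 100.0
    oc = OperatingCharacteristics(
        design_label=design.label,
        true_d=true_d,
        n_reps=n_reps,
        cumulative_significant_pct=cum_sig,
        futility_pct=fut,
        overall_significant_pct=overall,
        mean_cost=float(np.mean([o.animals_used for o in outcomes])),
        median_d_est_significant=winners_curse_summary(outcomes),
        monte_carlo_se_pct=float(100.0 * np.sqrt(p * (1 - p) / n_reps)),
    )
    return replace(oc, outcomes=tuple(outcomes)) if keep_outcomes else oc


def analytic_fixed_power(
    true_d: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Exact power of the two-sided pooled t test via the noncentral t.

    Noncentrality is d * sqrt(n / 2) with df = 2n - 2; at d = 0 this returns
    alpha exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    tcrit = t_dist.ppf(1 - alpha / 2, df)
    delta = true_d * np.sqrt(n_per_group / 2.0)
    if delta == 0.0:
        return float(alpha)
    return float(nct.sf(tcrit, df, delta) + nct.cdf(-tcrit, df, delta))


# ---------------------------------------------------------------------------
# Vectorized stage-statistic stream (common random numbers for calibration)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageStatArrays:
    """Per-stage pooled-t analyses for many simulated trials at once.

    Arrays have shape (n_reps, K).
    """

    schedule: StageSchedule
    true_d: float
    t: np.ndarray
    p: np.ndarray
    d_hat: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.t.shape[0]


def simulate_stage_statistics(
    schedule: StageSchedule,
    true_d: float,
    n_reps: int,
    seed: int,
    sd: float = 1.0,
) -> StageStatArrays:
    """Vectorized cumulative two-sample t statistics at every stage."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ns = schedule.cumulative_n_per_group
    n_final = ns[-1]
    a = rng.normal(0.0, sd, size=(n_reps, n_final))
    b = rng.normal(true_d * sd, sd, size=(n_reps, n_final))
    K = schedule.n_stages
    t = np.empty((n_reps, K))
    p = np.empty((n_reps, K))
    d_hat = np.empty((n_reps, K))
    for k, n in enumerate(ns):
        ak, bk = a[:, :n], b[:, :n]
        df = 2 * n - 2
        sp2 = ((n - 1) * ak.var(1, ddof=1) + (n - 1) * bk.var(1, ddof=1)) / df
        sp = np.sqrt(sp2)
        md = bk.mean(1) - ak.mean(1)
        tk = md / (sp * np.sqrt(2.0 / n))
        t[:, k] = tk
        p[:, k] = 2.0 * t_dist.sf(np.abs(tk), df)
        d_hat[:, k] = md / sp
    return StageStatArrays(schedule=schedule, true_d=true_d, t=t, p=p, d_hat=d_hat)


def apply_rule_matrix(
    rule: StoppingRule,
    arrs: StageStatArrays,
    bf_matrix: np.ndarray | None = None,
):
    """Vectorized stagewise decisions over a stage-statistic stream.

    Returns ``(significant, stop_stage)``: a boolean array and the 1-based
    stopping stage per trial.  Semantics match ``StoppingRule.decide``
    applied stage by stage (efficacy checked before binding futility).
    For Bayes-factor rules a precomputed BF10 matrix may be supplied to
    avoid recomputation across calibration candidates.
    """
    K = arrs.t.shape[1]
    n = arrs.n_reps
    if rule.kind == "fixed":
        eff = np.zeros((n, K), dtype=bool)
        eff[:, -1] = arrs.p[:, -1] < rule.alpha
        fut = np.zeros((n, K), dtype=bool)
    elif rule.kind == "freq_seq":
        if len(rule.stage_alphas) != K:
            raise ValueError("stage alpha count mismatch")
        eff = arrs.p < np.asarray(rule.stage_alphas)[None, :]
        fut = np.zeros((n, K), dtype=bool)
        if rule.futility_alpha is not None:
            fut[:, :-1] = arrs.p[:, :-1] > rule.futility_alpha
    elif rule.kind == "bayes_factor":
        if bf_matrix is None:
            bf_matrix = bf_matrix_for(arrs, rule.bf_prior_scale)
        eff = bf_matrix >= rule.bf_success
        fut = np.zeros((n, K), dtype=bool)
        if rule.bf_futility is not None:
            fut[:, :-1] = bf_matrix[:, :-1] <= rule.bf_futility
    elif rule.kind == "credible_interval":
        if len(rule.cri_levels) != K:
            raise ValueError("credible level count mismatch")
        # zero outside the level-L interval <=> two-sided p < 1 - L
        eff = arrs.p < (1.0 - np.asarray(rule.cri_levels))[None, :]
        fut = np.zeros((n, K), dtype=bool)
        if rule.cri_futility_level is not None:
            fut[:, :-1] = arrs.p[:, :-1] > rule.cri_futility_level
    else:  # pragma: no cover
        raise ValueError(rule.kind)

    fut = fut & ~eff  # efficacy takes precedence within a stage
    stop = eff | fut
    stop[:, -1] = True  # final look always terminates
    stop_stage = 1 + np.argmax(stop, axis=1)
    first = stop_stage - 1
    rows = np.arange(n)
    significant = eff[rows, first]
    return significant, stop_stage


def bf_matrix_for(arrs: StageStatArrays, prior_scale: float) -> np.ndarray:
    """BF10 at every (trial, stage) of a stage-statistic stream."""
    ns = arrs.schedule.cumulative_n_per_group
    out = np.empty_like(arrs.t)
    for k, n in enumerate(ns):
        out[:, k] = bf10_from_t(arrs.t[:, k], n, n, prior_scale)
    return out


# ---------------------------------------------------------------------------
# Full operating-characteristics table
# ---------------------------------------------------------------------------


def run_table1(
    n_reps: int = 10_000,
    seed: int = 0,
    effect_sizes: tuple[float, ...] = (0.0, 0.5, 1.0),
) -> pd.DataFrame:
    """Operating characteristics for every (study size, effect, approach) cell.

    One row per cell: cumulative stagewise significance percentages, interim
    futility percentages, overall rate, mean animal cost, and median d
    estimate among significant trials.
    """
    from .designs import table1_designs

    rows = []
    ss = np.random.SeedSequence(seed)
    designs = table1_designs()
    cells = [
        (study, approach, d)
        for study in designs
        for d in effect_sizes
        for approach in designs[study]
    ]
    child_seeds = ss.generate_state(len(cells)) % (2**31)
    for (study, approach, d), cell_seed in zip(cells, child_seeds):
        design = designs[study][approach]
        oc = estimate_operating_characteristics(
            design, true_d=d, n_reps=n_reps, seed=int(cell_seed)
        )
        row = {
            "study": study,
            "approach": approach,
            "true_d": d,
            "n_reps": n_reps,
            "overall_significant_pct": round(oc.overall_significant_pct, 1),
            "mean_cost": round(oc.mean_cost),
            "median_d_est_significant": (
                None
                if oc.median_d_est_significant is None
                else round(oc.median_d_est_significant, 2)
            ),
            "cell_seed": int(cell_seed),
        }
        for k, v in enumerate(oc.cumulative_significant_pct, start=1):
            row[f"cum_significant_pct_stage{k}"] = round(v, 1)
        for k, v in enumerate(oc.futility_pct, start=1):
            if k < design.schedule.n_stages:
                row[f"futility_pct_stage{k}"] = round(v, 1)
        rows.append(row)
    return pd.DataFrame(rows)
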