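"""Per-stage statistics and the four stop/continue decision procedures.

Every design analyses the *cumulative* data at each preplanned look with a
pooled-variance two-sample t test and then applies one of four rules:

* ``fixed``       — classical block design: a single analysis at the final
                    sample size at level alpha.
* ``freq_seq``    — frequentist group sequential: stop for efficacy when the
                    stage p value falls below the stage's nominal level;
                    optionally stop for futility at interim looks when the
                    p value exceeds ``futility_alpha`` (binding).
* ``bayes_factor``— stop for efficacy when BF10 reaches ``bf_success``;
                    optionally stop for futility at interim looks when BF10
                    falls to ``bf_futility``.
* ``credible_interval`` — stop for efficacy when zero lies outside the
                    stage's central credible interval; optionally stop for
                    futility when zero lies inside the 50% (or configured)
                    interval at an interim look.

Futility boundaries are binding: a trial stopped for futility is never
reanalysed, which is what makes a final-stage nominal level above the
overall alpha admissible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import t as t_dist

from .bayes import DEFAULT_PRIOR_SCALE, credible_interval, jzs_bayes_factor

__all__ = [
    "StageStatistics",
    "StoppingRule",
    "Action",
    "StageDecision",
    "two_sample_t",
    "decide_freq_seq",
    "decide_bayes_factor",
    "decide_credible_interval",
]


class Action(str, Enum):
    STOP_EFFICACY = "stop_efficacy"
    STOP_FUTILITY = "stop_futility"
    CONTINUE = "continue"
    FINAL_NONSIGNIFICANT = "final_nonsignificant"


@dataclass(frozen=True)
class StageDecision:
    action: Action
    stage_index: int


@dataclass(frozen=True)
class StageStatistics:
    """Pooled two-sample t analysis of the cumulative data at one look."""

    n_a: int
    n_b: int
    mean_diff: float
    pooled_sd: float
    t_value: float
    df: int
    p_two_sided: float
    d_hat: float


def two_sample_t(group_a, group_b) -> StageStatistics:
    """Pooled-variance Student t test (two-sided) with Cohen's d estimate.

    ``d_hat`` is the mean difference divided by the pooled SD, without
    small-sample correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if min(n_a, n_b) < 2:
        raise ValueError("need at least two observations per group")
    df = n_a + n_b - 2
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
    if sp2 <= 0:
        raise ValueError("degenerate data: zero pooled variance")
    sp = np.sqrt(sp2)
    mean_diff = b.mean() - a.mean()
    se = sp * np.sqrt(1.0 / n_a + 1.0 / n_b)
    t_value = mean_diff / se
    p = 2.0 * t_dist.sf(abs(t_value), df)
    return StageStatistics(
        n_a=n_a,
        n_b=n_b,
        mean_diff=float(mean_diff),
        pooled_sd=float(sp),
        t_value=float(t_value),
        df=df,
        p_two_sided=float(min(p, 1.0)),
        d_hat=float(mean_diff / sp),
    )


@dataclass(frozen=True)
class StoppingRule:
    """Tagged union over the four analysis approaches.

    Exactly the fields relevant to ``kind`` are used:

    * fixed: ``alpha``
    * freq_seq: ``stage_alphas`` (one per stage), optional ``futility_alpha``
    * bayes_factor: ``bf_success``, optional ``bf_futility``,
      ``bf_prior_scale``
    * credible_interval: ``cri_levels`` (one per stage), optional
      ``cri_futility_level``
    """

    kind: str
    alpha: float | None = None
    stage_alphas: tuple[float, ...] | None = None
    futility_alpha: float | None = None
    bf_success: float | None = None
    bf_futility: float | None = None
    bf_prior_scale: float = DEFAULT_PRIOR_SCALE
    cri_levels: tuple[float, ...] | None = None
    cri_futility_level: float | None = None
    label: str = ""

    _KINDS = ("fixed", "freq_seq", "bayes_factor", "credible_interval")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "fixed":
            if self.alpha is None or not 0 < self.alpha < 1:
                raise ValueError("fixed rule needs alpha in (0, 1)")
        elif self.kind == "freq_seq":
            if not self.stage_alphas or any(
                not 0 < a < 1 for a in self.stage_alphas
            ):
                raise ValueError("freq_seq rule needs stage_alphas in (0, 1)")
            object.__setattr__(self, "stage_alphas", tuple(self.stage_alphas))
        elif self.kind == "bayes_factor":
            if self.bf_success is None or self.bf_success <= 0:
                raise ValueError("bayes_factor rule needs positive bf_success")
            if self.bf_futility is not None and self.bf_futility <= 0:
                raise ValueError("bf_futility must be positive when set")
        elif self.kind == "credible_interval":
            if not self.cri_levels or any(
                not 0 < lv < 1 for lv in self.cri_levels
            ):
                raise ValueError("credible_interval rule needs cri_levels in (0, 1)")
            object.__setattr__(self, "cri_levels", tuple(self.cri_levels))
        if self.futility_alpha is not None and not 0 < self.futility_alpha < 1:
            raise ValueError("futility_alpha must lie in (0, 1)")
        if self.cri_futility_level is not None and not 0 < self.cri_futility_level < 1:
            raise ValueError("cri_futility_level must lie in (0, 1)")
        if self.bf_prior_scale <= 0:
            raise ValueError("bf_prior_scale must be positive")

    @property
    def n_stages_required(self) -> int | None:
        """Stage count implied by per-stage threshold lists, if any."""
        if self.kind == "freq_seq":
            return len(self.stage_alphas)
        if self.kind == "credible_interval":
            return len(self.cri_levels)
        if self.kind == "fixed":
            return 1
        return None

    def decide(self, stats: StageStatistics, stage: int, n_stages: int) -> StageDecision:
        """Apply the rule to the stage-``stage`` analysis of a K-stage design."""
        if self.kind == "fixed":
            if stage != n_stages:
                return StageDecision(Action.CONTINUE, stage)
            action = (
                Action.STOP_EFFICACY
                if stats.p_two_sided < self.alpha
                else Action.FINAL_NONSIGNIFICANT
            )
            return StageDecision(action, stage)
        if self.kind == "freq_seq":
            return decide_freq_seq(stats, self, stage, n_stages)
        if self.kind == "bayes_factor":
            bf = jzs_bayes_factor(stats, self.bf_prior_scale)
            return decide_bayes_factor(bf, self, stage, n_stages)
        interval = credible_interval(stats, self.cri_levels[stage - 1])
        fut_interval = None
        if self.cri_futility_level is not None and stage < n_stages:
            fut_interval = credible_interval(stats, self.cri_futility_level)
        return decide_credible_interval(interval, fut_interval, stage, n_stages)


def _check_stage(stage: int, n_stages: int) -> None:
    if not 1 <= stage <= n_stages:
        raise ValueError(f"stage {stage} outside 1..{n_stages}")


def decide_freq_seq(
    stats: StageStatistics, rule: StoppingRule, stage: int, n_stages: int
) -> StageDecision:
    """Frequentist sequential decision at one look (binding futility)."""
    _check_stage(stage, n_stages)
    if len(rule.stage_alphas) != n_stages:
        raise ValueError("rule has a different number of stage alphas than stages")
    p = stats.p_two_sided
    if p < rule.stage_alphas[stage - 1]:
        return StageDecision(Action.STOP_EFFICACY, stage)
    if stage < n_stages:
        if rule.futility_alpha is not None and p > rule.futility_alpha:
            return StageDecision(Action.STOP_FUTILITY, stage)
        return StageDecision(Action.CONTINUE, stage)
    return StageDecision(Action.FINAL_NONSIGNIFICANT, stage)


def decide_bayes_factor(
    bf10: float, rule: StoppingRule, stage: int, n_stages: int
) -> StageDecision:
    """Threshold BF10 for efficacy / interim futility."""
    _check_stage(stage, n_stages)
    if bf10 >= rule.bf_success:
        return StageDecision(Action.STOP_EFFICACY, stage)
    if stage < n_stages:
        if rule.bf_futility is not None and bf10 <= rule.bf_futility:
            return StageDecision(Action.STOP_FUTILITY, stage)
        return StageDecision(Action.CONTINUE, stage)
    return StageDecision(Action.FINAL_NONSIGNIFICANT, stage)


def decide_credible_interval(
    interval: tuple[float, float],
    futility_interval: tuple[float, float] | None,
    stage: int,
    n_stages: int,
) -> StageDecision:
    """Stop for efficacy when zero is outside the stage credible interval.

    At interim looks, stop for futility when zero lies inside the (narrow)
    futility interval, when one is configured.
    """
    _check_stage(stage, n_stages)
    lo, hi = interval
    if lo > 0.0 or hi < 0.0:
        return StageDecision(Action.STOP_EFFICACY, stage)
    if stage < n_stages:
        if futility_interval is not None:
            flo, fhi = futility_interval
            if flo <= 0.0 <= fhi:
                return StageDecision(Action.STOP_FUTILITY, stage)
        return StageDecision(Action.CONTINUE, stage)
    return StageDecision(Action.FINAL_NONSIGNIFICANT, stage)
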