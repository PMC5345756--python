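"""Preset designs for the two simulated study sizes.

Two study templates are provided, each analysed with four approaches:

* Small study, 18 animals per group, three looks at 6/12/18 per group,
  stopping for significance only.  Stage alphas for the frequentist
  sequential rule are the published O'Brien–Fleming-type triple
  (0.0006, 0.0151, 0.0471); the Bayes factor rule stops at BF10 >= 3 at
  every stage; the credible-interval rule uses a 99.8% interval at stage 1
  and 96.8% at stages 2 and 3.
* Larger study, 36 animals per group, two looks at 18/36 per group,
  stopping for significance or (binding) futility.  Frequentist: futility
  at p > 0.5, stage alphas (0.0065, 0.0525); Bayes factor: success at 2,
  futility at 0.5; credible interval: 99% then 95%, futility when zero lies
  inside the 50% interval.

The stage alphas are taken verbatim as published design inputs; the
frequentist-sequential sets are simulation-calibrated so the overall type I
error is about 5% (see the calibration module for redoing that calibration).
"""

from __future__ import annotations

from .engine import DesignSpec
from .rules import StoppingRule
from .schedule import StageSchedule

__all__ = [
    "SMALL_SCHEDULE",
    "SMALL_FIXED_SCHEDULE",
    "LARGER_SCHEDULE",
    "LARGER_FIXED_SCHEDULE",
    "SMALL_STAGE_ALPHAS",
    "LARGER_STAGE_ALPHAS",
    "small_study_designs",
    "larger_study_designs",
    "table1_designs",
]

SMALL_SCHEDULE = StageSchedule((6, 12, 18))
SMALL_FIXED_SCHEDULE = StageSchedule((18,))
LARGER_SCHEDULE = StageSchedule((18, 36))
LARGER_FIXED_SCHEDULE = StageSchedule((36,))

SMALL_STAGE_ALPHAS = (0.0006, 0.0151, 0.0471)
LARGER_STAGE_ALPHAS = (0.0065, 0.0525)


def small_study_designs() -> dict[str, DesignSpec]:
    """The four analysis approaches for the 3-stage small study."""
    return {
        "freq_nonseq": DesignSpec(
            SMALL_FIXED_SCHEDULE,
            StoppingRule(kind="fixed", alpha=0.05),
            label="small/freq_nonseq",
        ),
        "freq_seq": DesignSpec(
            SMALL_SCHEDULE,
            StoppingRule(kind="freq_seq", stage_alphas=SMALL_STAGE_ALPHAS),
            label="small/freq_seq",
        ),
        "bayes_factor": DesignSpec(
            SMALL_SCHEDULE,
            StoppingRule(kind="bayes_factor", bf_success=3.0),
            label="small/bayes_factor",
        ),
        "credible_interval": DesignSpec(
            SMALL_SCHEDULE,
            StoppingRule(
                kind="credible_interval", cri_levels=(0.998, 0.968, 0.968)
            ),
            label="small/credible_interval",
        ),
    }


def larger_study_designs() -> dict[str, DesignSpec]:
    """The four approaches for the 2-stage larger study with futility."""
    return {
        "freq_nonseq": DesignSpec(
            LARGER_FIXED_SCHEDULE,
            StoppingRule(kind="fixed", alpha=0.05),
            label="larger/freq_nonseq",
        ),
        "freq_seq": DesignSpec(
            LARGER_SCHEDULE,
            StoppingRule(
                kind="freq_seq",
                stage_alphas=LARGER_STAGE_ALPHAS,
                futility_alpha=0.5,
            ),
            label="larger/freq_seq",
        ),
        "bayes_factor": DesignSpec(
            LARGER_SCHEDULE,
            StoppingRule(kind="bayes_factor", bf_success=2.0, bf_futility=0.5),
            label="larger/bayes_factor",
        ),
        "credible_interval": DesignSpec(
            LARGER_SCHEDULE,
            StoppingRule(
                kind="credible_interval",
                cri_levels=(0.99, 0.95),
                cri_futility_level=0.5,
            ),
            label="larger/credible_interval",
        ),
    }


def table1_designs() -> dict[str, dict[str, DesignSpec]]:
    """Both study sizes keyed as {"small": {...}, "larger": {...}}."""
    return {"small": small_study_designs(), "larger": larger_study_designs()}
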