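"""Stage schedules for group sequential designs.

A schedule fixes the preplanned cumulative per-group sample size at each
interim and final analysis ("look").  The information fraction at look k is
the cumulative sample size divided by the final sample size; under the
staged-sampling model the sequence of standardized test statistics
(Z_1, ..., Z_K) is multivariate normal with corr(Z_i, Z_j) = sqrt(t_i / t_j)
for i <= j, which is what the boundary computations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StageSchedule", "ScheduleError"]


class ScheduleError(ValueError):
    """Raised for malformed stage schedules."""


@dataclass(frozen=True)
class StageSchedule:
    """Cumulative per-group sample sizes at each analysis.

    Parameters
    ----------
    cumulative_n_per_group
        Strictly increasing positive integers, one per stage; the last entry
        is the final per-group sample size.
    """

    cumulative_n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        ns = tuple(int(n) for n in self.cumulative_n_per_group)
        object.__setattr__(self, "cumulative_n_per_group", ns)
        if len(ns) == 0:
            raise ScheduleError("schedule needs at least one stage")
        if ns[0] < 1:
            raise ScheduleError("per-group sample sizes must be positive")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ScheduleError(
                f"cumulative sample sizes must be strictly increasing, got {ns}"
            )

    @property
    def n_stages(self) -> int:
        return len(self.cumulative_n_per_group)

    @property
    def final_n_per_group(self) -> int:
        return self.cumulative_n_per_group[-1]

    @property
    def information_fractions(self) -> np.ndarray:
        """t_k = n_k / n_K; strictly increasing, ends at exactly 1.0."""
        ns = np.asarray(self.cumulative_n_per_group, dtype=float)
        return ns / ns[-1]

    def stage_batch_sizes(self) -> tuple[int, ...]:
        """Per-group number of new observations collected at each stage."""
        ns = self.cumulative_n_per_group
        return (ns[0],) + tuple(b - a for a, b in zip(ns, ns[1:]))

    def animals_used(self, stage: int) -> int:
        """Total experimental units consumed if the trial stops at ``stage`` (1-based)."""
        if not 1 <= stage <= self.n_stages:
            raise ScheduleError(f"stage {stage} outside 1..{self.n_stages}")
        return 2 * self.cumulative_n_per_group[stage - 1]

    @classmethod
    def from_fractions(cls, final_n_per_group: int, fractions) -> "StageSchedule":
        """Build a schedule from information fractions (last must be 1)."""
        ns = tuple(int(round(f * final_n_per_group)) for f in fractions)
        return cls(ns)
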