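"""Classic group sequential stopping boundaries.

Computes stagewise crossing probabilities for two-sided symmetric boundaries
on the z scale by the Armitage–McPherson recursion: the joint law of the
sequential statistics is that of a Brownian motion observed at the
information fractions, and the sub-density of the process restricted to the
continuation region is propagated stage by stage with Gauss–Legendre
quadrature.  Boundary families:

* O'Brien–Fleming: z_k = c * sqrt(K / k) — very conservative early, close to
  the unadjusted level at the final look.
* Pocock: constant z boundary, i.e. the same nominal level at every look.
* Haybittle–Peto: fixed stringent interim level 0.001, unadjusted final level
  (no exact recalibration; the overall size is slightly above the target).

Boundaries are computed on the z scale and converted to two-sided nominal
levels 2 * (1 - Phi(z_k)); in the simulated designs these levels are applied
to exact t-test p values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .schedule import ScheduleError, StageSchedule

__all__ = [
    "BoundarySpec",
    "crossing_probability",
    "obf_levels",
    "pocock_levels",
    "haybittle_peto_levels",
]

# Gauss-Legendre resolution per stage; 160 nodes reproduces published
# constants to well beyond 4 decimals.
_DEFAULT_NODES = 160


@dataclass(frozen=True)
class BoundarySpec:
    """A boundary family instantiated on a stage schedule.

    ``nominal_levels`` are the per-stage two-sided significance levels
    implied by the z-scale bounds; ``z_bounds`` are the bounds themselves.
    """

    family: str  # {"obf", "pocock", "haybittle_peto", "custom"}
    overall_alpha: float
    nominal_levels: tuple[float, ...]
    z_bounds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not all(0.0 < a < 1.0 for a in self.nominal_levels):
            raise ValueError("nominal levels must lie in (0, 1)")

    def to_records(self) -> list[dict]:
        """Plain-value export, one record per stage."""
        return [
            {
                "family": self.family,
                "alpha": self.overall_alpha,
                "stage": k + 1,
                "z_bound": float(self.z_bounds[k]) if self.z_bounds else None,
                "nominal_level": float(self.nominal_levels[k]),
            }
            for k in range(len(self.nominal_levels))
        ]


def _check_schedule(schedule: StageSchedule) -> np.ndarray:
    t = schedule.information_fractions
    if np.any(np.diff(t) <= 0):
        raise ScheduleError("information fractions must be strictly increasing")
    return t


def crossing_probability(
    z_bounds: Sequence[float],
    schedule: StageSchedule,
    drift: float = 0.0,
    n_nodes: int = _DEFAULT_NODES,
) -> np.ndarray:
    """Per-stage first-crossing probabilities of a two-sided boundary.

    Parameters
    ----------
    z_bounds
        Boundary on the z-statistic scale, one positive value per stage.
    schedule
        Stage schedule supplying the information fractions.
    drift
        Expected value of the final-stage z statistic; 0 gives type-I-error
        contributions.  For a two-group comparison with standardized effect d
        and final per-group size n, ``drift = d * sqrt(n / 2)``.

    Returns
    -------
    ndarray of length K; element k is the probability that the boundary is
    first crossed (in either direction) at stage k.  The sum over stages is
    the overall crossing probability.
    """
    t = _check_schedule(schedule)
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")
    b = np.asarray(z_bounds, dtype=float)
    if b.shape != t.shape:
        raise ValueError("need one z bound per stage")
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("z bounds must be finite and positive")

    # Work on the score scale S_k = Z_k * sqrt(t_k): independent Gaussian
    # increments with var dt and mean drift * dt (unit information at t=1).
    sb = b * np.sqrt(t)
    x, w = np.polynomial.legendre.leggauss(n_nodes)

    probs = np.empty(len(t))
    mu, sd = drift * t[0], np.sqrt(t[0])
    probs[0] = norm.sf((sb[0] - mu) / sd) + norm.cdf((-sb[0] - mu) / sd)
    grid = sb[0] * x  # nodes on the continuation interval (-sb[0], sb[0])
    weights = w * sb[0]
    dens = norm.pdf((grid - mu) / sd) / sd

    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        sdk = np.sqrt(dt)
        mk = drift * dt
        upper = norm.sf((sb[k] - grid - mk) / sdk)
        lower = norm.cdf((-sb[k] - grid - mk) / sdk)
        probs[k] = np.sum(weights * dens * (upper + lower))
        if k < len(t) - 1:
            new_grid = sb[k] * x
            kern = norm.pdf((new_grid[:, None] - grid[None, :] - mk) / sdk) / sdk
            dens = kern @ (weights * dens)
            grid, weights = new_grid, w * sb[k]
    return probs


def _equal_schedule(K: int) -> StageSchedule:
    return StageSchedule(tuple(range(1, K + 1)))


def _solve_constant(
    shape: np.ndarray, schedule: StageSchedule, overall_alpha: float
) -> float:
    """Find c such that bounds c * shape have total crossing overall_alpha."""

    def excess(c: float) -> float:
        return crossing_probability(c * shape, schedule).sum() - overall_alpha

    try:
        return brentq(excess, 1.0, 6.0, xtol=1e-10)
    except ValueError as err:  # pragma: no cover - non-bracketing
        raise RuntimeError(
            f"boundary constant not bracketed in [1, 6] for alpha={overall_alpha}"
        ) from err


def _validate_alpha(overall_alpha: float) -> None:
    if not 0.0 < overall_alpha < 0.5:
        raise ValueError("overall_alpha must lie in (0, 0.5)")


def obf_levels(
    K: int, overall_alpha: float = 0.05, schedule: StageSchedule | None = None
) -> BoundarySpec:
    """O'Brien–Fleming nominal levels for K looks at overall two-sided alpha.

    The boundary z_k = c * sqrt(t_K / t_k) is scaled so that the total
    two-sided crossing probability equals ``overall_alpha`` exactly (to the
    accuracy of the recursion); the per-stage nominal level is 2*(1-Phi(z_k)).
    """
    _validate_alpha(overall_alpha)
    if K < 1:
        raise ValueError("K must be >= 1")
    schedule = schedule or _equal_schedule(K)
    if schedule.n_stages != K:
        raise ScheduleError("schedule has a different number of stages than K")
    t = _check_schedule(schedule)
    shape = 1.0 / np.sqrt(t)  # equal fractions: sqrt(K / k)
    if K == 1:
        z = np.array([norm.isf(overall_alpha / 2)])
    else:
        c = _solve_constant(shape, schedule, overall_alpha)
        z = c * shape
    return BoundarySpec(
        family="obf",
        overall_alpha=overall_alpha,
        nominal_levels=tuple(2 * norm.sf(z)),
        z_bounds=tuple(z),
    )


def pocock_levels(
    K: int, overall_alpha: float = 0.05, schedule: StageSchedule | None = None
) -> BoundarySpec:
    """Pocock boundary: the same nominal significance level at every look."""
    _validate_alpha(overall_alpha)
    if K < 1:
        raise ValueError("K must be >= 1")
    schedule = schedule or _equal_schedule(K)
    if schedule.n_stages != K:
        raise ScheduleError("schedule has a different number of stages than K")
    shape = np.ones(K)
    if K == 1:
        z = np.array([norm.isf(overall_alpha / 2)])
    else:
        c = _solve_constant(shape, schedule, overall_alpha)
        z = c * shape
    return BoundarySpec(
        family="pocock",
        overall_alpha=overall_alpha,
        nominal_levels=tuple(2 * norm.sf(z)),
        z_bounds=tuple(z),
    )


def haybittle_peto_levels(K: int, overall_alpha: float = 0.05) -> BoundarySpec:
    """Haybittle–Peto rule: interim levels 0.001, unadjusted final level.

    There is no recalibration, so the overall size slightly exceeds
    ``overall_alpha`` (for K=3, alpha=0.05 it is just above 0.05 and below
    0.052).
    """
    _validate_alpha(overall_alpha)
    if K < 2:
        raise ValueError("Haybittle–Peto needs at least one interim look (K >= 2)")
    levels = (0.001,) * (K - 1) + (overall_alpha,)
    z = tuple(norm.isf(a / 2) for a in levels)
    return BoundarySpec(
        family="haybittle_peto",
        overall_alpha=overall_alpha,
        nominal_levels=levels,
        z_bounds=z,
    )
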