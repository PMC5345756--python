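"""Default Bayes factor and noninformative-prior credible interval.

The Bayes factor is the two-sample Jeffreys–Zellner–Siow (JZS) default test:
under H1 the standardized effect d carries a Cauchy(0, r) prior (default
r = sqrt(2)/2) and the nuisance variance a Jeffreys prior; under H0, d = 0.
Writing the Cauchy as a scale mixture of normals, BF10 reduces to a
one-dimensional integral over the mixing variance g,

    BF10(t) = int_0^inf (1 + N g)^(-1/2)
              * [ (1 + t^2 / (nu (1 + N g))) / (1 + t^2 / nu) ]^(-(nu+1)/2)
              * r / sqrt(2 pi) * (g / r^2)^(-3/2) / r^2 * exp(-r^2 / (2 g)) dg

with nu = n_a + n_b - 2 and effective sample size N = n_a n_b / (n_a + n_b).
It is evaluated with Gauss–Legendre quadrature after mapping g = u / (1 - u),
which is accurate to ~1e-9 relative for the sample sizes used here.

The credible interval for the mean difference under the Jeffreys prior is
the shifted/scaled Student-t posterior interval, so exclusion of zero at
level L is equivalent to a two-sided p value below 1 - L; the interval is
returned on the Cohen's d scale (divided by the pooled SD).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist

__all__ = ["jzs_bayes_factor", "bf10_from_t", "credible_interval"]

DEFAULT_PRIOR_SCALE = float(np.sqrt(2) / 2)

_N_NODES = 512
_U, _W = np.polynomial.legendre.leggauss(_N_NODES)
# map [-1, 1] -> (0, 1) -> g in (0, inf)
_UU = 0.5 * (_U + 1.0)
_G = _UU / (1.0 - _UU)
_JAC = 0.5 / (1.0 - _UU) ** 2  # du/2 * dg/du


def bf10_from_t(t, n_a, n_b, prior_scale: float = DEFAULT_PRIOR_SCALE):
    """JZS Bayes factor BF10 for pooled-variance t statistic(s).

    Vectorized over ``t``.  Returns a scalar for scalar input.
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if min(n_a, n_b) < 2:
        raise ValueError("need at least two observations per group")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t statistics must be finite")
    nu = n_a + n_b - 2
    n_eff = n_a * n_b / (n_a + n_b)
    r2 = prior_scale**2

    g = _G[None, :]
    # inverse-gamma(1/2, r^2/2) mixing density
    log_prior = (
        -0.5 * np.log(2 * np.pi)
        + 0.5 * np.log(r2)
        - 1.5 * np.log(g)
        - r2 / (2 * g)
    )
    one_plus = 1.0 + n_eff * g
    tt = (t_arr**2)[:, None]
    log_lr = (
        -0.5 * np.log(one_plus)
        - 0.5 * (nu + 1) * np.log1p(tt / (nu * one_plus))
        + 0.5 * (nu + 1) * np.log1p(tt / nu)
    )
    vals = np.exp(log_lr + log_prior) * _JAC[None, :]
    bf = vals @ _W
    if np.any(~np.isfinite(bf)) or np.any(bf <= 0):
        raise ArithmeticError("Bayes factor quadrature failed to converge")
    return float(bf[0]) if np.isscalar(t) or np.ndim(t) == 0 else bf


def jzs_bayes_factor(stats, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """BF10 of the two-sided alternative over the point null for one analysis."""
    return bf10_from_t(stats.t_value, stats.n_a, stats.n_b, prior_scale)


def credible_interval(stats, level: float) -> tuple[float, float]:
    """Central posterior interval for the effect size d under a Jeffreys prior.

    The posterior of the mean difference is mean_diff + SE * t_df; the
    interval is scaled by the pooled SD so the endpoints are on the Cohen's d
    scale.  Zero is excluded at level L exactly when the two-sided t-test p
    value is below 1 - L.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if stats.pooled_sd <= 0:
        raise ValueError("degenerate data: pooled SD is zero")
    se = stats.pooled_sd * np.sqrt(1.0 / stats.n_a + 1.0 / stats.n_b)
    q = t_dist.ppf(0.5 + level / 2.0, stats.df)
    lo = (stats.mean_diff - q * se) / stats.pooled_sd
    hi = (stats.mean_diff + q * se) / stats.pooled_sd
    return float(lo), float(hi)
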