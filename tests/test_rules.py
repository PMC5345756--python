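"""Stage statistics, Bayes factor, credible intervals, and decisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from groupseq import (
    Action,
    StoppingRule,
    credible_interval,
    decide_bayes_factor,
    decide_credible_interval,
    decide_freq_seq,
    jzs_bayes_factor,
    two_sample_t,
)
from groupseq.bayes import bf10_from_t


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------


def test_identical_groups_give_null_statistics():
    s = two_sample_t([0, 0, 1, 1], [0, 0, 1, 1])
    assert s.t_value == 0.0
    assert s.p_two_sided == 1.0
    assert s.d_hat == 0.0
    assert s.df == 6


@pytest.mark.parametrize("seed", range(6))
def test_matches_textbook_formula_and_scipy(seed):
    r = np.random.default_rng(seed)
    a = r.normal(0, 1.3, size=r.integers(2, 25))
    b = r.normal(0.4, 1.3, size=r.integers(2, 25))
    s = two_sample_t(a, b)
    # independent recomputation via the pooled-t closed form + t CDF
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_manual = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert s.t_value == pytest.approx(t_manual, rel=1e-12)
    assert s.p_two_sided == pytest.approx(
        2 * sps.t.sf(abs(t_manual), na + nb - 2), rel=1e-12
    )
    res = sps.ttest_ind(b, a, equal_var=True)
    assert s.t_value == pytest.approx(res.statistic, rel=1e-10)
    assert s.p_two_sided == pytest.approx(res.pvalue, rel=1e-10)
    assert s.d_hat == pytest.approx((b.mean() - a.mean()) / np.sqrt(sp2), rel=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_label_swap_antisymmetry(seed):
    r = np.random.default_rng(seed)
    a = r.normal(size=5)
    b = r.normal(0.5, 1, size=7)
    s_ab, s_ba = two_sample_t(a, b), two_sample_t(b, a)
    assert s_ab.t_value == pytest.approx(-s_ba.t_value)
    assert s_ab.d_hat == pytest.approx(-s_ba.d_hat)
    assert s_ab.p_two_sided == pytest.approx(s_ba.p_two_sided)


def test_degenerate_data_rejected():
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        two_sample_t([1.0], [0.0, 1.0])


# ---------------------------------------------------------------------------
# frequentist sequential decisions
# ---------------------------------------------------------------------------


def _stats_with_p(p):
    """A StageStatistics carrier with a prescribed two-sided p value."""
    s = two_sample_t([0.0, 1.0, 2.0], [0.1, 1.1, 2.1])
    object.__setattr__(s, "p_two_sided", p)
    return s


SMALL_RULE = StoppingRule(kind="freq_seq", stage_alphas=(0.0006, 0.0151, 0.0471))
LARGER_RULE = StoppingRule(
    kind="freq_seq", stage_alphas=(0.0065, 0.0525), futility_alpha=0.5
)


@pytest.mark.parametrize(
    "p,rule,stage,K,expected",
    [
        (0.0001, SMALL_RULE, 1, 3, Action.STOP_EFFICACY),
        (0.6, LARGER_RULE, 1, 2, Action.STOP_FUTILITY),
        (0.03, SMALL_RULE, 2, 3, Action.CONTINUE),
        (0.03, SMALL_RULE, 3, 3, Action.STOP_EFFICACY),
        (0.6, SMALL_RULE, 1, 3, Action.CONTINUE),  # no futility in this design
        (0.2, SMALL_RULE, 3, 3, Action.FINAL_NONSIGNIFICANT),
    ],
)
def test_freq_seq_decisions(p, rule, stage, K, expected):
    assert decide_freq_seq(_stats_with_p(p), rule, stage, K).action is expected


def test_freq_seq_stage_bounds_checked():
    with pytest.raises(ValueError):
        decide_freq_seq(_stats_with_p(0.5), SMALL_RULE, 4, 3)


def test_decisions_are_pure():
    s = _stats_with_p(0.03)
    first = decide_freq_seq(s, SMALL_RULE, 2, 3)
    assert decide_freq_seq(s, SMALL_RULE, 2, 3) == first


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


def riemann_bf_oracle(t, n_a, n_b, r, n_grid=200_001):
    """Dense-grid Riemann sum of the Cauchy-prior marginal likelihood ratio.

    Integrates over d via the substitution d = r*tan(u) so the Cauchy tails
    are handled exactly; independent of the g-mixture route used by the
    implementation.  The grid is truncated where the noncentrality exceeds
    |t| + 40, beyond which the noncentral-t density underflows to zero.
    """
    nu = n_a + n_b - 2
    n_eff = n_a * n_b / (n_a + n_b)
    d_max = (abs(t) + 40.0) / np.sqrt(n_eff)
    u_max = np.arctan(d_max / r)
    u = np.linspace(-u_max, u_max, n_grid)
    d = r * np.tan(u)
    jac = r / np.cos(u) ** 2
    prior = sps.cauchy.pdf(d, 0, r)
    num = np.trapezoid(sps.nct.pdf(t, nu, d * np.sqrt(n_eff)) * prior * jac, u)
    return num / sps.t.pdf(t, nu)


def test_bf_below_one_when_data_match_null():
    for n in (4, 10, 30):
        assert bf10_from_t(0.0, n, n) < 1.0


def test_bf_strictly_increasing_in_abs_t():
    ts = np.linspace(0, 8, 33)
    bfs = bf10_from_t(ts, 9, 9)
    assert np.all(np.diff(bfs) > 0)
    np.testing.assert_allclose(bf10_from_t(-ts, 9, 9), bfs, rtol=1e-12)


def test_bf_quadrature_matches_riemann_oracle():
    """Gauss–Legendre g-integral vs a brute-force dense-grid oracle."""
    r = np.random.default_rng(12)
    for _ in range(20):
        t = float(r.uniform(-6, 6))
        n_a = int(r.integers(3, 40))
        n_b = int(r.integers(3, 40))
        scale = float(r.uniform(0.3, 1.2))
        ours = bf10_from_t(t, n_a, n_b, scale)
        oracle = riemann_bf_oracle(t, n_a, n_b, scale)
        assert ours == pytest.approx(oracle, rel=1e-6)


def test_jzs_wrapper_uses_stage_statistics(rng):
    a, b = rng.normal(size=8), rng.normal(1.0, 1, size=8)
    s = two_sample_t(a, b)
    assert jzs_bayes_factor(s) == pytest.approx(bf10_from_t(s.t_value, 8, 8))


BF_RULE = StoppingRule(kind="bayes_factor", bf_success=3.0)
BF_FUT_RULE = StoppingRule(kind="bayes_factor", bf_success=2.0, bf_futility=0.5)


@pytest.mark.parametrize(
    "bf,rule,stage,K,expected",
    [
        (3.5, BF_RULE, 1, 3, Action.STOP_EFFICACY),
        (0.4, BF_FUT_RULE, 1, 2, Action.STOP_FUTILITY),
        (1.0, BF_FUT_RULE, 1, 2, Action.CONTINUE),
        (1.0, BF_FUT_RULE, 2, 2, Action.FINAL_NONSIGNIFICANT),
        (0.4, BF_RULE, 1, 3, Action.CONTINUE),  # no futility threshold set
    ],
)
def test_bayes_factor_decisions(bf, rule, stage, K, expected):
    assert decide_bayes_factor(bf, rule, stage, K).action is expected


# ---------------------------------------------------------------------------
# credible intervals
# ---------------------------------------------------------------------------


def test_interval_symmetric_and_contains_zero_for_balanced_data():
    s = two_sample_t([0, 0, 1, 1], [0, 0, 1, 1])
    lo, hi = credible_interval(s, 0.95)
    assert lo == pytest.approx(-hi)
    assert lo < 0 < hi


def test_interval_zero_exclusion_equivalent_to_p_value(rng):
    """0 outside the level-L interval exactly when p < 1 - L."""
    for _ in range(200):
        a = rng.normal(size=int(rng.integers(3, 20)))
        b = rng.normal(rng.uniform(-1.5, 1.5), 1, size=int(rng.integers(3, 20)))
        s = two_sample_t(a, b)
        for level in (0.5, 0.95, 0.968, 0.998):
            lo, hi = credible_interval(s, level)
            excluded = lo > 0 or hi < 0
            assert excluded == (s.p_two_sided < 1 - level)


def test_interval_matches_posterior_sampling_oracle(rng):
    """Endpoints agree with 10^6 draws from the Jeffreys posterior."""
    a = rng.normal(size=10)
    b = rng.normal(0.8, 1, size=12)
    s = two_sample_t(a, b)
    n_draws = 1_000_000
    sigma2 = s.df * s.pooled_sd**2 / rng.chisquare(s.df, size=n_draws)
    delta = rng.normal(
        s.mean_diff, np.sqrt(sigma2 * (1 / s.n_a + 1 / s.n_b)), size=n_draws
    )
    d_draws = delta / s.pooled_sd
    lo, hi = credible_interval(s, 0.95)
    assert lo == pytest.approx(np.quantile(d_draws, 0.025), abs=0.01)
    assert hi == pytest.approx(np.quantile(d_draws, 0.975), abs=0.01)


def test_credible_interval_decisions():
    eff = decide_credible_interval((0.2, 1.4), None, 2, 3)
    assert eff.action is Action.STOP_EFFICACY
    fut = decide_credible_interval((-0.5, 1.0), (-0.1, 0.6), 1, 2)
    assert fut.action is Action.STOP_FUTILITY
    cont = decide_credible_interval((-0.5, 1.0), (0.05, 0.9), 1, 2)
    assert cont.action is Action.CONTINUE
    final = decide_credible_interval((-0.5, 1.0), None, 2, 2)
    assert final.action is Action.FINAL_NONSIGNIFICANT


def test_cri_rule_reproduces_stage_alphas(rng):
    """The 99.8%/96.8% levels act like stage alphas 0.002/0.032."""
    rule = StoppingRule(kind="credible_interval", cri_levels=(0.998, 0.968, 0.968))
    for _ in range(100):
        a = rng.normal(size=6)
        b = rng.normal(rng.uniform(-2, 2), 1, size=6)
        s = two_sample_t(a, b)
        dec = rule.decide(s, 1, 3)
        expect_stop = s.p_two_sided < 0.002
        assert (dec.action is Action.STOP_EFFICACY) == expect_stop


def test_rule_validation():
    with pytest.raises(ValueError):
        StoppingRule(kind="unknown")
    with pytest.raises(ValueError):
        StoppingRule(kind="fixed")
    with pytest.raises(ValueError):
        StoppingRule(kind="freq_seq", stage_alphas=(0.5, 1.5))
    with pytest.raises(ValueError):
        StoppingRule(kind="bayes_factor", bf_success=-1.0)
    with pytest.raises(ValueError):
        StoppingRule(kind="credible_interval", cri_levels=())
    with pytest.raises(ValueError):
        credible_interval(two_sample_t([0, 1, 2], [0, 1, 2]), 1.5)
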