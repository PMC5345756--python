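# Methods

## Setting and data model

The package simulates two-group comparisons as they are typically run in
preclinical laboratories: continuous outcomes, equal group sizes, and very
small n. Outcomes are normal with a common standard deviation σ (default 1);
group A is centred at 0 and group B at d·σ, so the true effect is the
standardized mean difference (Cohen's d). Data arrive in preplanned batches;
the analysis at look k uses all data accumulated so far. Batch or learning
effects across stages, attrition, unequal variances, and non-normal outcomes
are deliberately not modelled.

Every look is analysed with the pooled-variance two-sided Student t test.
The effect estimate d̂ is the mean difference divided by the pooled SD,
without the Hedges small-sample correction; its expectation at df = 34 is
about 1.02·d (tests verify this against the closed-form gamma-function
expectation).

Two study templates are preset. The *small study* observes 6/12/18 animals
per group over three looks and may stop early only for efficacy. The
*larger study* observes 18/36 per group over two looks and may also stop for
futility; futility stops are binding (never revisited), which is what makes
a final-stage nominal level slightly above the overall alpha admissible.

## Boundary computation

Under staged sampling the standardized statistics (Z_1, …, Z_K) at
information fractions t_k are jointly normal with corr(Z_i, Z_j) = √(t_i/t_j),
i.e. a Brownian motion observed at the t_k. First-crossing probabilities of
a two-sided boundary are computed by stagewise recursion on the score scale
S_k = Z_k√t_k: the sub-density of the process restricted to the continuation
region is propagated through the Gaussian increment kernel, with
Gauss–Legendre quadrature (160 nodes per stage) on each continuation
interval. Unequal information fractions are supported. Drift is
parameterized as the expected final-look z statistic; for a two-group design
with final per-group n, drift = d·√(n/2).

Boundary families solve for a single constant c by Brent root search on
c ∈ [1, 6] (tolerance 1e-10) so the total crossing probability equals the
overall alpha: O'Brien–Fleming uses z_k = c·√(t_K/t_k), Pocock a constant
boundary. Haybittle–Peto is not recalibrated (interim 0.001, final alpha),
so its overall size slightly exceeds the target — for three looks it lies
between 0.050 and 0.052. The recursion is validated in the test suite
against a 10^7-draw Monte-Carlo oracle that simulates the correlated looks
directly.

Boundaries are computed on the z scale and converted to nominal levels
2(1−Φ(z_k)); the simulated designs then apply those levels to exact t-test
p values at very small degrees of freedom. This normal-design/t-analysis
convention changes the realized type I error by a few tenths of a
percentage point, which the calibration module can absorb.

A note on the widely reproduced three-look O'Brien–Fleming triple
(0.0006, 0.0151, 0.0471): the exact normal-theory solution at overall
two-sided alpha 0.05 is (0.00052, 0.01411, 0.04507) (final z = 2.0040,
matching standard group-sequential references), and the recursion here
reproduces the exact values. The circulated triple corresponds to a
slightly smaller constant (final z ≈ 1.985) whose exact overall size is
0.0524 — consistent with early simulation-based tabulations of the
boundary. The preset small-study design nevertheless uses the circulated
triple *verbatim as given design inputs*, since those are the thresholds the
simulated designs are defined by; `obf_levels` itself always returns the
exact values. Similarly, the larger-study pair (0.0065, 0.0525) with binding
futility at p > 0.5 is used as given; under the exact recursion with binding
futility its overall size is 0.0500, so that pair is exactly calibrated.

## Decision rules

* **Fixed**: one analysis at the final sample size at level alpha.
* **Frequentist sequential**: stop for efficacy when the stage p value falls
  below the stage's nominal level; at interim looks, stop for futility when
  p exceeds the futility alpha (when configured).
* **Bayes factor**: the default two-sample Jeffreys–Zellner–Siow test.
  Under H1 the standardized effect has a Cauchy(0, r) prior with r = √2/2 by
  default (configurable); the variance carries a Jeffreys prior. Writing the
  Cauchy as a normal scale mixture reduces BF10 to a one-dimensional
  integral over the mixing variance, evaluated by 512-node Gauss–Legendre
  quadrature after mapping g = u/(1−u); tests verify ~1e-6 (observed ~1e-13)
  relative agreement with an independent dense-grid oracle that integrates
  noncentral-t × Cauchy directly. Stop for efficacy at BF10 ≥ threshold,
  for futility at BF10 ≤ the futility threshold (interim looks only).
  With the preset small-study threshold of 3, this Bayes factor reproduces
  the published stagewise stopping percentages closely, and calibrating the
  threshold to a 5% type I error returns ≈3.1 — evidence that the default
  JZS prior is the right reading of the published design.
* **Credible interval**: central posterior interval for the mean difference
  under the noninformative Jeffreys prior, which is the shifted/scaled
  Student-t interval; endpoints are reported on the d scale. Stopping when
  zero is excluded at level L is therefore *exactly* equivalent to a
  two-sided p value below 1−L — this equivalence is how calibrated credible
  levels (e.g. 99.8%/96.8% across the three looks) encode stage alphas
  (0.002/0.032). The equivalence, and the interval itself, are tested
  against a 10^6-draw posterior-sampling oracle.

Efficacy is checked before futility within a look; the final look never
continues.

## Monte-Carlo machinery

Operating characteristics default to 10,000 replicates per cell. Per-trial
seeds are spawned from the master seed (`numpy` SeedSequence), so any single
trial can be replayed. Reported quantities: cumulative stagewise
significance percentages, interim futility percentages, overall rate with
its binomial standard error, mean cost in experimental units (2 × cumulative
per-group n at stopping), and the median d̂ among significant trials,
recorded at the stopping analysis (not re-estimated later) so that the
winner's curse of early stopping is visible. The exact power of the fixed
design is available in closed form through the noncentral t distribution
and is used as an oracle for the simulated fixed-design cells.

Calibration tunes one free threshold at a time — the fixed-design alpha, the
Bayes-factor success threshold (shared across stages), or the post-stage-1
credible level — by bisection against the simulated type I error on a fixed
vectorized stream of null trials (common random numbers). On a fixed stream
the achieved rate is a monotone step function of the threshold, so the
search terminates either within tolerance (default 0.0025, about 3.6 MC
standard errors at the default 10^5 replicates) or when the interval
collapses onto a step. Multi-parameter families are calibrated by fixing
their shape and freeing a single scale, mirroring how the preset designs are
specified.

The vectorized stream recomputes the cumulative t statistics with the same
formulas as the per-trial engine; a dedicated test checks exact stagewise
agreement of the vectorized decision logic with `StoppingRule.decide`, and a
statistical test checks that stream-based and engine-based type I error
estimates coincide.

## Predictive-value analysis

For a discrete prior over true effects, each replicate draws d, runs one
trial, and records (d, significant). Reported: P(significant), PPV against
d ≠ 0 and against d ≥ 0.5 (classified by the *true* drawn d, not the
estimate), and their products — the overall probability that an experiment
yields a significant result that reflects a real (or substantial) effect.
A semi-analytic composition Σ_d w_d · power(d) from independent per-effect
power runs is returned alongside as a cross-check; for fixed designs the
closed-form mixture with noncentral-t powers serves as the test oracle.
The built-in "optimistic" ({0: 0.3, 0.5: 0.3, 1.0: 0.4}) and "pessimistic"
({0: 0.8, 0.5: 0.15, 1.0: 0.05}) presets are illustrative placeholders, not
canonical field distributions, and are meant to be overridden.

## Problem sizes and determinism

Default problem sizes: 10,000 replicates per operating-characteristic cell,
10^5 for calibration, 10^7 draws for the crossing-probability oracle; the
full 24-cell table runs in a couple of minutes on one core. All entry points
take explicit integer seeds and are reproducible bit-for-bit.

## Known limitations

* The outcome model is the idealized equal-variance normal; passing tests
  demonstrate correctness of the design machinery under that model, not
  robustness of sequential designs to heteroscedasticity, non-normality, or
  stage-to-stage drift in real laboratory data.
* Alpha-spending approaches (Lan–DeMets) for flexible look timing are out of
  scope; look schedules are fixed in advance.
* The Haybittle–Peto family is intentionally left uncalibrated, as is
  conventional.
* Credible-interval decisions are exact t-interval equivalents; Bayesian
  machinery that computes intervals by sampling can differ from them by
  Monte-Carlo error, and published interval-based stagewise percentages
  computed that way may differ slightly from this package's exact ones.
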