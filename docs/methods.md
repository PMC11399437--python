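# Methods

## The decision model

`vaxtrace` models binary accept/refuse decisions about eight COVID-19
vaccines as discrete risky choices.  For individual *i* and vaccine *v*,

    P(accept) = logistic(β_i + X_v·β_j + φ·V_iv)

* **β_i** — individual decision bias: the baseline log-odds of accepting any
  vaccine, independent of its evidence.
* **X_v·β_j** — vaccine-specific effects: an 8×4 sum-to-zero contrast matrix
  coding country of origin (US, China, other) and technology (mRNA, vector,
  other), with four coefficients shared across participants.
* **V_iv** — the prospect-theory valuation of the evidence the participant
  actually inspected:

      V_iv = Σ_se v(a_se)·w(p_se) + Σ_b v(a_b)·w(p_b)

  where `a` are the participant's signed affect ratings (−5…−1 for side
  effects, 1…5 for benefits) and `p` the displayed probabilities (benefit
  probabilities are the effectiveness percentages used directly).

The value function has three cases: `v(a) = −λ_i·|a|^α` for side effects,
`(1−λ_i)·a^α` for benefits, and `0` for outcomes that were never inspected.
λ_i ∈ (0,1) measures loss aversion; the conventional multiplier
Λ = λ/(1−λ) is reported (Λ > 1: losses loom larger; λ = 0.5 is loss
neutrality).  α > 0 allows a nonlinear use of the ordinal rating scale;
because e.g. α = 3 turns a rating of 5 into 125, the valuation is rescaled
by φ ∈ (0,1) inside the logit.

The decision-weight function has two cases: the one-parameter Prelec form
`w(p) = exp(−(−ln p)^γ_i)` when the probability was inspected (γ_i ∈ (0,1);
γ = 1 is linear weighting, γ → 0 collapses all weights to e⁻¹ ≈ 0.37, and
w has a fixed point at p = e⁻¹ for every γ), and a constant `w = 0.5` when
the outcome was inspected but its probability was not (probability
neglect): the decision-maker registers the outcome as probabilistic but
uses no probability information.  Benefits whose effectiveness was never
displayed (three "–" cells in the evidence table) have no probability box;
when their outcome is inspected they also receive w = 0.5, but they are
excluded from the *neglect* indices because nothing could have been
inspected.

## Hierarchy and priors

β_i = β + ζ_i^β, λ_i = Φ(λ^Φ + ζ_i^λ), γ_i = Φ(γ^Φ + ζ_i^γ), with
displacements ζ_i ~ MVN(0, Σ), Σ = diag(σ)·R·diag(σ) and Φ the standard
normal CDF (used in the CDF direction for both individual- and group-level
transforms, which is what makes standard-normal priors on the probit scale
uniform on (0,1)).  α and φ are group-level only — eight decisions per
participant cannot support individual estimates.

Priors: N(0,1) on β, β_j, λ^Φ, γ^Φ, φ^Φ; N(0, 0.5) on ln α (mode at linear
rating use); gamma(2, 1) on σ_β; N(0.5, 0.13) **truncated to (0,1)** on
σ_λ and σ_γ (the truncation makes the 0–1 support literal rather than
approximate — an untruncated normal leaks ~1e-4 mass outside); LKJ(η = 5)
on R, concentrating correlations in roughly (−0.5, 0.5).  Each attitude
group (anti / neutral / pro) is fitted independently.

## Sampling

No probabilistic-programming backend is used: the package evaluates the
joint log-density and its analytic gradient directly and samples with its
own multinomial no-U-turn sampler (NUTS) with Stan-style warm-up
(dual-averaging step size toward 0.8 acceptance; expanding windows for a
diagonal mass matrix).  The sampler's target is an unconstrained
reparameterization of the model:

* non-centered displacements `z_i ~ N(0, I)` with ζ_i = diag(σ)·L·z_i,
  L the Cholesky factor of R — equal in density to the centered
  specification, much better conditioned for HMC;
* log/logit transforms for the scale parameters, with their Jacobians;
* R coded by canonical partial correlations through `tanh`; under the
  C-vine construction the LKJ(η) density factorizes into independent
  shifted Beta(η + (K−1−ℓ)/2) distributions per vine level (Lewandowski,
  Kurowicka & Joe, 2009), which is the form the sampler uses.

The gradient is hand-derived and verified against central finite
differences at random points (relative error ~1e-9 in the tests).  The
likelihood forward/backward pass exists twice: a vectorized numpy reference
and a numba-compiled kernel; the test suite asserts they agree to
round-off, and the compiled path is used when numba imports.  A non-finite
density (e.g. α overflowing during early warm-up) is treated as a divergent
proposal rather than an error.

Default configurations: decision model 4 chains × (2000 warm-up + 3000
sampling), every second draw recorded → 6000 draws; regressions 4 chains ×
4000 iterations, first half burn-in, every second recorded → 4000 draws.
Convergence requires split-chain rank-normalized R-hat < 1.01 on every
coordinate (group-level and displacement).  Posterior intervals are
highest-density intervals (minimal-width window over sorted draws).
Predictive performance is balanced accuracy — the mean of the accept-class
and refuse-class accuracies at a 0.5 threshold — either in-sample from the
posterior-mean probability, or leave-one-out via Pareto-smoothed importance
sampling (arviz `psislw`) of the pointwise likelihood.

## Preprocessing of inspection logs

Hover events shorter than 200 ms are incidental and dropped (exactly 200 ms
is kept — the removal rule is strictly "less than").  All indices use
inspection counts, never durations, because box contents differ in length
and format.  Per trial: **full** deliberate ignorance (no evidence box
inspected), **none** (every box at least once), **partial** (otherwise).
Probability neglect per category (side effects overall, mild / severe /
extreme, benefits) is the strict, one-directional definition: an outcome
box inspected while its existing probability box never was.  Inspecting a
probability without its outcome is not neglect.  An optional weaker
count-based mode is deliberately not offered; the strict definition is the
one used throughout.

## Synthetic cohorts

The generator produces complete datasets — participants, ratings, hover
logs, decisions, and a ground-truth file — by sampling forward through the
model above, so preprocessing and fitting can be validated against planted
truth.  Decisions are drawn from the *exact* acceptance probability implied
by the stored individual parameters and the post-filter inspection pattern;
a test verifies this consistency to 1e-9.

The decision model says nothing about why people ignore information, so
inspection behavior is generated by a descriptive `InspectionPolicy`:
probabilities of full ignorance and of exhaustive inspection, per-category
probability-neglect rates given an inspected outcome, an outcome-inspection
rate of 0.75 within partial trials, and a 5% incidental-hover rate (50–199
ms, uniform).  Deliberate inspections draw log-normal durations (median
800 ms, σ = 0.5, floored at 200 ms) — only the 200 ms threshold matters
downstream.  Default rates are calibrated loosely to the study's observed
descriptives (full ignorance 18/9/7% of trials and side-effect neglect
around 15/13/9% for anti/neutral/pro); the planted-truth tests compare
against the policy's own rates, not against those study values.

Default generating parameters per group encode the study's qualitative
findings: a strong refusal bias and the lowest probability sensitivity in
the anti group (β = −2.5, λ = 0.70, γ = 0.30), the most linear weighting in
the neutral group (β = −0.6, λ = 0.80, γ = 0.60), an acceptance bias in the
pro group (β = 1.5, λ = 0.80, γ = 0.50); α = 1, φ = 0.3, σ = (1.5, 0.4,
0.4), R = I everywhere.  Affect ratings are drawn independently per outcome
from ordinal distributions per attitude × severity, tilted so extreme side
effects are rated more negatively than severe, severe more than mild, the
anti group most negative about risks and least positive about benefits.

What the generator does **not** emulate: within-participant correlation of
ratings, demographic effects on decisions, response-time structure, or any
motivated-reasoning mechanism behind ignorance.  Passing tests therefore
show that the pipeline recovers what the generative model plants — not that
real data satisfy the model's assumptions.

## Supporting regressions

Binary outcomes use hierarchical logistic regression, ordinal outcomes
(≥ 3 levels) hierarchical cumulative ordered-logit with strictly ordered
cutpoints, both with participant random intercepts (non-centered),
sum-to-zero contrasts for all categorical predictors, Student-t(3, 0, 2.5)
priors on coefficients (and cutpoints), and half-t(3, 0, 2.5) on the
random-intercept SD.  They run on the same in-package NUTS backend so the
whole pipeline is self-contained and testable against planted truth.
Predicted values per factor level set all other predictors to zero (with
sum-to-zero coding: grand mean plus the level's effect) and push through
the inverse link; pairwise comparisons subtract linear-scale values draw by
draw and flag a difference whose 95% HDI excludes zero.  Odds ratios mark
|log OR| ≥ 0.2 as the conventional practical-relevance boundary.

## Numerical choices and edge cases

* Probabilities are clamped to [1e-8, 1−1e-8] before the Prelec transform
  (the packaged table contains no 0/1, but user configs might).
* Affect ratings enter as magnitudes 1–5 for both outcome kinds; a rating
  of 0 is rejected (the scale excludes it).
* Classification threshold for balanced accuracy is fixed at 0.5.
* HDI computation requires ≥ 50 draws; R-hat requires ≥ 2 chains and ≥ 4
  draws per chain.
* The LKJ term in `model_log_density` is unnormalized ((η−1)·log det R);
  all other prior terms carry full normalizing constants.
* Ties in the minimal-width HDI window resolve to the leftmost window.

## Problem sizes

The packaged defaults match the study (1200 participants; 365/373/462 per
group).  The recovery analyses in the tests and the acceptance script use
one group of 200 participants × 8 trials at the full default sampler
configuration — large enough for group-level HDIs to be informative while a
complete fit stays in the ten-minute range on a single core.  Descriptive
(preprocessing) checks use 150–1200 participants, where binomial error on
trial-level proportions is a fraction of a percentage point.

## Known limitations

* LOO balanced accuracy uses Pareto-smoothed importance sampling, not exact
  refits; with eight highly dependent observations per participant the
  importance weights can be heavy-tailed for influential participants.
* The sampler is sequential; chains do not run in parallel.
* Ordered-logit predicted values report the expected category, which treats
  the ordinal levels as equally spaced for summary purposes only.
* Group-level recovery has been validated at n = 200 per group; individual-
  level parameters (600+ per group) are only weakly identified from eight
  decisions each and are not separately validated.
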