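# Methods

## Model class

`bayesize` fits Bayesian generalized linear models: a linear core
η = Xβ mapped by an inverse link to the mean of a noise family. Families and
links are restricted to combinations whose mean support is guaranteed by the
link alone — log for the positive-mean families (Poisson, negative binomial,
gamma, exponential, inverse Gaussian, lognormal), identity for the normal,
logit/probit for the binomial and beta. The negative binomial is
parameterized by mean μ and dispersion ϕ with Var = μ + μ²/ϕ; ϕ → ∞
recovers the Poisson (the test suite checks this limit numerically). For the
lognormal the linear predictor is the mean of log y, so the log link targets
the response median rather than its mean; predictions and simulations use
the exact lognormal sampling distribution.

Categorical predictors are dummy coded against the lexicographically first
level; coefficients are named `var[level]`, interactions `a[x]:b[y]`. A
model carries its categorical level sets explicitly so that a
data-generation model and its inference twin build identical design matrices
even when a small simulated replicate happens to miss a level.

Pairwise effects between levels of a categorical predictor are computed from
the coefficient contrasts (the reference level contributing zero) and
reported on the scale the link implies: differences (identity/probit),
multipliers (log), log-odds ratios and odds ratios (logit). This contrast
is well defined only when the predictor is not involved in an interaction;
the effect-matrix routine refuses otherwise.

## Priors

When the user does not specify priors, weakly informative data-scaled
defaults are used. Identity link: intercept ~ N(ȳ, 2.5·sd(y)), coefficient
of x ~ N(0, 2.5·sd(y)/sd(x)), scale-type auxiliary ~ Exponential(1/sd(y)).
Non-identity links move to the link scale: intercept ~ N(g(ȳ), 2.5),
coefficients ~ N(0, 2.5/sd(x)), positive auxiliaries ~ Exponential(1). The
rules depend only on column summaries, hence are invariant to row order, and
fail loudly on a zero-variance response. A `point` prior pins a parameter to
a constant; a model in the data-generation role must pin all of them.

## Sampling

The posterior is sampled by an adaptive random-walk Metropolis algorithm of
the package's own design, chosen for robustness across all supported
families and for exact, dependency-free reproducibility. Positive
parameters are log-transformed (with the Jacobian added), so proposals live
in an unconstrained space. All chains move in lockstep through vectorized
likelihood evaluations. During warmup the proposal covariance is estimated
from the pooled running moments of all chains (refreshed every 50
iterations, ridge 1e-8) and a Robbins–Monro recursion with decay t^-0.6
tunes the global step size toward 30% acceptance; both are frozen when
sampling starts, so retained draws come from a time-homogeneous chain.
Initial states are prior draws shrunk halfway to the prior median, retried
up to ten times if the log posterior is not finite. One
`numpy.random.Generator` seeded from the configuration drives everything,
making draws bitwise reproducible.

Random-walk proposals need more draws per effective sample than
gradient-based samplers; the default budget is therefore 4 chains × 1000
warmup + 2000 retained draws, which clears the diagnostic thresholds for
the few-parameter models the package targets. Validity is certified by
split-chain potential scale reduction (threshold 1.01; own implementation,
cross-checked against `arviz.rhat`), bulk effective sample size ≥ 400 in
total (delegated to `arviz.ess`), and a divergence count that is
identically zero because random-walk proposals have no divergent
trajectories. A fit passes only if all three hold. Simulation-based
calibration of the sampler (rank-histogram uniformity over 200 prior-drawn
replicates) is part of the test suite.

## Interval summaries

The equal-tailed interval uses type-7 (linearly interpolated) quantiles at
(1±mass)/2; the highest-density interval is the shortest window of sorted
draws containing ⌈mass·n⌉ values, ties resolved toward the smallest lower
bound. Both are deterministic; the HDI is tested for exact equality with an
exhaustive window scan. Defaults are mass 0.95 and HDI. Because the ETI
interpolates between order statistics, it can be marginally narrower than
the HDI at very small draw counts; on posterior-sized samples the HDI is
never wider. Note that tail quantiles are MC-noisy: the 2.5% quantile of S
autocorrelated draws has standard error ≈ σ·√(0.95·0.05/ESS)/φ(z₀.₀₂₅), so
width-sensitive decisions (precision goals) benefit from larger draw
budgets; the planning defaults below reflect this.

## Model criticism

Posterior predictive checks replicate the data at the observed predictor
values from evenly spaced posterior draws and compare a statistic of the
observations (mean, sd, max, proportion of zeros — location, spread,
extremes, zero inflation) with its replicated distribution; the two-sided
tail probability is twice the smaller tail fraction, capped at 1.

PSIS-LOO follows the Pareto-smoothed importance-sampling recipe: raw
importance ratios are reciprocal pointwise likelihoods; per observation the
M = min(0.2·S, 3·√S) largest ratios are replaced by expected order
statistics of a generalized Pareto fitted to the exceedances by the
Zhang–Stephens profile posterior mean (shape regularized toward 0.5 with 10
pseudo-observations); weights are truncated at the raw maximum and
normalized; elpd is the weighted log mean likelihood. Shape estimates above
0.7 are flagged. The implementation is validated against exact closed-form
leave-one-out refits of a conjugate normal model (|Δelpd| ≤ 0.2 at n=15)
and against `arviz.loo`. Model comparison reports elpd differences to the
best model with paired standard errors from pointwise contributions.

## Sample-size planning

Planning treats power as the probability, over replicated simulated
experiments, that a posterior-based goal is achieved. Goals are either
precision (credible-interval width ≤ w) or ROPE exclusion (interval wholly
outside a region of practical equivalence), decided by default on a 95%
HDI. For each candidate size, replicate r derives its seed deterministically
from (seed, r), simulates data from the data-generation model, fits the
inference model, and evaluates the goal; a replicate whose fit fails after
one retry counts as a failure. Wilson 95% score intervals accompany each
power estimate.

The candidate grid is searched by bisection under approximate monotonicity,
using a quarter of the replicate budget for interior probes; the frontier
candidate is then confirmed with the full budget, advancing one candidate
if confirmation fails. Defaults: 200 replicates (frontier standard error
≤ 0.035), 50-replicate probes, and a deliberately small inner sampler
(2 chains × 400 warmup + 600 draws) — adequate for the 2–3-parameter models
planned here and cheap enough for hundreds of fits per candidate.
Recommended n is the smallest tested candidate whose confirmed power
reaches the target; for multi-group designs candidates are per-group sizes
and reported totals are stated explicitly.

The conventional comparator solves the two-sample noncentral-t power
equation (scipy's noncentral t plus Brent root finding) for the real-valued
per-group size and returns ⌈2n⌉ as the total; it is tested against
statsmodels' independent power solver.

## The shipped open-field-test scenario

The open field test counts center entries of a rodent in an arena; counts
are overdispersed, so the natural model is negative binomial with log link,
while conventional practice reaches for the t-test. The reference
comparison that motivates the shipped scenario printed only two moments of
its data — a mean difference of 4.86 entries and a pooled SD of 4.49 — with
the underlying group means and dispersion living in an external dataset;
the exact published planning run is therefore not reconstructible, and the
package ships a stand-in. `bayesize.scenarios` fixes the baseline
(anxious-strain) mean at 0.5 entries per observation interval — the
low-count, strongly overdispersed regime in which the choice of noise model
matters most — and matches the printed moments exactly, giving group means
0.5 and 5.36 and ϕ ≈ 0.84 by moment matching of the average group variance
to the pooled variance. The goal excludes strain effects within 5% of the
baseline mean (multiplier band [1/1.05, 1.05] on the log scale for the NB
model; ±0.025 entries for the identity-link normal model), with 80% power
over per-group candidates {5, 8, 11, 14, 17}.

Under this scenario the NB planner typically recommends 8 animals per group
(16 in total) while planning with a normal inference model on the same
simulated truth needs more (usually 22–28 in total) and the conventional
power t-test asks for 29: assuming normality for overdispersed low counts
inflates the animal requirement roughly twofold. The two planners' power
curves are closer at higher baseline means, where the normal approximation
is less wrong; the recommended-size ordering (normal ≥ NB) held in every
configuration examined, but near-ties at grid resolution are possible since
the comparison is stochastic.

## What the simulations do and do not show

The synthetic generator draws independent, identically distributed
responses per group from the exact model family — no batch effects, no
heteroscedasticity beyond the family's mean–variance law, no measurement
error or missingness. Passing tests therefore demonstrate the correctness
and calibration of the machinery under the stated model, not robustness of
any particular scientific conclusion to model misspecification in real
data (the PPC and LOO tools exist precisely to probe that on a case-by-case
basis).

## Numerical conventions and limitations

Degenerate inputs fail loudly: all-missing columns, zero-variance responses
under autoscaled priors, empty candidate lists, all-equal Pareto tails.
Missing-data handling is complete-case only, with dropped rows enumerated.
Problem sizes in the test suite and the acceptance script (replicate counts,
draw budgets, candidate grids) are scaled for a desk-class single-CPU run;
the statistical conclusions they check are unchanged at larger budgets.
Report elements carry an optional wall-clock timestamp that is left empty
unless the caller stamps it, keeping rendered reports a pure function of
the run. Known limitations: no hierarchical/multilevel terms, no splines,
single-split HDIs only (no multimodal intervals), pairwise contrasts only
in effect matrices, and no imputation.
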