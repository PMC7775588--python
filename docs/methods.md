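# Methods

## The models

`medci` works with two recursive path models over observed variables.

Simple mediation (variables x, m, y):

    m = i_m + a x + e_m
    y = i_y + b m + c' x + e_y

Serial mediation (x, m1, m2, y):

    m1 = i_m1 + a x            + e_m1
    m2 = i_m2 + b1 m1 + d_xm2 x + e_m2
    y  = i_y  + b2 m2 + d_m1y m1 + c' x + e_y

The d-paths are zero in every generating population but always estimated, so
the fitted model is saturated (just-identified): it reproduces all sample
means and covariances exactly and the minimized discrepancy equals its
analytic floor.  The quantities of interest are the unstandardized indirect
effect, ab (or a b1 b2), and the completely standardized indirect effect,
ab·σx/σy, with σy taken from the model-implied covariance when working on
the parameter scale.

A point of care in the serial model: the standardized effect's denominator
is the implied Var(y) computed from the *full* parameter set, including the
estimated d-paths.  A formula that drops the zero-population paths coincides
with ours at the MLE (where the saturated model reproduces the sample
variance of y) but not at the constrained parameter values a profile search
passes through; the full form is the internally consistent choice and is
what we use everywhere.

## The five interval procedures

All intervals default to the 95% level.

**Percentile bootstrap** (`boot`).  n cases are resampled with replacement
B = 2000 times (configurable); in each resample the model's regressions are
re-estimated by OLS and the indirect effect recomputed — the standardized
variant recomputes the sample SDs within each resample.  The interval is
the empirical 2.5th/97.5th quantile pair with linear interpolation between
order statistics.  Internally the per-resample OLS solves are vectorized
through the resample covariance matrices, which is algebraically identical
to refitting (a test checks this against per-resample `statsmodels` fits);
rank-deficient resamples are redrawn and counted, and more than 5% redraws
flags the interval's status.

**Likelihood-based CI** (`lbci`, `lbci-adf`, `lbci-fx`).  The LBCI inverts
the 1-df likelihood-ratio test: the interval for a derived parameter g(θ)
is [min g, max g] over the region D(θ) − D(θ̂) ≤ χ²₁(0.95) = 3.8415, where D
is the engine's discrepancy.  The critical value comes from the chi-square
quantile function, not a rounded constant.  Three engines supply D:

* `lbci` — the multivariate-normal −2 ln L, computed from sample moments
  with the ML (divisor-n) covariance convention.  Means and intercepts are
  saturated and never enter the indirect effects, so they are concentrated
  out exactly and the profile search runs over the 6 (simple) or 10 (serial)
  covariance-structure parameters.  We profile −2 ln L directly
  (N-consistent scaling); an (N−1)-scaled variant would move endpoints by
  O(1/n).
* `lbci-adf` — Browne's asymptotically distribution-free quadratic form
  F = (s − σ(θ))' W⁻¹ (s − σ(θ)) over the half-vectorized covariances, with
  W[ij,kl] = m4[ijkl] − s_ij s_kl built from divisor-n central fourth
  moments; means are fitted saturated and excluded from W, since the
  indirect effects involve the covariance structure only.  The profiled
  statistic is (n−1)·F, the asymptotically chi-square scale.
* `lbci-fx` — the ML engine with the predictor variance σx² pinned to the
  divisor-n sample variance and removed from the free set, i.e. the
  fixed-regressor treatment of x.  For the saturated model this changes no
  point estimate; it changes the *interval* for the standardized effect
  because the sampling variability of σ̂x² no longer propagates.

The constrained extremization uses SLSQP from the closed-form optimum
(which is interior and strictly feasible), with error variances bounded
below by 1e−10 — positive error variances make the implied covariance of a
recursive system automatically positive definite, so the discrepancy is
finite everywhere the optimizer can step.  A failed bound search is
restarted up to 5 times from perturbed starting values; a bound that never
converges is flagged (`failed-lower`/`failed-upper`) and reported at the
best feasible value seen rather than dropped silently.  The generic search
is validated against a closed-form one-dimensional oracle (profile CI for a
normal variance) at 1e−4 and against a 10⁶-draw random-search oracle for
ab on an n=50 sample at the oracle's resolution (~1e−2).

**Monte Carlo** (`mc`).  1000 draws (configurable) per path from independent
normals centered at the OLS estimates with SDs equal to their standard
errors — cross-path covariance fixed at zero, the standard assumption for
these models; serial uses three independent normals.  The interval is the
percentile range of the products.  The standardized variant multiplies both
limits by sd(x)/sd(y) with the standardizers treated as fixed; this ignores
their sampling variability and is exactly the weakness the coverage study
exposes (the wider the true effect, the more conservative the interval).

## The synthetic populations

The generator builds each condition on a standardized scale in which every
observed variable has population mean 0 and variance 1:

* the predictor is drawn from one of five families — normal,
  exponential(rate 1) (skewness 2, excess kurtosis 6), Beta(1.5, 1.5)
  (excess kurtosis −1), t(5) (excess kurtosis 6), t(6) (excess kurtosis 3) —
  and standardized by the family's *population* mean and SD (0/1, 1/1,
  0.5/0.25, 0/√(5/3), 0/√(6/4));
* errors are normal with variances restoring unit variance downstream:
  var_em = 1 − a², var_ey = 1 − b² − c′² − 2abc′ for the simple model;
  var_em1 = 1 − a², var_em2 = 1 − b, var_ey = 1 − b − c′² − 2abc′ for the
  serial model with b1 = b2 = √b (the serial algebra is derived from the
  unit-variance constraints and verified by a 10⁶-case simulation oracle);
* the finished variables are affinely rescaled to means (3, 5, 4) and SDs
  (4, 5, 3) for x, m, y — serial: m1 to (5, 5) and m2 to (2, 2) — so that
  unstandardized and standardized effects genuinely differ.  After
  rescaling the true unstandardized effect is ab·SDy/SDx = 0.27 at
  a = b = 0.6, the standardized effect is unchanged at 0.36.

The direct effect is indexed by the R² increase d from adding the c′ path;
inverting the squared-semipartial-correlation identity gives
c′ = √(d/(1 − a²)), taken positive.  (The linear form d/(1−a²) sometimes
seen fails the worked example a = 0.6, c′ = 0.4 ⇔ d = 0.1024, which the
square-root form round-trips exactly.)

The design grid crosses model ∈ {simple, serial}, n ∈ {50, 100, 150, 200,
500}, eight standardized (a, b) pairs — equal paths at 0.376/0.600/0.714,
the nil pair, and unequal pairs fixing one path at 0.714 — d ∈ {0, 0.02,
0.13, 0.26}, and the five predictor families.  Cells whose implied
population R² of the outcome (1 − var_ey on the standardized scale) exceeds
0.80, or whose error-variance algebra turns negative, are dropped.  For the
serial model the R² cap is applied to its own implied R² (1 − var_ey with
the serial algebra), which prunes more large-effect cells than the simple
model's b² + c′² + 2abc′ — the honest generalization of the same rule.

Seeding: every replication owns a `SeedSequence`; the predictor and each
error vector use independent spawned substreams, as do the bootstrap and
Monte-Carlo draws, so no resampling shares a stream with data generation and
results are identical under any parallel scheduling.

What the generator does *not* emulate: nonnormal errors (the contrast case,
deliberately out of scope — conditional normality of the errors is the
point of the design), measurement error, missing data, or covariates.
Passing coverage here therefore speaks to the estimators' behaviour under
nonnormal *predictors* only.

## The coverage study

Coverage is the proportion of replications whose interval contains the true
population effect (closed-interval containment); 0.95 is nominal and
[0.935, 0.965] is the tolerable range (inclusive).  Replications whose
profile bound search fails are excluded from that method's denominator and
counted.  The number of replications per condition is a configuration value
(default 1000).

Problem sizes used by the shipped checks, chosen as reduced-scale
reproductions of the study's qualitative results: the two headline coverage
checks run 2000 replications each (bootstrap with 1000 resamples at n=500
for the standardized effect; ML LBCI at n=100 for the unstandardized
effect), where the binomial standard error is ≈0.005 — small against the
0.015 margin between nominal and tolerable coverage.  The heavy-tailed
contrast (exponential predictor, standardized effect 0.36, n=150, LBCI vs
LBCI-ADF) uses 800 replications, enough to separate ~0.92 from ~0.96
coverage by several standard errors.

## Numerical choices and edge cases

* Covariance divisor: n (ML convention) throughout the likelihood and the
  ADF weight matrix; sample SDs reported by OLS use n−1 (the ratio
  sd_x/sd_y is divisor-invariant, so the standardized effect is unaffected).
* Standardized OLS coefficients are computed by rescaling unstandardized
  ones with sample SDs, not by refitting z-scored data (identical in exact
  arithmetic; checked by a refit test), which keeps bootstrap loops cheap.
* Optimizer tolerances: 1e−8 on the fit objective, SLSQP ftol 1e−10 and at
  most 300 iterations per profile bound.
* Quantiles: linear interpolation between order statistics everywhere
  (numpy's default); percentile-interval equivariance under monotone
  transforms is exact when the quantile lands on an order statistic.
* Degenerate inputs: negative variances and non-positive implied outcome
  variance raise; rank-deficient designs raise in `ols_fit` and are redrawn
  in the bootstrap; a constant derived function collapses the profile
  interval to a point.
* Intercepts are always estimated (or concentrated out) but never enter the
  effect formulas.

## Known limitations

* The profile search is a local constrained optimizer; for the saturated
  models studied the feasible region is well behaved, but severely
  ill-conditioned samples can still defeat it — such bounds are flagged,
  never silently dropped.
* ADF needs n comfortably above the number of distinct covariance elements
  for a stable weight matrix; at n=50 with four variables it is usable but
  rough, which is exactly the regime where its coverage sags.
* Only complete-data, observed-variable, single-predictor models are
  supported; no partially standardized effects, covariates or latent
  variables.
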