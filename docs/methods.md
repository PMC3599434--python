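# Methods

## The mapping model

Let `y_i` be patient *i*'s EQ-5D-3L index under the UK social tariff and
`x_i` the intercept plus 11 dummies coding six follow-up answers (toilet
assistance, dressing assistance, mobility in 3 categories, general health
in 4, mood in 4, proxy response), each against its "no disability"
reference. The mapping is the linear predictor `x'β` estimated three ways:

- **OLS**: `β̂ = argmin Σ(y − x'β)²`. Inference uses the HC1 sandwich
  (`n/(n−k)`-scaled) because utility residuals are heteroscedastic —
  robust SEs change the intervals, not the point estimates. 95% CIs use
  the t distribution with `n−k` degrees of freedom.
- **Tobit**, right-censored at 1: the observed `y = min(y*, 1)` with
  latent `y* = x'β + ε`, `ε ~ N(0, σ²)`. Uncensored rows contribute
  `φ((y−x'β)/σ)/σ` to the likelihood, ceiling rows contribute
  `1 − Φ((1−x'β)/σ)`. Only the upper bound is modelled: the ceiling is a
  measurement artefact of the instrument, whereas the lower bound −0.594
  is a genuine boundary of the tariff's range, not a censoring point.
- **CLAD** (Powell): `β̂ = argmin Σ|y − min(x'β, 1)|`, the censored
  median regression. It needs only a conditional-median-zero error, so it
  is the robustness benchmark when normality/homoscedasticity are doubtful.

Predictions censor at 1 for Tobit and CLAD (the rule under which they
were estimated); OLS predictions are returned raw — uncapped above and
unfloored below — because the OLS model's range *is* its output; a
prediction below −0.594 is logged as infeasible but preserved.

## Numerical choices

- **Tobit optimisation**: BFGS on `(β, log σ)` with the analytic gradient,
  started from the OLS solution; the *mean* negative log-likelihood is
  minimised so the gradient tolerance (1e−8) is per-observation and
  size-independent. A line-search stop with gradient infinity norm below
  1e−6 is accepted as converged. The coefficient covariance is the inverse
  observed information, computed by finite differences of the
  log-likelihood in the direct `(β, σ)` parameterisation; CIs are normal.
- **Tobit pseudo-R²** is McFadden's `1 − ℓ/ℓ₀` against a censored
  intercept-only null. With a continuous outcome and σ ≈ 0.2 the
  log-likelihood is positive, so this statistic can leave [0, 1]; it is a
  declared convention, reported for completeness, and not comparable
  across likelihood scales or with the published pseudo-R² values (whose
  defining formula was never stated and whose source data are
  unavailable).
- **Quantile engine**: the check-loss minimisation is solved as an exact
  linear programme (HiGHS; β free, positive/negative residual parts) for
  problems up to 2,000 rows, and by statsmodels' IRLS (`p_tol=1e−9`)
  above, where the LP's exactness is not worth its cubic-ish cost. Ties
  in the median fit are resolved by the solver's deterministic pivoting
  given a fixed row order, so results are reproducible.
- **CLAD iteration** (iterative linear programming): fit a median
  regression on the retained rows, recompute fitted values on *all* rows,
  retain those with `x'β̂ ≤ 1`, repeat. Stopping rule: retained-set
  equality; cycle detection by hashing the retained mask; iteration cap
  100. On a cycle or cap the best-objective iterate (objective evaluated
  on all rows with the censored predictor) is returned with
  `converged=False`. Note the deletion condition is strict
  extrapolation above the ceiling: with purely categorical designs the
  cell median saturates at exactly 1 and no deletion occurs, which is the
  estimator behaving correctly, not a failure.
- **CLAD inference**: nonparametric percentile bootstrap (default 1,000
  replicates), re-running the entire deletion iteration per resample;
  identical seeds give identical intervals. Percentile bounds are widened
  to include the point estimate if a small-sample resample distribution
  fails to bracket it.
- **Degenerate inputs**: rank-deficient designs are rejected with the
  dependent columns named (QR with pivoting); an all-censored Tobit
  sample raises a degenerate-likelihood error; a CLAD retained set
  smaller than the column count raises an insufficient-data error.

## The validation battery

Errors are `observed − predicted`, so *over*-prediction yields negative
means. MAE and MSE are the plain means of `|e|` and `e²`; the AE<0.05 and
AE<0.10 fractions use strict inequality. Band means stratify by the
*observed* utility into (−∞, 0), [0, 0.25), [0.25, 0.5), [0.5, 0.75) and
[0.75, 1] — half-open on the left bands, closed at the top so the ceiling
atom belongs to the last band; an empty band is reported absent rather
than zero, and the count-weighted band means reproduce the overall mean
error exactly. The cluster test splits at observed utility 0.5 and
compares mean errors with a two-sided Welch (unequal-variance) t test,
since the low-utility band has visibly larger error variance. VIFs are
`1/(1−R²_j)` from regressing each dummy on the others with intercept;
exact collinearity reports as infinite.

## The synthetic cohort generator

The generator emulates the statistical structure the mapping assumes, not
any real register extract. Each patient draws a latent severity
`u ~ N(0,1)`; every registry variable gets its own Gaussian score
`z = λu + √(1−λ²)ε` cut at normal quantiles of the target marginals, so
marginal prevalences are exact while variables are positively associated
(pairwise latent correlation λ², default λ = 0.7 — strong, as between
toileting dependence and immobility in practice). Defaults: n = 544 with
a random 272/272 half-split, mirroring the study design the package
accompanies; generating coefficients = the published OLS set; residual SD
0.21 utility, which yields cohort OLS R² near 0.72 and observed-utility
mean ≈ 0.60, SD ≈ 0.32–0.40 — the neighbourhood of the real cohort's
0.61/0.41.

Marginal prevalences of the six follow-up variables are not published for
the source cohort, so the defaults (15% toilet assistance, 20% dressing
assistance, 65/25/10% mobility, 20/50/22/8% general health,
40/40/13/7% mood, 10% proxy) are declared assumptions of a moderately
impaired 3-month post-stroke population, chosen once for plausibility and
exposed in `GeneratorConfig` for anyone who disagrees.

Noise regimes:

- `linear`: `y = x'β + ε`, Gaussian, floored at the tariff minimum
  −0.594 (clips are counted). The upper side is deliberately left
  uncensored: this mode is the uncensored idealisation in which OLS is
  the consistent estimator, used to verify OLS recovery; imposing the
  ceiling here would contaminate that check with censoring bias, which
  is exactly what `latent_censored` exists to represent.
- `latent_censored`: `y = min(x'β + ε, 1)`, the Tobit generating model;
  default cohorts put roughly 12–15% of observations at the ceiling.
- `robust_stress`: two-piece noise — with probability ½ a negative
  half-normal scaled by 0.4s, else a positive half-normal scaled by 1.6s,
  with `s = noise_sd·(0.5 + max(0, 1 − x'β))` — then censored at 1. The
  conditional median is exactly `x'β` (CLAD's estimand) while the noise
  is right-skewed and heteroscedastic, growing with impairment; Gaussian
  likelihood methods are biased here by construction, which is the point.

What passing tests on these cohorts shows: the estimators recover the
coefficients of their own generating processes (OLS within ±0.02, Tobit
±0.03, CLAD ±0.04 at n = 20,000) and CLAD's robustness advantage
materialises under `robust_stress`. What they cannot show: performance
under real-data features the generator omits — item non-response and
partially completed forms, proxy-specific response styles, cohort drift
between collection waves, or discreteness of observed indices (real
EQ-5D-3L indices take at most 243 values; the generator's are
continuous). Conclusions about real registry extracts still require
validation on real data.

## Known limitations

- The published coefficient sets are stored at the 3-decimal precision at
  which they were reported; reconstructed quantities (e.g. the worst-case
  OLS prediction −0.504) inherit that rounding.
- CLAD point estimates from the IRLS engine (n > 2,000) agree with the
  exact LP optimum only to solver tolerance; all stated recovery margins
  are far wider than that gap.
- The Welch cluster test treats the two error groups as independent
  samples; with a fitted model the errors share estimated coefficients,
  so the test is approximate — matching its descriptive role.
- No alternative tariffs ship with the package; `UKTariff` is a value
  object, so a country-specific value set can be injected where one
  exists.
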