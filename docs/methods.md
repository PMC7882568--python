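# Methods

## The model

For one focal game type the analysis variables are a binary exposure X
(played the type in the last 12 months), six mediators M1–M6 and the capped
problem-gambling severity score Y. The parallel multiple mediation model is
estimated by ordinary least squares path analysis:

- a-paths: six simple regressions `M_j = α_j + a_j X + ε`,
- outcome model: `Y = α + c′X + Σ_j b_j M_j + ε`,
- indirect effects `a_j b_j`, total effect `c′ + Σ_j a_j b_j`.

Because every regression contains an intercept, the decomposition identity
`total = c′ + Σ a_j b_j = cov(X,Y)/var(X)` holds algebraically; the engine
tracks the largest relative violation seen in any fit or resample
(`decomposition_gap`) as a numerical self-check, and the test suite requires
it below 1e-10.

Inference is by nonparametric percentile bootstrap. Rows are resampled with
replacement B times (default 5000); all paths are refit per resample; the
confidence interval of each effect (a, b, indirect, c′, total) is the
empirical (α/2, 1−α/2) quantile of its bootstrap distribution at the
configured level (default 95%). An effect is *relevant* when the interval
excludes zero. p-levels are deliberately not adjusted for multiple
comparisons — the design favours power over strict type-I control in this
screening setting — though a Bonferroni switch exists in the configuration.

Mediators enter untransformed: ordinal frequency categories are treated as
metric, as is conventional in OLS path analysis of survey intensity
measures. The known cost is that effect sizes across mediators with
different scales are only comparable through the shared X and Y metrics.

### Bootstrap implementation

Resampling with replacement is algebraically a vector of integer count
weights summing to n, so each resample's centered cross-product matrix is a
weighted moment of precomputed per-row outer products. One BLAS product
`W @ Q` plus a batched (m+1)×(m+1) solve evaluates thousands of resamples at
once; 5000 resamples of a ~4000-row table take well under a second. All
variables are centered and scaled by their full-sample standard deviation
before the solve (the Gram matrix becomes correlation-like, conditioning the
system); slopes are mapped back exactly afterwards, which also yields exact
affine equivariance: rescaling Y by k rescales every effect and interval by
k and changes no relevance flag.

Degenerate resamples — the exposure or a mediator constant, or an exactly
collinear design, detected by a relative eigenvalue threshold of 1e-9 on the
equilibrated Gram matrix — are redrawn rather than dropped, keeping the
bootstrap distribution at exactly B draws (percentile ranks assume fixed B).
If redraws exceed 10% of B the fit aborts with a diagnostic, since the data
are then too sparse for resampling inference. Every game type receives its
own seed derived from the master seed, so the 15 fits are independent,
reproducible streams.

## Feature engineering

Operating on last-year gamblers only (≥ 1 non-missing frequency ≥ 1):

1. missing frequency/spending responses are replaced by 0 (never / 0 spent);
2. spending is winsorized per game type at the 1st/99th percentile, pooled
   across survey years;
3. participation indicators, breadth (capped at 7 types), within/beyond
   aggregates (beyond = maximum over the 14 other types, on winsorized
   spending) and the capped outcome (score > 6 → 6) are derived;
4. the propensity score is the fitted probability of scoring ≥ 5 (at least
   moderate risk) from a logistic regression on male gender, education
   (three ordered levels entered as one metric term), single status and age,
   fit on complete cases; respondents with missing demographics receive the
   mean score of the scored rows.

Fixed caps (breadth 7, outcome 6) are the defaults for comparability across
datasets; a `percentile99` mode re-derives them from the data at hand. The
imputation-before-winsorization order is the default so that the pooled
percentiles are defined over the full analysis sample; the opposite order is
available via `impute_before_winsorize=False`. The propensity score defaults
to the probability scale; the linear predictor is available by option. The
beyond-aggregation uses the maximum rather than a sum deliberately: a sum
over 14 types is nearly collinear with breadth.

### Quantile conventions

Winsorization bounds use closest-rank order statistics taken *outward*
(lower bound rounded down, upper rounded up). Both bounds are then actual
observations and winsorization is exactly idempotent — with interpolated
bounds the recomputed percentile of already-winsorized data creeps upward on
re-application, which breaks idempotence and makes repeated pipeline passes
non-reproducible. Bootstrap interval quantiles, where no such re-application
exists, use standard linear interpolation between closest ranks.

## Cohort statistics

Participation per game type across survey years is tested with the
asymptotic chi-square statistic (no continuity correction) and Cramér's
V = sqrt(χ²/(N·min(r−1, c−1))); a sparse flag marks tables with any expected
cell below 5, with the analyst free to fall back on exact methods there.
Ordinal/metric variables use the tie-corrected Kruskal–Wallis H with
eta-squared computed as (H − k + 1)/(n − k). Participation growth is the
last-year/first-year rate ratio per type with unweighted means per mode
(offline/online); a zero first-year rate leaves the ratio undefined and the
type excluded from the mean. These are descriptive homogeneity diagnostics;
the judgment that small effects justify pooling cohorts stays with the
analyst.

## Dominant-mediator profiles

Per game type, indirect effects that are relevant *and* positive are ranked
by their unrounded point estimates (ties broken by fixed mediator order
M1…M6). The largest names the dominant mediator; the dominance ratio is
largest/second-largest and is undefined with fewer than two such effects
(a single relevant effect is dominant outright). The default threshold 2.0
separates distinct from equivocal profiles: in the motivating analyses the
distinct cases all had ratios ≥ 2.20 and the sole equivocal case 1.64, so 2
cleanly splits the observed range; it is configurable. Negative indirect
effects (problem-decreasing mechanisms) never enter the ranking regardless
of magnitude, and no inferential test is attached to the ratio itself — it
is a descriptive rule of thumb.

## Synthetic data generator

`generate_survey` emulates three merged cross-sectional prevalence surveys
(default years 2007/2011/2017 with per-year sizes 2631/1887/2703):

- **Participation/frequency.** One latent standard-normal involvement factor
  per respondent; each type's latent intensity is `√ρ·Z + √(1−ρ)·ε` (default
  ρ = 0.45), thresholded so the marginal participation equals the configured
  per-year probability exactly in expectation. Defaults mirror the published
  per-year participation rates among last-year gamblers (0.2%–79% range),
  scaled by the 61.3% last-year-gambling fraction to population marginals.
  Within participants, the conditional tail position maps to ordinal
  categories 1–5 through cut-points (0.55, 0.85, 0.95, 0.99); non-monotone
  cut-points are a configuration error.
- **Spending.** Participants draw lognormal amounts (log-mean 7 ≈ 1100 ISK,
  log-sd 1) coupled to the latent intensity (correlation 0.4 — the
  within-type frequency/spending coupling is a parameter, not an assertion);
  a rare outlier component (rate 1%, ×20) produces the heavy tail that makes
  winsorization consequential. Non-participants skip the question (missing).
- **Demographics and propensity.** Gender/age/education/partnership match
  the survey margins (49.8% male; age ~N(42.6, 14.4²) truncated to 18–70;
  education 24.4/42.4/33.2%; 63.2% partnered). The demographic high-risk
  link is an exact logistic model with odds ratios 5.026 (male), 0.527
  (education), 1.671 (single), 0.951 (age/year); its intercept (−2.6) gives
  a ≈ 1.2% mean demographic risk.
- **Outcome.** The severity score is a rounded, truncated-at-zero linear
  predictor over the six mediator constructs of a chosen focal type plus a
  scale-mixture noise (12% of draws at 4.5× scale, giving realistic
  overdispersion). The intercept (−2.4) calibrates ≈ 90% zeros and ≈ 1.2%
  of last-year gamblers at or above the moderate-risk threshold. Non-gamblers
  score 0 by definition.
- **Missingness.** Per-cell rates for frequency (1%) and spending (5%)
  blocks, and a per-row 2.94% rate blanking one random demographic field —
  so the propensity stage's imputation bookkeeping is exercised.

Ground truth records the b-coefficients (the planted β), the realized
a-paths (mean construct difference by focal participation among gamblers)
and their products. Because the observed score is rounded, truncated and
later capped, the fitted b-paths are attenuated relative to β; exact-recovery
experiments therefore use `simulate_mediation_dataset`, which plants a/b
paths directly on feature-level data (`M_j = a_j X + ε`,
`Y = c′X + Σ b_j M_j + ε`), and `simulate_demographics_outcome`, which
draws the binary outcome from the exact logistic model. The latter defaults
to an intercept giving a ≈ 5% event rate: odds-ratio recovery is a check on
the estimator, and at a 1.2% rate the Monte-Carlo error of the male-gender
log-odds-ratio would dominate a 10% tolerance even at n = 50,000.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: demographic selection into game types (the propensity
mediator is null by construction), item-level response styles, panel
conditioning, survey weights, or the exact joint distribution of the
Icelandic surveys. It reproduces marginals, cross-type correlation, heavy
tails, zero inflation and plantable causal structure, which is what the
pipeline's correctness arguments need.

## Simulation sizes used in the checks

Chosen to make each property decisive at desk scale: parameter recovery
uses 100 replicates at n = 5000, B = 1000; bootstrap type-I calibration 500
replicates at n = 1000, B = 1000 with the null mediator planted as a ≠ 0,
b = 0 (the asymptotically normal regime — with both paths zero the
percentile bootstrap of a product is known to be conservative, which would
test a different property); profile recovery 50 replicates of 15 types at
n = 2000, B = 500 with dominance ratio 5 planted (at a planted ratio near
the threshold, sampling noise in the ratio — not the classifier — would
drive occasional equivocal calls); odds-ratio recovery n = 50,000.

## Known limitations

- Cross-sectional mediation: no temporal precedence, no causal claims.
- OLS on skewed, bounded, integer outcomes; estimates are consistent for
  the linear projection but the score is not conditionally normal.
- The percentile bootstrap's redraw rule for degenerate resamples slightly
  conditions the resampling distribution on non-degeneracy; at the sample
  sizes of interest redraws are rare (they are counted and reported).
- Very rare game types can make frequency-within numerically identical to
  participation (all participants in one category); such fits abort with a
  collinearity diagnostic rather than returning unstable estimates.
- Survey weighting is out of scope; analyses treat the merged sample as one
  unweighted population.
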