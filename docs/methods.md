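# Methods

## The model

Walk distance is modelled multiplicatively,

    distance = a_sex · height_cm^b · mass_kg^c · exp(d · age) · exp(ε),

with ε ~ N(0, σ_log²) on the natural-log scale. The model assumes (i) power-law
scaling of endurance performance with body dimensions, (ii) an exponential
(constant-proportional) age decline, (iii) sex affecting only the level, not
the exponents, and (iv) homoscedastic multiplicative errors. Under (iv),
taking natural logs yields a linear model whose OLS fit is the maximum-
likelihood estimator:

    log(distance) = β₀ + β_f·1[female] + b·log(height) + c·log(mass) + d·age + ε.

`fit_allometric` solves this via `statsmodels.OLS` with an overall intercept
plus a female shift, then back-transforms `a_male = exp(β₀)`,
`a_female = exp(β₀ + β_f)`. Natural logarithms are used throughout; the base
does not affect predictions but fixes the scale of `d` (per-year log-distance
slope). Adjusted R², coefficient standard errors and the residual SD are
reported on the log scale, where the model is linear; no back-transformed R²
is reported. No weighted, intercept-free or sex-interaction variants are
offered. The age coefficient is stored signed (negative = decline); the
reporting layer prints the derived summary 100·(1 − e^d) as "% decline per
year" (0.896 % for d = −0.009, displayed as 0.9 %).

Degenerate inputs: fitting requires n ≥ 5, strictly positive height, mass and
distance, and both sexes unless the caller opts into one shared intercept
(`allow_single_sex=True`, giving `a_male == a_female`). A rank-deficient
design (constant covariate, or a single sex without the opt-in) raises
`SingularDesignError` rather than returning an arbitrary least-norm solution.

## Agreement statistics

For one (actual, predicted) pairing the report carries: Pearson r with a
two-sided p from the t distribution on n−2 df; the paired t statistic
mean(diff)/(SD(diff)/√n) with a two-sided p on n−1 df (identical to a
one-sample t on the differences); bias = mean(predicted − actual);
SD of differences with the n−1 denominator; and

    CV% = 100 · SD(differences) / mean(predicted).

This CV definition is a reconstruction: published tables of this design print
a CV row without stating the formula, and 100·SD_diff/mean_predicted
reproduces the printed row to one decimal in 8 of 10 columns (e.g.
67/512 → 13.1, 73/570 → 12.8, 88.8/507.4 → 17.5; the remaining two,
78.4/582 → 13.47 vs printed 13.4 and 67.3/573 → 11.75 vs printed 11.7,
appear truncated rather than rounded). It is adopted as the package
definition. Two further anomalies in the source tables are documented but
not emulated: the printed "Differences" row equals exactly twice
(mean predicted − mean actual) in every column — the package computes the
self-consistent value — and one study's SD of differences is referred to as
a "bias" in the surrounding text; the package keeps the two labels distinct.
Identical vectors are well-defined (bias 0, SD 0, r = 1, t = 0, p = 1); a
zero-variance vector makes r undefined and raises rather than emitting NaN.
P-values are two-sided with no multiplicity correction.

## Synthetic cohorts

The generator emulates two samples of community-dwelling European adults:
62 M / 63 F with age 65.3 ± 7.5 y (`sample1_like`, the evaluation sample) and
74 M / 172 F with age 68.3 ± 5.3 y (`sample2_like`, the derivation sample).
Per cohort, one explicitly seeded `numpy` Generator drives everything; no
global RNG state is touched.

- **Ages**: truncated normal on [50, 85] by rejection sampling. Configs whose
  normal places < 1e-6 mass in the window are rejected at construction.
- **Height and mass**: neither source sample reports anthropometric
  summaries, so defaults are plausible European older-adult values —
  height mean ± SD 172 ± 7 cm (men), 159 ± 6 cm (women); mass lognormal with
  median 78 kg (men) / 68 kg (women) and log-SD 0.15; log-scale height–mass
  correlation 0.4. All are overridable, and parameter recovery of the fit is
  unbiased regardless of these choices. To draw (log height, log mass)
  jointly normal while honouring the natural-scale height mean/SD, the
  height marginal is a lognormal moment-matched to that mean and SD (at
  SD/mean ≈ 0.04 the lognormal and normal are numerically indistinguishable).
- **Distances**: the generating allometric model (default: the published
  coefficients above) times exp(ε), ε ~ N(0, σ_log²), default σ_log = 0.12 —
  chosen so that a single n = 246 fit reproduces log-scale standard errors of
  the same order as the published ones (≈0.2 for b, ≈0.05 for c, ≈0.002 for
  d) and an adjusted R² in the 0.3–0.5 range. σ_log = 0 gives exact,
  noise-free closure: fitting returns the generating coefficients to
  numerical precision.

What the generator does **not** emulate: real anthropometric covariance
beyond a single log-scale correlation, cohort-specific exclusion criteria,
learning/test–retest effects, or any deviation from the multiplicative error
model. Passing tests therefore demonstrate that the estimators are correct
and well-calibrated *under the model's own assumptions*, not that the model
describes any particular real population.

## Equation registry

Reference equations are data, not code: a JSON list in which each entry has
per-sex `{intercept, terms}` over the closed covariate set
`{age_years, height_cm, mass_kg}` (units fixed by the key names; equations
published with height in metres are converted on entry), a stated age-validity
range, citation and provenance note. Sex dummies in the original publications
are folded into per-sex intercepts. Evaluating a subject outside an
equation's stated age range, or obtaining a non-positive prediction, warns
but does not fail — applying equations outside their source population is the
analysis's central use case. Several shipped coefficient sets could not be
re-verified against the original publications and are flagged UNVERIFIED in
their provenance fields; no test and no headline result depends on shipped
coefficient values, only on registry structure and evaluation mechanics.

## Workflow determinism and problem sizes

All persisted JSON is written with sorted keys and no timestamps, so a fixed
(config, seed) manifest reproduces every output byte-identically; `replicate`
derives the derivation-cohort seed as `seed + 10000` and records both seeds
in the manifest. The default verification sizes — 200 replicates of n = 246
for parameter recovery and CI coverage, 50 paired replicates of n = 246 vs
n = 2000 for consistency, n = 10,000 for distributional checks — keep
Monte-Carlo error well below the tolerances being asserted (2 MC SEs ≈ 0.03
on the height exponent) while the whole suite runs in seconds.

## Known limitations

- Back-transformed predictions are medians, not means, of the lognormal
  conditional distribution; no smearing correction is applied (matching the
  published equations' use).
- The model fixes exponents across sexes by design; populations with
  sex-specific scaling would need an interaction variant that is explicitly
  out of scope.
- The registry's unverified coefficient entries make stage-1 outputs
  illustrative rather than clinically interpretable until those entries are
  checked against the primary sources.
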