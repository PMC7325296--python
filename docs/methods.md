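# Methods

## Outcome and sample

The outcome is TEHB, tobacco expenditure as a percentage of total monthly
household expenditure, defined for the *analysis sample*: households with
positive tobacco expenditure in the reference month. The
positive-expenditure filter is applied after validation
(`prepare_analysis_sample`); the number of dropped households is logged and
row-count conservation is asserted. TEHB is kept in percent (0–100)
throughout; the concentration index is scale-free, so this choice affects
only descriptive tables.

## Wealth index and ranking

Socioeconomic status is an asset index: the first principal component of
the household's binary/ordinal asset and housing indicators, each
standardized to zero mean and unit variance first (a correlation-matrix
PCA — the indicator list mixes counts, areas and binaries, so raw
covariances would let large-unit items dominate). The component's sign is
arbitrary; it is oriented so the score correlates positively with the
plain sum of indicators (higher = richer). Indicators must be pre-coded
numeric columns; polychoric PCA and multiple correspondence analysis are
out of scope.

Scores are computed by per-column accumulation rather than a BLAS matrix
product so that households with identical indicators receive bit-identical
scores — exact ties must remain exact for the tie rules below to act.

**Quintiles.** Households are classified into five population-share
quintile groups of the score. Assignment goes through mean sorted
positions (average ranks): a block of tied scores shares the quintile of
its mean position. Consequences: with distinct scores classes are as even
as possible (n = 10 gives exactly 2 per class); class sizes differ only by
boundary-tie counts; and fully identical inputs collapse into a single
class rather than being split arbitrarily by input order. The 20/40/60/80
percentile cut points of the training scores are stored on the model as
metadata for scoring new data against the training distribution.

**Fractional rank.** `r_i = i/n` with ties given the mean of their
positions (unbiased rank expectation, standard in this literature). The
midpoint convention `(i − 0.5)/n` is available as an option; it is a
constant shift of `1/(2n)` and leaves any covariance-based index
unchanged.

## Concentration curve and index

The curve orders households by rank (poorest first) and plots cumulative
outcome share against cumulative population share, pooling rank ties into
one step; it starts at (0,0) and ends at (1,1) and lies above the diagonal
when the outcome is concentrated among the poor.

The index is the OLS slope of the convenient regression
`2σ_r²(y_i/μ) = α + φ r_i + ε_i`, with `σ_r²` the *population*
(divide-by-n) variance of the realized ranks, treated as a known scaling
constant. With that convention the slope equals `2 cov(y, r)/μ`
identically, which the implementation records and verifies
(`c_cov` on every result). Confidence intervals: the published analyses
this mirrors report 95% CIs without naming a variance estimator; the
package uses heteroskedasticity-robust (HC1) standard errors with a normal
approximation, the standard practice for this estimator. A
serial-correlation-robust option (`cov_type="HAC"`) is exposed but off by
default, since survey households are exchangeable. Degenerate inputs are
errors: zero outcome mean, constant ranks, n < 3.

No small-sample `1 − 1/n` bound correction is applied and the headline
index is the plain one. Because TEHB is bounded in [0, 100], Erreygers and
Wagstaff normalizations are offered as clearly labelled optional outputs
(`normalized_indices`), never silently substituted.

**Subgroups.** Urban/rural and development-tier analyses treat each level
as a self-contained sample: fractional ranks are recomputed within the
subgroup from the wealth score before estimating its index. Levels with
fewer than 3 households are skipped with a warning.

## Decomposition

For the linear model `y = α + Σ β_k x_k + ε` (OLS, intercept always
included, categoricals reference-coded: male head, literate head,
household size < 4, poorest quintile, urban, low-HDI), the index
decomposes as `C = Σ η_k C_k + 2 cov(ε̂, r)/μ` with elasticity
`η_k = β_k x̄_k/μ` and `C_k` the covariate's concentration index against
the *same* wealth rank. The residual term is computed from the OLS
residuals, not by subtraction, which makes the adding-up identity exact by
bilinearity of covariance; the implementation still verifies it to 1e-8
and the tests to 1e-10. Relative contributions are
`100 × contribution / C`.

Wealth-quintile indicators enter the model as covariates even though the
rank derives from the same score; their resulting dominance of the
explained share is documented behaviour of this standard specification,
not a bug. A covariate with zero mean has no defined `C_k`; its row
reports NaN elasticity/`C_k` with a warning while its absolute
contribution is computed directly as `2 β cov(x, r)/μ` so the identity
survives. Significance stars use robust-SE p-values at 1/5/10%. Standard
errors for the contributions themselves are out of scope.

## Synthetic data generator

The generator emulates a national household income–expenditure survey at
the level the analysis needs, with one latent standard-normal wealth
factor `W` per household driving everything wealth-related:

- **Assets**: each of 14 indicators is Bernoulli with
  `logit p_k = b_{0k} + 2.5 · loading_k · W`, base intercepts spread over
  [−1.2, 1.2], loadings 0.5–1.0. This yields a PCA score whose Spearman
  correlation with `W` is ≈ 0.93 at the default size.
- **Participation**: positive tobacco spending is logistic in `W` (slope
  −0.3 log-odds/SD; poorer households spend more often). The intercept is
  solved numerically (Gauss–Hermite + Brent) so the *marginal* rate equals
  the configured 20% regardless of the slope.
- **Intensity**: among spenders, TEHB (%) is linear in `W` and centred
  covariate effects plus Gaussian noise (SD 3), floored at 0.1 and capped
  at 100. A linear truth is deliberate: the decomposition model is linear,
  so linear truth makes parameter-recovery tests sharp. Participation and
  intensity get separate wealth slopes because prevalence (~20%) and mean
  budget share (~5%) are distinct phenomena.
- **Covariates**: head age N(49.9, 13.6²) clipped to [18, 95]; female head
  5.2%; illiterate head 20.7% with log-odds slope −0.9/SD wealth (literacy
  concentrated among the rich); household size 1 + Poisson(2.9) (≈ 52%
  of households of size ≥ 4); percent male N(55.2, 15²) clipped to
  [0, 100]. Centred effects on TEHB: urban −1.2, HDI tier (+1.0/−0.1/−0.9
  for low/middle/high), age +0.02/yr, female +1.5, illiterate +1.5,
  size ≥ 4 −0.4, percent male −0.005/pp.
- **Strata**: urban share 0.47; provinces 1–31 partitioned 11/10/10 across
  low/middle/high development tiers with household probabilities
  0.36/0.33/0.31; the urban wealth slope is scaled by 1.1 so the urban
  gradient is stronger than the rural one, matching the pattern of the
  study conditions emulated.
- **Expenditure levels**: total expenditure is log-normal in wealth.
  Currency magnitudes are arbitrary — TEHB is a share.

Calibration: `tehb_intercept = 4.82` and `tehb_wealth_slope = −1.17` were
set, once, so that the latent-rank oracle gives C ≈ −0.1425 at n = 10⁶ and
the realized mean TEHB among spenders ≈ 5.2–5.3%; these defaults define
the package's reference study conditions and are not tuned per run.

**Oracle.** `true_concentration_index` is the brute-force ground truth: it
simulates a large population, ranks *by latent wealth* (bypassing the
asset-PCA stage entirely) and applies the covariance formula on the
spender subsample. The asset route is a noisy measurement of `W`, so the
pipeline estimate is mildly attenuated toward zero relative to the oracle
(≈ 6–8% at the default asset strengths); the recovery tests bound the
total error (attenuation + sampling) at 0.02 in absolute value.

**What the generator does not emulate**, hence what passing tests cannot
show about real surveys: cluster sampling designs and survey weights (the
analysis is unweighted throughout); covariate cross-correlations beyond
the single latent factor (e.g. wealth is independent of urbanicity and
province tier by construction, so the ecological covariates' own
concentration indices are near zero here, unlike in real data);
multi-product tobacco composition; heaping, recall error and other
reporting artefacts; and the skewed, zero-inflated shape of real
expenditure shares beyond a floored Gaussian.

## Problem sizes

Module tests run on 10,000 generated households (~2,000 spenders). The
end-to-end acceptance checks use 10,000 households per seed for recovery
(20 seeds), 50,000 for prevalence calibration and curve geometry, and 10⁶
for the Monte-Carlo oracle — sizes at which Monte-Carlo error is small
relative to every asserted tolerance while the whole suite stays fast on
one CPU.

## Reference-table audit

The national decomposition table that serves as the worked example prints
rounded inputs (elasticity and covariate index at 3 decimals, relative
contributions at 1). The audit recomputes `elasticity × C_x` and
`100 × contribution / (−0.142)` per row and compares at printed precision
with the tolerance implied by input rounding (±5e-4 on each 3-dp input,
propagated, plus half a unit in the printed place). Three wealth-quintile
rows and the printed column sum are mutually inconsistent as printed and
are reported but not asserted.
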