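# Methods

`vawmi` implements a two-track psychometric analysis of the 15-item WHO
violence-against-women (VAW) instrument for binary ("yes"/"no", past 12
months) responses: a limited-information exploratory factor analysis that
establishes the three-domain structure (psychological, physical, sexual),
and a Bayesian MIMIC (multiple-indicator multiple-cause) probit model that
tests whether the items measure those domains the same way across
population subgroups. A synthetic-data generator with study-shaped
presets makes every stage testable end to end.

## The model

For respondent i and item j,

    eta_i  = B x_i + zeta_i,          zeta_i ~ N3(0, Psi)
    y*_ij  = nu_j + lambda_j' eta_i + a_j' x_i + eps_ij,  eps_ij ~ N(0, 1)
    y_ij   = 1  iff  y*_ij > 0

where x_i collects dummy-coded categorical covariates (site, age group,
marital status, schooling, education, religion, ethnicity, sexual debut,
food insecurity, wealth tercile, intervention invitation). The three
factors are correlated violence propensities; identification fixes
diag(Psi) = 1 and the residual variance of y* at 1 (theta
parameterization). A covariate acting through B shifts latent means
("population heterogeneity"); a nonzero direct effect a_jc means item j
responds to covariate c *beyond* the factors — scalar noninvariance
(differential item functioning). Reported estimates are standardized
(STDYX): loadings by SD(eta_k)/SD(y*_j), covariate effects additionally by
the sample SD of the dummy column, with SD(y*_j) from the full
model-implied variance.

## Stage 1 — descriptives

Per-item prevalence, the cumulative acts-of-violence distribution
(thresholds >= 1 ... >= 15; "at least half" of 15 acts is read as >= 8,
the smallest integer above 7.5), sample composition tables, and a wealth
index: first principal component of the correlation matrix of binary
asset indicators, oriented positively toward total assets owned, cut into
terciles at the 33.33/66.67 percentiles with ties kept low.

## Stage 2 — tetrachoric ESEM (configural structure)

Each item pair's 2x2 table is fit by a dichotomized bivariate normal:
thresholds from the margins (tau_j = Phi^-1(1 - prevalence_j), matching
the y* > 0 convention), correlation by profile maximum likelihood.
Orthant probabilities use an Owen's-T expression of the bivariate normal
CDF (abs. error ~1e-14). A continuity correction (+0.5 to every cell
when any cell is empty — relevant for the 1.6%-prevalence item in
subsamples) is on by default; tables with a zero margin are fatal without
it. The pairwise matrix is repaired to positive semidefinite by
eigenvalue clipping (floor 1e-8, diagonal renormalized) when needed, and
the repair is flagged. Asymptotic variances treat thresholds as fixed
(two-step): Var(rho-hat) = 1/(n I), I = phi2(tau1,tau2;rho)^2 * sum(1/pi_c).

The 3-factor model is estimated by diagonally weighted least squares on
the non-redundant correlations, F = sum_r (s_r - sigma_r)^2 / v_r with
v_r the (unit-level) tetrachoric variances; start values are principal
factors of the SMC-reduced matrix; Heywood rows are rescaled onto the
admissible boundary (uniqueness floor 1e-3) and flagged. The chi-square
is the unadjusted T = n F_min; the mean-and-variance-adjusted statistic
of commercial DWLS software is proprietary and not reproduced, so printed
fit indices are comparable only up to that adjustment. Oblique Geomin
rotation (epsilon = 0.001) uses gradient projection with 30 seeded random
orthonormal starts plus identity; ties within 1e-8 break by lexicographic
loading order; the projected-gradient tolerance is 1e-6 with a
stagnation break (tighter tolerances are below float64 resolution of the
criterion near the optimum). Columns are aligned to the WHO domain order
by absolute congruence and signed so each column's dominant loading is
positive. Fit: CFI and TLI against the independence baseline (free
thresholds, zero correlations), RMSEA = sqrt(max(T - df, 0)/(df n)) with
a 90% CI from inverting the noncentral chi-square CDF in the
noncentrality parameter, and WRMR.

## Stage 3 — frequentist covariate screen

Per item, a probit model adjusted for {invitation, site, age} is fit with
one candidate covariate at a time; block likelihood-ratio tests (df =
k - 1 for a k-category covariate) at p <= 0.10 admit candidates to a
per-item multivariable probit, where blocks significant at p <= 0.05
(single pass, no iteration) define the item's screened direct effects.
No multiple-testing correction is applied across items — the screen is a
variable-selection device, not confirmatory inference. Perfect
separation falls back to a ridge-penalized Newton fit (penalty 1e-4) with
a warning. Because the screen is *marginal* (it never conditions on the
factors), covariates with strong factor effects are screened onto many
items of that factor; this is expected, and the Bayesian stage is what
separates direct from factor-mediated effects.

## Stage 4 — Bayesian MIMIC (invariance testing)

Gibbs sampling with Albert–Chib data augmentation: truncated-normal
latent responses, multivariate-normal factor scores, conjugate normal
rows for (nu_j, lambda_j, a_j), a conjugate update for B (diagonalized in
a fixed eigenbasis of X'X), and a parameter-expanded inverse-Wishart step
for Psi (draw the unconstrained covariance, map back to the identified
space through the model's scale-invariance group). Defaults: 2 chains,
20,000 iterations, first half burn-in, thinning 2, split-PSR threshold
1.1. Convergence failures are warnings, not errors; flag reporting from
unconverged runs requires `force=True`.

Priors follow the BSEM device of replacing exact zeros with informative
small-variance normals:

- cross-loadings: N(0, 0.01) on the probit scale. This is deliberately
  *not* rescaled per item to the standardized scale: with communalities
  up to 0.96 the standardized-scale reading loosens the rotation anchor
  enough that factors wander between labelings within chains. The firm
  anchor costs a known bias — items whose true cross-loadings are large
  (~0.3) have their major loadings absorbed upward by roughly 0.1 at
  n ~ 2,000, and factor correlations are somewhat inflated relative to
  the ESEM solution (the same qualitative gap the original analysis
  reports between its Bayesian and ESEM factor correlations).
- diffuse parameters (intercepts, major loadings, screened direct
  effects, B): N(0, 25) on the standardized scale, implemented by fixed
  empirical rescaling — design columns are standardized internally and
  item scales 1/(1 - SMC_j) come from the tetrachoric matrix — so that
  e.g. an intercept of -9.9 on the probit scale of a high-communality
  item is not accidentally shrunk.
- identification-shrink direct effects: N(0, 0.01) on the probit scale
  for the always-retained covariates (invitation, site, age), which are
  free on all 15 items and therefore not separable from their factor
  effects (only lambda_j'B + a_j is identified; three flat directions
  per covariate). The same demotion is applied, per covariate, to all
  but the strongest-evidence screened item when a screened set covers an
  entire factor (majority anchoring); otherwise the factor regression
  would again be unidentified against the direct effects.

Residual label switching between chains is resolved post hoc by aligning
each chain (column permutation + sign) to the WHO pattern via congruence
of its mean loadings.

Model fit uses a posterior predictive p-value with a limited-information
discrepancy: squared standardized residuals of the 15 item margins and
105 pairwise both-yes proportions against their model-implied values
(factors integrated out; pairwise probabilities from the latent-response
correlations with margin-matched thresholds — covariate heterogeneity
beyond the margins is ignored identically for observed and replicated
data). A purely marginal (likelihood-based) discrepancy was rejected: it
is provably blind to dependence-structure misfit, which is precisely what
a factor model must be checked against. PPP is the fraction of retained
iterations with D(y_rep, theta) >= D(y_obs, theta); values near 0.5
indicate good fit.

An item–covariate-level pair is flagged noninvariant when the 95%
equal-tailed credible interval of its standardized direct effect excludes
zero.

## Synthetic data

`generate_survey` draws covariates independently from stated categorical
marginals (the wealth tercile comes from the same latent normal wealth
score that drives a 12-item asset battery with logistic ownership
curves, slope 1.5, intercepts spanning ~10–90% ownership), then factors,
latent responses and items exactly per the model above. Closed forms are
provided for the conditional response probability, the population
prevalence (exact, via blockwise convolution of the linear predictor's
discrete distribution), and the implied pairwise latent correlation —
these serve as the oracles for the generator's own tests.

Two presets mirror the published Nairobi DREAMS analysis (n = 1,081):
`study_preset` carries the published standardized loadings, factor
correlations, covariate effects on factors, and the five noninvariant
items' direct effects; `measurement_preset` is the measurement model
alone (B = A = 0), the correct truth for factor-recovery experiments
because covariate effects inflate Var(eta) beyond Psi and shift the
marginal factor structure. Item intercepts are solved numerically
(Brent, tolerance 1e-8) so marginal prevalences match a study-shaped
profile: the published extremes (26.5% and 1.6%) are exact anchors and
the remaining 13 values are synthetic, calibrated once so the cumulative
acts distribution reproduces the published ~44% (>= 1 act) and ~2.7%
(>= 8 acts). Covariate marginals reproduce the published sample where
printed (site 617:464, 57.8% in school, 59.4% sexually active, 78%
never married, 84.8% Christian) and are realistic fill-ins elsewhere.

What the generator does not emulate: missing data (none reported),
within-household or interviewer clustering, any dependence among
covariates beyond the wealth–asset link, and the far tail of the acts
distribution (the published 0.3% with >= 14 acts is beyond a 3-factor
probit with these correlations). Passing recovery tests therefore shows
the estimators work under the model's own assumptions at study-like
margins — not that real interview data meet those assumptions.

## Problem sizes used in the test suite

Generator-vs-closed-form checks run at n = 200,000; ESEM recovery at
n = 100,000; MIMIC recovery at n = 2,000 with 2 x 5,000 iterations;
credible-interval calibration on 100 datasets of n = 1,000 with
2 x 2,000 iterations; PPP calibration on 50 datasets of n = 500. The
acceptance script runs the full pipeline at the study scale n = 1,081
with 2 x 8,000 iterations.

## Known limitations

- The unadjusted DWLS chi-square differs from mean-and-variance-adjusted
  statistics; fit indices agree closely in well-fitting models but are
  not identical to commercial output.
- At study scale (n ~ 1,000) the rarest items (< 2%, i.e. ~16 positive
  responses) make both the tetrachoric matrix and the covariate screen
  noisy: Geomin solutions can deviate visibly from the population
  rotation, the screen admits unstable blocks, and the MIMIC stage can
  flag spurious direct effects on those items. This mirrors the method's
  behavior on real data of this size, and is the reason the original
  analysis's caution about its rarest item is well taken.
- Under the BSEM cross-loading prior, major loadings of items with
  substantial true cross-loadings are biased upward (~0.1 at n = 2,000);
  see the prior discussion above.
- The PPP's pairwise-moment discrepancy ignores covariate-induced
  heterogeneity beyond the margins; gross structural misfit is detected,
  subtle covariate-dependent misfit may not be.
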