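# Methods

## The biometric model

A twin pair's phenotype vector (k traits per twin, 2k per family) is modelled
as multivariate normal with a covariance implied by latent components:
additive genetic (A), shared environment (C) *or* dominance (D), and
non-shared environment (E). Within-twin covariance is Σ = A + C + D + E;
cross-twin covariance is r_A·A + C + r_D·D with r_A = 1 (MZ) or 0.5 (DZ) and
r_D = 1 or 0.25. E never crosses twins, so it also absorbs measurement
error. C and D cannot be separated with twins reared together (the ACDE
model is unidentified), so a model contains at most one of them; DE is
refused outright because dominance without additive variance is biologically
implausible.

Four structures parameterize the component matrices:

- **univariate** — scalar paths a, c/d, e; component variances are the
  squared paths, hence non-negative by construction.
- **cholesky** — per component a lower-triangular path matrix L with
  covariance L·Lᵀ. This is the saturated biometric structure; its
  correlated-factors transform r_ij = X_ij/√(X_ii·X_jj) (X = L·Lᵀ) yields
  the genetic/environmental correlation matrices. The transform is a pure
  reparameterization: component covariances rebuilt from (r, standardized
  variances) equal L·Lᵀ to machine precision, which the tests assert.
- **independent pathway** — per component, one common factor loading
  directly on all traits plus a trait-specific path:
  X = f·fᵀ + diag(s²).
- **common pathway** — a single latent phenotypic factor with component
  paths (a_F, c_F, e_F), loadings λ_i, and trait-specific residual paths:
  X_c = path_c²·λλᵀ + diag(s_c²).

Every common-pathway model is expressible as an independent-pathway model
(common loadings λ·path_c), and every independent-pathway model as a
Cholesky model (factor the component covariance); the package provides
these conversions and tests that implied covariances agree to machine
precision.

## Identification and degrees of freedom

The common-pathway factor is identified by fixing its variance to 1:
a_F² + c_F² + e_F² = 1, with loadings free. Means are one per trait, shared
across twins and zygosity groups. Free-parameter counts for k = 4, AE:
Cholesky 2·10 + 4 = 24, independent pathway 2·8 + 4 = 20, common pathway
1 + 4 + 8 + 4 = 17; with complete data on 1958 pairs (15,664 observations)
the df ladder is 15,640 / 15,644 / 15,647, and the univariate ladder
(3916 observations) is 3912 (ACE) / 3913 (AE, CE) / 3914 (E). df is always
"non-missing phenotype observations minus free parameters". The saturated
baseline frees per-group means per twin position and the full 2k×2k
covariance (10 parameters for k = 1).

Sign conventions: Cholesky diagonal non-negative (column flips), first
loading of every factor non-negative, specific paths reported as absolute
values. None of these change the implied covariance.

## Estimation

All biometric models are fitted by full-information maximum likelihood on
raw data: each family contributes −2·log N(observed subvector; μ, Σ_zyg
submatrix), so families with a missing co-twin still contribute. Families
are grouped by (zygosity, missingness pattern) and summarized by sufficient
statistics (n, Σx, Σxxᵀ), making an objective evaluation one Cholesky
factorization per pattern; with complete data this equals the closed-form
two-group multivariate-normal likelihood at the group moments (asserted at
1e-6 relative tolerance in the tests). A non-positive-definite implied
covariance returns a large penalty (1e12 plus a slope in the most negative
eigenvalue), never an exception.

Optimization is quasi-Newton (L-BFGS-B, numerical gradients) with
moment-based starting values — Falconer-style component estimates from the
MZ/DZ covariance blocks, eigendecompositions for factor starts — plus
seeded random multiplicative restarts (default 5; recovery loops use 1
because the moment starts already sit in the right basin). Convergence is
declared when the objective changes by less than 1e-8 between iterations.
The saturated model uses the closed form whenever a group is complete and
numeric optimization over mean + Cholesky-parameterized covariance
otherwise.

**Profile-likelihood CIs** (univariate): the 95% bound for a standardized
component is the value at which the profiled −2lnL rises 3.8415 (χ²₁)
above the minimum, re-optimizing total variance, the split of the remaining
components and the mean at each fixed share (Nelder-Mead inner fits with a
warm-start chain; after a jump in the constrained share larger than 0.05
the unconstrained fit is also tried as a start and the better optimum
kept). Roots are located by Brent's method; a side with no root inside
[0, 1] is clipped to the boundary and flagged. The χ²₁ threshold is used
regardless of boundary proximity, so coverage at a boundary can exceed the
nominal level (the 50:50 mixture correction is deliberately not applied —
this matches the naive-χ² reporting convention of the comparison tables,
e.g. p = 0.08 for Δχ² = 3.02 at Δdf = 1).

## Model selection conventions

χ² for a structured model is its −2lnL minus the saturated −2lnL, reported
with the model's own df; Δχ² between nested structured models uses their
difference in −2lnL and df. AIC = χ² − 2·df and BIC = χ² − df·ln(n_units)
with **n_units = number of families** (not individuals) — the convention
that reproduces the reference tables' arithmetic exactly. Selection
minimizes BIC (AIC available), breaking ties toward the larger-df (more
parsimonious) model. Writers print criteria to 2 decimals and truncate
p-values below 0.01 to "< 0.01"; full precision is kept internally.

## Phenotypic layer

- Descriptives pool both twins (SD with n−1).
- Correlations are individual-level Pearson; partial correlations are
  correlations of residuals after pooled OLS on age (linear) and sex (0/1).
  CIs are Fisher-z with effective n = individuals. The pooling ignores the
  within-family dependence for these point estimates; no inference is drawn
  from the regression itself, and the exact CI construction behind the
  reference study's table cannot be identified from its printed digits, so
  CIs here are validated by construction (Fisher z), not digit-matching.
- ICCs are constrained-ML bivariate-normal correlations (equal means and
  variances across twin order), r̂ = 2s₁₂/(s₁₁+s₂₂) about the grand mean —
  exactly invariant to twin order, cross-checked in the tests against
  direct numerical maximization. CIs are Fisher-z on pair count.
- The one-factor CFA minimizes the ML discrepancy
  F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − k on a correlation matrix, χ² = (n−1)F,
  with the independence model (free variances) as CFI baseline, RMSEA from
  the non-centrality per df, and SRMR as the RMS residual over the lower
  triangle including the diagonal. From raw twin data the input is one
  randomly selected twin per family (seeded) to avoid within-pair
  dependence.
- Scale scores are means of available items after reversing keyed items
  (x → 6 − x on the 1–5 range); a score requires at least half the items
  answered (configurable). Cronbach's α uses complete rows.

## The simulator and its calibration

Simulation is latent-variable based: per component, standard-normal factor
scores are drawn per twin with the component's cross-twin correlation
(via a shared/own decomposition z = √r·z_shared + √(1−r)·z_own) and
composed through the structure's path matrices — distributionally identical
to drawing from the implied 2k-normal, but component realizations are
available for debugging. Age is uniform on 9–18 years and shared within
pair; sex is Bernoulli(1/2), identical in MZ pairs, independent across
twins in DZ pairs. Covariate effects are linear, centred, and applied on
the observed scale; implied covariances therefore describe the
covariate-free scores. Optional Likert discretization (round and clip to
1–5) serves item-style fixtures; analyses consume continuous scores.

`study_mirror_spec()` is an AE common-pathway model calibrated to the
reference study's published summary statistics: loadings
λ = (0.90, 0.88, 0.87, 0.86), factor paths a_F = 0.85,
e_F = √(1 − 0.85²) — reproducing the reported factor heritability
(≈ 0.72) and the (0.90, 0.85, 0.22) triple of the published worked share
formula — with specific paths solved so each trait has unit unscaled
variance and heritabilities (0.634, 0.630, 0.640, 0.630). Trait means
(3.13–3.15), SDs (0.41–0.52) and small age/sex effects (β_age = 0.02 per
year, β_sex = 0.03) match the published descriptives; the covariate effects
are sized so residual–original correlations stay above 0.98, as reported.

Two calibration tensions are intrinsic and documented rather than hidden:
(i) under any AE generative model the implied MZ intraclass correlation
equals the standardized heritability, so with h² calibrated to 0.62–0.64
the implied MZ ICCs (0.63–0.64) sit slightly above the published saturated
ICCs (0.56–0.61) — the published table's ICCs and AE estimates come from
different models fitted to the same raw data, which no single generative
spec can match simultaneously; heritabilities, DZ ICCs and the correlation
structure were prioritized. (ii) with the fixed loadings the largest
implied phenotypic correlation is 0.90·0.88 = 0.792, at the upper edge of
the published 0.74–0.79 (it rounds to 0.79).

What passing recovery tests show — and do not show: the simulator realizes
exactly the assumed biometric model (normal latents, no sex limitation, no
assortative mating, no sibling interaction, no rater bias, linear covariate
effects, continuous scores). Parameter recovery under these conditions
validates the estimation machinery; it cannot validate those substantive
assumptions against real questionnaire data, where rater effects and
Likert coarseness are certainly present.

## Problem sizes used in the checks

Recovery and coverage checks use 200 replicates at the study's zygosity
sample sizes (1135 MZ / 823 DZ); simulator-moment checks use 10⁵ pairs with
3–3.5 Monte-Carlo SE bands (the wider band for the 36-entry matrix-wide
maximum); smaller smoke datasets (a few hundred pairs) exercise the
pipeline end to end.

## Known limitations

- No sex-limitation or opposite-sex-specific models (opposite-sex DZ pairs
  are pooled with same-sex DZ); no extended pedigrees, bootstrap CIs, or
  heterogeneous means/variances by sex or zygosity.
- Profile CIs are implemented for univariate standardized components;
  multivariate solutions report point estimates.
- The independent-pathway structure uses a single set of common factors
  (one per component).
- BIC last digits can differ by ~0.01 from tables recomputed from rounded
  printed χ² values; writers carry full precision.
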