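# Methods

## Model and procedure

`cndclr` operationalizes compositional nutrient diagnosis (CND-clr) as a
five-stage pipeline per group of samples.

**1. Closure and clr transform.** Each sample's 11 nutrient concentrations
are expressed in mg kg⁻¹ (macronutrients arrive in g kg⁻¹ and are scaled by
1000) and closed with a filler component R = 1,000,000 − Σ(nutrients), the
unanalyzed rest of the dry matter. The centred log-ratio of the 12-part
composition, clr_j = ln(x_j) − mean(ln x), is the working coordinate system:
it is scale-invariant, treats every nutrient relative to the whole
composition, and sums to zero by construction. Zeros are rejected rather
than imputed — the pipeline is defined for complete analyses, and any
imputation policy would be a modelling decision this package does not make.
The filler is a full citizen of the composition (it appears in clr vectors,
norms, indices and correlations) with one exception, below.

**2. Outlier screen.** Within each dataset, the squared Mahalanobis distance
of each sample from the dataset's own centroid is computed on the 11
nutrient clr coordinates, with the unbiased (n−1) covariance estimator. The
filler coordinate is dropped here: the zero-sum constraint makes the full
12-coordinate covariance singular. Samples above the χ²(df=11) upper-α
quantile (default α = 0.05) are excluded in a single pass — no iterative
re-filtering, since each pass would recentre the estimate on a shrinking
set. The filter runs on the dataset *before* reference selection. Exclusion
is monotone in α and every exclusion is itemized in the report.

**3. Norms.** The high-yield reference subpopulation is selected by one of
three rules: top fraction of yields (default 0.5; boundary ties are all
included so the rule is permutation-safe), explicit yield threshold, or
explicit id list. Its per-component clr means V* and SDs SD* are the norms.
Uncertainty bounds are the standard two-sided t interval V* ±
t₁₋α/₂,ₙ₋₁·SD*/√n with n the reference size — so UCB and LCB are exactly
symmetric about V*, an identity the reporting layer re-checks on every
emitted table. On the index scale the band is ∓ t/√n around zero, and a
sample's nutrient is called balanced when its index lies inside the closed
band, deficient below, excess above (closed interval: band edges count as
balanced, so the classification is stable under round-tripping through
serialized norms).

**4. Indices and imbalance.** I_X = (V_X − V*_X)/SD*_X over all 12
components, and r² = Σ I_X². For draws from the fitted normal in index
space the expected r² is the component count (12); for real clr vectors the
zero-sum constraint removes one effective dimension, so group means nearer
11 are expected and normal.

**5. Critical levels and sufficiency ranges.** For each nutrient, ordinary
least squares fits tissue concentration (response, native units) on CND
index (predictor); the model's prediction at index zero is the critical
level NC. The regression direction follows from the definition of NC: the
index is *set* to zero and the concentration is read off. The default model
is linear (a quadratic is available by configuration); with the linear form
NC is the intercept. The sufficiency range is NC ± ⅔·SD of the reference
subpopulation's concentration, making NC the exact midpoint — the one
exception is a lower bound that would fall below zero, which is clipped to
zero with a logged warning. Output tables are emitted unrounded; rounding
is presentation-layer only.

## Multivariate screens

* **PCA** runs on the correlation matrix (all variables standardized) of the
  12 clr variables, integer-coded grouping factors (region, cultivar, year;
  coded by first appearance and logged) and yield. Coding categoricals as
  integers for a PCA is statistically unorthodox; it is retained
  deliberately because it mirrors established survey practice in this
  literature, and it is confined to this screen. Factors with eigenvalue
  greater than 1 are retained; loadings with magnitude ≥ 0.70 are flagged
  as contributing.
* **Canonical discriminant analysis** solves the generalized symmetric
  eigenproblem B v = λ W v on the 11 nutrient clr coordinates (the filler is
  dropped for the same singularity reason as in the distance screen).
  Wilks' Λ is reported overall (Π 1/(1+λ)), stepwise per root, and per
  variable (univariate within/total sum-of-squares ratio). Root count is
  capped at min(groups − 1, variables).
* **Two-group comparisons** use the pooled-variance two-sample t per clr
  variable (equivalent to a two-group one-way ANOVA); Welch's t is available
  by flag. Groups are declared similar on a variable at p > 0.05.
* **Yield correlations** are plain Pearson r with two-sided p, computed for
  the native-unit concentrations and for the clr variables, starred at
  p < 0.05.

## Synthetic data: what it emulates, what it does not

The generator draws clr vectors componentwise-normal around a configured
mean (optionally with exchangeable correlation), re-centres them to the
zero-sum space, and maps them through the inverse clr onto closed
compositions — so feasibility (positive parts, exact closure) holds by
construction and never needs resampling. Yield is
max(0, yield_mean + slope·r² + noise) with the generating r² measured
against the true parameters and slope ≤ 0, so imbalance depresses yield;
`yield_mean` is therefore the yield of a perfectly balanced plant, and the
realized group mean sits ≈ 12·slope below it. A configured fraction of
samples is planted as outliers by shifting two randomly chosen nutrient
coordinates by a configured number of SDs (nutrients only — a filler-only
shift would be invisible to the screen that drops the filler).

The default study configuration encodes a seven-group grapevine survey:
group sizes 53, 93, 95, 96, 99, 21 and 36; published per-nutrient clr
means and SDs per group, with the filler mean closing each vector to zero
sum and a filler clr SD of 0.08 (the filler is >90 % of dry mass and varies
little on the log scale; no published value exists); yield ranges per group
mapped to mean = midpoint and SD = range/6; outlier fraction 0.02 at +6 SD;
imbalance slope −0.3 t ha⁻¹ per unit r². One property of these defaults is
worth stating plainly: the published 11-nutrient clr means, once closed by
the zero-sum constraint, determine the full composition, and the implied
native-unit concentrations are larger than real leaf mass fractions
(e.g. N ≈ 150 g kg⁻¹). The defaults therefore reproduce the *clr geometry*
of the published standards exactly while the native-unit scale is stylized.
Every computation in the pipeline is invariant to this (clr methods are
scale-free), and no test compares synthetic native concentrations to field
values. Other things the generator does not emulate: analytical measurement
error structure, year/plot random effects, nutrient-specific covariance
(beyond the exchangeable knob), and censoring or missingness. Passing tests
therefore demonstrate correctness and statistical calibration of the
pipeline, not field realism of any particular concentration value.

Calibration groups used in tests and in the acceptance script use the same
published mean vector with a uniform clr SD of 0.2. The concentration–index
relation is exponential (conc ≈ g·e^{μ+SD·I}), so the linear NC estimate
carries a curvature bias of roughly e^{SD²/2} − 1 relative — about 2 % at
SD 0.2, but >10 % at the largest published SDs (~1.1). Recovery claims are
therefore made, and tested, in the moderate-SD regime that matches the
median published spread (~0.3); the bias at extreme spreads is a property of
the linear critical-level model itself, not of this implementation.

## Numerical choices

* Covariance inversion and the W⁻¹B eigenproblem go through dense solvers
  with a condition-number guard at 1e12; beyond it the computation refuses
  with a suggestion (regularize, enlarge, or reduce variables) rather than
  returning noise.
* Mahalanobis distances satisfy the exact trace identity Σ MD = d·(n−1)
  under the n−1 estimator; the test suite pins this.
* `inverse_clr` rejects rows whose coordinates sum beyond 1e-6 of zero
  instead of silently re-centring user input; the generator's own draws are
  explicitly re-centred before inversion.
* Eigenvector sign is fixed (largest-magnitude element positive) so PCA and
  CDA outputs are deterministic across runs and platforms.
* Minimum sizes: n ≥ d+2 for the distance screen, n ≥ 5 for norms and
  regressions; a reference below 5 via explicit threshold rules is allowed
  with a logged warning, below 1 is an error.
* Problem sizes in tests and the acceptance script (groups of 100–500,
  20 outlier-recall replicates, 1000-draw Monte Carlo) were chosen as the
  smallest sizes at which the binomial/CLT tolerances of each check are
  comfortably separated from its failure modes; the full suite runs in a
  few seconds.

## Known limitations

* Only the clr flavour of log-ratio analysis is implemented (no ilr/alr),
  and only single-pass outlier filtering (no robust/MCD covariance).
* The critical-level model is a global linear (optionally quadratic) fit;
  boundary-line and quantile approaches are out of scope.
* The published survey's exact exclusion counts and confidence-interval
  widths are not reproducible without its data; this package documents its
  own rules (χ² cutoff, t interval with the reference n) and verifies the
  identities those tables do satisfy instead of chasing printed digits.
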