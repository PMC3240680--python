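# Methods

This note documents the statistical procedures `reefeye` implements, the
choices made where the methods literature leaves latitude, what the
synthetic generator does and does not emulate, and known limitations.

## Data model and preprocessing

The unit of observation is a specimen: taxonomic metadata, a diel class
(nocturnal/diurnal), standard length (mm), body mass (g), and up to two
eyes, each with five measurements in mm (ED eyeball diameter, AL axial
length, LD horizontal lens diameter, PDmax/PDmin largest/smallest pupil
diameter). Preprocessing is fixed: per-specimen trait values are the
arithmetic mean of the available eye sides; species values are
unweighted means of specimen values; analyses on the log scale use
log₁₀ values rounded to four significant figures. Significant-figure
rounding is applied to the signed log value (−1.154901 → −1.155, the
same result as `%.4g`); the convention is centralized in
`core_data.round_sig`. Ratio statistics are computed from the
untransformed species means, not from the rounded logs.

Anguilliform families (default Muraenidae, Congridae, Ophichthidae) can
be excluded from the eye-size-vs-mass regression: their elongated
bodies give them large mass relative to head (and eye) size, which
would distort a mass-based size correction. The family list is
configurable.

Units: body mass in grams, lengths in millimetres. Intercepts of
log-log regressions are therefore log₁₀ mm at 1 g.

## SMA line fitting and inference

Allometric comparisons use the standardized major axis, the symmetric
line-fitting method standard in allometry where neither variable is an
error-free predictor:

* estimate: `b̂ = sign(r)·s_y/s_x`, intercept `â = ȳ − b̂·x̄`;
* slope CI: the exact pivot `B = F(1, n−2; conf)·(1−r²)/(n−2)` with
  bounds `b̂(√(B+1) ± √B)`;
* slope test of `b₀`: `t = r_uv·√((n−2)/(1−r²_uv))` on n−2 df, where
  `r_uv` is the correlation between residual scores `y − b₀x` and axis
  scores `y + b₀x`; at `b₀ = b̂` the statistic is 0 and p = 1; exactly
  collinear data give p = 0 for any other slope;
* common slope across k groups: `b̂_c` minimises
  `Σ_k n_k·(−ln(1 − r²_uv,k(b)))` (a 1-D profile statistic, Brent-style
  bounded search bracketed by the group slopes and widened as needed,
  relative tolerance 1e−10, no randomness); the minimised value is the
  likelihood-ratio statistic for slope equality on χ²(k−1);
* intercepts at the common slope are group means of `z = y − b̂_c·x`,
  contrasted by a Wald statistic with per-group variance
  `s²_z/n_k + x̄_k²·Var(b̂_c)`, where `Var(b̂_c)` comes from the numerical
  curvature of the profile statistic; the slope-uncertainty term is
  included (whether published intercept contrasts include it is usually
  undocumented; we state our choice here);
* the eye-size factor for an ordered pair of groups is
  `10^(â_A − â_B)` at the common slope;
* intercept (elevation) CI: `â ± t_{n−2}·√(s²_z/n + x̄²·Var(b̂))` with
  `Var(b̂) = b̂²(1−r²)/(n−2)`. This is a first-order approximation; on
  strongly skewed residuals (e.g. pupil roundness near its ceiling) its
  realised coverage runs 1–3 points below nominal at n ≈ 50.

Composite regressors for the optical-ratio framings (LD², ED·AL,
PDmin², LD·PDmin, ED·PDmax) are formed on the natural scale and then
log-transformed (with the same 4-significant-figure rounding), so each
ratio's numerator is regressed on its denominator without
size-dependent bias. Confidence level defaults to 0.95; all tests are
two-sided. Monte-Carlo checks in the test suite confirm nominal type-I
error for the slope test and the slope-equality LR test, and nominal
coverage for the slope CI.

## Optical ratios and pupil geometry

The optical ratio OPT = A²/(RD·PND) indexes light-gathering capacity
but its optical variables are not measurable on preserved specimens, so
three morphological proxies are computed per species: LD²/(ED·AL),
PDmin²/(ED·AL), and (LD·PDmin)/(ED·PDmax). Pupil roundness is
PDmin/PDmax and the aphakic-gap fraction is 1 − LD/PDmax; a negative
gap (lens wider than the pupil's long axis) is preserved, not clipped,
with an informational log message. All five statistics are invariant to
a common rescaling of a species' traits. Class variances of the ratios
are computed on the natural ratio scale by default (log-scale variances
are available behind a flag). The class comparison of gap fractions
uses Welch's two-sample t-test (the R default, and robust to the
unequal class variances this data structure produces). True optical
quantities (focal length, f-number, Matthiessen's ratio) are out of
scope.

## Morphospace

PCA is performed on the Pearson correlation matrix of the selected log
traits (3-trait preset: ED, AL, LD; 5-trait preset adds PDmax, PDmin).
Standardization uses the n−1 variance; for a correlation-matrix PCA the
choice only rescales scores uniformly and is immaterial to every
reported quantity. Eigenvector signs are arbitrary, so a deterministic
convention is applied (largest-magnitude loading entry positive);
comparisons with published loadings should be made up to a global sign
per axis.

Because log eye traits are dominated by a shared size factor, PC1
absorbs ~98% of variance and its scores track the log geometric mean of
the traits (row mean of the logs) almost perfectly; the per-axis SMA
regression of scores on that geometric mean (R² and correlation p) is
the size-axis diagnostic. Shape differences between classes are tested
by a MANOVA (Wilks' lambda with Rao's F) on the PC2–PC3 scores — exact
for two groups, where it coincides with Hotelling's T² (verified to
1e−10 in the tests). Morphospace occupancy uses minimum convex polygons
(scipy Qhull) with boundary-inclusive point-in-polygon tests (shapely).
p-values below 1e−15 are reported as "< 1e−15", never 0.

## Discriminant analysis

All classifiers use priors equal to training-set class frequencies and
report resubstitution error (a single proportion on the full table; a
cross-validation option exists but is off by default, since the
headline numbers this package is designed to produce are resubstitution
proportions). One Gaussian engine underlies LDA/QDA/RDA; the
regularized covariance blends class covariance toward the pooled
covariance with Friedman-style sample-size weights,

    S_k(λ) = [(1−λ)(n_k−1)S_k + λ(n−K)S_pooled] / [(1−λ)(n_k−1) + λ(n−K)],

optionally shrunk toward a scaled identity by γ (default 0). λ = 1
reproduces LDA and λ = 0 reproduces QDA exactly, which pins down the
scan endpoints; the λ scan covers 0–1 in steps of 0.01 and reports the
full set of minimisers because flat plateaus are the norm. FDA is
optimal scoring with a linear regression basis: regress the class
indicator matrix on the traits, eigendecompose the induced scoring
problem, and classify in the resulting variates with a pooled Gaussian
rule. With a linear basis the variates span the LDA canonical subspace,
so FDA predictions coincide with LDA — the reason published linear and
flexible DA error rates agree. Posterior ties break toward the
alphabetically first class.

## Disparity and rarefaction

Disparity of a class is the summed sample variance of its scores on
shape axes PC2–PC5 of the 5-trait PCA. Because the diurnal class is
~4× larger, the comparison is rarefied: each iteration draws a diurnal
subsample of the nocturnal size m without replacement, re-runs the
correlation PCA on the combined 2m-species table (axes are re-derived
per iteration, not projected from fixed full-data axes), and records
both classes' shape variances. The one-sided p-value uses the add-one
permutation convention `p = (1 + #{diurnal ≤ nocturnal})/(n_iter + 1)`,
which can never be exactly zero and matches "p < 0.001"-style
reporting. A single explicitly passed seeded generator makes the whole
distribution bit-reproducible. The full analysis uses 100,000
iterations; the test suite and the acceptance script use 200–5,000,
which bounds the resolvable p at ~1/(n_iter+1) but leaves the variance
distributions' locations unchanged. Note the p-value conditions on the
fixed nocturnal sample: under a null of identical class distributions
it is approximately uniform across datasets, not concentrated near 0.5.

## Synthetic data generator

The generator produces specimen tables with the structure the analysis
assumes: class-specific log-linear allometry of ED on body mass,
near-isometric trait ratios (AL/ED, LD/ED, PDmax/LD, PDmin/PDmax) with
small log-normal scatter, a class difference in pupil roundness and
relative lens size, a diurnal shape-dispersion multiplier, and
specimen- plus eye-level measurement noise, all on the log₁₀ scale.

Two structural choices matter:

* **Allometric noise is symmetric (errors-in-variables).** Both log
  mass and log ED scatter around a shared latent size (x-noise sd =
  resid_sd/slope, y-noise sd = resid_sd). A regression-style generator
  (noise only on ED) would make the SMA slope systematically exceed the
  nominal parameter by ≈ resid²/(2·slope·var x); since SMA is an
  errors-in-variables estimator, the symmetric model is the one under
  which "the generator's slope" is a well-defined recoverable quantity.
* **Pupil roundness is a negated gamma split across both axes.** The
  roundness log-ratio d = log₁₀(PDmin/PDmax) is drawn from a negated
  gamma with mean exactly the intercept parameter and the configured
  sd; its support (−∞, 0] enforces PDmin ≤ PDmax by construction with
  no truncation shift of the mean. d is split half onto each pupil axis
  around a shared centre, making the PDmin-vs-PDmax SMA slope exactly 1
  and its intercept the parameter; the centre is offset so the mean
  PDmax/LD ratio stays at its own parameter. Pupil axes share their
  specimen- and eye-level noise so no noise draw can flip the ordering.
  (A truncated Gaussian, the more obvious choice, both shifts the mean
  by ~sd·φ/Φ and inflates the SMA slope, biasing the recovered
  intercept by an amount comparable to its CI.)

Preset defaults (`paper_like_preset`): 211 diurnal / 54 nocturnal
species, 1–5 specimens each; allometric slopes 0.296/0.270 with
intercepts 0.506/0.671 (log₁₀ mm at 1 g); log₁₀ mass mean 1.8, sd 0.55
(≈ 6–630 g, matching a 44–638 mm standard-length range through a
cube-law length-mass map with log₁₀ SL = 1.57 + log₁₀ M/3); allometric
residual sd 0.04; trait-ratio means AL/ED 0, LD/ED −0.35 (diurnal) /
−0.32 (nocturnal), PDmax/LD +0.0835 / +0.047 (aphakic gaps of 17.5% and
10.3% of PDmax); roundness intercepts −0.063 / −0.021 with sd 0.018;
ratio sds 0.012–0.018; specimen sd 0.01 and eye-side sd 0.008; diurnal
shape-dispersion multiplier √(0.105/0.055) ≈ 1.382, so diurnal shape
variance is ≈ 1.9× nocturnal. Absolute trait scales (ED ≈ 5–30 mm) are
plausible rather than authoritative; regression-level quantities are
the calibrated ones.

What the generator does **not** emulate: phylogenetic covariance among
species (families are synthetic labels with no covariance structure),
ontogenetic effects, heteroscedastic measurement error, missing eye
sides, or trait-specific departures from log-normality. Passing tests
therefore demonstrate the correctness and calibration of the
*statistical machinery* under the stated model, not robustness of the
biological conclusions to phylogeny or sampling artefacts.

## Numerical choices and degenerate inputs

* Common-slope optimisation: bounded Brent search, relative tolerance
  1e−10, deterministic; bracket widened ×2 until the minimum is
  interior (error after ~20 doublings).
* Exactly collinear data: r = ±1, slope CIs collapse to a point, slope
  tests return p = 0 (b₀ ≠ slope) or 1 (b₀ = slope); zero-variance
  groups in the intercept Wald are floored to keep weights finite.
* PCA requires n > p, no missing values, and no constant variable;
  a constant column raises rather than silently dropping.
* RDA raises a regularization error naming the class whose blended
  covariance is singular at the requested (λ, γ).
* Duplicate specimen ids, conflicting diel class or family within a
  species, non-positive measurements, and PDmin > PDmax are hard errors
  naming the offending row.
* Problem sizes used by the checked-in checks: the test suite runs
  Monte-Carlo calibrations at 300–1,000 replicates, parameter recovery
  at 150 generator replicates, and rarefaction at 200–1,000 iterations;
  the acceptance script uses 5,000 rarefaction iterations. These sizes
  give binomial/Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* No phylogenetic comparative correction (PGLS, phylogenetic PCA or
  DA): class contrasts treat species as exchangeable.
* Resubstitution error flatters all discriminant methods equally; use
  `--cv` for an honest error estimate when comparing to other
  classifiers.
* The elevation CI undercovers slightly on strongly skewed residuals
  (see above); a bootstrap CI would be preferable when the residual
  distribution is visibly asymmetric.
* A third (crepuscular/cathemeral) activity class is not modelled; the
  data model is deliberately dichotomous until quantitative behavioural
  data justify more.
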