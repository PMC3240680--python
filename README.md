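# reefeye

Comparative eye morphometrics of nocturnal versus diurnal teleost reef
fish. Night-active reef fish must form images at light levels several
orders of magnitude below daylight, and physiological optics predicts a
syndrome of morphological responses: relatively larger eyes, relatively
larger lenses, and large, round pupils — together with reduced
morphological diversity, because dim-light image formation leaves little
room to deviate from the optimum. `reefeye` implements the full
statistical toolkit for testing these predictions on a specimen-level
trait table (eyeball diameter ED, axial length AL, lens diameter LD,
largest and smallest pupil diameters PDmax and PDmin, plus body mass and
a nocturnal/diurnal classification), and ships a calibrated synthetic
data generator so the entire pipeline is testable without access to a
measured dataset.

It is aimed at evolutionary ecomorphologists and at anyone who needs a
self-contained Python implementation of SMA allometry with common-slope
inference, size-corrected PCA morphospace, or rarefied disparity tests.

## Methods at its core

* **SMA allometry** — standardized major axis fits of log₁₀ ED on log₁₀
  body mass: slope `b = sign(r)·s_y/s_x`, isometry tests against
  `b₀ = 1/3` via the correlation of residual scores `y − b₀x` with axis
  scores `y + b₀x`, a likelihood-ratio test of slope equality between
  diel classes, intercepts recomputed at the common slope, and the
  implied eye-size factor `10^Δintercept`.
* **Optical ratios** — morphological proxies of the optical ratio
  OPT = A²/(RD·PND): `OPT_morph1 = LD²/(ED·AL)`,
  `OPT_morph2 = PDmin²/(ED·AL)`, `OPT_morph3 = (LD·PDmin)/(ED·PDmax)`,
  pupil roundness PDmin/PDmax, and the aphakic-gap fraction
  `1 − LD/PDmax`.
* **Morphospace** — correlation-matrix PCA of the log traits. PC1 is a
  size axis (scores track the log geometric mean of the traits); PCs 2+
  are shape axes, compared between classes by a Wilks'-lambda MANOVA and
  minimum convex polygons.
* **Discriminant analysis** — LDA, QDA, regularized DA (class
  covariances blended toward the pooled covariance by λ, so λ=1 ≡ LDA
  and λ=0 ≡ QDA, scanned over λ ∈ {0, 0.01, …, 1}), and flexible DA via
  optimal scoring with a linear basis; training-set priors and
  resubstitution error.
* **Disparity by rarefaction** — summed score variance on shape axes
  PC2–PC5; the larger diurnal class is repeatedly subsampled to the
  nocturnal size without replacement, the PCA re-run each time, and the
  one-sided p-value is `(1 + #{diurnal var ≤ nocturnal var})/(iters + 1)`.

## Worked example

Simulate a study-sized dataset (211 diurnal and 54 nocturnal species)
and run the eye-size allometry:

```sh
$ reefeye simulate --preset paper --seed 7 --out table.csv
$ reefeye sma table.csv --preset eye_size --exclude-anguilliform --b0 0.333
    pooled: n=265 slope=0.2957 intercept=0.5239 r=0.8991
   diurnal: n=211 slope=0.2985 intercept=0.4941 r=0.9466
 nocturnal: n=54 slope=0.2589 intercept=0.6812 r=0.9201
slope equality p = 0.01547; common slope = 0.2927; intercept contrast p = 4.189e-12
pooled slope vs b0=0.333: p = 1.524e-05
```

Both classes scale with negative allometry (slopes below the isometric
1/3), and the nocturnal intercept is far above the diurnal one: at a
given body mass, nocturnal fish carry larger eyes
(`10^(0.681−0.494) ≈ 1.5×` at these per-class fits). Pupil geometry and
the optical ratios tell the same story:

```sh
$ reefeye optics table.csv
aphakic gap, nocturnal: 9.7% of PDmax
aphakic gap, diurnal: 17.4% of PDmax
t-test p = 1.237e-21
```

The nocturnal lens nearly fills the pupil's long axis (small aphakic
gap), consistent with a rounder pupil maximising aperture. Finally, the
shape-space disparity comparison:

```sh
$ reefeye rarefy table.csv --iterations 2000 --seed 7
{
  "observed": {"diurnal": 0.0503, "nocturnal": 0.0312},
  "p_value": 0.0005, ...
}
```

Diurnal shape variance on PCs 2–5 is roughly twice the nocturnal value,
and essentially no size-matched diurnal subsample has variance as low
as the nocturnal class — diversity of nocturnal eye shape is genuinely
restricted, not a sample-size artefact.

`reefeye run-all table.csv --out-dir results/ --seed 7` executes every
stage and writes species tables, per-stage CSVs, and a `summary.json`.

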