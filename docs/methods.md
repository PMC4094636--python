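# Methods

`rvgeom` quantifies the geometry of retinal vascular bifurcations on
fundus-style images and runs the comparative, regression, predictive and
patient-classification statistics used to relate that geometry to diabetic
retinopathy (DR) severity and progression. This note records the models, the
defaults and their rationale, and what the synthetic data do and do not show.

## Measurement model

A bifurcation is annotated with four centerline points (the junction apex and
the far endpoints of the parent and two child segments) plus one rectangle
seed per segment (center on the centerline, axis along the local vessel
direction, a length and a rough initial width). Measurement proceeds:

1. **Profiles.** At evenly spaced stations along each rectangle, the image is
   sampled perpendicular to the axis with bilinear interpolation at 0.25-px
   steps, out to ±2× the initial width. Vessels are assumed darker than the
   background (fundus green channel); a polarity switch handles bright-vessel
   imagery.
2. **Width.** Per profile, the background is the median of the outer 25% of
   samples and the vessel core the minimum of the central 50%. The default
   (*rectangle half-height*) rule places each edge at the sub-pixel crossing
   of the mid-level between background and core; the segment width is the
   mean edge-to-edge distance across stations (averaging across stations is a
   choice; a single-station width is recoverable by `n_stations=1`). A
   secondary *FWHM* estimator uses the half-maximum of the
   background-minus-profile curve with a parabolic peak refinement. A
   caller-supplied manual edge pair overrides the automatic rule, preserving
   the observer-adapted behaviour of interactive tools.
3. **Angles.** The parent flow direction is `apex − parent_end` extrapolated
   through the apex. Each child's branching (deflection) angle is the
   unsigned angle in [0°, 180°] between the child vector and that direction;
   θ = θ₁ + θ₂ by construction. A flag records the degenerate case of both
   children on one side of the parent axis.
4. **Roles.** The strictly wider child is the "larger" child (d₁, θ₁); exact
   width ties break deterministically toward the smaller deflection angle.
5. **Junction exponent.** χ solves d₁^χ + d₂^χ = d₀^χ. After scaling by d₀
   the residual is strictly decreasing in χ, so a unique positive root exists
   whenever d₀ > d₁; it is found by bracketed bisection on [10⁻³, 50] to
   |f| ≤ 10⁻⁹. When d₀ ≤ d₁ (or the root exceeds the bracket, which requires
   d₁/d₀ within ~1.4% of 1) χ is recorded missing with reason "no finite
   root", and downstream means exclude it with an exclusion count. Murray's
   cube law corresponds to χ = 3.
6. **Derived ratios.** These formulas are implementation choices (the field
   uses several variants): junction exponent ratio
   `jer = d0/(d1³+d2³)^{1/3}` (1 at Murray optimality), asymmetry ratio
   `(d2/d1)²`, area ratio `(d1²+d2²)/d0²`.
7. **Distance ratio.** Apex-to-ONH-center distance over the ONH diameter —
   the resolution-free position covariate used by the classifier.

Failures (rectangle out of bounds, flat profile, wrong contrast polarity,
degenerate annotation) flag the record unusable instead of aborting the
image; flags are carried into the output CSV and pipeline reports.

Coordinates are 0-based with origin top-left, x = column, y = row; angles in
degrees; widths in pixels throughout (no micrometre conversion).

## Cohort statistics

The unit of analysis is the **bifurcation**, pooled within patients. This
matches the reference analysis design but means standard errors ignore
within-eye clustering; every regression result carries this warning, and the
calibration simulations below quantify the consequence. All tests are
two-sided at α = 0.05; no multiple-testing correction is applied beyond FLSD
protection.

- **Grade comparisons.** Classical one-way ANOVA (explicit between/within
  sum-of-squares decomposition). When the omnibus p ≤ α, Fisher-protected LSD
  post-hoc pairwise t-tests use the pooled within-group mean square and its
  df; otherwise every pair is declared non-significant. Homogeneous-subset
  letters summarise the pairwise matrix (groups sorted by mean; each maximal
  run of mutually non-different groups shares a letter).
- **Risk-factor models.** Nested OLS models on bifurcation-level features:
  model 1 = age + sex; model 2 adds diabetes type + hypertension; model 3
  adds duration + hypercholesterolemia. Binary covariates are coded female=1,
  type 2=1, present=1 (the coding string is embedded in every result). An
  image-mean unit switch is available. Rank-deficient designs fail loudly,
  naming the collinear columns.
- **Progression odds ratios.** Maximum-likelihood logistic regression of the
  patient-level progression flag on one baseline bifurcation-level feature;
  Wald 95% CIs. Complete separation falls back to a ridge penalty of 10⁻⁶
  and the result is marked penalized.
- **Repeatability.** For repeated marking sessions of the same bifurcations,
  the within-bifurcation SD is the square root of the one-way-ANOVA
  within-group mean square (bifurcations as groups); CoV = 100 × SD / grand
  mean, averaged within the width and angle feature families. Bifurcations
  with one session are excluded with a warning.

## Grade classification

Because bifurcation geometry varies with distance from the optic nerve head
and marking distributions differ between images, patients are first matched
on mean ONH distance ratio: the patient with the lowest mean is the
(untrimmed) reference; every other patient repeatedly loses its
highest-ratio bifurcation until its mean falls strictly below the reference
("just lower": restoring the last removal would bring it back to ≥).
Removal ties break toward the later-indexed row; a patient reduced to one
bifurcation while still ≥ reference is kept at one row and flagged
unmatchable; reference ties break by patient id.

Patient profiles are the means of d₀ and θ₂ over kept rows (vessel types
pooled; the "smaller-child deflection angle" is taken to be θ₂). Two
leave-one-out logistic models follow, decided at probability 0.5
(configurable):

- **Model one** — no retinopathy vs any retinopathy (minimal/severe/
  proliferative merged), predictors mean d₀ and mean θ₂;
- **Model two** — proliferative vs non-proliferative among retinopathy
  cases, predictor mean d₀ only; held-out no-retinopathy patients can be
  scored as extra negatives for an overall specificity.

Each fold fits on all other patients with an in-package Newton solver (ridge
fallback on separation, as above), guaranteeing strict holdout: a fold's
coefficients are bit-identical regardless of the held-out patient's feature
values. Folds whose training set loses a class are excluded with a warning.
Fits are on raw feature scales (no standardisation).

## Synthetic data

**Rendered scenes.** Three straight segments radiate from an apex; each pixel
gets the maximum coverage over segments, where box profiles use 1-px linear
edge anti-aliasing (the half-height rule then recovers the true width
exactly on noiseless scenes) and Gaussian profiles have FWHM equal to the
true width. Optional additive Gaussian noise is seeded. The emitted
annotation's seeds sit on the true centerlines at 65% of each segment's
length; ground-truth angles come from the direction fields. The random test
scenes keep inter-child separations ≥ ~56° so one segment's profiles never
cross a sibling. The render → annotate → measure round trip is the
end-to-end oracle for the geometry module (tolerances 0.5 px, 1°).

**Feature cohorts.** Bifurcation features are drawn hierarchically per
patient. Grade × vessel-type means/SDs default to a reference 51-eye
cross-sectional cohort (10/10/12/19 patients over no-DR, minimal NPDR,
severe NPDR, PDR; arteriolar/venular tables; e.g. venular d₀ from
7.42 ± 1.87 px at no-DR to 9.55 ± 2.88 px at PDR), with per-grade arteriole
fractions from the same cohort's bifurcation counts. Key defaults:

- `bifurcations_per_image = 30` per analysed eye (two 50° photographic
  fields at ~15 markable bifurcations each), reproducing the reference
  per-grade bifurcation totals (242/310/372/594).
- `patient_sd_frac = 0.15`: patient random effects at 15% of each feature's
  SD (~2% of bifurcation-level variance). The reference cohort's
  patient-level classification performance implies patient means far tighter
  than the pooled bifurcation SDs, i.e. that spread is dominated by
  within-eye vessel-size diversity; a small residual patient effect is the
  realistic regime.
- `width_shared_frac = 0.98`: d₀/d₁/d₂ share a per-bifurcation size factor
  for this fraction of their non-patient variance. The joint structure is
  unconstrained by the reference tables (marginals only); this value keeps
  the d₀ ≥ d₁ ≥ d₂ ordering enforcement (a descending sort, after clipping
  widths at 0.5 px) from perturbing the configured marginal means by more
  than ~0.01 px.
- Covariate effects (age −0.02 px/yr on widths; duration +0.003 px/month;
  female −0.3 px on venular d₀/d₁; type 2 +0.3 px on arteriolar widths;
  hypertension +0.3 px on venular d₀/d₁; cholesterol +3° on arteriolar θ₂)
  follow the reference risk-factor directions at modest magnitudes, applied
  to covariates centred at their per-grade clipped-normal means so group
  means stay at the configured values. Covariates are drawn from the
  per-grade demographic distributions (ages clipped to 26–65 years,
  durations to 2–456 months).
- Distance ratios are lognormal around ~2.2 ONH diameters with patient-level
  log-SD 0.10 and within-patient log-SD 0.50 — modest real between-patient
  location differences under a broad within-eye spread. Under this model the
  matching step keeps roughly two thirds of bifurcations, consistent with a
  study whose patient-level models worked on kept-row means.
- θ is generated as θ₁ + θ₂ with independent angle draws, so the generated θ
  SD (~√(σ₁²+σ₂²)) exceeds the reference pooled θ SD — the reference angles
  were negatively correlated within junctions, a joint property the tables
  do not constrain. Means are unaffected.
- χ is computed from the generated widths (never drawn), so its distribution
  is an emergent property; generated-χ means are not calibrated to the
  reference χ rows.
- `GroupGenerativeParams.null()` is the null of the pooled bifurcation-level
  ANOVA: equal grade means, a grade-constant vessel-type mix, no covariate
  effects, no progression shift and **no patient random effects**. With
  patient effects present the pooled ANOVA's size is inflated by design —
  the documented cost of the bifurcation-level unit of analysis.

**Progression cohorts.** Two arms (default 5 patients each) over three
visits with patient latents persisting across visits. Progressors' baseline
smaller-child width is shifted by `d2_progression_shift = −0.35 px`, the
value implied by the reference progression log-odds of −0.318 per px through
the equal-variance-Gaussian ⇔ logistic-coefficient identity
(shift = coefficient × var(d₂)). Final-visit progressors are labelled PDR.

**Repeatability sessions** re-measure a feature table with multiplicative
Gaussian error at the configured intra-observer CoV (widths 4.2%, angles
3.8%). The pooled ANOVA CoV recovers these up to the rms/mean factor of the
feature distribution (≈ 4.3% / 3.9%), since the pooled estimator normalises
by the grand mean rather than per-bifurcation.

**What passing tests do not show.** The generator draws feature values
directly for cohort-scale statistics (rendering is reserved for geometry
tests), emulates marginals plus a simple latent structure rather than real
joint vessel geometry, uses straight segments without tortuosity, central
reflex, pathology (microaneurysms, haemorrhages) or media opacity, and knows
nothing about camera optics. Passing recovery tests therefore validates the
analysis machinery under the stated distributional assumptions, not the
measurement technique's behaviour on real fundus photographs.

## Problem sizes and numerical choices

Simulation-based tests use 51-patient cohorts (reference group sizes) for
classifier checks, 100 seeds for median operating characteristics, 500
replicates for CI coverage and ANOVA calibration, 1000 random triples for
the junction-exponent oracle, and 100 rendered scenes for geometry round
trips — sizes at which the Monte Carlo error is well below every asserted
tolerance. The junction-exponent oracle is a 10⁻⁴-step sign-change grid
refined by Brent's method inside the bracketing interval, independent of the
production bisection path. Reports serialise with sorted keys so identical
config + data give byte-identical output; all randomness descends from
explicit integer seeds.

## Known limitations

- No patient-level clustering correction (by design, documented above).
- Automatic vessel segmentation and bifurcation detection are out of scope:
  annotations are inputs. Only the rectangle half-height and FWHM width
  estimators are provided; other estimators are an extension point.
- Widths are reported in pixels; cross-visit width comparisons are excluded
  in the predictive pipeline because pixel scales may differ between
  cameras/visits.
- The asymmetry/area/JER ratio formulas are package choices (flagged in the
  docstrings), not community standards.
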