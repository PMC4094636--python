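# rvgeom

Retinal vascular geometry at bifurcations: measurement, statistics and
retinopathy-grade classification.

Vessel calibre alone says little about the state of a retinal vascular
network; the geometry of its **bifurcations** — parent and child widths,
branching angles, and how closely the junction obeys Murray's cube law —
carries additional signal about microvascular dysfunction in diabetic
retinopathy (DR). `rvgeom` is a library + CLI for researchers who have
fundus-style images with marked bifurcations (or who want fully synthetic
cohorts with known ground truth) and want to go from annotations to
grade-level statistics and patient-level classification reproducibly.

## What it computes

At each annotated junction, from perpendicular intensity profiles over
rectangles aligned with the segment centerlines:

- widths of the parent, larger and smaller child: d₀ ≥ d₁ ≥ d₂ (pixels),
  via sub-pixel half-height edge detection (FWHM as an alternative);
- branching angles of the larger and smaller child against the extrapolated
  parent direction, θ₁ and θ₂, and the bifurcation angle θ = θ₁ + θ₂;
- the junction exponent χ solving d₁^χ + d₂^χ = d₀^χ (Murray's law predicts
  χ = 3), by bracketed bisection, with non-existent roots reported missing;
- derived optimality ratios (junction exponent ratio, asymmetry ratio, area
  ratio) and the distance of the apex from the optic nerve head in ONH
  diameters.

On a cohort's feature table it then runs: grade-wise one-way ANOVA with
Fisher-protected LSD letters (overall / arteriolar / venular strata), nested
demographic/clinical OLS risk-factor models, binary logistic odds ratios for
progression from baseline features, intra-observer repeatability CoV, and
two leave-one-out logistic grade models (no-DR vs retinopathy; proliferative
vs non-proliferative) after matching patients on ONH distance ratio. A
seeded synthetic module supplies rendered bifurcation images with exact
ground truth and hierarchical feature cohorts. See `docs/methods.md` for the
models and defaults.

## Worked example

Simulate a 51-patient cohort (10/10/12/19 across the four DR grades, ~30
bifurcations per eye), compare grades, and classify patients:

```bash
rvgeom simulate cohort --seed 11 --out cohort
# wrote 1587 bifurcations, 51 patients to cohort

rvgeom compare --features cohort/features.csv --patients cohort/patients.csv \
       --out compare.json

rvgeom classify --model one --features cohort/features.csv \
       --patients cohort/patients.csv --report model_one.json
# model one: sensitivity 95.1% specificity 90.0%
```

The comparative report (here: parent width d₀ and smaller-child deflection
θ₂, pooled strata) contains per-grade means ± SD, the ANOVA p-value and FLSD
homogeneous-subset letters — grades sharing a letter are not separable at
α = 0.05:

```
d0     NoDR         6.83 ± 1.55   n 265  p 0.000   a
d0     MinimalNPDR  8.36 ± 2.53   n 330  p 0.000   b
d0     SevereNPDR   8.64 ± 2.37   n 381  p 0.000   bc
d0     PDR          8.80 ± 2.68   n 611  p 0.000   c
theta2 NoDR         54.13 ± 19.72 n 265  p 0.028   a
theta2 MinimalNPDR  56.16 ± 21.31 n 330  p 0.028   ab
theta2 SevereNPDR   55.70 ± 22.12 n 381  p 0.028   a
theta2 PDR          58.60 ± 23.15 n 611  p 0.028   b
```

Reading: vessels dilate with increasing DR severity (the no-DR grade is
cleanly separated from all retinopathy grades on d₀) and the smaller child
deflects more at PDR; the leave-one-out model separates no-DR from
retinopathy patients at 95.1% sensitivity / 90.0% specificity on this
cohort. Other subcommands: `rvgeom simulate images|progression`,
`rvgeom measure` (image + annotation JSON → geometry CSV), `rvgeom regress`,
`rvgeom predict-progression`.

Library use mirrors the CLI:

```python
from rvgeom import generate_cohort, match_distance_ratio
from rvgeom.classify import build_patient_profiles, loo_classify, model_labels

cohort = generate_cohort(seed=11)
profiles = build_patient_profiles(match_distance_ratio(cohort.features))
report = loo_classify(profiles, model_labels(cohort.patients, "one"))
print(report.sensitivity, report.specificity)
```

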