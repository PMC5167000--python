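# Methods

## The statistical model

The analysis is cross-sectional: each patient contributes one MRI-derived
regional thickness vector and one disease duration (years since first motor
symptom), and *rates* of atrophy are estimated as regression slopes across
patients, not within them. Patients are stratified at a duration cutoff
(default 10 years, boundary inclusive on the Early side) into Early and
Late groups, and each (region, hemisphere, stage) cell is modelled as

    thickness = intercept + rate × duration + ε,   ε ~ N(0, σ²)

with an independent linear segment per stage — no continuity is imposed at
the cutoff, because the two groups are different patients and the stages
are fitted separately. The quantities of interest are:

* the per-stage OLS slope (mm/year; negative = thinning);
* the Early − Late slope difference Δ = β_E − β_L with a bootstrap CI;
* the Early − Late mean-thickness difference per region (Welch *t*), with
  Benjamini–Hochberg FDR control applied separately per hemisphere;
* duration–thickness Pearson correlations within subgroups, and paired
  left-vs-right comparisons within motor-lateralized subsets.

A note on sign conventions, which are a recurring source of confusion in
this analysis family: the slope contrast is fixed as **Early − Late**
throughout (negative Δ with an all-negative CI ⇒ faster early atrophy);
the group mean difference is **Early − Late** (positive ⇒ Late thinner);
the motor laterality index is **right-extremity mean − left-extremity
mean** of UPDRS-III Off item scores (negative ⇒ predominantly left-sided
symptoms).

## Bootstrap design

The resampling unit is the patient (case resampling), drawn with
replacement within a stage; this is robust to heteroscedasticity and does
not condition on the observed durations. For the slope difference, each of
the `n_boot` replicates resamples Early and Late independently, refits
both regressions, and records the refitted difference; the CI is the
(α/2, 1−α/2) percentile pair. The point estimate always comes from the
unresampled data; the bootstrap supplies only the interval. BCa correction
is not used — percentile intervals are simpler, and their small-sample
anti-conservatism is quantified directly by the coverage experiment below.

Reproducibility is structural rather than incidental: every (region,
hemisphere, stage-subset) gets its own `numpy` random stream seeded by
(master seed, CRC32 of the region key, CRC32 of the subset's data bytes).
Consequences worth knowing:

* adding or removing regions never changes any other region's CI;
* rerunning with the same seed is bit-for-bit identical;
* swapping the two groups negates every bootstrap replicate exactly, so
  the contrast is exactly antisymmetric (tested, not just asymptotically).

Degenerate resamples (all resampled durations equal, slope undefined) are
redrawn, with a capped retry count (100 rounds) and a logged tally; they
only occur when a stage has very few distinct durations.

## Multiplicity

"FDR control per hemisphere" is implemented as Benjamini–Hochberg step-up
within the left-hemisphere p-value set and, separately, the
right-hemisphere set, at level q = 0.1. A region is a discovery iff its
BH-adjusted value is ≤ q — stated this way (rather than via the step-up
index) because the two formulations are equivalent in exact arithmetic but
the adjusted-value form is the one that is stable under floating point and
is what the output column `q_value` reports. With 60 of 75 regions per
hemisphere truly null, the expected false-discovery proportion is
q·m₀/m = 0.08; the calibration experiment reproduces this.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cutoff` | 10 | years | stage boundary; boundary value is Early ("≤") |
| `n_boot` | 2000 | replicates | CI quantile noise ≪ CI width; 200 floor enforced |
| `alpha` | 0.05 | — | 95% percentile CIs |
| `q` | 0.1 | — | per-hemisphere FDR level |
| `threshold_sd` | 1.0 | SD | motor-lateralized subgroup selection |
| `equal_var` | False | — | Welch *t* by default; pooled variance behind a flag for sensitivity |
| `noise_sd` (generator) | 0.15 | mm | plausible within-region measurement SD; an assumption, since cohort-level regional variances are not published |

The Welch choice, the percentile (not BCa) bootstrap, the BH procedure and
the paired (not unpaired) hemispheric test are all conventions this package
fixes where the analysis family leaves them open; each is logged at INFO on
every pipeline run so a result can be audited against its settings, and
the pooled/unpaired variants remain available for sensitivity checks.
The paired choice for the left-vs-right comparison follows from the design:
both hemispheres are measured in the same patients, and an unpaired test
would discard that pairing.

## The synthetic cohort generator

The generator emulates the *statistical structure* the estimators assume:

* durations uniform within each stage's range (defaults 2.2–9.9 and
  10.1–27.1 years) — uniform is the least-structured choice consistent
  with a known range;
* thickness per (hemisphere, region) = stage baseline + stage rate ×
  duration + homoscedastic Gaussian noise, segments independent across
  stages and regions;
* clinical covariates (age ≈ N(62, 9) years with onset = assessment −
  duration, sex ≈ 2:1 M:F, handedness R:L:NR ≈ 0.83:0.10:0.07, UPDRS-III
  Off ≈ N(41, 13) with a stage-dependent On-state improvement);
* 8 extremity UPDRS items per side (4 per limb × 2 limbs), integers 0–4,
  with a configurable mean shift for a lateralized subset of patients
  (defaults ≈ 17% left- and 16% right-lateralized). The exact UPDRS-III
  item set constituting "extremity scores" is a convention; the analysis
  only requires equal-length per-side lists.

`generate_null_cohort` produces the null/signal mixture used for FDR
calibration: null regions identical in distribution across stages, signal
regions given a fixed Early − Late mean contrast.

What it does **not** emulate — and therefore what passing tests do not
establish about real data: spatial correlation between neighbouring
regions (regions are independent here, so region-wise error control on
correlated real data inherits only BH's robustness under positive
dependence), non-Gaussian or heteroscedastic measurement error, scanner
and segmentation batch effects, duration measurement error (symptom-onset
recall), and any nonlinear trajectory. The default region list carries 75
names per hemisphere to match the count conventionally quoted for this
sulco-gyral parcellation (the modern FreeSurfer table labels 74; the list
adds the vertical frontal sulcus from the earlier revision of the same
nomenclature). Nothing downstream depends on the count — any subset is
accepted.

## Degenerate inputs and edge policies

* `assign_stage` requires positive duration; 10.0 → Early.
* OLS needs ≥ 3 points and non-constant durations; group tests need ≥ 2
  per group; correlations need ≥ 3 and non-zero variance in both
  variables. All violations raise with the offending quantity named.
* Two groups with zero variance and equal means: p defined as 1.
* Motor laterality with zero cohort SD of the index: if every index is
  exactly 0 (perfect symmetry) nobody is selected; otherwise SD-based
  selection is undefined and an error is raised.
* Handedness outside {R, L} maps to NR (not recorded) with a logged
  count; NR is a first-class category, never imputed.
* Subjects present in only one of the two input tables abort the run with
  the ids listed — never a silent inner join.

## Validation experiments and problem sizes

The test suite runs the analysis against independently coded closed-form
oracles (normal equations, Welch formulas, textbook paired *t*, product-
moment correlation, brute-force BH) to 1e−10 over ≥ 1000 randomized cases,
plus these simulation experiments (sizes chosen so the whole suite stays
interactive on one CPU):

* **CI coverage**: 500 replicate cohorts (60 + 60 patients, noise
  0.15 mm, n_boot = 1000); the 95% CI for Δ covers the generating value
  within ±2 percentage points of nominal. Percentile intervals at n = 60
  per group sit near 94–95% here.
* **FDR calibration**: 500 replicates of the 60-null + 15-signal mixture
  (40 + 40 patients); mean FDP ≤ 0.1 (observed ≈ 0.08, matching q·m₀/m).
* **Recovery at n = 5000**: published regional rates (−0.072, −0.063,
  −0.022 mm/year Early; −0.061 Late), the 0.1084 mm group contrast and
  the r = −0.83 duration–thickness correlation, each used as generating
  truth, are recovered within ±0.005 mm/year, ±0.01 mm and ±0.02
  respectively. For the correlation target the noise SD is solved from
  r = bσₓ/√(b²σₓ² + σ²) given the slope b and the uniform-duration σₓ.

`scripts/acceptance.py --seed S --out F` re-runs all of these from scratch
with seeds derived from S and writes the measured values as JSON.

## Known limitations

* Cross-sectional "rates" are between-patient regression slopes; they
  coincide with longitudinal rates only absent cohort effects.
* The percentile bootstrap is mildly anti-conservative at small n; with
  ~10 patients per subgroup (as in the handedness sub-analyses) CIs and
  p-values should be read qualitatively.
* The Early − Late slope difference compares two independently fitted
  cross-sectional slopes; it is not a formal test of a change-point model.
* FDR is controlled per hemisphere by design, so cross-hemisphere
  comparisons of discovery counts are descriptive, not inferential.
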