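# cortasym

**Hemispheric asymmetry of cortical atrophy in cross-sectional Parkinson's
disease cohorts.**

Parkinson's disease is clinically asymmetric, and several lines of evidence
suggest the left cerebral hemisphere is more susceptible to early
neurodegeneration than the right. Testing this on structural MRI data
requires a stage-stratified, region-wise statistical pipeline: patients are
split into **Early** (disease duration ≤ 10 years since first motor symptom)
and **Late** (> 10 years) groups, and regional cortical thickness — one value
per Destrieux region per hemisphere, in mm, as produced by FreeSurfer's
`aparcstats2table` — is analysed three ways:

1. **Group comparison.** Per region, a two-sample (Welch) *t*-test of mean
   thickness between Early and Late groups, oriented Early − Late so positive
   values mean the Late group is thinner; Benjamini–Hochberg FDR control is
   applied *separately within each hemisphere* at q = 0.1.
2. **Atrophy rates.** Per region and stage, the cross-sectional atrophy rate
   is the OLS slope β of thickness on duration (mm/year, negative =
   thinning). Uncertainty comes from a percentile bootstrap that resamples
   patients with replacement within the stage. The **Early − Late slope
   difference** Δ = β_E − β_L is bootstrapped by resampling both stages
   independently in each replicate; a region shows significantly faster
   early atrophy when both 95% CI limits of Δ are negative, and faster late
   atrophy when both are positive (the CI-sign rule).
3. **Laterality sub-analyses.** Pearson correlations between duration and
   thickness within handedness subgroups; a per-patient motor laterality
   index (mean right-extremity − mean left-extremity UPDRS-III Off item
   scores, negative = left-predominant symptoms) selecting patients > 1 SD
   from the cohort mean; and paired left-vs-right thickness tests within the
   motor-lateralized subsets.

Because clinical MRI cohorts of this kind are not publicly shareable, the
package ships a first-class **synthetic cohort generator**: piecewise-linear
thinning with an independent linear segment per stage, homoscedastic
Gaussian measurement noise, realistic clinical covariates, and full ground
truth returned for every run — so coverage, FDR calibration and parameter
recovery can be verified end to end.

Intended users: neuroimaging statisticians and methods-minded clinicians who
already have regional thickness tables and want a reproducible, testable
implementation of this analysis rather than a one-off script.

## Worked example

```python
from cortasym import (SimulationConfig, generate_cohort, estimate_rates,
                      slope_difference, compare_regions)

rate_early = {"G_insular_short": -0.072, "S_orbital_med-olfact": -0.063,
              "G_occipital_sup": -0.005}
rate_late  = {"G_insular_short": -0.01, "S_orbital_med-olfact": -0.01,
              "G_occipital_sup": -0.049}
# Late-stage segments start from the thickness reached after 10 early years
baseline_late = {r: 2.8 + (rate_early[r] - rate_late[r]) * 10.0 for r in rate_early}

cfg = SimulationConfig(
    n_early=109, n_late=96, regions=tuple(rate_early),
    rate_early=rate_early, rate_late=rate_late,
    baseline_early=2.8, baseline_late=baseline_late,
    noise_sd=0.15, seed=42,
)
cohort, thickness, truth = generate_cohort(cfg)

rates = estimate_rates(cohort, thickness, "Early", n_boot=2000, seed=0)
print(rates[rates.hemisphere == "left"][["region", "slope", "ci_low", "ci_high", "n"]])

sd = slope_difference(cohort, thickness, "G_insular_short", "left",
                      n_boot=2000, seed=0)
print(sd.difference, (sd.ci_low, sd.ci_high), sd.significant_early)

res = compare_regions(cohort, thickness, q=0.1)
print(res[res.hemisphere == "left"][["region", "difference", "q_value", "discovery"]])
```

Output (left hemisphere):

```
              region   slope  ci_low  ci_high   n
     G_insular_short -0.0681 -0.0821  -0.0551 109
S_orbital_med-olfact -0.0718 -0.0844  -0.0587 109
     G_occipital_sup  0.0060 -0.0074   0.0189 109

Early-Late slope difference (L insular short gyrus): -0.0580 mm/yr,
95% CI [-0.0727, -0.0434], faster early atrophy: True

              region  difference  p_value  q_value  discovery
     G_insular_short      0.3759      0.0      0.0       True
S_orbital_med-olfact      0.3029      0.0      0.0       True
     G_occipital_sup      0.4691      0.0      0.0       True
```

Reading it: with 109 Early patients the insular short gyrus slope estimate
−0.068 mm/year (bootstrap 95% CI −0.082 to −0.055) recovers the generating
rate of −0.072; the slope difference −0.058 mm/year has an all-negative CI,
so the region is flagged for faster early-stage atrophy; and all three
regions are FDR discoveries because the Late group is genuinely thinner by
construction (positive Early − Late differences).

## Command line

```bash
cortasym synth --config sim.yaml --out-dir data/ --seed 42   # synthetic tables
cortasym compare --clinical data/clinical.csv --thickness data/thickness.tsv --out cmp.csv
cortasym rates   --clinical ... --thickness ... --out-dir out/ --n-boot 2000 --seed 0
cortasym laterality --clinical ... --thickness ... --subgroup left-handed --out lat.csv
cortasym run --config pipeline.yaml --out-dir out/ --seed 0  # full pipeline
```

Exit codes: 0 ok, 1 validation error, 2 runtime error.

### Input formats

Clinical CSV (header shown with 3 example rows; `left_ext_1..8` /
`right_ext_1..8` are per-extremity UPDRS-III Off item scores):

```
patient_id,sex,age_assessment,age_onset,duration,handedness,updrs3_off,updrs3_on,left_ext_1,...,left_ext_8,right_ext_1,...,right_ext_8
sub-0001,M,61.3,54.4,6.9,R,40,20,1,...,2,1,...,0
sub-0002,F,63.2,49.3,13.8,L,42,18,3,...,2,2,...,1
sub-0003,M,58.0,50.1,7.9,NR,35,15,0,...,1,1,...,1
```

Thickness TSV (FreeSurfer `aparcstats2table` layout, mm):

```
subject	lh_G_insular_short_thickness	rh_G_insular_short_thickness	...
sub-0001	3.38	3.37	...
sub-0002	3.12	3.20	...
sub-0003	3.42	3.28	...
```

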