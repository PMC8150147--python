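# coagree

Agreement, trending-ability and sample-size statistics for
method-comparison studies of cardiac-output monitors — the setting where
a less invasive device (bioreactance, pulse-contour analysis, …) is
validated against bolus thermodilution via a pulmonary artery catheter,
with **many paired cardiac-index (CI) measurements per patient**.

Repeated measurements per patient break the textbook Bland–Altman
recipe: the SD of the differences mixes within-patient and
between-patient variation, and naive confidence intervals ignore the
clustering. `coagree` implements the statistics this field's validation
studies actually report, for data of exactly that shape:

* **Repeated-measures Bland–Altman.** Differences d = CI_test − CI_ref
  are decomposed by one-way ANOVA with patient as the factor:
  σ̂²_w = MS_within, σ̂²_b = max(0, (MS_between − MS_within)/n₀) with
  n₀ = (N² − Σmᵢ²)/((k−1)N). The limits of agreement are
  d̄ ± 1.96·σ̂_tot, σ̂_tot² = σ̂²_b + σ̂²_w — the "true value varies"
  variant appropriate when CI genuinely changes between readings.
  CIs: t-based for the bias; MOVER (square-and-add over per-component
  chi-square limits) or delta method for each LOA.
* **Percentage error** PE = 100·1.96·σ̂_tot / mean CI (Critchley
  criterion: interchangeable if < 30%), with a patient-cluster
  bootstrap CI.
* **Proportional bias**: OLS of difference on pairwise mean with
  patient-clustered standard errors.
* **Trending**: consecutive-change (ΔCI) pairs per patient, the
  four-quadrant concordance rate with a central exclusion zone, and the
  four-zone error grid built from 5%/15% change bins (zone 1 same
  direction and extent, zone 2 same direction different extent, zone 3
  only one device changed, zone 4 opposite directions).
* **Sample size**: the TOST equivalence formula
  N = 2(z₁₋α + z₁₋β/₂)²σ²/(Δ − |δ|)² and Bland's LOA-precision size
  N = 3(1.96·σ/w)².
* **Synthetic cohorts**: a seeded generator of OPCAB-like paired series
  (patient random effects, AR(1) within-patient drift, phase shifts,
  multiplicative thermodilution noise, constant + proportional device
  bias) with closed-form expected bias/variance, so every estimator has
  a parameter-recovery oracle.

## Worked example

The numbered drivers under `analysis/` run the whole study pipeline on
a synthetic 20-patient cohort (579-measurement scale, four clinical
phases) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py   # cohort.csv + ground_truth.json
python analysis/02_agreement_tables.py  # Bland–Altman table + figure
python analysis/03_trending.py          # 4Q concordance + error grid
python analysis/04_sample_size.py       # TOST and LOA-precision N
python analysis/05_ci_calibration.py    # coverage of the 95% CIs
```

`02_agreement_tables.py` prints (seed 2018):

```
             phase   n   bias  loa_lower  loa_upper  percentage_error  prop_bias_slope
               all 580  0.028     -1.188      1.245            53.853            0.505
          baseline  20 -0.209     -1.518      1.100            55.064            0.408
 aortic_side_clamp  20  0.072     -1.420      1.564            67.707            0.674
distal_anastomoses  80 -0.048     -1.095      1.000            53.479            0.359
icu_pre_extubation 100  0.002     -1.233      1.236            53.220            0.583

pooled percentage error 53.9% (exceeds the 30% interchangeability bound)
```

Read: the device's mean bias is negligible (0.03 L·min⁻¹·m⁻²) but the
limits of agreement span ≈ ±1.2 L·min⁻¹·m⁻² and the percentage error is
~54%, far above the 30% bound — accurate on average, too imprecise to
interchange with thermodilution. `03_trending.py` adds the trending
verdict (e.g. 4Q concordance 61.9% after excluding changes < 10%, error
grid 30.7/20.0/24.8/24.5% in zones 1–4; phases with fewer than 30 change
pairs are suppressed), and `04_sample_size.py` reports the two design
sizes, N = 414 (TOST equivalence) and N = 141 (LOA precision).

The same pipeline runs on real data from a CSV with columns
`patient_id,time_index,phase,ci_ref,ci_test` (remappable) through the
CLI:

```sh
coagree analyze --input cohort.csv --out report/ --seed 1
coagree simulate --out sim/ --seed 7
coagree samplesize equivalence --sd 0.7 --margin 0.36 --true-diff 0.2
```

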