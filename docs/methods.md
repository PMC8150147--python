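# Methods

## Setting and data model

The package analyzes paired cardiac-index (CI, L·min⁻¹·m⁻²) series from
method-comparison studies of cardiac-output monitors: each patient
contributes a time-ordered sequence of simultaneous readings from a
reference method (bolus thermodilution via pulmonary artery catheter)
and a test device. The canonical layout is tidy-wide — one row per
timepoint with both devices' values — because every statistic here is
pairwise by construction. Phase is carried as a column (the clinical
phases of an off-pump bypass protocol: baseline, aortic side-clamping,
distal anastomoses, ICU pre-extubation, other), never inferred from
time, since phases are defined clinically. Timestamps are abstract
integer ranks: only ordering matters, both for validation and for
consecutive-change pairs. The sign convention is fixed at
difference = test − reference, so positive bias means the test device
overestimates; every result echoes this.

## Repeated-measures Bland–Altman

With k patients and mᵢ paired readings each (N total), the differences
dᵢⱼ are decomposed by one-way ANOVA with patient as the factor:

    MS_between = Σ mᵢ(d̄ᵢ − d̄)² / (k−1)
    MS_within  = Σ (dᵢⱼ − d̄ᵢ)² / (N−k)
    n₀         = (N² − Σmᵢ²) / ((k−1)N)
    σ̂²_w = MS_within,   σ̂²_b = max(0, (MS_between − MS_within)/n₀)

and the limits of agreement are d̄ ± 1.96·σ̂_tot with
σ̂_tot² = σ̂²_b + σ̂²_w. This is the "true value varies" variant: the
within-patient spread reflects genuine CI changes plus device error, and
the total SD is the one relevant to a clinician reading a single paired
measurement. A negative raw between-patient estimate is truncated to
zero and flagged (`truncated`); with one measurement per patient the
within df vanish, n₀ = 1, and σ̂_tot degenerates exactly to the ordinary
sample SD, recovering classical Bland–Altman. z is fixed at 1.96 rather
than t-adjusted, matching the LOA convention.

### Confidence intervals

* **Bias**: Var(d̄) = (σ̂²_b·Σmᵢ² + σ̂²_w·N)/N², t interval on k−1 df
  (the patient count, not N, carries the information about the
  between-patient component).
* **LOA, MOVER (default)**: σ̂_tot² is the linear combination
  (1/n₀)·MS_between + (1 − 1/n₀)·MS_within of independent mean squares.
  Each gets exact chi-square limits on its own df; the component
  half-widths are combined by square-and-add around the point value
  (modified-large-sample / Graybill–Wang). Each limit d̄ ± 1.96·σ̂_tot
  then gets the mean and SD uncertainties combined by the MOVER
  square-and-add rule, with the outer/inner sides paired correctly
  (for the lower limit, the downward half-width uses the upper variance
  limit). The mean component inside this combination uses normal
  quantiles, the MOVER convention; in calibration simulations at the
  default study design (k = 20, m = 29) this construction covers the
  true limits at 0.94–0.96 against a nominal 0.95, whereas substituting
  a t quantile pushed the lower-limit coverage to ≈ 0.97
  (over-conservative).
* **LOA, delta (option)**: Var(limit) ≈ Var(d̄) + 1.96²·Var(σ̂_tot),
  Var(σ̂_tot) ≈ Var(σ̂_tot²)/(4σ̂_tot²) with Var(MS) = 2·MS²/df per
  component; normal quantiles. Slightly anti-conservative for the
  outer limit at k = 20 (coverage ≈ 0.92 in the same simulations);
  retained as the cheap asymptotic cross-check.
* Degenerate inputs: σ̂_tot = 0 yields zero-width CIs with a warning.

### Percentage error

PE = 100·1.96·σ̂_tot / (mean CI). The denominator is the mean
**reference** CI by default — the percentage-error criterion is defined
against the reference method's mean cardiac output — with the mean of
pairwise means available as an option; the choice is echoed in every
result. The CI is a percentile cluster bootstrap (default B = 2000):
patients are resampled with replacement, resampled copies counting as
distinct clusters so k is preserved, and the full PE pipeline is
recomputed per replicate. Clustering by patient respects the
repeated-measures structure; an observation-level bootstrap would be
falsely narrow.

### Proportional bias

OLS of difference on pairwise mean, slope unstandardized with sign
preserved (a summary-table slope reported "as absolute values" is read
as unstandardized, not magnitude — tables in this literature contain
negative coefficients). The slope CI uses patient-clustered robust
standard errors with a t reference on k−1 df. Note the estimand is the
observational slope of d on the pairwise mean, which differs from the
generator's proportional-bias parameter: shared device noise appears in
both the difference and the mean, so the recovery test's oracle is a
Monte-Carlo regression on an independent large draw from the same
generator, not the raw parameter.

## Trending

Consecutive-change pairs are formed within patient between adjacent
timepoints — percent change relative to the earlier reading of the same
device, the standard four-quadrant convention — giving exactly N − k
pairs for contiguous series. Deltas may span phase boundaries (a
20-patient, 579-measurement cohort yields 559 pairs, which is only
possible if changes are formed across the whole series); phase-level
trending keeps the pairs whose later endpoint lies in the phase.

Magnitude bins: |Δ| < 5% "none", 5–15% inclusive "moderate", > 15%
"large". The 5–15 band is read closed on both ends so the bins
partition the line with boundaries resolved downward; boundary behavior
is tested explicitly. Error-grid zones follow from the bins: both
"none" → zone 1 (two no-changes lead to the same clinical decision:
do nothing); exactly one "none" → zone 3; both changed, same sign →
zone 1 if the bins match else zone 2; opposite signs → zone 4. The
classification is symmetric under swapping the devices. Error grids
for sets with fewer than 30 pairs (configurable) are computed but
flagged unreported — mirroring the convention of suppressing the grid
for sparsely measured phases.

The four-quadrant concordance rate excludes pairs where **both**
devices' changes fall below the exclusion threshold (default 10% in
percent mode; an absolute mode in L·min⁻¹·m⁻² is provided since both
conventions circulate), then reports the percentage of retained pairs
with equal change sign; exact zeros are concordant only with zeros. The
configured threshold and mode are echoed in the result, as no single
exclusion size is standard.

## Sample sizes

* Equivalence (TOST, paired differences, normal approximation):
  N = 2(z₁₋α + z₁₋β/₂)²·σ²/(Δ − |δ|)². The β/2 quantile is the
  two-one-sided-tests convention (each one-sided test must reject).
  With σ = 0.7, Δ = 0.36, δ = 0.2, α = 0.05, power 0.9 this gives
  414.3 → 414.
* LOA precision: N = 3(1.96·σ/w)², from SE(LOA) ≈ σ√(3/N), where w is
  the half-width of one limit's 95% CI (a full-width reading would give
  N ≈ 565, inconsistent with the published use of this formula). With
  σ = 0.7, w = 0.2 this gives 141.2 → 141.

Both round to the nearest integer — the convention under which the
published figures (414, 141) arise from the raw values — and also
return the raw N. The factor-2 TOST formula is conservative for a
one-sample paired design: Monte-Carlo TOST power at N = 414 under the
design parameters is ≈ 0.999 against the nominal 0.90; the
`tost_rejection_rate` helper makes this check reproducible. No design
effect for repeated measurements per patient is applied: the N refers
to measurements treated as independent, and the caveat is deliberate,
documented rather than corrected.

## Synthetic cohort generator

Per patient i: baseline Tᵢ ~ N(μ, σ_p²); the latent true CI follows
tᵢⱼ = max(0.5, Tᵢ + phase_effect + aᵢⱼ) with aᵢⱼ an AR(1) process
(coefficient φ, innovation SD σ_e) started at stationarity. Observed:

    ci_ref  = max(0.1, t·(1+ε)),        ε ~ N(0, cv²)
    ci_test = max(0.1, t + b₀ + b₁(t−μ) + uᵢ + η)

Reference noise is multiplicative because thermodilution precision is
quoted proportionally (±20% ⇒ cv ≈ 0.10, since ±1.96·cv ≈ 0.20); test
noise is additive to match the absolute bias/LOA scale of the agreement
tables. Truncation at small positive floors (0.5 latent, 0.1 observed)
keeps determinism and row counts, with floors far below physiological
relevance; at default noise levels the floors are ~10-σ events, and the
reference floor exists only to guarantee the dataset's positivity
invariant. Defaults: 20 patients × 29 readings (phase counts
1/1/4/5/18 per patient, mirroring the 24/27/85/104-of-579 phase sizes of
a 20-patient cohort), μ = 2.4, σ_p = 0.4, φ = 0.8, σ_e = 0.25, phase
shift −0.3 during distal anastomoses, b₀ = 0.13, b₁ = 0.3, σ_u = 0.3,
σ_η = 0.5. The device-error values were chosen once so the implied
difference SD (≈ 0.66) and percentage error (≈ 55%) sit at the
magnitudes these monitors show against thermodilution; φ = 0.8 is a
stand-in (no published within-patient CI autocorrelation exists) and is
treated as a free parameter by all tests.

`expected_agreement` gives the closed-form implications, term by term:
bias = b₀ + b₁·p̄ (p̄ the count-weighted mean phase effect);
between-patient difference variance b₁²σ_p² + σ_u²; within-patient
b₁²(σ_e²/(1−φ²) + var_p) + σ_η² + cv²·E[t²]. Truncation is ignored in
the closed form.

What the generator does *not* emulate: measurement-to-measurement
device drift or recalibration events, phase-specific device error,
heavy-tailed or skewed noise, informative measurement timing, and the
response-time mismatch between an intermittent reference and continuous
monitors. Passing recovery and calibration tests therefore demonstrate
correctness of the estimators under a Gaussian AR(1) random-effects
world of matching second moments — not robustness of the statistics to
those real-data features.

## Problem sizes and numerical checks

Oracle equivalence runs the ANOVA against an independent brute-force
implementation on 200 random unbalanced datasets and the zone
classifier against a signed-bin oracle on an exhaustive 49-cell grid.
Parameter recovery uses 200-patient × 30-reading cohorts; because a
single such cohort leaves the total-SD estimator with ≈ 1.5% relative
Monte-Carlo error, the closed-form comparison (2% band) averages eight
independent cohorts of that design, while bias is checked per cohort
against 3 Monte-Carlo SEs. CI calibration uses 3000 replicates of the
20 × 29 design in the test suite (coverage SE ≈ 0.4%) and 1000 in the
narrative driver. The cluster bootstrap is exercised at reduced B in
unit tests; the default B = 2000 is the reporting setting.

## Known limitations

Variance components come from method-of-moments ANOVA, not REML; devices
are analyzed independently (no joint model across test devices); no
polar-plot trending; sample sizes ignore clustering (above); the MOVER
coverage statements are established by simulation at the default design,
not analytically, and small-k behavior below ~10 patients is untested.
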