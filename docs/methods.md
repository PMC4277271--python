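# Methods

## Cohort model and admission filter

A patient record is one adult (≥ 18 y) AHF admission with an irregularly
sampled serum-creatinine series in µmol/L, timed in hours relative to
admission (negative = pre-admission, accepted back to 90 days), an outcome
(in-hospital death or discharge, with the time in hours), an RRT flag, and
the covariates used by the adjusted mortality models.

The admission filter removes records the criteria cannot assess or that
represent chronic rather than cardiorenal-acute disease, in this fixed
order: no SCr measurement in the first 168 h; death before 48 h; stay
shorter than 48 h; ESRD on maintenance dialysis; first post-admission SCr
≥ 309.4 µmol/L (3.5 mg/dL at 88.4 µmol/L per mg/dL, compared inclusively);
malignancy; cardiac-surgery- or contrast-associated AKI. Assigning each
excluded patient the *first* matching reason makes the tally well defined
for multi-reason patients, so retained + Σ tally always equals the input
size and the filter is idempotent. "Admission SCr" means the first
measurement with t ≥ 0; ties in time are broken by input order.

## Baseline creatinine

Relative AKI clauses need a pre-morbid reference. The cascade:

1. admission SCr within the sex-specific normal range → the minimum of the
   admission value and any value from the prior 90 days (ties → the
   admission value, so the source label is deterministic);
2. admission elevated, prior value available → the minimum prior value;
3. admission elevated, no prior value → back-calculation from the
   4-variable MDRD equation at a presumed GFR of 75 ml/min/1.73 m².

The MDRD form is the IDMS-traceable re-expression
`eGFR = 175 · SCr[mg/dL]^−1.154 · age^−0.203 · (0.742 if female)` with the
race factor fixed at 1 (the intended population is Chinese). The inversion
is closed-form and exact (round-trips to < 1e−9 relative; property-tested).
Patients in branch 3 whose admission value exceeds the imputed baseline by
a criterion's margin are AKI by construction — an intended behaviour of the
presumed-GFR convention, not an artifact.

Defaults, all configurable: normal-range upper limits 104 µmol/L (male) /
84 µmol/L (female) — typical Jaffé-method laboratory limits, chosen because
laboratory-specific ranges differ; MDRD coefficient 175; presumed GFR 75;
lookback 2160 h.

## Rule engines

Detection is evaluated on measurements in the closed window [0, 168] h:

- **RIFLE**: some measurement ≥ 1.5 × baseline; onset is the earliest such
  time.
- **AKIN**: some ordered pair (i, j) with 0 < t_j − t_i ≤ 48 h and either
  an absolute rise ≥ 26.5 µmol/L or v_j ≥ 1.5 · v_i. This *rolling pair*
  reading compares to the earlier pair member, not to baseline; it is the
  sensitive reading and the package default. A baseline-referenced variant
  (`relative_reference="baseline"`: a rise within 48 h to ≥ 1.5 × baseline)
  is provided because the consensus texts do not pin this down.
- **KDIGO**: AKIN's absolute 48-h clause OR RIFLE's 7-day relative clause.

Onset is the earliest time any clause fires; at tied onsets the trigger
label follows the precedence absolute_48h > relative_48h > relative_7d.
Every threshold comparison is inclusive (≥).

**Union property.** KDIGO's clauses are the disjunction of RIFLE's clause
and AKIN's absolute clause, and AKIN's relative pair clause implies the
7-day relative clause whenever the earlier pair member is at or above
baseline. On trajectories that do not dip well below their baseline —
which includes everything the generator produces and the typical AHF
course — KDIGO therefore detects exactly the union of RIFLE and AKIN
cases; the suite asserts this on 10,000 generated trajectories. A series
that first falls far below baseline and then rebounds ≥ 1.5 × within 48 h
(without a 26.5 µmol/L rise) is AKIN-positive but KDIGO-negative under the
pair reading; such rebound-from-nadir shapes are outside the generator's
scope and the reason the baseline-referenced AKIN variant exists.

**Staging.** The stage ratio uses the peak SCr over the *whole stay*
(detection stays confined to the first week; the asymmetry is deliberate).
Stage 3 extras: RIFLE — peak ≥ 354 µmol/L with an acute rise ≥ 44 µmol/L;
AKIN — peak ≥ 354 with a rise ≥ 26.5, or RRT; KDIGO — peak ≥ 354, or RRT.
RIFLE has no RRT override. The "acute rise" is operationalized as peak
minus the minimum in-stay value measured strictly before the peak (zero
when the peak is the first measurement, so the tier cannot fire on a
single high value — consistent with its "rise to" wording).

## Concordance

Incidence tables report counts and percentages of the retained cohort to
one decimal, half-up. Cross-tabulations are 4×4 (stage 0 = no AKI
included, so cells partition the cohort). Discordant sets: K(+)R(−) =
KDIGO⁺ ∧ RIFLE⁻, K(+)A(−) = KDIGO⁺ ∧ AKIN⁻, their union, and the
triple-positive set. Where a percentage is naturally read against the
KDIGO-positive count (e.g. "share of KDIGO diagnoses missed by RIFLE"),
both denominators are emitted and labelled.

## Survival analysis

In-hospital death is the event; discharge alive is right-censoring at
discharge. The Kaplan–Meier estimator and the two-group log-rank test come
from `lifelines`. Cox models maximize the **Breslow** partial likelihood —
the long-standing default of the clinical statistics packages this
literature uses — via `statsmodels` `PHReg`, followed by a damped
Newton–Raphson polish to max |score| < 1e−8 (or relative log-likelihood
change < 1e−10), so the `converged` flag has an exact meaning. Estimates
with |β| > 20 en route or > 15 at rest are flagged as non-converged
(monotone likelihood / separation) and rejected rather than reported;
collinear covariates raise a singular-information error. Confidence
intervals are normal approximations on the log scale with z = 1.96. The
adjusted models use sex, age, hemoglobin, serum albumin, ACEI/ARB and
diuretic use, with complete-case handling of missing covariates (the
dropped count is carried in the fit object and the report). Clinical
papers in this area often print Cox estimates as "OR"; all outputs here
are named and interpreted as hazard ratios.

The discordant-union model is fitted on the subcohort of KDIGO-negative
patients plus the union group, so its hazard ratio is not diluted by
concordant AKI patients.

Internal identities kept under test: KM with no censoring equals the
empirical survival function; the log-rank statistic equals the Breslow Cox
score test at β = 0 for a binary covariate without ties; the 3-subject
partial likelihood has its known closed-form maximum.

## Synthetic cohort generator

The generator emulates a ~1005-patient AHF cohort with daily ward
laboratory sampling: an admission draw in [0, 6] h, then every 24 ± 6 h
(uniform jitter) until discharge. Stays are lognormal (median 12 days,
log-SD 0.68, clipped to 3–60 days). Ages are Normal(68.5, 15) truncated to
[18, 100]; 43.7 % of patients are female; hemoglobin, albumin and
medication indicators are drawn independently — they exist to make the
adjusted model estimable, not to claim clinical realism. Baselines are
truncated normals per sex (male 88 ± 14, female 70 ± 11 µmol/L) capped at
96 % of the normal-range limit so the admission value stays in range;
pre-admission values (available with probability 0.27) are drawn at
1.00–1.08 × baseline, mimicking a slightly higher chronic value.

Five trajectory archetypes exercise every clause (mix in parentheses):

- `stable` (0.610): fluctuation within ±6 % of baseline; no clause fires.
- `fast_riser` (0.280): 1.6 × baseline by day 1; a drawn peak ratio spreads
  stages 1/2/3 at 0.47/0.37/0.16, keeping ≥ 4σ clear of the 2× and 3×
  cutoffs; 60 % of stage-3 risers receive RRT.
- `slow_creeper` (0.042): +12 % of baseline per day to 1.6 × on day 5;
  every ≤ 48-h rise stays far below both pair thresholds → RIFLE⁺ KDIGO⁺
  AKIN⁻. Creeper stays are at least 7.5 days so the day-5 trigger exists.
- `small_bump` (0.058): a 32–34 µmol/L rise inside one sampling step with
  peak ≤ 1.41 × baseline → AKIN⁺ KDIGO⁺ RIFLE⁻ (baseline ≥ 79 µmol/L
  required; enforced).
- `high_baseline_abs` (0.010): chronic baseline 270–290 µmol/L rising to
  372–380 µmol/L (ratio ≤ 1.40): with a prior value pinning the baseline,
  stage 3 by the absolute tier under KDIGO/AKIN while RIFLE misses the
  patient; without one, the imputed baseline makes the patient concordant
  stage-3 AKI — mirroring how the presumed-GFR convention treats such
  admissions.

This mix puts the expected detection fractions at RIFLE 32.2 %, AKIN
34.8 %, KDIGO 39.0 % and the KDIGO-only union near 10.3 %, the discordance
structure the package is designed to study. Measurement noise is
multiplicative lognormal with CV 1 % (modern assay imprecision); all shape
margins are sized so the probability that noise flips an archetype's
intended detection pattern is below ~1e−4 per patient at that CV. At CV
≳ 2 % the small-bump margins cannot be maintained below the female
normal-range cap, so the default is the noise level at which the
archetype guarantees genuinely hold; raising the CV is possible but voids
those guarantees.

Outcomes: death times are 48 h + Exponential, with rate =
0.0061/day × {1, 3.6, 3.2} for the no-AKI / concordant-AKI / discordant-AKI
groups. The group comes from the actual classifier output, the shift to
48 h respects the early-death exclusion (generated cohorts pass the filter
with zero exclusions), and the baseline rate is calibrated so overall
mortality sits near 13.5 % (no-AKI ≈ 7.4 %, AKI groups ≈ 22–23 %). Because
classification precedes outcome drawing, the lab series is *not* truncated
when a death shortens the stay; post-mortem measurements are a documented
simulation artifact that keeps the hazard groups exactly equal to the
classified groups (re-classifying a written cohort can therefore stage a
handful of early deaths slightly differently). Parameter recovery is
verified in the suite: over 200 replicate cohorts, the discordant-vs-no-AKI
Cox fit recovers ln 3.2 with |mean bias| < 0.05 and ~95 % CI coverage.

What passing tests do and do not show: the generator demonstrates the
pipeline's correctness on trajectories with known ground truth and
clinically plausible sampling; it does not reproduce real-data features
such as RRT-driven creatinine drops, diuretic-induced hemoconcentration,
informative measurement frequency, correlated covariates, or baseline
drift, so calibration results are statements about the simulation, not
about any real cohort.

## Numerical and interface choices

- Times in hours, creatinine in µmol/L everywhere; 1 mg/dL = 88.4 µmol/L.
- Percentages one decimal, half-up (`decimal.Decimal`), matching clinical
  table conventions.
- CSV I/O round-trips floats exactly (`float_precision="round_trip"`).
- Randomness flows through `numpy.random.default_rng` (PCG64, recorded in
  cohort provenance); outcome draws use a child seed sequence of the
  cohort seed so generation and outcome randomness are independent streams.
- The public surface is the importable API plus `examples/`; the `cardiorenal`
  CLI is a thin wrapper for shell use (simulate / classify / compare /
  survive / run).

## Known limitations

Urine-output criteria and RIFLE's outcome classes (Loss, ESRD) are out of
scope by design. The baseline cascade cannot distinguish acute-on-chronic
disease from pure AKI when no prior creatinine exists (it will call such
patients AKI, as the presumed-GFR convention dictates). Cox models assume
proportional hazards and are fitted without time-varying covariates or
competing risks; no Schoenfeld-style diagnostics are run. The synthetic
covariates are independent of AKI status, so adjusted and unadjusted
hazard ratios coincide in expectation on simulated data.
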