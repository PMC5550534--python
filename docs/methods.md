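# Methods

## The exposure model

`hgintake` implements deterministic dietary-exposure arithmetic for
mercury in fish meals. A meal contributes

    intake [μg] = C · m · 1000

where *C* is the total-Hg concentration of the tissue (mg/kg wet weight)
and *m* the edible portion mass (kg). Over a meal schedule the package
reports the total, the mean daily intake (total divided by the number of
*fish-consumption* days, not calendar days — the division that matches the
convention of intervention studies with fish-free weekends; calendar-day
division is available via `daily_intake(..., calendar_days=True)`), and the
mean weekly intake (total divided by the number of schedule weeks). Body
weight normalisation gives the estimated daily and weekly intakes

    EDI = daily / bw        [μg/kg bw/day]
    EWI = weekly / bw       [μg/kg bw/week]

Note that EWI = 7·EDI only when consumption is daily over a full week;
the package does not force that identity.

Risk characterization compares the EWI with intake limits:

    HI  = EWI / PTWI        (hazard index)
    RI  = 100 · HI          (risk index, % of PTWI)

Shipped limits: JECFA PTWI 1.6 μg MeHg/kg bw/week and 4 μg THg/kg bw/week,
the US-NRC limit 0.7 μg/kg bw/week, the Japanese PTWI 3.4 μg/kg bw/week,
and the EC maximum permitted concentration 0.5 mg/kg wet weight for fish
tissue. All are overridable through `ThresholdSet` or a thresholds YAML.

**MeHg fraction.** Total Hg in fish muscle is predominantly methylmercury.
The default `mehg_fraction = 1.0` treats all measured THg as MeHg — the
conservative assumption under which the shipped headline numbers are
computed; 0.9 is the commonly used alternative and scales the EWI/EDI/HI
linearly (total/daily/weekly intake fields remain THg).

**Exceedance convention.** A subject sitting exactly at a limit counts as
compliant (strict `>`); `inclusive=True` flips the convention.

## Descriptive statistics

One percentile convention is used everywhere: linear interpolation between
closest ranks (Hyndman–Fan type 7, numpy's default). Standard deviations
are sample (n−1) SDs; a singleton group reports SD 0. The shipped
per-species reference statistics were computed by the original laboratory
from raw samples that were never deposited, so the package fixes its own
convention and verifies it against an independent sort-and-interpolate
oracle rather than against the published P95 values.

**Raw-vs-fried notation.** The source study reports the fried-minus-raw
mean difference in an idiosyncratic "%" notation that is numerically the
absolute mg/kg difference × 100 (0.060 − 0.049 = 0.011 mg/kg is reported
as "1.1%"). `raw_fried_difference` reproduces that reading as `study_pct`,
clearly labelled, alongside the conventional relative change (`rel_pct`);
the package does not arbitrate which the original authors intended.

**MPC compliance** is assessed on the species mean (the regulatory reading
used by the study), boundary inclusive; a strict mode compares the
per-sample maximum.

**Analyzer QC.** Detection and quantification limits are 3× and 6× the
blank's standard deviation, so QL/DL = 2 exactly; the printed instrument
pair (0.0025/0.0051 ng) is consistent with this definition only to its
printed rounding. CRM recovery is 100 × measured/certified.

## Biomarkers

Blood Hg (μg/l) is summarised at the four intervention timepoints, hair Hg
(μg/g) at baseline and one month post-study. The hair-to-blood ratio uses
the study's unit convention — (μg/g)/(μg/l), i.e. without the factor 1000
between a litre of blood and a gram of hair that the conventional ~250:1
ratio includes — and pairs hair at T4 with blood at T3, because post-study
hair growth records the end-of-study blood level. The headline ratio is
the mean of per-subject ratios (the reading consistent with a reported
median/P95/range of a per-subject distribution); ratio-of-means is
available as an option. The hair-on-blood relationship is fitted by OLS
(scipy) with Pearson's r; a constant response reports r = 0 by convention.
Hypothesis tests are deliberately absent: the module is descriptive, and
significance statements about the original cohort cannot be reproduced
without its raw data.

## Synthetic data generator

The generator exists so that every pipeline stage is testable with no
external data. It emulates the *population* structure of the intervention:

| parameter | default | unit | provenance |
|---|---|---|---|
| n_subjects | 67 | — | study cohort size |
| BMI | 26.9 ± 4.3, range 17.8–40.2 | kg/m² | published cohort summary |
| height | 1.77 ± 0.07 | m | **assumed** (study gives BMI only); chosen so mean body weight ≈ 85 kg, the value back-derived from the published mean EWI |
| smoker / amalgam prevalence | 0.21 / 0.34 | — | published cohort summary |
| tissue Hg per species/state | shipped reference mean/SD/range | mg/kg | published table, n = 12 per group |
| blood Hg T1–T4 | 0.62/0.90/1.28/0.78 (SD 0.41/0.46/0.49/0.60) | μg/l | published means |
| hair Hg T1 | 0.24 ± 0.16 | μg/g | published mean |
| hair:blood ratio | 0.23 | (μg/g)/(μg/l) | published mean |
| ratio_cv, uptake_cv | 0.30 | — | free parameters; per-subject dispersion is unknowable from the published summaries, 0.30 reproduces the order of magnitude of the published ratio range (0.069–0.442) |

Distributional choices:

- **BMI**: truncated normal on [17.8, 40.2]. Plain truncation of
  N(26.9, 4.3) would bias the realized mean to ≈ 27.07, so the generator
  solves for the pre-truncation location/scale whose *truncated* moments
  equal the published ones.
- **Tissue concentrations**: scaled Beta on the published [min, max],
  moment-matched to the published mean/SD. A truncated lognormal was
  considered and rejected: for several species the published n = 12 sample
  range is so tight relative to the SD that no truncated lognormal attains
  both (the best fit misses the SD by up to ~26%); the Beta matches both
  moments exactly in expectation while staying positive, bounded, and
  right-skewed wherever the mean sits below the range midpoint.
- **Biomarker trajectories**: baseline blood is a non-negative truncated
  normal; T2/T3 add an uptake term proportional to the subject's cumulative
  intake per kg body weight (through day 7 / day 14) with multiplicative
  lognormal noise; the proportionality constant is calibrated per timepoint
  against the realized cohort, so generated population means hit the
  targets by construction. T4 relaxes the T3 increment toward baseline by
  the fraction the T4 target implies (≈ 0.24). This is a *simulation
  device calibrated to population means*, explicitly non-mechanistic: it
  is not a toxicokinetic model and supports no inference about uptake or
  elimination kinetics. Hair at T4 is ratio × blood(T3) × noise; baseline
  hair is drawn from its own distribution because it reflects pre-study
  diet — the published baseline hair mean (0.24 μg/g) is inconsistent with
  ratio × baseline blood (0.23 × 0.62 ≈ 0.14 μg/g).
- **Seeding**: a single integer seed spawns independent substreams
  (cohort, fish, biomarkers) via `numpy.random.SeedSequence`, so adding
  draws to one component never perturbs the others, and identical configs
  produce byte-identical outputs.

What passing tests on synthetic data do and do not show: they verify the
arithmetic, the calibration loop (generated data pushed through the
analysis recovers the generating parameters), and schema round-trips. They
do not validate the published per-subject distributions — real cohorts
have covariate structure (age, diet history, amalgam load correlating with
baseline) that the generator deliberately omits, and the published
exceedance fraction (32.8% above the US-NRC limit) depends on the real
body-weight dispersion, which is not recoverable from the published
summaries.

## Numerical and degenerate-input conventions

- Internal computation is full precision; rounding happens only when
  rendering reports (3 decimals for mg/kg quantities by default).
- Empty sample groups, empty cohorts, zero consumption days, non-positive
  body weights, zero certified values, zero-variance predictors and
  unknown species all raise `ValueError`/`KeyError` with the offending
  item named.
- A schedule with no events has total intake 0; its daily intake is
  undefined and raises.
- Body-weight resolution order: explicit weight > BMI × height²; when both
  are given they must agree within 0.5 kg.

## Problem sizes

The shipped checks run the generator at the study size (n = 67) for
calibration-recovery properties, n = 10 000 for moment recovery, and
n = 2 000 for the analytic exceedance cross-check; the whole suite
completes in a few seconds on one CPU.

## Known limitations

- The study never prints the cohort's mean body weight; 85 kg is inferred
  by inverting the published mean EWI and is shipped as a clearly labelled
  constant, not as measured data.
- Published figures that require the unavailable per-subject data (EWI
  range 0.36–0.96, 32.8% NRC exceedance, per-timepoint biomarker SDs as
  *sampling* outcomes, the hair-on-blood regression coefficients) are
  emulated, not reproduced.
- Weekly intake divides the schedule total by whole weeks; a sliding
  7-consecutive-day window is not implemented.
- The international comparison table is documentation only; its inputs are
  not available for recomputation.
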