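# Methods

## Screening model

A screen consists of antibody-secreting B-cell cultures, each seeded with a
fixed number of B cells (default 500), whose supernatants are assayed on
fixed tumor-cell monolayers by a cell-based ELISA.  Every 96-well assay plate
carries triplicate positive-control wells (a monoclonal antibody with known
binding to the target cells) and triplicate negative-control wells
(non-specific human IgG).  Two normalized quantities are derived per sample
well, always from the controls on its own plate:

- fold increase = OD / mean(neg-ctrl OD) — the reactivity measure used in
  all cohort statistics;
- relative absorbance = OD / mean(pos-ctrl OD) — the calling scale, on which
  the plate's mean positive control is exactly 1.

Both are ratios of same-plate ODs, hence invariant to any plate-wide
multiplicative effect (development time, substrate lot).  Cross-plate
pooling of controls is deliberately not offered; the per-plate rule is what
makes the 0.75 threshold comparable across plates.

A well is **reactive** when relative absorbance > 0.75, with strict
inequality (a well exactly at 0.75 is not called).  The threshold is
configurable but 0.75 is the screening default.  A clone is
**tumor-specific** when reactive on ≥ 1 tumor line and on none of the
supplied normal lines.  Reported reactive percentages round half-up to
integers; raw values are kept in machine output.

Plate QC defaults: ≥ 3 wells per control role, control CV ≤ 20 %, positive
mean ≥ 2× negative mean.  Failing plates are excluded with a warning and
counted in the run manifest.  QC is monotone in the CV ceiling: tightening
it can only exclude more plates.

Flow-cytometry binding is summarized as MFI above isotype,
max(0, MFI<sub>sample</sub> − MFI<sub>isotype</sub>); the floor encodes that
below-isotype signal is noise rather than negative binding.

## Limiting-dilution frequency estimation

The single-hit model assumes one reactive B cell makes a well reactive, so
with per-cell frequency f and dose n cells/well,
P(non-reactive) = exp(−f·n), and the number of non-reactive wells at each
dose is Binomial(m, exp(−f·n)).

**37 % crossing.**  At n = 1/f the expected non-reactive fraction is
e⁻¹ ≈ 37 %.  The classical graphical estimator reads the crossing dose off a
semi-log plot; here it is made reproducible by linear interpolation of
ln(fraction non-reactive) against dose between the two bracketing doses —
exact under the model, where ln F₀(n) = −f·n is linear through the origin.
If no dose pair brackets e⁻¹ (frequency too low or too high for the plating
range) the estimator raises and points to the MLE.  All-reactive doses get a
0.5-count continuity correction for interpolation and plotting only, never
in the likelihood.

**Maximum likelihood.**  The binomial log-likelihood is concave in f, so the
score equation has a unique root, solved by bracketed root-finding
(closed form −ln(k/m)/n for a single dose).  Confidence intervals are
profile-likelihood by default (χ²₁ cutoff), with a seeded percentile
bootstrap (1,000 resamples of well counts) as an option.  Degenerate series
— every well reactive, or every well non-reactive — produce boundary
estimates with a warning and a one-sided interval (for the all-non-reactive
case the upper bound has the closed form χ²/2 ÷ Σmᵢnᵢ).

**Goodness of fit.**  The residual deviance of the fitted single-hit curve
against the saturated per-dose model is compared to χ² on (doses − 1)
degrees of freedom.  With discrete binomial counts at ~24 wells/dose the
resulting p-values are only approximately uniform under the null; the
calibration property that holds (and is tested) is that the nominal 5 %
level rejects ≈ 5 % of null data sets.  Single-dose series return a
not-applicable sentinel.

**Aggregate frequency.**  f̂ = positives / (cultures × cells per culture)
under the assumption that each positive culture arises from exactly one
reactive B cell.  When f·cells is not ≪ 1, wells seeded with several
reactive clones still count once, so the estimator is biased low; this
directional bias is asserted by simulation in the test suite.  Note the
one-clone assumption at 500 cells/well and a 28 % positive rate gives
1 in ≈ 1,786 — "1 in N" values are reported with N rounded to the nearest
10 (here 1,790), with the raw frequency always retained.

## Cohort statistics

Patient summaries use the t-interval on the per-culture mean fold increase
(the level is configurable; patients with a single culture get no interval).
Stage-group rows are **unweighted means of patient-level values** — mean of
patient means, of patient maxima, of patient CI bounds, of patient percent
reactive — which is the aggregation that exactly reproduces the packaged
21-patient reference table's group rows at printed precision.  Pooling
cultures across patients instead (patients with more cultures weigh more)
is available through `summarize_cohort`'s per-culture columns and generally
yields higher stage means; the two weightings answer different questions
and are kept distinct.  Reporting precision is 1 decimal for fold values and
integer percentages, matching the reference table; note its per-patient CI
bounds are printed at integer precision, so group CI bounds recomputed from
the printed values can differ from the originally computed ones in the last
digit.

Two-group contrasts use the pooled-variance two-sided Student t
(df = n₁+n₂−2); identical degenerate groups return t = 0, p = 1 with a
flag.  Stage comparisons use one-way ANOVA with Tukey's HSD post-hoc pairs
(statsmodels).  Stage I is excluded from stage-wise inference when it
contains a single patient.

## Synthetic-data generator

The generator emulates the screen's statistical structure, not its images or
sequences.  Defaults are the study conditions: 500 cells/culture, 90
cultures/patient (design range 60–120), cohort of 1 + 8 + 6 + 6 patients in
stages I–IV, triplicate plate controls, dilution doses 125–2,500 cells/well
at 24 wells/dose (two plate columns; the original well counts per dose are
not recorded anywhere, so 24 is the package's configurable default), and
2-hour co-cultures at 5-minute frames with a 3:1 effector:target ratio.

- **Clone counts** are Binomial(cells, f) per well — exact for finite
  plating, indistinguishable from Poisson at the frequencies involved.
- **Stage frequencies** default to the inversion f = −ln(1−p)/500 of the
  single-hit model at the per-stage reactive fractions p of the reference
  cohort's group means (I 2 %, II 33 %, III 30 %, IV 24 %), i.e. roughly
  1/24,700, 1/1,250, 1/1,400 and 1/1,820.  They live in a config mapping,
  not in the sampling code.
- **OD noise** is multiplicative log-normal, parameterized by mean and CV
  (negative/background 0.30 ± 10 %, positive control 1.00 ± 10 %, reactive
  wells 1.10 ± 15 %).  Reactive-well OD is independent of clone count beyond
  presence/absence — a documented simplification; the assay's titer-dose
  relationship is not modeled.
- **Dilution series** draw non-reactive counts directly from
  Binomial(wells, e^{−f·n}).
- **ADCC runs** place static tumor cells in a 400 µm field; effector cells
  perform 2-D Gaussian random walks with per-frame step SD 0.43 µm while
  within 10 µm of a tumor cell and 0.85 µm otherwise (chosen so 24-step
  expected path lengths are ≈ 13 and ≈ 26 µm).  Tumor cells die with a
  per-frame hazard matching a 2-hour kill probability of 0.82
  (tumor-specific antibody scenario) or 0.05 (non-binding control); death is
  absorbing.  Live-cell calcein bleaches to 67 % of baseline over 2 h; dead
  cells' calcein decays with a 20-minute half-life to a 5 % residual.  These
  defaults put the endpoint viability and relative-intensity values in the
  ranges reported for the two antibody classes.
- **Seeding**: one global seed fans out to named child streams (stable
  SHA-256-derived spawn keys), so adding a table never perturbs earlier ones
  and fixed seeds reproduce every table byte for byte.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real screens: per-patient frequency heterogeneity
within a stage (every simulated patient in a stage shares f, whereas real
percent-reactive values vary enormously between patients of the same stage),
plate-position effects and edge artifacts, titer-dependent OD, antigen
spectrum and cross-reactivity structure, and effector-cell behavior beyond
an isotropic random walk with a binary contact state.

A consequence worth stating: with stage II and III calibrated only three
percentage points apart in reactive fraction, a single simulated cohort
(8 + 6 + 6 patients) shows the strict II > III > IV ordering of stage-group
means in only ~80 % of seeds — the ordering is a property of the means, not
of every finite cohort.  The test suite therefore checks the analytic
monotonicity of the calibrated frequencies and the ordering of stage means
averaged across seeds, plus a fixed-seed end-to-end run.

## Numerical choices and degenerate inputs

- Root-finding and profile bounds use `scipy.optimize.brentq` at tight
  tolerances; the likelihood is evaluated with `log1p(−e^{−fn})` for
  stability at small f.
- Duplicate-dose rows are pooled and rows sorted on construction, making
  estimates invariant to row order and dose splitting.
- The goodness-of-fit power check uses a configured alternative in which a
  well needs three reactive cells (a strongly saturating dose-response);
  at 24 wells/dose this is detected at the 5 % level in > 95 % of data sets.
- Off-grid ADCC time queries snap to the nearest 5-minute frame with a
  warning.  "In contact" classification requires the per-frame contact flag
  in ≥ 50 % of frames (configurable); total path length is the primary
  movement measure with net displacement reported alongside, since tracking
  exports differ in convention.
- Simulation sizes in the test suite (e.g. 200 replicates per frequency for
  parameter recovery, 200-replicate null calibrations, 10⁵–10⁶-well
  analytic-limit checks) were chosen to make the checked properties
  statistically decisive while keeping the default suite fast.

## Known limitations

- The MLE assumes a homogeneous single-hit process; multi-hit or
  heterogeneous-frequency alternatives are detected (goodness of fit) but
  not modeled.
- Frequencies from different patients are point estimates juxtaposed, not
  formally compared.
- The ADCC module consumes tabular tracking exports; segmentation and
  tracking quality are outside its scope.
- Group CI bounds recomputed from integer-printed patient CI bounds can
  disagree with originally computed group CIs in the final digit (see
  Cohort statistics above).
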