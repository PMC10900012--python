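# Methods

## The rhythm model

Epoch-level activity `y(t)` (METs, 1-min epochs by default) is modelled as a
two-component cosinor,

    y(t) = M + A1·cos(ω1·t − θ1) + A2·cos(ω2·t − θ2) + e(t),

with the periods fixed at 24 h and 12 h (ω = 2π/T). Time `t` is real-valued
hours since the subject's first midnight; because the basis is periodic,
multi-day records enter the fit directly with no folding. The default fits
the full record; an averaged-day mode (fold to a mean 24-h profile before
fitting) is available via `averaged_day=True` and agrees with the full-record
fit on stationary signals.

The fit linearizes each component as `a = A cos θ`, `b = A sin θ` and solves
the least-squares problem in closed form (`numpy.linalg.lstsq` on the
cos/sin design; tests verify against explicit normal equations). Amplitude
and acrophase are recovered as `A = hypot(a, b)`,
`θ = atan2(b, a) mod 2π`; the acrophase divided by ω gives the component's
peak clock time. A constant series has zero total sum of squares and raises
a degenerate-input error (R² undefined); a rank-deficient design (too few
distinct sampling times) raises a fit error.

**CAR parameters.** The six rhythm descriptors are the mesor, the maximum,
minimum and range (= max − min, exact by construction) of the fitted
composite curve over one clock day, and the clock times of the maximum and
minimum. Effectively single-component fits (other amplitudes below 1e-12)
use the closed form (max = M + A, phases θ/ω and θ/ω + T/2, exact).
Composite curves are evaluated on a 60-s grid over [0, 24); every local
extremum is refined on a 1-s grid aligned to whole seconds, so the reported
extremum coincides with an exhaustive 1-s search; ties break to the earliest
clock time.

**Period scan.** Candidate periods are T = 24/n h for n = 1…720 (shortest
2 min; the value quoted for the original scan's smallest period is read as
3.3333E-2 h, i.e. 24/720). Each candidate is fitted as a single-component
cosinor and ranked by R²; candidates shorter than two epochs are skipped
with a warning. On ward-style actigraphy the 24-h and 12-h cycles rank on
top, which is what motivates the composite model.

## Sleep scoring

The 1-min Cole-Kripke weighted sum is applied to activity counts:
`D(t) = 0.001 · Σ_{j=−4..+2} w_j · counts(t+j)` with
`w = (106, 54, 58, 76, 230, 74, 67)`; the minute is sleep iff `D < 1`.
Missing neighbours contribute 0; invalid minutes are scored *unknown* and
excluded from every sleep sum. The device reports METs, not counts, so a
linear bridge `counts = max(0, METs − 1) × scale` is used; the scale
(default 18 counts per MET above rest) is a calibration parameter — chosen
once so that scripted nocturnal sleep in the synthetic cohort scores as
sleep and scripted daytime rest scores as wake — because the device's count
units are proprietary. Weights, scale factor, threshold and counts scale are
all configurable.

**Main-sleep detection.** The published metrics need a nightly sleep period
but no bout rule is standard, so the package defines its own: nights run
noon-to-noon; sleep runs of ≥ 10 min anchor a bout; anchors separated by
≤ 40 min of non-sleep merge, so nocturnal arousals (including their
edge-spillover in the weighted-sum scoring) stay inside the bout as
wake-within-bout; the longest merged bout whose onset falls in the
18:00–12:00 search window is the night's main sleep. Bouts clipped by the
record boundary are flagged truncated and excluded from averaging — a
5-weekday record that starts at midnight Monday begins mid-sleep, so the
default cohort averages the 4 fully observed nights; total sleep time and
efficiency are per-night quantities and unaffected by the count.

**Nightly metrics.** Per night: sleep period = bout duration (unknown
minutes excluded), arousal = wake minutes inside the bout,
TST = period − arousal, efficiency = 100 × (period − arousal)/period —
algebraically identical to TST divided by the sleep period, and equal to the
conventional TST/time-in-bed when time in bed is delimited by the same bout
(the `efficiency_denominator` flag exists for that reading). Bed time and
waking time are the bout onset/offset clock hours; metrics are averaged
across scored nights (bed times averaged on a noon-folded scale to avoid
midnight wrap).

## Intensity classification

SB < 1.6 METs ≤ LIPA < 3.0 METs ≤ MVPA. The printed bins (1.0–1.5 /
1.6–2.9 / ≥ 3.0) leave (1.5, 1.6) and (2.9, 3.0) unassigned for continuous
values; the half-open convention keeps both printed edges correctly
classified. Minutes are totalled per complete day (SB around the clock;
daytime SB excludes the 22:00–07:00 night window) and averaged over days
with ≥ 80% valid epochs; invalid epochs count toward no class and shrink the
day's denominator, so fully valid days satisfy SB + LIPA + MVPA = 1440 min
exactly.

## Cohort statistics

Two-group comparisons use Welch's unequal-variance t or the Mann-Whitney U
(exact null for combined n ≤ 20 without cross-group ties — within-group ties
do not change U — tie-corrected normal approximation otherwise).
Correlations are Pearson or Spearman; `auto` picks Pearson only when both
vectors pass Shapiro-Wilk at α = 0.05. Because the original per-cell method
choice is not reconstructible, the report grids carry both statistics for
every cell. Regressions are OLS with per-coefficient p-values, overall F/R²,
the Durbin-Watson statistic `d = Σ(eₜ−eₜ₋₁)²/Σeₜ²` computed on residuals in
subject order (order-dependence noted in the report), and VIFs computed from
the definition 1/(1−R²ⱼ) by regressing each predictor on the others.
α = 0.05 two-sided throughout, and no multiplicity adjustment is applied —
the analysis plan this mirrors applied none — which every report header
records. Exactly collinear predictors are dropped with a report rather than
silently regularized.

## The synthetic cohort

No inpatient actigraphy is distributed with the package; the generator is a
first-class, tested component that emulates the study population so the
pipeline is verifiable end to end. Each subject's series is built from:

1. **A latent two-harmonic rhythm.** A single activity-propensity factor
   `u ∈ [0, 1]` — the scaled daily light-activity budget, drawn from a
   right-skewed Beta(0.5, 1.45) prior scaled to 480 min — drives the 24-h
   amplitude (A1 = 0.05 + 0.26·u METs) and, with it, the 12-h amplitude
   (A2/A1 ∈ [0.36, 0.48]). The 24-h peak is Normal(11.4 h, 1.3 h). Because
   a real daily activity waveform is non-sinusoidal, its semidiurnal content
   is a *harmonic of the same waveform*: the 12-h phase is chosen to
   maximize the realized 12-h amplitude of the subject's own noise-free day
   template (±0.4 h scatter). Without this phase-locking, the nocturnal
   sleep window masks the latent 12-h wave and spills 24-h energy into the
   8-h harmonic, which then out-ranks 12 h in the period scan for many
   subjects — the opposite of what ward actigraphy shows.
2. **The ward schedule.** Meals at 07:00/12:00/18:00 (15–25 min, sub-LIPA
   bumps) and a daily light-activity budget spent in habitual slots — the
   three rehabilitation sessions (one in 09:00–12:00, two in 13:00–17:00,
   40–60 min) first, then ward activity around them, concentrated in the
   09:00–17:00 core. During a bout the METs level rides just above the
   latent curve with a light-activity floor that scales with propensity and
   a semidiurnal modulation (morning vigour, post-lunch dip). The budget
   quantile is stratified by subject index (mod 34), so any cohort of ~34
   covers the budget distribution evenly and cohort summaries are stable
   across seeds.
3. **Scripted sleep.** Habitual bed/rise times Normal(21.84 h, 0.85 h) /
   Normal(6.21 h, 0.80 h) with ±7 min nightly jitter; during sleep the
   above-floor level drops to 0.05 METs, interrupted by scripted arousal
   episodes (3–8 min, ≥ 25 min apart, a Beta-distributed fraction of the
   night) that the scoring rule detects as wake.
4. **Noise.** Log-normal multiplicative noise on the above-floor component
   (σ = 0.10 awake, 0.13 in bouts, 0.30 asleep), so the 1.0 METs device
   floor is respected without truncation artifacts and residual variance
   scales with activity level.

The mesor target is affine in the subject's *expected* LIPA minutes
(computed in closed form under the log-normal noise), which keeps the
cohort-level mesor-vs-sedentary-time relation linear — as observed in this
population — rather than convex in the propensity. Subjects on hypnotics
(prevalence 10/34) have the latent peak delayed and morning activity damped
(redistributed to the afternoon), sized so the *composite* peak lands
≈ 2.5–3 h later while scripted sleep metrics are untouched. Covariates
(age, sex, BMI, diagnosis, MMSE, motor FIM, medication, locomotive
independence) are drawn to match the cohort's published prevalences and are
otherwise inert. Weekends are not generated (recordings run
Monday–Friday). Per-subject random streams derive from
`SeedSequence(seed, spawn_key=(i,))`, so identical (config, seed) pairs are
bit-for-bit reproducible and enlarging a cohort never perturbs earlier
subjects.

**What the generator does not emulate:** raw tri-axial acceleration and the
device's proprietary METs conversion, naps and off-wrist intervals,
weekend/family-visit dynamics, day-to-day habit drift, and any
covariate-rhythm associations beyond the hypnotics effect. Passing tests
therefore show that the analysis recovers known structure from data *shaped
like* ward actigraphy, not that the device or the clinical findings are
themselves validated.

## Numerical choices and degenerate inputs

- Epoch length 60 s by default (configurable); off-grid timestamps are a
  format error, whole-epoch gaps are filled as invalid epochs.
- METs below the 1.0 floor are clamped to 1.0 with a warning on read.
- Extremum refinement at 1-s resolution; agreement with exhaustive search to
  1e-6 METs and 1/3600 h is a tested invariant.
- Cosinor component amplitudes ≤ 1e-12 are treated as absent so the exact
  closed form applies to effectively single-component fits.
- Series with < 80% valid epochs fail validation (report-only); days with
  < 80% valid epochs are dropped from activity averaging; nights with no
  detectable bout are omitted from sleep averaging with a warning.
- Problem sizes used in the test suite and acceptance script: 34 subjects ×
  5 days × 1440 epochs for cohort-level checks; 200 replicate series for
  parameter-recovery statistics; 200 seeded cohorts for the
  hypnotics-detection power check.

## Known limitations

- The composite-curve minimum of the default cohort sits slightly later
  (~02:30–03:00) than the published minimum phase time (~01:41); the
  phase-locked 12-h geometry trades this cosmetic offset for correct period
  ranking.
- The generator's LIPA distribution has a slightly heavier upper tail than
  the printed range; cohort means remain within one published SD.
- Durbin-Watson on a cross-sectional cohort depends on subject order; it is
  reported for parity with the original analysis plan, not as evidence of
  serial structure.
- About 2% of synthetic subjects across seeds rank a period other than 12 h
  second in the scan (razor-thin contests in near-flat subjects); the 24-h
  cycle always ranks first and the cohort-aggregate ranking is stable.
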