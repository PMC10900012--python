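# actirhythm

Circadian activity rhythm (CAR) analysis for epoch-level wrist-actigraphy
data expressed in METs, aimed at rehabilitation-ward and geriatric research:
therapists and researchers who want to quantify *when* and *how much* their
inpatients move, and how that rhythm relates to sedentary time and sleep.

Hospitalized elderly patients live under a fixed ward schedule (lights on
07:00, meals 07:00/12:00/18:00, rehabilitation sessions morning and
afternoon, lights out 22:00). Their daily activity pattern is summarized here
by a **two-component cosinor (periodic) regression**

```
y(t) = M + A1·cos(ω1·t − θ1) + A2·cos(ω2·t − θ2) + e(t)
```

with fixed angular frequencies ω1 = 2π/24 h⁻¹ and ω2 = 2π/12 h⁻¹. The model
is linear in `a_k = A_k cos θ_k`, `b_k = A_k sin θ_k`, so the fit is a
closed-form least squares on the cos/sin design. Six CAR parameters are
derived from the fitted composite curve: mesor `M`, maximum, minimum,
range = maximum − minimum, and the clock times of the daily maximum and
minimum. A 720-candidate period scan (T = 24/n h, n = 1…720) ranks candidate
cycles by R² and motivates the 24 h + 12 h pair.

Around the rhythm model the package provides, as one pipeline:

- **Sleep scoring** — the 1-min Cole-Kripke weighted-sum rule
  (weights 106, 54, 58, 76, 230, 74, 67 for lags −4…+2 min, scale 0.001,
  sleep iff the sum < 1) on counts bridged from METs, main nocturnal bout
  detection, and nightly total sleep time / sleep efficiency / bed and
  waking times averaged across nights.
- **Intensity classification** — sedentary behaviour (SB, < 1.6 METs),
  light activity (LIPA, 1.6–2.9 METs) and moderate-to-vigorous activity
  (MVPA, ≥ 3.0 METs) minutes per day, plus daytime SB excluding 22:00–07:00.
- **Cohort statistics** — Welch / Mann-Whitney group comparisons, Pearson /
  Spearman correlation grids, and OLS regressions of CAR parameters on
  activity classes with Durbin-Watson and VIF diagnostics.
- **A calibrated synthetic cohort generator** — inpatient-like METs series
  with known ground truth (latent rhythm, ward schedule bouts, scripted
  sleep), whose defaults reproduce published cohort summaries for this
  population; it makes the whole pipeline testable without any device data.

## Worked example

```python
from actirhythm import CosinorModel, GeneratorConfig, generate_subject

record, series, truth = generate_subject(GeneratorConfig(), 0)
fit = CosinorModel.from_series(series).fit()
print(fit.summary())
```

```
Multi-component cosinor regression
==============================================
n epochs used                   7200
mesor (METs)                  1.1443
R-squared                     0.8021
----------------------------------------------
period (h)   amplitude   acrophase  peak (h)
     24.00      0.0727      3.2022     12.23
     12.00      0.0398      4.6592      8.90
----------------------------------------------
maximum (METs)                1.2384
minimum (METs)                1.0438
range (METs)                  0.1945
max phase time (h)             9.936
min phase time (h)             2.066
```

This subject's rhythm-adjusted mean activity is 1.14 METs (quiet, sedentary
days), the fitted curve peaks at 09:56 at 1.24 METs and bottoms out at 02:04
near the 1.0 METs resting floor; the two-harmonic model explains 80% of the
epoch-to-epoch variance. `fit.predict(t)` evaluates the curve,
`fit.car_parameters()` returns the six CAR parameters as a dataclass, and
`actirhythm.plotting.plot_subject_rhythm` renders the raw epochs with the
fitted curve.

The full pipeline — simulate (or read CSVs), validate, fit the CAR, score
sleep, classify intensity, and emit the cohort comparison/correlation/
regression report bundle — is one call or one command:

```python
from actirhythm import run_pipeline
result = run_pipeline(out_dir="run")        # default synthetic cohort, n=34
print(result.cohort[["subject_id", "mesor", "range", "total_sleep_time"]].head())
```

```bash
actirhythm run --out run                    # same, from the shell
actirhythm simulate --out cohort --subjects 34
actirhythm car --epochs cohort/epochs.csv --out car.tsv
```

Epoch CSVs have columns `subject_id, timestamp (ISO-8601), mets[, valid]`;
all defaults can be overridden with a YAML file (see `configs/default.yaml`).

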