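# Full default pipeline configuration (echoes the built-in defaults;
# pass to `actirhythm run --config configs/default.yaml`).
simulate: true
generator:
  n_subjects: 34
  n_days: 5
  epoch_seconds: 60
  seed: 20180601
  start_date: '2018-06-04'
  lights_on: 7.0
  lights_out: 22.0
  meal_times:
  - 7.0
  - 12.0
  - 18.0
  meal_duration_min:
  - 15.0
  - 25.0
  morning_rehab_window:
  - 9.0
  - 12.0
  afternoon_rehab_window:
  - 13.0
  - 17.0
  rehab_duration_min:
  - 40.0
  - 60.0
  lipa_budget_beta:
  - 0.5
  - 1.45
  lipa_budget_max: 480.0
  amp24_range:
  - 0.05
  - 0.31
  amp12_ratio_range:
  - 0.36
  - 0.48
  peak_time_mean: 11.4
  peak_time_sd: 1.3
  secondary_peak_jitter: 0.4
  mesor_base: 0.158
  mesor_span: 0.33
  mesor_jitter_sd: 0.005
  latent_min_bounds:
  - 0.03
  - 0.2
  activity_above_floor: 0.62
  activity_above_span: 0.16
  activity_above_margin: 0.1
  activity_mod12: 0.25
  meal_above_base: 0.2
  meal_above_span: 0.35
  noise_sigma_day: 0.1
  noise_sigma_bout: 0.13
  noise_sigma_sleep: 0.3
  sleep_above: 0.05
  resting_above: 0.1
  bed_time_mean: 21.84
  bed_time_sd: 0.85
  wake_time_mean: 6.21
  wake_time_sd: 0.8
  night_jitter_sd: 0.12
  arousal_beta:
  - 2.0
  - 21.0
  arousal_episode_min:
  - 3.0
  - 8.0
  arousal_above:
  - 0.12
  - 0.18
  p_male: 0.38235294117647056
  p_cerebrovascular: 0.6470588235294118
  p_hypnotics: 0.29411764705882354
  p_psychotropics: 0.058823529411764705
  p_locomotive_independent: 0.5882352941176471
  age_mean: 77.5
  age_sd: 7.7
  bmi_mean: 22.3
  bmi_sd: 3.3
  mmse_mean: 28.0
  mmse_sd: 1.7
  fim_mean: 67.8
  fim_sd: 17.4
  hypnotic_peak_delay_h: 3.3
  hypnotic_morning_damping: 0.6
epoch_seconds: 60
periods:
- 24.0
- 12.0
averaged_day: false
ck_weights:
- 106.0
- 54.0
- 58.0
- 76.0
- 230.0
- 74.0
- 67.0
ck_scale_factor: 0.001
ck_threshold: 1.0
counts_scale: 18.0
bout_gap_tolerance_min: 40.0
sleep_onset_window:
- 18.0
- 12.0
night_window:
- 22.0
- 7.0
min_valid_fraction: 0.8
make_plots: false
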