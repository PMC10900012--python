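"""Synthetic inpatient actigraphy cohorts with known ground truth.

Each subject's METs series is built from four layers that emulate life on a
rehabilitation ward:

* a latent two-harmonic (24 h + 12 h) circadian rhythm above the 1.0 METs
  device floor, whose amplitude scales with a per-subject activity propensity;
* scheduled activity bouts — three meals (07:00 / 12:00 / 18:00) and three
  rehabilitation sessions of 40-60 min (one in 09:00-12:00, two in
  13:00-17:00) whose intensity also scales with propensity;
* scripted nocturnal sleep (lights-out 22:00, lights-on 07:00; habitual bed
  and rise times drawn per subject) during which activity drops to just above
  the floor, interrupted by brief scripted arousal episodes;
* positive-skewed noise, log-normal on the above-floor component so the
  METs >= 1.0 floor is respected without truncation artifacts and residual
  variance scales with activity level.

Weekend days are not generated (recordings run Monday-Friday).  Subjects
taking hypnotics have their latent peak delayed (default 2.5 h) and their
morning rehabilitation participation damped, which delays the composite peak
while leaving the scripted sleep metrics untouched.

Per-subject random streams derive from ``SeedSequence(seed, spawn_key=(i,))``,
so enlarging a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .epochs import EpochSeries, SubjectRecord, write_epoch_series, write_metadata

__all__ = [
    "GeneratorConfig",
    "SubjectTruth",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "describe_ground_truth",
    "simulate_harmonic_series",
]


@dataclasses.dataclass
class GeneratorConfig:
    """Defaults reproduce the study conditions: 34 subjects, 5 weekday
    recordings of 1-min epochs, ward schedule, cohort-calibrated priors."""

    n_subjects: int = 34
    n_days: int = 5
    epoch_seconds: int = 60
    seed: int = 20180601
    start_date: str = "2018-06-04"  # a Monday

    # ward schedule (clock hours)
    lights_on: float = 7.0
    lights_out: float = 22.0
    meal_times: tuple[float, ...] = (7.0, 12.0, 18.0)
    meal_duration_min: tuple[float, float] = (15.0, 25.0)
    morning_rehab_window: tuple[float, float] = (9.0, 12.0)
    afternoon_rehab_window: tuple[float, float] = (13.0, 17.0)
    rehab_duration_min: tuple[float, float] = (40.0, 60.0)

    # latent rhythm priors.  A single activity-propensity factor u in [0, 1]
    # (the scaled daily light-activity budget) drives both the latent rhythm
    # amplitude and the scheduled activity below, which is what couples the
    # fitted mesor to SB/LIPA time across subjects.
    lipa_budget_beta: tuple[float, float] = (0.5, 1.45)  # budget = max * Beta(a, b)
    lipa_budget_max: float = 480.0  # min/day of scheduled above-SB activity
    amp24_range: tuple[float, float] = (0.05, 0.31)  # A1 = lo + span * u
    amp12_ratio_range: tuple[float, float] = (0.36, 0.48)  # A2 / A1
    peak_time_mean: float = 11.4  # latent 24-h peak clock hour
    peak_time_sd: float = 1.3
    secondary_peak_jitter: float = 0.4  # h; scatter around the phase-locked 12-h peak
    # mesor = 1 + base + span * (expected LIPA / budget max) + jitter (METs):
    # anchoring the rhythm-adjusted mean to the subject's realized light-activity
    # time keeps the cohort-level mesor-vs-SB relation linear, as observed
    mesor_base: float = 0.158
    mesor_span: float = 0.33
    mesor_jitter_sd: float = 0.005
    latent_min_bounds: tuple[float, float] = (0.03, 0.20)  # latent minimum above floor

    # scheduled activity: the daily budget is spent in habitual slots (rehab
    # sessions first, then ward activity around them); during a bout the METs
    # level rides just above the latent curve with a light-activity floor.
    activity_above_floor: float = 0.62  # minimum above-floor level in a bout
    activity_above_span: float = 0.16  # + span * u: fitter subjects work harder
    activity_above_margin: float = 0.10  # lift over the latent curve in a bout
    activity_mod12: float = 0.25  # semidiurnal modulation of bout intensity
    #   (morning vigour / post-lunch dip, phase-locked to the latent 12-h peak)
    meal_above_base: float = 0.20
    meal_above_span: float = 0.35

    # noise (log-normal sigma on the above-floor component)
    noise_sigma_day: float = 0.10
    noise_sigma_bout: float = 0.13
    noise_sigma_sleep: float = 0.30
    sleep_above: float = 0.05  # above-floor level during scripted sleep
    resting_above: float = 0.10  # awake floor: quiet rest in bed/room (METs above 1.0)

    # scripted sleep
    bed_time_mean: float = 21.84
    bed_time_sd: float = 0.85
    wake_time_mean: float = 6.21
    wake_time_sd: float = 0.80
    night_jitter_sd: float = 0.12
    arousal_beta: tuple[float, float] = (2.0, 21.0)  # wake fraction of the night
    arousal_episode_min: tuple[float, float] = (3.0, 8.0)
    arousal_above: tuple[float, float] = (0.12, 0.18)

    # covariate model (cohort prevalences)
    p_male: float = 13 / 34
    p_cerebrovascular: float = 22 / 34
    p_hypnotics: float = 10 / 34
    p_psychotropics: float = 2 / 34
    p_locomotive_independent: float = 20 / 34
    age_mean: float = 77.5
    age_sd: float = 7.7
    bmi_mean: float = 22.3
    bmi_sd: float = 3.3
    mmse_mean: float = 28.0
    mmse_sd: float = 1.7
    fim_mean: float = 67.8
    fim_sd: float = 17.4

    # medication effects
    hypnotic_peak_delay_h: float = 3.3
    hypnotic_morning_damping: float = 0.6

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1 or self.epoch_seconds <= 0:
            raise ValueError("n_subjects, n_days and epoch_seconds must be positive")
        if self.amp24_range[0] < 0 or self.noise_sigma_day <= 0:
            raise ValueError("amplitudes must be >= 0 and noise scale > 0")
        if self.lipa_budget_max < 0 or self.activity_above_floor < 0:
            raise ValueError("activity budget and levels must be non-negative")
        for p in (
            self.p_male,
            self.p_cerebrovascular,
            self.p_hypnotics,
            self.p_psychotropics,
            self.p_locomotive_independent,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")


@dataclasses.dataclass
class SubjectTruth:
    """Latent parameters and scripted events behind one generated subject."""

    subject_id: str
    propensity: float
    mesor: float
    amp_24h: float
    peak_24h: float  # clock hour of the latent 24-h component peak
    amp_12h: float
    peak_12h: float
    latent_min: float  # latent curve minimum (METs)
    bed_times: list[float]  # hours since first midnight, one per night
    wake_times: list[float]
    arousal_minutes: list[float]  # scripted wake minutes per night
    arousal_episodes: list[tuple[float, float]]  # scripted arousal intervals (h)
    bouts: list[tuple[float, float, float]]  # (start_h, end_h, above_floor_level)
    hypnotics: bool


@dataclasses.dataclass
class Cohort:
    config: GeneratorConfig
    records: list[SubjectRecord]
    series: list[EpochSeries]
    truths: list[SubjectTruth]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_epoch_series(self.series, out / "epochs.csv")
        write_metadata(self.records, out / "metadata.csv")
        truths = [dataclasses.asdict(t) for t in self.truths]
        (out / "ground_truth.json").write_text(json.dumps(truths, indent=1))


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """Stated seed-splitting rule: stream i = SeedSequence(seed, spawn_key=(i,))."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_record(cfg: GeneratorConfig, rng: np.random.Generator, sid: str) -> SubjectRecord:
    return SubjectRecord(
        subject_id=sid,
        age=float(np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd)), 66, 90)),
        sex="male" if rng.random() < cfg.p_male else "female",
        bmi=float(np.round(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 1)),
        diagnosis="cerebrovascular" if rng.random() < cfg.p_cerebrovascular else "orthopedic",
        mmse=int(np.clip(np.round(rng.normal(cfg.mmse_mean, cfg.mmse_sd)), 24, 30)),
        motor_fim=int(np.clip(np.round(rng.normal(cfg.fim_mean, cfg.fim_sd)), 13, 91)),
        hypnotics=bool(rng.random() < cfg.p_hypnotics),
        psychotropics=bool(rng.random() < cfg.p_psychotropics),
        locomotive_independent=bool(rng.random() < cfg.p_locomotive_independent),
    )


# Habitual daily activity slots (clock hour, capacity in minutes) in fill
# order: the three rehabilitation sessions first, then ward/leisure activity
# around them.  A subject's daily light-activity budget is spent down this
# list, so low-budget subjects only attend (part of) their rehab sessions
# while high-budget subjects are on their feet most of the day.
_ACTIVITY_SLOTS: tuple[tuple[float, float], ...] = (
    (9.2, 60.0),    # morning rehab (09:00-12:00 window)
    (13.1, 60.0),   # afternoon rehab 1 (13:00-17:00 window)
    (15.1, 60.0),   # afternoon rehab 2
    (10.3, 85.0),   # ward activity, late morning
    (16.0, 55.0),   # ward activity, late afternoon
    (14.2, 50.0),   # ward activity, mid afternoon
    (11.75, 40.0),  # before lunch
    (12.45, 30.0),  # after lunch
    (8.3, 45.0),    # after breakfast (largest budgets only)
    (17.1, 45.0),   # pre-dinner stroll (largest budgets only)
)


def _activity_plan(
    cfg: GeneratorConfig, rng: np.random.Generator, budget_min: float, hypnotics: bool
) -> list[tuple[float, float]]:
    """Subject-habitual (start_clock_h, duration_min) bouts for one day template."""
    plan = []
    remaining = budget_min
    for start, cap in _ACTIVITY_SLOTS:
        if remaining <= 0:
            break
        if hypnotics and start < 12.0:
            cap *= 1.0 - cfg.hypnotic_morning_damping
        dur = min(cap, remaining)
        plan.append((start + rng.uniform(-0.15, 0.15), dur))
        remaining -= dur
    return plan


def _draw_bouts(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    day: int,
    plan: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """One day's realized activity bouts (start_h, end_h) with daily jitter."""
    base = 24.0 * day
    bouts = []
    for start, dur in plan:
        jitter = rng.normal(0.0, 0.25)
        d = dur * rng.uniform(0.8, 1.2)
        s0 = base + start + jitter
        bouts.append((s0, s0 + d / 60.0))
    return bouts


def generate_subject(
    config: GeneratorConfig, index: int
) -> tuple[SubjectRecord, EpochSeries, SubjectTruth]:
    """Generate one subject: covariates, METs epoch series and ground truth."""
    config.validate()
    rng = _subject_rng(config.seed, index)
    sid = f"S{index + 1:02d}"
    record = _draw_record(config, rng, sid)

    # stratified draw of the activity budget: subject i samples the i-th
    # quantile band of the Beta prior (mod 34), so any cohort of ~34 covers
    # the budget distribution evenly and cohort-level summaries are stable
    q = ((index % 34) + rng.uniform()) / 34.0
    budget = float(
        config.lipa_budget_max * scipy.stats.beta.ppf(q, *config.lipa_budget_beta)
    )
    u = budget / config.lipa_budget_max
    a_lo, a_hi = config.amp24_range
    amp24 = a_lo + (a_hi - a_lo) * u
    amp12 = amp24 * rng.uniform(*config.amp12_ratio_range)
    peak24 = float(rng.normal(config.peak_time_mean, config.peak_time_sd))
    if record.hypnotics:
        peak24 += config.hypnotic_peak_delay_h
    peak24 = float(np.clip(peak24, 8.0, 18.5))
    # provisional mesor target; refined below from the expected LIPA time
    mesor_jitter = float(rng.normal(0.0, config.mesor_jitter_sd))
    mesor_target = 1.0 + config.mesor_base + config.mesor_span * u + mesor_jitter

    w1 = 2.0 * np.pi / 24.0
    w2 = 2.0 * np.pi / 12.0

    # habitual schedule, drawn before the rhythm phase is fixed
    bed_hab = float(np.clip(rng.normal(config.bed_time_mean, config.bed_time_sd), 20.8, 23.4))
    wake_hab = float(np.clip(rng.normal(config.wake_time_mean, config.wake_time_sd), 4.6, 7.3))
    plan = _activity_plan(config, rng, budget, record.hypnotics)
    meal_above = config.meal_above_base + config.meal_above_span * u
    meal_durs = [rng.uniform(*config.meal_duration_min) / 60.0 for _ in config.meal_times]

    lo_min, hi_min = config.latent_min_bounds

    def _mesor_for(rhythm_min: float) -> float:
        # hit the affine mesor target while keeping the latent minimum sane
        min_level = float(np.clip(mesor_target - 1.0 + rhythm_min, lo_min, hi_min))
        return 1.0 + min_level - rhythm_min

    def day_template(p12: float, grid: np.ndarray) -> np.ndarray:
        """Noise-free above-floor METs over one habitual day."""
        rhythm = amp24 * np.cos(w1 * (grid - peak24)) + amp12 * np.cos(w2 * (grid - p12))
        mes = _mesor_for(float(rhythm.min()))
        above = np.maximum(mes - 1.0 + rhythm, config.resting_above)
        for mt, dur in zip(config.meal_times, meal_durs):
            sel = (grid >= mt) & (grid < mt + dur)
            above[sel] = np.maximum(above[sel], meal_above)
        floor = config.activity_above_floor + config.activity_above_span * u
        for start, dur in plan:
            sel = (grid >= start) & (grid < start + dur / 60.0)
            mod12 = 1.0 + config.activity_mod12 * np.cos(w2 * (grid[sel] - p12))
            lat = mes - 1.0 + rhythm[sel]
            above[sel] = np.maximum(lat + 0.10, floor * mod12)
        night = (grid < wake_hab) | (grid >= bed_hab)
        above[night] = config.sleep_above
        return above

    # The daily waveform is non-sinusoidal, so its 12-h content is a harmonic
    # of the waveform itself: pick the 12-h phase that maximizes the realized
    # semidiurnal amplitude of the subject's own noise-free day template,
    # then add individual scatter.
    grid = np.arange(0.0, 24.0, 1.0 / 60.0)
    cos12, sin12 = np.cos(w2 * grid), np.sin(w2 * grid)
    best_p12, best_amp = 0.0, -1.0
    for cand in np.arange(0.0, 12.0, 0.25):
        y = day_template(cand, grid)
        amp = np.hypot(2.0 * np.mean((y - y.mean()) * cos12), 2.0 * np.mean((y - y.mean()) * sin12))
        if amp > best_amp:
            best_p12, best_amp = float(cand), float(amp)
    peak12 = float((best_p12 + rng.normal(0.0, config.secondary_peak_jitter)) % 12.0)

    # expected light-activity minutes of the noise-free day (closed form under
    # the log-normal noise); the mesor target is affine in this quantity
    y_day = day_template(peak12, grid)
    sig = config.noise_sigma_day
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(y_day, 1e-12) / 0.6) - 0.5 * sig**2) / sig
    expected_lipa = float(scipy.stats.norm.cdf(z).sum())  # 1-min grid -> minutes
    mesor_target = (
        1.0 + config.mesor_base
        + config.mesor_span * expected_lipa / config.lipa_budget_max
        + mesor_jitter
    )

    def rhythm(t: np.ndarray) -> np.ndarray:
        return amp24 * np.cos(w1 * (t - peak24)) + amp12 * np.cos(w2 * (t - peak12))

    fine = np.arange(0.0, 24.0, 1.0 / 60.0)
    mesor = _mesor_for(float(rhythm(fine).min()))

    n = config.n_days * int(round(86400 / config.epoch_seconds))
    dt = config.epoch_seconds / 3600.0
    t = np.arange(n) * dt
    latent_above = mesor - 1.0 + rhythm(t)
    above = np.maximum(latent_above, config.resting_above)

    # meals: brief sub-LIPA bumps at the ward meal times
    bout_mask = np.zeros(n, dtype=bool)
    bouts: list[tuple[float, float, float]] = []
    for day in range(config.n_days):
        for mt, dur in zip(config.meal_times, meal_durs):
            s0 = 24.0 * day + mt + rng.uniform(0.0, 0.1)
            level = meal_above * rng.uniform(0.85, 1.15)
            sel = (t >= s0) & (t < s0 + dur)
            above[sel] = np.maximum(above[sel], level)
            bouts.append((s0, s0 + dur, level))

    # scheduled light activity: spend the daily budget in the habitual slots;
    # during a bout the level rides just above the latent curve
    for day in range(config.n_days):
        for s0, e0 in _draw_bouts(config, rng, day, plan):
            sel = (t >= s0) & (t < e0)
            if not sel.any():
                continue
            mod12 = 1.0 + config.activity_mod12 * np.cos(w2 * (t[sel] - peak12))
            level = np.maximum(
                latent_above[sel] + config.activity_above_margin,
                (config.activity_above_floor + config.activity_above_span * u) * mod12,
            )
            above[sel] = np.maximum(above[sel], level)
            bout_mask |= sel
            bouts.append((s0, e0, float(level.mean())))

    # scripted nocturnal sleep around the habitual bed / rise times
    arousal_frac = float(rng.beta(*config.arousal_beta))
    sleep_mask = np.zeros(n, dtype=bool)
    arousal_mask = np.zeros(n, dtype=bool)
    arousal_level = np.zeros(n)
    bed_times, wake_times, arousal_minutes = [], [], []
    arousal_episodes: list[tuple[float, float]] = []
    epoch_min = config.epoch_seconds / 60.0
    for night in range(-1, config.n_days):
        bed = 24.0 * night + bed_hab + float(rng.normal(0.0, config.night_jitter_sd))
        wake = 24.0 * (night + 1) + wake_hab + float(rng.normal(0.0, config.night_jitter_sd))
        i0 = max(0, int(np.ceil(bed / dt)))
        i1 = min(n, int(np.floor(wake / dt)))
        if i1 <= i0:
            continue
        sleep_mask[i0:i1] = True
        bed_times.append(bed)
        wake_times.append(wake)
        # scripted arousal episodes inside the night, away from the edges
        night_min = (i1 - i0) * epoch_min
        target = arousal_frac * night_min * float(rng.uniform(0.8, 1.2))
        placed = 0.0
        guard = int(round(20.0 / epoch_min))
        attempts = 0
        while placed < target and attempts < 200:
            attempts += 1
            ep_len = int(round(rng.uniform(*config.arousal_episode_min) / epoch_min))
            j0 = int(rng.integers(i0 + guard, max(i0 + guard + 1, i1 - guard - ep_len)))
            j1 = min(j0 + ep_len, i1 - guard)
            # keep episodes well separated so the main bout never fragments
            sep = int(round(25.0 / epoch_min))
            if j1 <= j0 or arousal_mask[max(i0, j0 - sep) : min(i1, j1 + sep)].any():
                continue
            arousal_mask[j0:j1] = True
            arousal_level[j0:j1] = rng.uniform(*config.arousal_above)
            arousal_episodes.append((j0 * dt, j1 * dt))
            placed += (j1 - j0) * epoch_min
        arousal_minutes.append(placed)

    quiet = sleep_mask & ~arousal_mask
    above[quiet] = config.sleep_above
    above[arousal_mask] = arousal_level[arousal_mask]

    sigma = np.full(n, config.noise_sigma_day)
    sigma[bout_mask & ~sleep_mask] = config.noise_sigma_bout
    sigma[sleep_mask] = config.noise_sigma_sleep
    eps = rng.standard_normal(n)
    mets = 1.0 + above * np.exp(sigma * eps - 0.5 * sigma**2)
    mets = np.maximum(1.0, mets)

    start = pd.Timestamp(config.start_date)
    series = EpochSeries(sid, start, config.epoch_seconds, mets, np.ones(n, dtype=bool))
    truth = SubjectTruth(
        subject_id=sid,
        propensity=u,
        mesor=mesor,
        amp_24h=amp24,
        peak_24h=peak24 % 24.0,
        amp_12h=amp12,
        peak_12h=peak12 % 12.0,
        latent_min=float(mesor + rhythm(fine).min()),
        bed_times=bed_times,
        wake_times=wake_times,
        arousal_minutes=arousal_minutes,
        arousal_episodes=arousal_episodes,
        bouts=bouts,
        hypnotics=record.hypnotics,
    )
    return record, series, truth


def generate_cohort(config: GeneratorConfig | None = None, out_dir: str | Path | None = None) -> Cohort:
    """Generate ``config.n_subjects`` independent subjects; optionally write
    the epoch CSV, metadata CSV and ground-truth JSON."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    records, series, truths = [], [], []
    for i in range(cfg.n_subjects):
        rec, ser, tru = generate_subject(cfg, i)
        records.append(rec)
        series.append(ser)
        truths.append(tru)
    cohort = Cohort(cfg, records, series, truths)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def describe_ground_truth(cohort: Cohort) -> pd.DataFrame:
    """Per-subject latent parameters and scripted sleep, for recovery tests."""
    rows = []
    for tr in cohort.truths:
        rows.append(
            {
                "subject_id": tr.subject_id,
                "propensity": tr.propensity,
                "mesor": tr.mesor,
                "amp_24h": tr.amp_24h,
                "peak_24h": tr.peak_24h,
                "amp_12h": tr.amp_12h,
                "peak_12h": tr.peak_12h,
                "latent_min": tr.latent_min,
                "mean_bed_clock": float(np.mean([b % 24.0 for b in tr.bed_times])),
                "mean_wake_clock": float(np.mean([w % 24.0 for w in tr.wake_times])),
                "mean_arousal_min": float(np.mean(tr.arousal_minutes)),
                "hypnotics": tr.hypnotics,
            }
        )
    return pd.DataFrame(rows)


def simulate_harmonic_series(
    mesor: float,
    components: Sequence[tuple[float, float, float]],
    sigma: float,
    n_days: int = 5,
    epoch_seconds: int = 60,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "SIM",
) -> EpochSeries:
    """Pure cosinor signal plus i.i.d. Gaussian noise (statistical fixture).

    ``components`` are (period_h, amplitude, acrophase_rad) triples.  The METs
    validity floor is deliberately not enforced here so that parameter-recovery
    statistics are unbiased.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = n_days * int(round(86400 / epoch_seconds))
    t = np.arange(n) * (epoch_seconds / 3600.0)
    y = np.full(n, float(mesor))
    for period, amp, theta in components:
        y += amp * np.cos(2.0 * np.pi / period * t - theta)
    y += sigma * rng.standard_normal(n)
    return EpochSeries(subject_id, pd.Timestamp("2018-06-04"), epoch_seconds, y, np.ones(n, bool))
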