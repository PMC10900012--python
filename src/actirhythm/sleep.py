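"""Cole-Kripke sleep/wake scoring, main-sleep-bout detection and sleep metrics.

Scoring uses the published 1-min Cole-Kripke weighted-sum rule: with activity
counts ``A_j`` at lags -4..+2 minutes around the scored minute,

    D = P * (W-4*A-4 + ... + W0*A0 + ... + W+2*A+2),   sleep iff D < 1

with the standard wrist weights (106, 54, 58, 76, 230, 74, 67) and P = 0.001.
The device at hand reports METs rather than raw counts, so a linear bridge
``counts = max(0, METs - 1) * counts_scale`` is applied first; the scale is a
calibration parameter because the device's count units are proprietary.

Nightly metrics follow the study formulas: the nightly sleep period is the
detected main bout, arousal minutes are wake epochs inside it, total sleep
time = period - arousals, and sleep efficiency = 100 * (period - arousals) /
period (algebraically TST / period).  Metrics are averaged across nights.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .epochs import EpochSeries

__all__ = [
    "COLE_KRIPKE_WEIGHTS",
    "COLE_KRIPKE_SCALE",
    "COLE_KRIPKE_THRESHOLD",
    "DEFAULT_COUNTS_SCALE",
    "SleepWakeSeries",
    "SleepBout",
    "SleepSummary",
    "mets_to_counts",
    "cole_kripke",
    "detect_main_sleep",
    "sleep_summary",
]

# 1-min rescoring weights for lags -4..+2 minutes.
COLE_KRIPKE_WEIGHTS: tuple[float, ...] = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)
COLE_KRIPKE_SCALE = 0.001
COLE_KRIPKE_THRESHOLD = 1.0
DEFAULT_COUNTS_SCALE = 18.0

WAKE, SLEEP, UNKNOWN = 0, 1, -1


@dataclasses.dataclass
class SleepWakeSeries:
    """Per-epoch sleep/wake states aligned to an EpochSeries."""

    series: EpochSeries
    states: np.ndarray  # int8: 1 sleep, 0 wake, -1 unknown
    weights: tuple[float, ...]
    scale_factor: float
    threshold: float
    counts_scale: float


@dataclasses.dataclass
class SleepBout:
    """Main nocturnal sleep period of one night (hours since first midnight)."""

    night_index: int
    onset_hour: float
    offset_hour: float  # end of the last sleep epoch
    truncated: bool  # clipped by the record boundary

    @property
    def duration_hours(self) -> float:
        return self.offset_hour - self.onset_hour


@dataclasses.dataclass
class SleepSummary:
    """Per-subject sleep metrics averaged across scored nights."""

    total_sleep_time: float  # min/night
    sleep_efficiency: float  # percent
    waking_time: float  # clock hours, decimal
    bed_time: float  # clock hours, decimal
    n_nights_averaged: int


def mets_to_counts(series: EpochSeries, scale: float = DEFAULT_COUNTS_SCALE) -> np.ndarray:
    """Bridge METs to activity counts: counts = max(0, METs - 1) * scale.

    Invalid epochs map to NaN.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = np.maximum(0.0, series.mets - 1.0) * scale
    counts[~series.valid] = np.nan
    return counts


def cole_kripke(
    series: EpochSeries,
    counts: np.ndarray | None = None,
    weights: Sequence[float] = COLE_KRIPKE_WEIGHTS,
    scale_factor: float = COLE_KRIPKE_SCALE,
    threshold: float = COLE_KRIPKE_THRESHOLD,
    counts_scale: float = DEFAULT_COUNTS_SCALE,
    resample: bool = False,
) -> SleepWakeSeries:
    """Score each 1-min epoch sleep/wake with the Cole-Kripke weighted sum.

    Missing neighbours contribute 0 to the sum; epochs that are themselves
    invalid are scored ``unknown``.  Requires 1-min epochs; pass
    ``resample=True`` to average finer epochs into minutes first.
    """
    if series.epoch_seconds != 60:
        if not resample:
            raise ValueError(
                "Cole-Kripke scoring needs 1-min epochs; pass resample=True to "
                "average finer epochs into minutes"
            )
        if 60 % series.epoch_seconds != 0:
            raise ValueError("epoch length must divide 60 s for resampling")
        k = 60 // series.epoch_seconds
        n = (series.n_epochs // k) * k
        mets = series.mets[:n].reshape(-1, k)
        valid = series.valid[:n].reshape(-1, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mets_min = np.nanmean(np.where(valid, mets, np.nan), axis=1)
        series = EpochSeries(
            series.subject_id, series.start, 60, mets_min, np.isfinite(mets_min)
        )
        counts = None
    weights = tuple(float(w) for w in weights)
    if len(weights) != 7:
        raise ValueError("weights must cover lags -4..+2 (length 7)")
    if counts is None:
        counts = mets_to_counts(series, counts_scale)
    counts = np.asarray(counts, dtype=float)
    filled = np.nan_to_num(counts, nan=0.0)
    n = filled.size
    score = np.zeros(n)
    for j, w in zip(range(-4, 3), weights):
        shifted = np.zeros(n)
        if j < 0:
            shifted[-j:] = filled[:j]
        elif j > 0:
            shifted[:-j] = filled[j:]
        else:
            shifted = filled
        score += w * shifted
    score *= scale_factor
    states = np.where(score < threshold, SLEEP, WAKE).astype(np.int8)
    states[~series.valid] = UNKNOWN
    return SleepWakeSeries(series, states, weights, scale_factor, threshold, counts_scale)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_main_sleep(
    sw: SleepWakeSeries,
    onset_window: tuple[float, float] = (18.0, 12.0),
    gap_tolerance_min: float = 40.0,
    anchor_min: float = 10.0,
) -> list[SleepBout]:
    """Locate the main nocturnal sleep period of each night.

    Nights run noon-to-noon.  Sleep runs of at least ``anchor_min`` minutes
    anchor the bout; consecutive anchors separated by no more than
    ``gap_tolerance_min`` of non-sleep are merged, so nocturnal arousals up to
    the tolerance stay inside the bout and count as wake-within-bout.  The
    longest merged bout whose onset clock time falls in ``onset_window`` wins.
    Bouts clipped by the record boundary are flagged truncated (their bed or
    waking time is unobserved).
    """
    series = sw.series
    hours = series.hours
    epoch_h = series.epoch_hours
    h_lo, h_hi = hours[0], hours[-1] + epoch_h
    sleep = sw.states == SLEEP

    win_lo, win_hi = onset_window

    def onset_ok(clock: float) -> bool:
        if win_lo <= win_hi:
            return win_lo <= clock < win_hi
        return clock >= win_lo or clock < win_hi

    bouts: list[SleepBout] = []
    first_noon = np.floor((h_lo - 12.0) / 24.0) * 24.0 + 12.0
    k = 0
    night_start = first_noon
    while night_start < h_hi - 1e-9:
        night_end = night_start + 24.0
        in_night = (hours >= night_start - 1e-9) & (hours < night_end - 1e-9)
        idx = np.nonzero(in_night)[0]
        if idx.size:
            night_sleep = sleep[idx]
            runs = [
                (s, e)
                for s, e in _runs(night_sleep)
                if (e - s) * series.epoch_minutes >= anchor_min - 1e-9
            ]
            merged: list[list[int]] = []
            for s, e in runs:
                if merged and (s - merged[-1][1]) * series.epoch_minutes <= gap_tolerance_min + 1e-9:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            candidates = [
                m for m in merged if onset_ok(hours[idx[m[0]]] % 24.0)
            ]
            best = max(candidates, key=lambda m: m[1] - m[0], default=None)
            if best is not None:
                i0, i1 = idx[best[0]], idx[best[1] - 1]
                onset = hours[i0]
                offset = hours[i1] + epoch_h
                truncated = i0 == 0 or i1 == series.n_epochs - 1
                bouts.append(SleepBout(k, float(onset), float(offset), truncated))
            else:
                warnings.warn(
                    f"night {k}: no sleep bout found in the onset window", stacklevel=2
                )
        night_start = night_end
        k += 1
    return bouts


def _mean_clock(values: list[float], fold_at: float) -> float:
    """Average clock hours on a window starting at ``fold_at`` to dodge midnight wrap."""
    shifted = [(v - fold_at) % 24.0 for v in values]
    return (float(np.mean(shifted)) + fold_at) % 24.0


def sleep_summary(
    bouts: Sequence[SleepBout],
    sw: SleepWakeSeries,
    include_truncated: bool = False,
    efficiency_denominator: str = "sleep_period",
) -> SleepSummary:
    """Average per-night sleep metrics over scored nights.

    Per night: nightly sleep period = bout duration (unknown epochs excluded),
    arousal minutes = wake epochs inside the bout, TST = period - arousals,
    efficiency = 100 * (period - arousals) / period.  ``efficiency_denominator``
    may be ``"sleep_period"`` (the study formula) or ``"time_in_bed"``
    (conventional TST / time-in-bed; identical here because time in bed is
    delimited by the same detected bout).
    """
    if efficiency_denominator not in ("sleep_period", "time_in_bed"):
        raise ValueError("efficiency_denominator must be 'sleep_period' or 'time_in_bed'")
    series = sw.series
    hours = series.hours
    epoch_min = series.epoch_minutes
    tsts, effs, onsets, offsets = [], [], [], []
    for bout in bouts:
        if bout.truncated and not include_truncated:
            continue
        inside = (hours >= bout.onset_hour - 1e-9) & (hours < bout.offset_hour - 1e-9)
        st = sw.states[inside]
        sleep_min = float(np.sum(st == SLEEP)) * epoch_min
        wake_min = float(np.sum(st == WAKE)) * epoch_min
        period_min = sleep_min + wake_min  # unknown epochs excluded from all sums
        if period_min <= 0:
            continue
        tst = period_min - wake_min
        tsts.append(tst)
        effs.append(100.0 * tst / period_min)
        onsets.append(bout.onset_hour % 24.0)
        offsets.append(bout.offset_hour % 24.0)
    if not tsts:
        raise ValueError("no valid nights to summarize")
    return SleepSummary(
        total_sleep_time=float(np.mean(tsts)),
        sleep_efficiency=float(np.mean(effs)),
        waking_time=_mean_clock(offsets, fold_at=0.0),
        bed_time=_mean_clock(onsets, fold_at=12.0),
        n_nights_averaged=len(tsts),
    )
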