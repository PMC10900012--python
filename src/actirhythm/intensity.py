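"""METs-based exercise-intensity classification (SB / LIPA / MVPA).

Cut-points follow the standard epidemiological convention: sedentary behaviour
below 1.6 METs, light-intensity physical activity from 1.6 up to (not
including) 3.0 METs, moderate-to-vigorous activity at 3.0 METs and above.
The printed bins (1.0-1.5 / 1.6-2.9 / >=3.0) leave the open intervals
(1.5, 1.6) and (2.9, 3.0) unassigned for continuous METs; half-open boundaries
at 1.6 and 3.0 keep both printed bin edges correctly classified.

Daily totals count minutes per category around the clock (SB continues after
lights-off); daytime SB additionally excludes the night window
[22:00, 07:00).  Totals are averaged over complete, sufficiently-valid days.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .epochs import DayWindow, EpochSeries, split_days

__all__ = [
    "SB_UPPER",
    "MVPA_LOWER",
    "ActivitySummary",
    "classify_epoch",
    "classify",
    "summarize_activity",
]

SB_UPPER = 1.6  # SB < 1.6 <= LIPA
MVPA_LOWER = 3.0  # LIPA < 3.0 <= MVPA

SB, LIPA, MVPA = 0, 1, 2
_CATEGORY_NAMES = {SB: "SB", LIPA: "LIPA", MVPA: "MVPA"}


@dataclasses.dataclass
class ActivitySummary:
    """Per-subject minutes per intensity class, averaged across complete days."""

    sb_min_per_day: float
    daytime_sb_min_per_day: float
    lipa_min_per_day: float
    mvpa_min_per_day: float
    n_days_averaged: int


def classify_epoch(mets: float) -> str:
    """Classify one METs value into 'SB', 'LIPA' or 'MVPA'."""
    if mets < 1.0:
        raise ValueError(f"METs {mets} below the 1.0 device floor (clamp upstream)")
    return _CATEGORY_NAMES[int(classify(np.asarray([mets]))[0])]


def classify(mets: np.ndarray) -> np.ndarray:
    """Vectorized category codes (0=SB, 1=LIPA, 2=MVPA); NaN-safe (-1)."""
    mets = np.asarray(mets, dtype=float)
    out = np.full(mets.shape, -1, dtype=np.int8)
    ok = np.isfinite(mets)
    out[ok & (mets < SB_UPPER)] = SB
    out[ok & (mets >= SB_UPPER) & (mets < MVPA_LOWER)] = LIPA
    out[ok & (mets >= MVPA_LOWER)] = MVPA
    return out


def summarize_activity(
    series: EpochSeries,
    days: Sequence[DayWindow] | None = None,
    night_window: tuple[float, float] = (22.0, 7.0),
    min_valid_fraction: float = 0.8,
) -> ActivitySummary:
    """Average SB/LIPA/MVPA minutes per day and the daytime-SB total.

    Only complete days with at least ``min_valid_fraction`` valid epochs enter
    the average; invalid epochs contribute to no category.
    """
    if days is None:
        days = split_days(series)
    epoch_min = series.epoch_minutes
    clock = series.clock_hours
    lo, hi = night_window
    in_night = (clock >= lo) | (clock < hi) if lo > hi else (clock >= lo) & (clock < hi)
    codes = classify(np.where(series.valid, series.mets, np.nan))
    per_day = []
    for day in days:
        if not day.complete:
            continue
        mask = day.epoch_mask(series)
        n_total = int(mask.sum())
        if n_total == 0:
            continue
        if series.valid[mask].mean() < min_valid_fraction:
            continue
        c = codes[mask]
        sb = float(np.sum(c == SB)) * epoch_min
        lipa = float(np.sum(c == LIPA)) * epoch_min
        mvpa = float(np.sum(c == MVPA)) * epoch_min
        day_sb = float(np.sum((c == SB) & ~in_night[mask])) * epoch_min
        per_day.append((sb, day_sb, lipa, mvpa))
    if not per_day:
        raise ValueError("no complete, sufficiently valid day to summarize")
    arr = np.asarray(per_day)
    means = arr.mean(axis=0)
    return ActivitySummary(
        sb_min_per_day=float(means[0]),
        daytime_sb_min_per_day=float(means[1]),
        lipa_min_per_day=float(means[2]),
        mvpa_min_per_day=float(means[3]),
        n_days_averaged=len(per_day),
    )
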