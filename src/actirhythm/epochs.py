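"""Epoch-level actigraphy containers, CSV I/O, validation and day segmentation.

The analysis layer works on fixed-length epochs (default 60 s) of exercise
intensity expressed in METs (metabolic equivalents; 1 MET = seated rest, the
device floor).  Time is carried internally as real-valued hours since the
subject's first midnight, so the periodic regression basis needs no folding of
multi-day records; clock time of day is simply ``t mod 24``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METS_FLOOR = 1.0

__all__ = [
    "METS_FLOOR",
    "EpochSeries",
    "SubjectRecord",
    "DayWindow",
    "ValidationReport",
    "read_epoch_series",
    "write_epoch_series",
    "read_metadata",
    "write_metadata",
    "split_days",
    "validate_series",
]


class EpochFormatError(ValueError):
    """Raised when an epoch CSV cannot be coerced onto a constant-spacing grid."""


@dataclasses.dataclass
class EpochSeries:
    """One subject's timestamped per-epoch METs record.

    Parameters
    ----------
    subject_id : str
    start : pandas.Timestamp
        Clock time of the first epoch start (1-s precision).
    epoch_seconds : int
        Constant epoch length; spacing is constant by construction.
    mets : ndarray of float
        METs per epoch; NaN where the epoch is invalid.
    valid : ndarray of bool
        Device-worn / data-present mask.
    """

    subject_id: str
    start: pd.Timestamp
    epoch_seconds: int
    mets: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.mets = np.asarray(self.mets, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.mets.shape != self.valid.shape or self.mets.ndim != 1:
            raise ValueError("mets and valid must be 1-D arrays of equal length")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")

    def __len__(self) -> int:
        return self.mets.size

    @property
    def n_epochs(self) -> int:
        return self.mets.size

    @property
    def epoch_hours(self) -> float:
        return self.epoch_seconds / 3600.0

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    @property
    def first_midnight(self) -> pd.Timestamp:
        return self.start.normalize()

    @property
    def hours(self) -> np.ndarray:
        """Epoch start times in hours since the subject's first midnight."""
        offset = (self.start - self.first_midnight).total_seconds() / 3600.0
        return offset + np.arange(self.n_epochs) * self.epoch_hours

    @property
    def clock_hours(self) -> np.ndarray:
        return self.hours % 24.0

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_seconds, unit="s"
        )

    @property
    def span_hours(self) -> float:
        return self.n_epochs * self.epoch_hours

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.n_epochs else 0.0


@dataclasses.dataclass
class SubjectRecord:
    """Baseline covariates for one subject (ward medical-record fields)."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float
    diagnosis: str  # "cerebrovascular" | "orthopedic"
    mmse: int  # 0-30
    motor_fim: int  # 13-91
    hypnotics: bool
    psychotropics: bool
    locomotive_independent: bool

    def check(self) -> list[str]:
        """Inclusion-rule warnings (MMSE >= 24, age >= 65); never rejects."""
        issues = []
        if self.mmse < 24:
            issues.append(f"{self.subject_id}: MMSE {self.mmse} below inclusion cut-off 24")
        if self.age < 65:
            issues.append(f"{self.subject_id}: age {self.age} below inclusion cut-off 65")
        return issues


@dataclasses.dataclass
class DayWindow:
    """One calendar-day window at the configured boundary (default midnight).

    ``start_hour``/``end_hour`` are hours since the subject's first midnight.
    """

    day_index: int
    start_hour: float
    end_hour: float
    complete: bool

    def epoch_mask(self, series: EpochSeries) -> np.ndarray:
        h = series.hours
        return (h >= self.start_hour - 1e-9) & (h < self.end_hour - 1e-9)


@dataclasses.dataclass
class ValidationReport:
    subject_id: str
    issues: list[str]
    valid_fraction: float
    span_days: float
    passed: bool


def _series_from_frame(
    subject_id: str, sub: pd.DataFrame, epoch_seconds: int, clamp_floor: bool
) -> EpochSeries:
    ts = sub["timestamp"].to_numpy()
    offsets = (ts - ts[0]) / np.timedelta64(1, "s")
    if np.any(np.diff(offsets) <= 0):
        raise EpochFormatError(f"subject {subject_id}: timestamps not strictly increasing")
    steps = offsets / epoch_seconds
    if not np.allclose(steps, np.round(steps), atol=1e-6):
        raise EpochFormatError(
            f"subject {subject_id}: timestamps are not aligned to a {epoch_seconds}-s grid"
        )
    idx = np.round(steps).astype(int)
    n = idx[-1] + 1
    mets = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    mets[idx] = sub["mets"].to_numpy(dtype=float)
    valid[idx] = sub["valid"].to_numpy(dtype=float) > 0
    valid &= np.isfinite(mets)
    mets[~valid] = np.nan
    low = valid & (mets < METS_FLOOR)
    if clamp_floor and low.any():
        warnings.warn(
            f"subject {subject_id}: {int(low.sum())} METs value(s) below the 1.0 floor "
            "clamped to 1.0",
            stacklevel=3,
        )
        mets[low] = METS_FLOOR
    return EpochSeries(subject_id, pd.Timestamp(ts[0]), epoch_seconds, mets, valid)


def read_epoch_series(
    path: str | Path, epoch_seconds: int = 60, clamp_floor: bool = True
) -> list[EpochSeries]:
    """Read an epoch CSV (subject_id, timestamp, mets[, valid]) into EpochSeries.

    Gaps that are whole multiples of the epoch length are filled with invalid
    epochs so spacing stays constant; off-grid timestamps raise
    :class:`EpochFormatError`.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "timestamp", "mets"}
    missing = required - set(df.columns)
    if missing:
        raise EpochFormatError(f"epoch CSV missing columns: {sorted(missing)}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise EpochFormatError(
            f"malformed timestamp {df['timestamp'].iloc[row]!r} at row {row + 2}"
        )
    df = df.assign(timestamp=parsed)
    if "valid" not in df.columns:
        df["valid"] = 1
    df["valid"] = df["valid"].fillna(1)
    out = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("timestamp")
        if sub["timestamp"].duplicated().any():
            raise EpochFormatError(f"subject {sid}: duplicate timestamps")
        out.append(_series_from_frame(str(sid), sub, epoch_seconds, clamp_floor))
    return out


def write_epoch_series(series_list: Iterable[EpochSeries], path: str | Path) -> None:
    """Write EpochSeries to the epoch CSV format (inverse of read_epoch_series)."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
                    "mets": s.mets,
                    "valid": s.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


_META_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "bmi",
    "diagnosis",
    "mmse",
    "motor_fim",
    "hypnotics",
    "psychotropics",
    "locomotive_independent",
]


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise EpochFormatError(f"metadata CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]).lower(),
                bmi=float(row["bmi"]),
                diagnosis=str(row["diagnosis"]).lower(),
                mmse=int(row["mmse"]),
                motor_fim=int(row["motor_fim"]),
                hypnotics=bool(int(row["hypnotics"])),
                psychotropics=bool(int(row["psychotropics"])),
                locomotive_independent=bool(int(row["locomotive_independent"])),
            )
        )
    return records


def write_metadata(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for key in ("hypnotics", "psychotropics", "locomotive_independent"):
            d[key] = int(d[key])
        rows.append(d)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def split_days(series: EpochSeries, day_boundary_hour: float = 0.0) -> list[DayWindow]:
    """Segment a series into contiguous day windows at the configured boundary.

    Windows partition the record; partial first/last days are flagged
    ``complete=False``.
    """
    h0 = series.hours[0]
    h1 = series.hours[-1] + series.epoch_hours  # end of last epoch
    if h1 - h0 < 0:
        raise ValueError("empty series")
    b = day_boundary_hour % 24.0
    first = np.floor((h0 - b) / 24.0) * 24.0 + b
    windows = []
    k = 0
    start = first
    while start < h1 - 1e-9:
        end = start + 24.0
        complete = start >= h0 - 1e-9 and end <= h1 + 1e-9
        windows.append(
            DayWindow(
                day_index=k,
                start_hour=max(start, h0),
                end_hour=min(end, h1),
                complete=complete,
            )
        )
        start = end
        k += 1
    return windows


def validate_series(
    series: EpochSeries, min_valid_fraction: float = 0.8
) -> ValidationReport:
    """Report-only quality checks: METs floor, coverage, record span."""
    issues = []
    valid_mets = series.mets[series.valid]
    n_low = int(np.sum(valid_mets < METS_FLOOR - 1e-12))
    if n_low:
        issues.append(f"{n_low} valid epoch(s) below the 1.0 METs floor")
    frac = series.valid_fraction
    if frac < min_valid_fraction:
        issues.append(
            f"valid fraction {frac:.3f} below required minimum {min_valid_fraction:.2f}"
        )
    span_days = series.span_hours / 24.0
    if span_days < 1.0 - 1e-9:
        issues.append(f"record spans {span_days:.2f} days; at least 1 whole day required")
    if span_days > 7.0 + 1e-9:
        issues.append(f"record spans {span_days:.2f} days; more than 7 days unsupported")
    passed = frac >= min_valid_fraction and 1.0 - 1e-9 <= span_days <= 7.0 + 1e-9 and n_low == 0
    return ValidationReport(series.subject_id, issues, frac, span_days, passed)
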