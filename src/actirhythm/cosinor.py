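"""Multi-component cosinor (periodic) regression and CAR parameter extraction.

The model is the classical multi-component cosinor

    y(t) = M + sum_k A_k * cos(omega_k * t - theta_k) + e(t)

with angular frequencies ``omega_k = 2*pi / T_k`` fixed by the chosen periods
(24 h and 12 h for the two-component rest--activity model).  Because the model
is linear in ``a_k = A_k cos(theta_k)``, ``b_k = A_k sin(theta_k)``, the fit is
a closed-form least-squares solve on the cos/sin design; no iterative
optimizer is involved.  Amplitude and acrophase are recovered per component as
``A_k = hypot(a_k, b_k)`` and ``theta_k = atan2(b_k, a_k) mod 2*pi``.

The circadian activity rhythm (CAR) is summarized by six parameters of the
fitted composite curve: mesor, maximum, minimum, range (= maximum - minimum),
and the clock times of the daily maximum and minimum.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np

from .epochs import EpochSeries

__all__ = [
    "CosinorModel",
    "CosinorResults",
    "CosinorComponent",
    "CARParameters",
    "PeriodScanResult",
    "DegenerateSeriesError",
    "fit_harmonics",
    "evaluate_curve",
    "extract_car",
    "scan_periods",
]

TWO_PI = 2.0 * math.pi


class DegenerateSeriesError(ValueError):
    """Constant series: total sum of squares is zero, R^2 undefined."""


class CosinorFitError(ValueError):
    """Rank-deficient design (too few distinct sampling times)."""


@dataclasses.dataclass(frozen=True)
class CosinorComponent:
    """One fitted periodic component."""

    period: float  # hours
    amplitude: float  # METs, >= 0
    acrophase: float  # radians in [0, 2*pi)

    @property
    def omega(self) -> float:
        return TWO_PI / self.period

    @property
    def peak_time(self) -> float:
        """Earliest clock time (hours) at which this component peaks."""
        return (self.acrophase / self.omega) % self.period


@dataclasses.dataclass(frozen=True)
class CARParameters:
    """Six-parameter circadian activity rhythm summary of a fitted curve."""

    mesor: float
    maximum: float
    minimum: float
    range: float
    max_phase_time: float  # clock hours in [0, 24)
    min_phase_time: float  # clock hours in [0, 24)
    r_squared: float


class CosinorModel:
    """Multi-component cosinor regression model.

    Parameters
    ----------
    t : array-like
        Sampling times in hours (any origin; the basis is periodic).
    y : array-like
        Observed METs per epoch.
    periods : sequence of float
        Component periods in hours, distinct and positive
        (default ``(24.0, 12.0)``, the composite rest--activity model).
    """

    def __init__(self, t, y, periods: Sequence[float] = (24.0, 12.0)):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        keep = np.isfinite(t) & np.isfinite(y)
        self.t = t[keep]
        self.y = y[keep]
        periods = tuple(float(p) for p in periods)
        if len(set(periods)) != len(periods) or any(p <= 0 for p in periods):
            raise ValueError("periods must be distinct and positive")
        self.periods = periods
        if self.t.size < 2 * len(periods) + 1:
            raise CosinorFitError(
                f"need at least {2 * len(periods) + 1} valid epochs, got {self.t.size}"
            )

    @classmethod
    def from_series(
        cls,
        series: EpochSeries,
        periods: Sequence[float] = (24.0, 12.0),
        averaged_day: bool = False,
    ) -> "CosinorModel":
        """Build a model from an EpochSeries (valid epochs only).

        With ``averaged_day=True`` the record is first folded into a mean
        24-h profile by clock epoch; the default fits the full multi-day
        record, which the periodic basis accommodates directly.
        """
        t = series.hours[series.valid]
        y = series.mets[series.valid]
        if averaged_day:
            clock = t % 24.0
            step = series.epoch_hours
            bins = np.round(clock / step).astype(int) % int(round(24.0 / step))
            order = np.argsort(bins)
            bins = bins[order]
            sums = np.bincount(bins, weights=y[order])
            counts = np.bincount(bins)
            present = counts > 0
            t = np.nonzero(present)[0] * step
            y = sums[present] / counts[present]
        return cls(t, y, periods)

    def design_matrix(self, t: np.ndarray | None = None) -> np.ndarray:
        t = self.t if t is None else np.asarray(t, dtype=float)
        cols = [np.ones_like(t)]
        for p in self.periods:
            w = TWO_PI / p
            cols.append(np.cos(w * t))
            cols.append(np.sin(w * t))
        return np.column_stack(cols)

    def fit(self) -> "CosinorResults":
        X = self.design_matrix()
        if np.ptp(self.y) == 0.0:
            raise DegenerateSeriesError(
                "constant series: total sum of squares is zero, R^2 undefined"
            )
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        beta, _, rank, _ = np.linalg.lstsq(X, self.y, rcond=None)
        if rank < X.shape[1]:
            raise CosinorFitError(
                "rank-deficient cosinor design (too few distinct sampling times "
                "for the requested periods)"
            )
        resid = self.y - X @ beta
        ssr = float(resid @ resid)
        components = []
        for k, p in enumerate(self.periods):
            a, b = beta[1 + 2 * k], beta[2 + 2 * k]
            amp = math.hypot(a, b)
            theta = math.atan2(b, a) % TWO_PI
            components.append(CosinorComponent(period=p, amplitude=amp, acrophase=theta))
        return CosinorResults(
            model=self,
            mesor=float(beta[0]),
            components=tuple(components),
            r_squared=1.0 - ssr / sst,
            n_epochs_used=int(self.t.size),
            _beta=beta,
        )


@dataclasses.dataclass
class CosinorResults:
    """Fitted multi-component cosinor: estimates, fit quality and derived CAR."""

    model: CosinorModel
    mesor: float
    components: tuple[CosinorComponent, ...]
    r_squared: float
    n_epochs_used: int
    _beta: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def amplitude_sum(self) -> float:
        return sum(c.amplitude for c in self.components)

    def predict(self, t) -> np.ndarray | float:
        """Evaluate the fitted composite curve at hours ``t`` (vectorized)."""
        t_arr = np.asarray(t, dtype=float)
        out = np.full_like(t_arr, self.mesor, dtype=float)
        for c in self.components:
            out = out + c.amplitude * np.cos(c.omega * t_arr - c.acrophase)
        return out if t_arr.ndim else float(out)

    # -- CAR extraction -----------------------------------------------------

    def _refine(self, t_coarse: float, half_width_s: int, sign: float) -> tuple[float, float]:
        # 1-s grid around a coarse candidate, aligned to absolute whole seconds
        lo = int(round(t_coarse * 3600.0)) - half_width_s
        grid = (np.arange(lo, lo + 2 * half_width_s + 1) / 3600.0) % 24.0
        vals = sign * np.asarray(self.predict(grid))
        j = int(np.argmax(vals))
        return float(grid[j]), float(sign * vals[j])

    def car_parameters(self, grid_seconds: int = 60) -> CARParameters:
        """Extract the six CAR parameters from the fitted composite curve.

        Single-component curves use the closed form (exact); composites are
        located on a coarse clock-day grid, every local extremum refined to
        1-s resolution, ties broken by earliest clock time.
        """
        # amplitudes at numerical-noise level are treated as absent so the
        # closed form applies to effectively single-component fits
        active = [c for c in self.components if c.amplitude > 1e-12]
        if not active:
            return CARParameters(self.mesor, self.mesor, self.mesor, 0.0, 0.0, 0.0, self.r_squared)
        if len(active) == 1:
            c = active[0]
            tmax = c.peak_time
            tmin = (tmax + c.period / 2.0) % c.period
            return CARParameters(
                mesor=self.mesor,
                maximum=self.mesor + c.amplitude,
                minimum=self.mesor - c.amplitude,
                range=2.0 * c.amplitude,
                max_phase_time=tmax,
                min_phase_time=tmin,
                r_squared=self.r_squared,
            )
        n = int(round(24.0 * 3600.0 / grid_seconds))
        coarse = np.arange(n) * (grid_seconds / 3600.0)
        vals = np.asarray(self.predict(coarse))
        extrema = {}
        for sign in (1.0, -1.0):
            v = sign * vals
            is_loc = (v >= np.roll(v, 1)) & (v >= np.roll(v, -1))
            best_val, best_t = -np.inf, None
            for i in np.nonzero(is_loc)[0]:
                t_ref, v_ref = self._refine(float(coarse[i]), grid_seconds, sign)
                v_cmp = sign * v_ref
                if v_cmp > best_val + 1e-15 or (
                    abs(v_cmp - best_val) <= 1e-15 and t_ref < best_t
                ):
                    best_val, best_t = v_cmp, t_ref
            extrema[sign] = (best_t, sign * best_val)
        tmax, vmax = extrema[1.0]
        tmin, vmin = extrema[-1.0]
        return CARParameters(
            mesor=self.mesor,
            maximum=vmax,
            minimum=vmin,
            range=vmax - vmin,
            max_phase_time=tmax,
            min_phase_time=tmin,
            r_squared=self.r_squared,
        )

    def summary(self) -> str:
        lines = [
            "Multi-component cosinor regression",
            "=" * 46,
            f"{'n epochs used':<24}{self.n_epochs_used:>12d}",
            f"{'mesor (METs)':<24}{self.mesor:>12.4f}",
            f"{'R-squared':<24}{self.r_squared:>12.4f}",
            "-" * 46,
            f"{'period (h)':>10}{'amplitude':>12}{'acrophase':>12}{'peak (h)':>10}",
        ]
        for c in self.components:
            lines.append(
                f"{c.period:>10.2f}{c.amplitude:>12.4f}{c.acrophase:>12.4f}{c.peak_time:>10.2f}"
            )
        car = self.car_parameters()
        lines += [
            "-" * 46,
            f"{'maximum (METs)':<24}{car.maximum:>12.4f}",
            f"{'minimum (METs)':<24}{car.minimum:>12.4f}",
            f"{'range (METs)':<24}{car.range:>12.4f}",
            f"{'max phase time (h)':<24}{car.max_phase_time:>12.3f}",
            f"{'min phase time (h)':<24}{car.min_phase_time:>12.3f}",
        ]
        return "\n".join(lines)


@dataclasses.dataclass
class PeriodScanResult:
    """Ranked single-component period scan (descending R^2)."""

    periods: np.ndarray
    r_squared: np.ndarray
    skipped: list[float]

    def top(self, k: int = 2) -> list[tuple[float, float]]:
        return [(float(self.periods[i]), float(self.r_squared[i])) for i in range(k)]


def fit_harmonics(
    series: EpochSeries,
    periods: Sequence[float] = (24.0, 12.0),
    averaged_day: bool = False,
) -> CosinorResults:
    """Least-squares multi-component cosinor fit of an epoch series."""
    return CosinorModel.from_series(series, periods, averaged_day=averaged_day).fit()


def evaluate_curve(fit: CosinorResults, t) -> np.ndarray | float:
    """Evaluate a fitted composite curve at hours ``t``."""
    return fit.predict(t)


def extract_car(fit: CosinorResults, grid_seconds: int = 60) -> CARParameters:
    """Six CAR parameters (mesor, max, min, range, phase times) from a fit."""
    return fit.car_parameters(grid_seconds=grid_seconds)


def scan_periods(series: EpochSeries, n_components: int = 720) -> PeriodScanResult:
    """Rank the candidate periods T = 24/n h, n = 1..n_components, by R^2.

    Each candidate is fitted as a single-component cosinor; periods that would
    need sub-epoch resolution (shorter than two epochs) are skipped with a
    warning.  The two top-ranked periods on ward actigraphy are expected to be
    the 24-h and 12-h cycles, motivating the composite model.
    """
    t = series.hours[series.valid]
    y = series.mets[series.valid]
    if np.ptp(y) == 0.0:
        raise DegenerateSeriesError("constant series: period scan undefined")
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    min_period = 2.0 * series.epoch_hours
    periods, rsqs, skipped = [], [], []
    for n in range(1, n_components + 1):
        p = 24.0 / n
        if p < min_period:
            skipped.append(p)
            continue
        w = TWO_PI / p
        X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            skipped.append(p)
            continue
        resid = y - X @ beta
        rsqs.append(1.0 - float(resid @ resid) / sst)
        periods.append(p)
    if skipped:
        warnings.warn(
            f"{len(skipped)} candidate period(s) shorter than two epochs skipped",
            stacklevel=2,
        )
    periods = np.asarray(periods)
    rsqs = np.asarray(rsqs)
    order = np.argsort(-rsqs, kind="stable")
    return PeriodScanResult(periods[order], rsqs[order], skipped)
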