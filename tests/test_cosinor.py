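import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actirhythm.cosinor import (
    CosinorModel,
    DegenerateSeriesError,
    evaluate_curve,
    extract_car,
    fit_harmonics,
    scan_periods,
)
from actirhythm.simulate import simulate_harmonic_series

from conftest import cosinor_series, make_series

PI = math.pi


def normal_equations_fit(t, y, periods):
    """Independent oracle: explicit normal equations (X'X)^-1 X'y."""
    cols = [np.ones_like(t)]
    for p in periods:
        w = 2 * PI / p
        cols += [np.cos(w * t), np.sin(w * t)]
    X = np.column_stack(cols)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    out = {"mesor": beta[0]}
    for k, p in enumerate(periods):
        a, b = beta[1 + 2 * k], beta[2 + 2 * k]
        out[p] = (math.hypot(a, b), math.atan2(b, a) % (2 * PI))
    return out


def test_noise_free_exact_recovery():
    series = cosinor_series(1.2, [(24.0, 0.2, PI)], n_days=1)
    fit = fit_harmonics(series, periods=(24.0, 12.0))
    assert fit.mesor == pytest.approx(1.2, abs=1e-9)
    assert fit.components[0].amplitude == pytest.approx(0.2, abs=1e-9)
    assert fit.components[0].acrophase == pytest.approx(PI, abs=1e-9)
    assert fit.components[1].amplitude == pytest.approx(0.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_constant_series_degenerate():
    with pytest.raises(DegenerateSeriesError):
        fit_harmonics(make_series(np.full(1440, 1.3)))


def test_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    series = simulate_harmonic_series(
        1.25, [(24.0, 0.18, 2.1), (12.0, 0.07, 0.8)], sigma=0.1, n_days=5, rng=rng
    )
    fit = fit_harmonics(series)
    oracle = normal_equations_fit(series.hours, series.mets, (24.0, 12.0))
    assert fit.mesor == pytest.approx(oracle["mesor"], abs=1e-8)
    for comp in fit.components:
        amp, theta = oracle[comp.period]
        assert comp.amplitude == pytest.approx(amp, abs=1e-8)
        assert comp.acrophase == pytest.approx(theta, abs=1e-8)


def test_evaluate_curve_values():
    series = cosinor_series(1.2, [(24.0, 0.15, PI), (12.0, 0.05, 0.0)])
    fit = fit_harmonics(series)
    assert evaluate_curve(fit, 12.0) == pytest.approx(1.4, abs=1e-9)
    # direct evaluation oracle at t=3
    expected = 1.2 + 0.15 * math.cos(2 * PI / 24 * 3 - PI) + 0.05 * math.cos(2 * PI / 12 * 3)
    assert expected == pytest.approx(1.0939, abs=1e-4)
    assert evaluate_curve(fit, 3.0) == pytest.approx(expected, abs=1e-9)
    assert evaluate_curve(fit, np.array([0.0, 6.0])).shape == (2,)


def test_extract_car_single_component_closed_form():
    theta = 1.3
    series = cosinor_series(1.2, [(24.0, 0.2, theta)])
    fit = fit_harmonics(series, periods=(24.0, 12.0))
    car = extract_car(fit)
    w = 2 * PI / 24
    assert car.maximum == pytest.approx(1.4, abs=1e-9)
    assert car.minimum == pytest.approx(1.0, abs=1e-9)
    assert car.range == pytest.approx(0.4, abs=1e-9)
    assert car.max_phase_time == pytest.approx((theta / w) % 24, abs=1e-9)
    assert car.min_phase_time == pytest.approx((theta / w + 12) % 24, abs=1e-9)


def test_extract_car_composite_aligned_peaks():
    series = cosinor_series(1.2, [(24.0, 0.15, PI), (12.0, 0.05, 0.0)])
    fit = fit_harmonics(series)
    car = extract_car(fit)
    assert car.maximum == pytest.approx(1.4, abs=1e-7)
    assert car.max_phase_time == pytest.approx(12.0, abs=1e-3)
    # brute-force 1-s oracle for the minimum
    grid = np.arange(0, 24 * 3600) / 3600.0
    vals = np.asarray(fit.predict(grid))
    assert car.minimum == pytest.approx(vals.min(), abs=1e-9)
    assert car.min_phase_time == pytest.approx(grid[int(np.argmin(vals))], abs=1e-9)
    assert car.minimum == pytest.approx(1.094, abs=1e-3)


def test_extract_car_invariants_random_fits():
    rng = np.random.default_rng(7)
    for _ in range(25):
        m = rng.uniform(1.0, 1.6)
        comps = [(24.0, rng.uniform(0.01, 0.4), rng.uniform(0, 2 * PI)),
                 (12.0, rng.uniform(0.0, 0.2), rng.uniform(0, 2 * PI))]
        fit = fit_harmonics(cosinor_series(m, comps))
        car = extract_car(fit)
        total = fit.amplitude_sum
        assert car.range == pytest.approx(car.maximum - car.minimum, abs=0)
        assert car.minimum >= fit.mesor - total - 1e-9
        assert car.maximum <= fit.mesor + total + 1e-9
        assert car.minimum - 1e-9 <= car.mesor <= car.maximum + 1e-9
        if car.range > 0:
            assert car.max_phase_time != car.min_phase_time


def test_orthogonality_mesor_equals_mean():
    rng = np.random.default_rng(3)
    y = 1.3 + 0.2 * np.cos(2 * PI / 24 * np.arange(2 * 1440) / 60) + 0.05 * rng.standard_normal(2 * 1440)
    series = make_series(y)
    fit = fit_harmonics(series)
    assert fit.mesor == pytest.approx(y.mean(), abs=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(shift=st.floats(-0.5, 0.5), k=st.integers(-2, 2))
def test_rsquared_invariant_to_offset_and_period_shifts(shift, k):
    rng = np.random.default_rng(11)
    n = 2 * 1440
    t = np.arange(n) / 60.0
    y = 1.3 + 0.2 * np.cos(2 * PI / 24 * t - 1.0) + 0.05 * rng.standard_normal(n)
    base = CosinorModel(t, y).fit().r_squared
    shifted = CosinorModel(t, y + shift).fit().r_squared
    moved = CosinorModel(t + 24.0 * k, y).fit().r_squared
    assert shifted == pytest.approx(base, abs=1e-9)
    assert moved == pytest.approx(base, abs=1e-9)


def test_scan_pure_signals_rank_true_period():
    pure24 = cosinor_series(1.2, [(24.0, 0.2, 1.0)], n_days=5, noise=0.02,
                            rng=np.random.default_rng(0))
    assert scan_periods(pure24).top(1)[0][0] == pytest.approx(24.0)
    pure8 = cosinor_series(1.2, [(8.0, 0.2, 1.0)], n_days=5, noise=0.02,
                           rng=np.random.default_rng(1))
    assert scan_periods(pure8).top(1)[0][0] == pytest.approx(8.0)


def test_scan_skips_subepoch_periods():
    series = cosinor_series(1.2, [(24.0, 0.2, 1.0)], epoch_seconds=300)
    with pytest.warns(UserWarning, match="skipped"):
        res = scan_periods(series, n_components=300)
    assert min(res.periods) >= 2 * 300 / 3600.0
    assert len(res.skipped) > 0


def test_averaged_day_mode_agrees_on_stationary_signal():
    rng = np.random.default_rng(5)
    series = simulate_harmonic_series(1.3, [(24.0, 0.2, 1.5), (12.0, 0.06, 0.4)],
                                      sigma=0.05, n_days=5, rng=rng)
    full = fit_harmonics(series, averaged_day=False)
    folded = fit_harmonics(series, averaged_day=True)
    assert folded.mesor == pytest.approx(full.mesor, abs=1e-6)
    assert folded.components[0].amplitude == pytest.approx(
        full.components[0].amplitude, abs=1e-6
    )


def test_summary_mentions_key_quantities():
    fit = fit_harmonics(cosinor_series(1.2, [(24.0, 0.15, PI), (12.0, 0.05, 0.0)]))
    text = fit.summary()
    for token in ("mesor", "R-squared", "24.00", "12.00", "range"):
        assert token in text
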