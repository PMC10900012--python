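import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson
import statsmodels.api as sm

from actirhythm.cosinor import fit_harmonics
from actirhythm.simulate import GeneratorConfig, generate_cohort
from actirhythm.stats import (
    GroupingError,
    UndefinedCorrelationError,
    cohort_report,
    compare_groups,
    correlate,
    durbin_watson,
    multiple_regression,
    simple_regression,
    variance_inflation,
)


def test_identical_groups_mann_whitney_p_one():
    vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    groups = np.array(["a"] * 3 + ["b"] * 3)
    res = compare_groups(vals, groups, method="mann_whitney")
    assert res.pvalue == pytest.approx(1.0)


def test_mann_whitney_extreme_exact_enumeration():
    """{0,0,0} vs {10,10,10}: U = 0 and the minimal two-sided exact p.

    Oracle: enumerate all C(6,3)=20 rank assignments; only the two extreme
    orderings give |U - 4.5| >= 4.5, hence p = 2/20 = 0.1.
    """
    pooled = [0.0, 0.0, 0.0, 10.0, 10.0, 10.0]
    us = []
    for combo in itertools.combinations(range(6), 3):
        x = [pooled[i] for i in combo]
        y = [pooled[i] for i in range(6) if i not in combo]
        u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        us.append(u)
    observed = 0.0
    p_exact = np.mean([abs(u - 4.5) >= abs(observed - 4.5) for u in us])
    res = compare_groups(
        np.array(pooled), np.array(["a"] * 3 + ["b"] * 3), method="mann_whitney"
    )
    assert res.statistic in (0.0, 9.0)
    assert res.pvalue == pytest.approx(p_exact) == pytest.approx(0.1)


def test_welch_on_shifted_groups():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    y = rng.normal(2, 3, 25)
    res = compare_groups(
        np.concatenate([x, y]), np.array(["a"] * 30 + ["b"] * 25), method="welch"
    )
    assert res.pvalue < 0.05


def test_compare_groups_errors():
    with pytest.raises(GroupingError):
        compare_groups([1, 2, 3], ["a", "a", "a"])


def test_correlate_perfect_linear_and_monotone():
    x = np.arange(10.0)
    assert correlate(x, 2 * x + 1, method="pearson").r == pytest.approx(1.0)
    assert correlate(x, np.exp(x), method="spearman").r == pytest.approx(1.0)
    with pytest.raises(UndefinedCorrelationError):
        correlate(x, np.ones_like(x))


def test_correlate_symmetry_and_sign_flip():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=20), rng.normal(size=20)
    for method in ("pearson", "spearman"):
        assert correlate(x, y, method).r == pytest.approx(correlate(y, x, method).r)
        assert correlate(-x, y, method).r == pytest.approx(-correlate(x, y, method).r)


def test_correlate_auto_picks_by_normality():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    y = x + 0.5 * rng.normal(size=50)
    assert correlate(x, y, method="auto").method == "pearson"
    skewed = np.exp(3 * x)
    assert correlate(x, skewed, method="auto").method == "spearman"


def test_durbin_watson_toy_cases():
    assert durbin_watson([1.0, 1.0, 1.0]) == pytest.approx(0.0)
    assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)


def test_durbin_watson_iid_near_two():
    e = np.random.default_rng(0).standard_normal(1000)
    d = durbin_watson(e)
    assert 1.8 <= d <= 2.2
    assert d == pytest.approx(sm_durbin_watson(e), abs=1e-12)


def test_simple_regression_exact_line_and_standardized_slope():
    x = np.arange(20.0)
    res = simple_regression(3 * x + 1, x)
    assert res.rsquared == pytest.approx(1.0)
    assert res.pvalues.iloc[1] < 1e-12
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    y = 0.6 * x + rng.normal(size=40)
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    slope = simple_regression(zy, zx).params.iloc[1]
    assert slope == pytest.approx(correlate(x, y, "pearson").r, abs=1e-9)


def test_simple_regression_constant_x_raises():
    with pytest.raises(np.linalg.LinAlgError):
        simple_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_multiple_regression_vif_oracle():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(
        {"a": rng.normal(size=60), "b": rng.normal(size=60)}
    )
    X["c"] = 0.7 * X["a"] + 0.5 * rng.normal(size=60)
    y = X["a"] + X["b"] + rng.normal(size=60)
    res = multiple_regression(y.to_numpy(), X)
    # independent oracle: statsmodels variance_inflation_factor
    exog = sm.add_constant(X).to_numpy()
    for j, col in enumerate(X.columns):
        assert res.vif[col] == pytest.approx(
            variance_inflation_factor(exog, j + 1), rel=1e-8
        )
    # orthogonal predictors -> VIF ~ 1
    Q = pd.DataFrame(np.linalg.qr(rng.normal(size=(50, 2)))[0], columns=["u", "v"])
    res_o = multiple_regression(rng.normal(size=50), Q)
    assert res_o.vif.max() < 1.05


def test_duplicated_predictor_dropped():
    rng = np.random.default_rng(5)
    a = rng.normal(size=30)
    X = pd.DataFrame({"a": a, "b": a})
    res = multiple_regression(rng.normal(size=30), X)
    assert res.dropped == ["b"]


def test_cohort_report_schema_and_grid(default_cohort_table):
    report = cohort_report(default_cohort_table)
    comp, corr = report["comparisons"], report["correlations"]
    assert set(comp["factor"]) == {
        "sex", "diagnosis", "locomotive_independent", "hypnotics", "psychotropics"
    }
    assert comp.shape[0] == 5 * 10
    assert corr.shape[0] == 11 * 10 - 4  # self-pairs excluded
    missing = default_cohort_table.drop(columns=["mesor"])
    with pytest.raises(KeyError, match="mesor"):
        cohort_report(missing)


def test_activity_correlation_sign_pattern(default_cohort_table):
    """SB negatively, LIPA positively associated with mesor/maximum/range."""
    for outcome in ("mesor", "maximum", "range"):
        sb = correlate(default_cohort_table["sb_min"], default_cohort_table[outcome], "spearman")
        lipa = correlate(default_cohort_table["lipa_min"], default_cohort_table[outcome], "spearman")
        assert sb.r < -0.8 and sb.pvalue < 0.001
        assert lipa.r > 0.8 and lipa.pvalue < 0.001


def test_hypnotics_phase_delay_power():
    """Welch detects the hypnotics peak-time delay in >= 80% of 200 cohorts."""
    detected = 0
    n_seeds = 200
    for seed in range(n_seeds):
        cohort = generate_cohort(GeneratorConfig(seed=10_000 + seed))
        phases, hyp = [], []
        for series, record in zip(cohort.series, cohort.records):
            car = fit_harmonics(series).car_parameters()
            phases.append(car.max_phase_time)
            hyp.append(record.hypnotics)
        hyp = np.array(hyp)
        if hyp.sum() < 2 or (~hyp).sum() < 2:
            continue
        res = compare_groups(np.array(phases), hyp, method="welch")
        detected += res.pvalue < 0.05
    assert detected / n_seeds >= 0.80
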