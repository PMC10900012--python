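"""Cohort-level statistics: group comparisons, correlations, regressions.

Mirrors a conventional cross-sectional analysis plan: Welch's unequal-variance
t test or the Mann-Whitney U test for two-group comparisons, Pearson or
Spearman correlation (with an automatic normality-based choice), and ordinary
least squares with Durbin-Watson and variance-inflation diagnostics.  Alpha is
0.05 two-sided throughout and no multiplicity adjustment is applied; every
report header records that choice.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupComparison",
    "Correlation",
    "RegressionResult",
    "compare_groups",
    "correlate",
    "simple_regression",
    "multiple_regression",
    "durbin_watson",
    "variance_inflation",
    "cohort_report",
    "standard_regressions",
    "CAR_OUTCOMES",
    "COMPARISON_FACTORS",
    "CORRELATION_FACTORS",
]

ALPHA = 0.05
NO_ADJUSTMENT_NOTE = (
    "alpha = 0.05 two-sided; no multiple-testing correction applied"
)


class GroupingError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclasses.dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


@dataclasses.dataclass
class Correlation:
    r: float
    pvalue: float
    method: str
    n: int


@dataclasses.dataclass
class RegressionResult:
    """OLS estimates with the diagnostics the analysis plan reports."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    rsquared: float
    durbin_watson: float
    vif: pd.Series | None
    nobs: int
    dropped: list[str] = dataclasses.field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "OLS regression",
            "=" * 56,
            f"n = {self.nobs}   R^2 = {self.rsquared:.4f}   "
            f"F = {self.fvalue:.3f} (p = {self.f_pvalue:.4g})",
            f"Durbin-Watson = {self.durbin_watson:.3f}",
            NO_ADJUSTMENT_NOTE,
            "-" * 56,
            f"{'term':<20}{'coef':>12}{'se':>10}{'p':>10}" + ("{:>8}".format("VIF") if self.vif is not None else ""),
        ]
        for name in self.params.index:
            row = f"{name:<20}{self.params[name]:>12.5f}{self.bse[name]:>10.4f}{self.pvalues[name]:>10.4g}"
            if self.vif is not None and name in self.vif.index:
                row += f"{self.vif[name]:>8.3f}"
            lines.append(row)
        if self.dropped:
            lines.append(f"dropped collinear columns: {', '.join(self.dropped)}")
        return "\n".join(lines)


def compare_groups(
    values: Sequence[float], groups: Sequence, method: str = "welch"
) -> GroupComparison:
    """Two-group comparison by Welch's t or the Mann-Whitney U test.

    Mann-Whitney uses the exact null distribution for combined n <= 20 without
    ties, the tie-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise GroupingError(f"need exactly 2 groups, got {len(levels)}")
    x = values[groups == levels[0]]
    y = values[groups == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise GroupingError("need at least 2 observations per group")
    if method == "welch":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
    elif method == "mann_whitney":
        # cross-group ties break the exact null distribution; within-group
        # ties do not change U
        has_cross_ties = np.intersect1d(x, y).size > 0
        mw_method = (
            "exact" if (len(x) + len(y) <= 20 and not has_cross_ties) else "asymptotic"
        )
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=mw_method)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(float(stat), float(p), method, len(x), len(y))


def correlate(x, y, method: str = "auto") -> Correlation:
    """Pearson or Spearman correlation with two-sided p.

    ``auto`` picks Pearson when both vectors pass a Shapiro-Wilk normality
    check at alpha = 0.05, Spearman otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedCorrelationError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    if method == "auto":
        px = sps.shapiro(x).pvalue
        py = sps.shapiro(y).pvalue
        method = "pearson" if (px > ALPHA and py > ALPHA) else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Correlation(float(r), float(p), method, int(x.size))


def durbin_watson(resid: Sequence[float]) -> float:
    """d = sum_(t>=2) (e_t - e_(t-1))^2 / sum e_t^2, on residuals in given order."""
    e = np.asarray(resid, dtype=float)
    denom = float(e @ e)
    if denom == 0.0:
        return 0.0
    return float(np.sum(np.diff(e) ** 2) / denom)


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) from regressing each predictor on the others."""
    vifs = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        exog = sm.add_constant(others.to_numpy(dtype=float))
        r2 = sm.OLS(X[col].to_numpy(dtype=float), exog).fit().rsquared
        vifs[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def _ols(y: np.ndarray, X: pd.DataFrame, with_vif: bool) -> RegressionResult:
    exog = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, exog.to_numpy(dtype=float)).fit()
    names = list(exog.columns)
    params = pd.Series(fit.params, index=names)
    vif = variance_inflation(X) if with_vif and X.shape[1] > 1 else None
    return RegressionResult(
        params=params,
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        rsquared=float(fit.rsquared),
        durbin_watson=durbin_watson(fit.resid),
        vif=vif,
        nobs=int(fit.nobs),
    )


def simple_regression(y, x, name: str = "x") -> RegressionResult:
    """OLS of y on one predictor with F, p, R^2 and Durbin-Watson."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant predictor: rank deficient")
    return _ols(y, pd.DataFrame({name: x}), with_vif=False)


def multiple_regression(y, X: pd.DataFrame, condition_threshold: float = 1e10) -> RegressionResult:
    """OLS of y on several predictors with per-predictor VIF and Durbin-Watson.

    Exactly collinear predictor columns (beyond ``condition_threshold``) are
    dropped with a report rather than silently regularized.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[ok], X.loc[ok]
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    dropped: list[str] = []
    Z = X.to_numpy()
    centered = Z - Z.mean(axis=0)
    # greedy QR-style screen for dependent columns
    keep: list[int] = []
    for j in range(Z.shape[1]):
        cand = centered[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=None) == len(keep) + 1:
            s = np.linalg.svd(cand, compute_uv=False)
            if s[0] / max(s[-1], 1e-300) < condition_threshold:
                keep.append(j)
                continue
        dropped.append(X.columns[j])
    if not keep:
        raise np.linalg.LinAlgError("all predictors constant or collinear")
    X_kept = X.iloc[:, keep]
    res = _ols(y, X_kept, with_vif=True)
    res.dropped = dropped
    return res


# ---------------------------------------------------------------------------
# Cohort report grids

CAR_OUTCOMES = [
    "mesor",
    "maximum",
    "minimum",
    "range",
    "max_phase_time",
    "min_phase_time",
    "total_sleep_time",
    "sleep_efficiency",
    "waking_time",
    "bed_time",
]

COMPARISON_FACTORS = {
    "sex": ("male", "female"),
    "diagnosis": ("cerebrovascular", "orthopedic"),
    "locomotive_independent": (True, False),
    "hypnotics": (True, False),
    "psychotropics": (True, False),
}

CORRELATION_FACTORS = [
    "age",
    "bmi",
    "mmse",
    "motor_fim",
    "total_sleep_time",
    "sleep_efficiency",
    "waking_time",
    "bed_time",
    "sb_min",
    "lipa_min",
    "mvpa_min",
]


def cohort_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full comparison and correlation grids over the merged subject table.

    Returns ``{"comparisons": ..., "correlations": ...}`` long-format frames;
    both Welch and Mann-Whitney (resp. Pearson and Spearman) are reported for
    every cell because the per-cell method choice of the original analysis
    plan is not fully reconstructible.
    """
    missing = [c for c in CAR_OUTCOMES if c not in cohort.columns]
    missing += [c for c in COMPARISON_FACTORS if c not in cohort.columns]
    missing += [c for c in CORRELATION_FACTORS if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table missing columns: {sorted(set(missing))}")
    if cohort["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort table")

    comp_rows = []
    for factor, (lvl_a, lvl_b) in COMPARISON_FACTORS.items():
        labels = cohort[factor]
        for outcome in CAR_OUTCOMES:
            row = {"factor": factor, "outcome": outcome}
            vals = cohort[outcome].to_numpy(dtype=float)
            a = vals[(labels == lvl_a).to_numpy()]
            b = vals[(labels == lvl_b).to_numpy()]
            row["mean_a"], row["mean_b"] = float(np.mean(a)), float(np.mean(b))
            row["sd_a"], row["sd_b"] = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
            for method in ("welch", "mann_whitney"):
                try:
                    res = compare_groups(vals, labels.to_numpy(), method=method)
                    row[f"{method}_stat"] = res.statistic
                    row[f"{method}_p"] = res.pvalue
                except (GroupingError, ValueError):
                    row[f"{method}_stat"] = np.nan
                    row[f"{method}_p"] = np.nan
            comp_rows.append(row)

    corr_rows = []
    for factor in CORRELATION_FACTORS:
        for outcome in CAR_OUTCOMES:
            if factor == outcome:
                continue
            row = {"factor": factor, "outcome": outcome}
            for method in ("pearson", "spearman"):
                try:
                    res = correlate(cohort[factor], cohort[outcome], method=method)
                    row[f"{method}_r"] = res.r
                    row[f"{method}_p"] = res.pvalue
                except UndefinedCorrelationError:
                    row[f"{method}_r"] = np.nan
                    row[f"{method}_p"] = np.nan
            corr_rows.append(row)

    return {
        "comparisons": pd.DataFrame(comp_rows),
        "correlations": pd.DataFrame(corr_rows),
    }


def standard_regressions(cohort: pd.DataFrame) -> dict[str, RegressionResult]:
    """The reported regression set: each CAR outcome on each activity class,
    plus mesor models adjusted for nocturnal sleep duration."""
    out: dict[str, RegressionResult] = {}
    for outcome in ("mesor", "maximum", "range"):
        for predictor in ("sb_min", "lipa_min", "mvpa_min"):
            try:
                out[f"{outcome}~{predictor}"] = simple_regression(
                    cohort[outcome], cohort[predictor], name=predictor
                )
            except np.linalg.LinAlgError:
                # e.g. a cohort with no MVPA at all: the model is not estimable
                continue
    for predictor in ("sb_min", "lipa_min"):
        X = cohort[[predictor, "total_sleep_time"]]
        out[f"mesor~{predictor}+total_sleep_time"] = multiple_regression(
            cohort["mesor"].to_numpy(dtype=float), X
        )
    return out
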