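"""Association statistics: univariate OLS of AUC(CV > CV_T) on covariates.

The statistical layer mirrors a small-cohort pilot analysis: ordinary
least squares of the heterogeneity statistic on one covariate at a time
(age, height, lung-function indices), reporting Pearson's r, the slope
with its t-based 95% confidence interval, r^2, the two-sided p-value and
n; plus a two-group comparison run as a regression on a 0/1 indicator,
whose slope is the group mean difference. Covariates enter in raw
(non-normalized) units. No multiple-testing correction is applied.

A 15-subject characteristics table (13 healthy subjects and 2 patients
with documented airway disease, with their published AUC values) ships
with the package as ``table1.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary for one covariate: r, slope with 95% CI, r^2, p, n."""

    r: float
    b: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "b": self.b,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "r2": self.r2,
            "p": self.p,
            "n": self.n,
        }


def load_subject_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cohort characteristics table (default: the packaged one)."""
    if path is None:
        source = resources.files("lungcv.data").joinpath("table1.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return df


def univariate_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on a single covariate x.

    Returns Pearson's r, the slope with its t-based 95% confidence
    interval, the coefficient of determination and the two-sided p-value
    for the slope.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b = float(model.params[1])
    ci = model.conf_int(alpha=0.05)
    # constant y: slope and correlation are both 0 (Pearson r undefined)
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        r=r,
        b=b,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r2=float(r * r),
        p=float(model.pvalues[1]),
        n=int(n),
    )


def group_compare(y: np.ndarray, group: np.ndarray) -> RegressionResult:
    """Two-group comparison via regression on a 0/1 indicator.

    The slope equals the difference of group means; the p-value is the
    two-sided t-test of that difference (equal variances).
    """
    group = np.asarray(group).astype(bool).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if group.all() or not group.any():
        raise ValueError("both groups must be nonempty")
    return univariate_regression(group.astype(float), y)


def regression_table(
    df: pd.DataFrame,
    covariates: list[str],
    y_column: str = "auc_gt_20",
    healthy_only: bool = True,
) -> pd.DataFrame:
    """Univariate regressions of ``y_column`` on each covariate.

    With ``healthy_only`` the patient rows (abnormal lung function) are
    dropped, matching the covariate analysis of the reference cohort.
    Rows are ordered by decreasing |r|.
    """
    data = df
    if healthy_only and "lung_function_abnormal" in df.columns:
        data = df[~_as_bool(df["lung_function_abnormal"])]
    rows = []
    for cov in covariates:
        res = univariate_regression(data[cov].to_numpy(), data[y_column].to_numpy())
        rows.append({"variable": cov, **res.as_dict()})
    out = pd.DataFrame(rows)
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def _as_bool(series: pd.Series) -> np.ndarray:
    if series.dtype == bool:
        return series.to_numpy()
    return series.astype(str).str.strip().str.lower().isin(["yes", "true", "1"]).to_numpy()


def residual_diagnostics(x: np.ndarray, y: np.ndarray) -> dict:
    """Regression-assumption report: residual normality and homoscedasticity.

    Emitted for inspection, not enforced: Shapiro-Wilk on the residuals
    and the Breusch-Pagan test against the covariate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    X = sm.add_constant(x)
    model = sm.OLS(y, X).fit()
    resid = model.resid
    shapiro = sps.shapiro(resid)
    bp = sm.stats.diagnostic.het_breuschpagan(resid, X)
    return {
        "shapiro_stat": float(shapiro.statistic),
        "shapiro_p": float(shapiro.pvalue),
        "breusch_pagan_lm": float(bp[0]),
        "breusch_pagan_p": float(bp[1]),
        "n": int(x.size),
    }
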