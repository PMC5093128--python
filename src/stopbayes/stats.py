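"""Cohort-level statistics: group comparisons, correlations, and regressions.

Covers the group analyses run on the cohort table: pooled-variance t-tests
with Cohen's d (including a summary-statistic entry point so printed group
means/SDs can be checked without raw data), Pearson/Spearman correlations,
the multi-covariate second-level regression of ROI contrast values on the
personality traits (NS, HA, RD) with age and the two gender indicators, and
the classical pooled-variance comparison of regression slopes between two
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "two_sample_t",
    "two_sample_t_from_stats",
    "correlate",
    "second_level_regression",
    "compare_slopes",
    "bonferroni_alpha",
]

#: Predictors of the second-level regression, in reporting order.
SECOND_LEVEL_PREDICTORS = ["ns", "ha", "rd", "age", "male", "female"]


@dataclass
class RegressionReport:
    """Per-predictor inference from a least-squares fit."""

    predictors: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )


def two_sample_t(group_a, group_b) -> tuple[float, int, float, float]:
    """Pooled-variance two-sample t-test with Cohen's d.

    Returns ``(t, dof, p, d)`` with ``dof = n_a + n_b - 2`` and d the mean
    difference over the pooled SD.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return two_sample_t_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, int, float, float]:
    """Same test from printed summary statistics (means, SDs, ns)."""
    dof = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / dof
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: t and Cohen's d are undefined")
    t, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    d = (mean_a - mean_b) / np.sqrt(pooled_var)
    return float(t), int(dof), float(p), float(d)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Pearson p-values come from the t transform with n - 2 df; Spearman is
    Pearson on average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


def second_level_regression(
    table: pd.DataFrame, dependent: str, predictors: list[str] | None = None
) -> RegressionReport:
    """Regression of a contrast value on traits, age, and gender indicators.

    The design uses the NS, HA and RD scores, age, and *two* gender
    indicator columns with no separate intercept (the indicators span it);
    adding a constant to the dependent variable therefore moves only the
    gender coefficients.  ``table`` must carry a ``gender`` column coded
    M/F, or explicit ``male``/``female`` indicator columns.
    """
    if predictors is None:
        predictors = SECOND_LEVEL_PREDICTORS
    df = table.copy()
    if "male" not in df.columns or "female" not in df.columns:
        if "gender" not in df.columns:
            raise ValueError("table needs 'gender' or male/female indicator columns")
        df["male"] = (df["gender"] == "M").astype(float)
        df["female"] = (df["gender"] == "F").astype(float)
    missing = [c for c in predictors + [dependent] if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    X = df[predictors].to_numpy(dtype=float)
    y = df[dependent].to_numpy(dtype=float)
    if len(df) <= len(predictors):
        raise ValueError("need more subjects than predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear predictors beyond the designed gender pair")
    res = sm.OLS(y, X).fit()
    return RegressionReport(
        predictors=list(predictors),
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        r_squared=float(res.rsquared),
        n=len(df),
    )


def compare_slopes(x1, y1, x2, y2) -> tuple[float, int, float]:
    """Classical test for equality of two simple-regression slopes.

    t = (b1 - b2) / SE_diff with residual variance pooled across the two
    fits and dof = n1 + n2 - 4.
    """
    x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
    if x1.size < 3 or x2.size < 3:
        raise ValueError("each group needs at least 3 observations")
    out = []
    for x, y in ((x1, y1), (x2, y2)):
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx == 0.0:
            raise ValueError("zero x-variance in a group: slope undefined")
        b = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        resid = y - y.mean() - b * (x - x.mean())
        out.append((b, sxx, float(resid @ resid)))
    (b1, sxx1, rss1), (b2, sxx2, rss2) = out
    dof = x1.size + x2.size - 4
    s2 = (rss1 + rss2) / dof
    se = np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    t = (b1 - b2) / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), int(dof), float(p)


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 3) -> float:
    """Bonferroni-corrected per-test alpha (0.05 / 3 for trait pairs)."""
    return alpha / n_tests
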