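"""Cross-cell-line comparison of per-region depletion scores.

Covers the differential-essentiality analyses: ordinary least-squares
regression between two screens' depletion scores, a mean-shift outlier
test on externally studentized residuals with Bonferroni control, the
empirical Brown's method for combining dependent p values, and a
chi-square test for local (locus-level) enrichment of essential elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    p_slope: float
    r: float
    n: int
    removed_outliers: list | None = None


def fit_score_regression(
    x: Sequence[float],
    y: Sequence[float],
    remove_outliers: bool = False,
    outlier_alpha: float = 0.1,
) -> RegressionFit:
    """OLS of y on x with a t-test on the slope.

    With ``remove_outliers`` the mean-shift outlier test is run once,
    flagged points are dropped, and the model is refit (flag-remove-refit,
    a single iteration).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("need >= 3 finite paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    removed = None
    if remove_outliers:
        table = detect_outlier_regions(x, y, alpha=outlier_alpha)
        keep = ~table["outlier"].to_numpy()
        removed = list(np.flatnonzero(~keep))
        x, y = x[keep], y[keep]
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_slope=float(model.pvalues[1]),
        r=r,
        n=len(x),
        removed_outliers=removed,
    )


def detect_outlier_regions(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.1,
    region_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean-shift outlier test on the regression of y on x.

    Each point's externally studentized residual t_i is referred to a
    t distribution with n - 3 degrees of freedom (n - 2 parameters plus
    the left-out observation); the two-sided p is Bonferroni-corrected by
    n and points with adjusted p < ``alpha`` are flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need >= 5 observations for the outlier test")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    infl = OLSInfluence(model)
    t_ext = infl.resid_studentized_external
    df = n - 3
    if df < 1:
        raise ValueError("too few observations for the t reference")
    p_raw = 2.0 * stats.t.sf(np.abs(t_ext), df)
    p_bonf = np.minimum(1.0, n * p_raw)
    out = pd.DataFrame(
        {
            "region_id": region_ids if region_ids is not None else np.arange(n),
            "score_a": x,
            "score_b": y,
            "residual": model.resid,
            "studentized_t": t_ext,
            "p_raw": p_raw,
            "bonferroni_p": p_bonf,
            "outlier": p_bonf < alpha,
        }
    )
    return out


def comparative_table(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    locus_map: Mapping[str, str] | None = None,
    essential_p: float = 0.05,
    outlier_alpha: float = 0.1,
    score_column: str = "depletion_score",
) -> pd.DataFrame:
    """Join two screens' region tables and run the outlier test.

    ``essential_a``/``essential_b`` flag regions with ``p_region`` below
    ``essential_p`` in each screen; the threshold is an explicit recorded
    parameter, not a hidden constant.
    """
    merged = scores_a.merge(
        scores_b, on="region_id", suffixes=("_a", "_b"), how="inner"
    )
    table = detect_outlier_regions(
        merged[f"{score_column}_a"],
        merged[f"{score_column}_b"],
        alpha=outlier_alpha,
        region_ids=merged["region_id"],
    )
    table["essential_a"] = (merged["p_region_a"] < essential_p).to_numpy()
    table["essential_b"] = (merged["p_region_b"] < essential_p).to_numpy()
    table["essential_p_threshold"] = essential_p
    if locus_map is not None:
        table["locus"] = table["region_id"].map(locus_map).fillna("")
    return table


# ---------------------------------------------------------------------------
# empirical Brown's method


def _transformed_tail(data_row: np.ndarray) -> np.ndarray:
    """w(x) = -2 log(empirical right-tail CDF of x within its row)."""
    n = len(data_row)
    # right-tail ECDF: fraction of values >= x (never zero at observed points)
    order = stats.rankdata(-data_row, method="max")
    return -2.0 * np.log(order / n)


def combine_pvalues_browns(
    p_values: Sequence[float], data_matrix: np.ndarray
) -> float:
    """Empirical Brown's method for dependent p values.

    Each condition's score vector is transformed to
    w = -2 log(empirical right-tail CDF); the empirical covariance of the
    w rows calibrates a scaled chi-square: f = 2 (2k)^2 / Var(sum w),
    c = Var / (2 * 2k), and the combined p is
    P(chi2_f > sum(-2 log p_i) / c). With independent rows this reduces to
    Fisher's method; a single p passes through unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    k = len(p)
    if k == 1:
        return float(p[0])
    data = np.asarray(data_matrix, dtype=float)
    if data.shape[0] != k:
        raise ValueError("data_matrix rows must align with p entries")
    if (np.ptp(data, axis=1) == 0).any():
        raise ValueError("degenerate (constant) data row")
    w = np.vstack([_transformed_tail(row) for row in data])
    cov = np.cov(w)
    expected = 2.0 * k
    var = float(cov.sum())
    f = 2.0 * expected**2 / var
    c = var / (2.0 * expected)
    if f > 2 * k:  # cannot beat independence; fall back to Fisher
        f, c = 2.0 * k, 1.0
    stat = float(-2.0 * np.log(p).sum())
    return float(stats.chi2.sf(stat / c, f))


def fisher_combine(p_values: Sequence[float]) -> float:
    p = np.asarray(p_values, dtype=float)
    return float(stats.chi2.sf(-2.0 * np.log(p).sum(), 2 * len(p)))


# ---------------------------------------------------------------------------
# locus enrichment


@dataclass
class LocusEnrichment:
    locus: str
    statistic: float
    p: float
    table: np.ndarray  # 2x2 [in/out locus] x [essential/not]
    essential_rule: str
    low_expected: bool
    fisher_p: float | None = None


def locus_enrichment_test(
    table: pd.DataFrame,
    locus: str,
    essential_column: str = "essential_a",
) -> LocusEnrichment:
    """Pearson chi-square (1 df, no continuity correction) for enrichment
    of essential regions inside a locus; Fisher's exact p is attached as a
    fallback when an expected cell drops below 1."""
    in_locus = (table["locus"] == locus).to_numpy()
    if in_locus.all() or not in_locus.any():
        raise ValueError("need regions both inside and outside the locus")
    ess = table[essential_column].to_numpy().astype(bool)
    c = np.array(
        [
            [np.sum(in_locus & ess), np.sum(in_locus & ~ess)],
            [np.sum(~in_locus & ess), np.sum(~in_locus & ~ess)],
        ],
        dtype=float,
    )
    if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any():
        stat, p = 0.0, 1.0
        expected = c
    else:
        stat, p, _, expected = stats.chi2_contingency(c, correction=False)
    low = bool((expected < 1).any())
    fisher_p = None
    if low:
        fisher_p = float(stats.fisher_exact(c.astype(int))[1])
    rule = str(table["essential_p_threshold"].iloc[0]) if "essential_p_threshold" in table else "custom"
    return LocusEnrichment(
        locus=locus,
        statistic=float(stat),
        p=float(p),
        table=c,
        essential_rule=f"p_region < {rule}",
        low_expected=low,
        fisher_p=fisher_p,
    )
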