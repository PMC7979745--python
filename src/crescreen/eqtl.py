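"""Methylation-stratified eQTL analysis.

The cohort carries, per sample, an additive risk-allele dosage (0/1/2), a
CpG methylation fraction at an insulator CTCF site (a surrogate for CTCF
occupancy), and positive expression values for a focal gene and its
neighbors. Expression is Box-Cox transformed (lambda = -0.1 by default, a
fixed input rather than a re-estimated value), the cohort is dichotomized
at the median methylation, and expression is regressed on dosage within
each stratum; a pooled model with a genotype x stratum interaction term is
reported alongside. Stratum-specific co-expression (Pearson r between the
focal gene and each neighbor) probes whether co-regulation exists only
when the insulator site is methylated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import boxcox as _boxcox
import statsmodels.api as sm

DEFAULT_LAMBDA = -0.1


def boxcox_transform(x: Sequence[float], lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Box-Cox power transform: (x^lam - 1)/lam, or log(x) at lam = 0.

    Strictly increasing for every lambda; raises on any non-positive
    input rather than silently offsetting.
    """
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    return _boxcox(arr, lam)


def dichotomize_by_median(meth: Sequence[float]) -> pd.Series:
    """'high' where methylation > median, 'low' otherwise (ties at the
    median go low). Warns on a degenerate split."""
    m = np.asarray(meth, dtype=float)
    if len(m) < 4:
        raise ValueError("need n >= 4")
    med = float(np.median(m))
    labels = np.where(m > med, "high", "low")
    if (m == med).mean() > 0.5:
        warnings.warn("more than half the values tie at the median", stacklevel=2)
    return pd.Series(labels, name="stratum")


@dataclass
class EqtlResult:
    stratum: str
    n: int
    beta: float
    p: float
    transform_lambda: float
    note: str = ""


def _stratum_fit(expr: np.ndarray, geno: np.ndarray, stratum: str, lam: float) -> EqtlResult:
    if len(expr) < 3 or len(np.unique(geno)) < 2:
        return EqtlResult(
            stratum=stratum, n=len(expr), beta=float("nan"), p=float("nan"),
            transform_lambda=lam,
            note="monomorphic genotype or too few samples",
        )
    model = sm.OLS(expr, sm.add_constant(geno.astype(float))).fit()
    return EqtlResult(
        stratum=stratum,
        n=len(expr),
        beta=float(model.params[1]),
        p=float(model.pvalues[1]),
        transform_lambda=lam,
    )


def stratified_eqtl(
    cohort: pd.DataFrame,
    gene: str,
    lam: float = DEFAULT_LAMBDA,
    meth_column: str = "meth",
    genotype_column: str = "genotype",
) -> dict:
    """Per-stratum eQTL regression plus a pooled interaction model.

    Returns ``{"high": EqtlResult, "low": EqtlResult, "interaction":
    {beta, p}, "strata": Series}``. The interaction model is
    y ~ genotype + stratum + genotype:stratum on the pooled transformed
    expression; its interaction p asks whether the genotype effect differs
    between strata.
    """
    y = boxcox_transform(cohort[gene].to_numpy(), lam)
    g = cohort[genotype_column].to_numpy()
    strata = dichotomize_by_median(cohort[meth_column].to_numpy())
    results = {}
    for label in ("high", "low"):
        mask = (strata == label).to_numpy()
        results[label] = _stratum_fit(y[mask], g[mask], label, lam)
    is_high = (strata == "high").to_numpy().astype(float)
    X = np.column_stack([g.astype(float), is_high, g * is_high])
    inter = sm.OLS(y, sm.add_constant(X)).fit()
    results["interaction"] = {
        "beta": float(inter.params[3]),
        "p": float(inter.pvalues[3]),
    }
    results["strata"] = strata
    return results


def coexpression_by_stratum(
    cohort: pd.DataFrame,
    focal_gene: str,
    neighbor_genes: Sequence[str],
    lam: float = DEFAULT_LAMBDA,
    meth_column: str = "meth",
) -> pd.DataFrame:
    """Pearson correlation of the focal gene with each neighbor, computed
    separately in the high- and low-methylation strata on the Box-Cox
    transformed expression scale."""
    strata = dichotomize_by_median(cohort[meth_column].to_numpy())
    focal = boxcox_transform(cohort[focal_gene].to_numpy(), lam)
    rows = []
    for gene in neighbor_genes:
        expr = boxcox_transform(cohort[gene].to_numpy(), lam)
        for label in ("high", "low"):
            mask = (strata == label).to_numpy()
            if mask.sum() < 3:
                raise ValueError(f"stratum {label} has fewer than 3 samples")
            f, e = focal[mask], expr[mask]
            if np.ptp(f) == 0 or np.ptp(e) == 0:
                rows.append({"gene": gene, "stratum": label, "n": int(mask.sum()),
                             "r": np.nan, "p": np.nan, "note": "constant gene"})
                continue
            res = stats.pearsonr(f, e)
            rows.append(
                {
                    "gene": gene,
                    "stratum": label,
                    "n": int(mask.sum()),
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
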