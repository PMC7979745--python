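"""Associating depletion scores with epigenomic signal and risk-SNP effect
sizes, plus PWM motif scanning and methylation-binding correlation.

Signal tracks are piecewise-constant bedGraph intervals (0-based,
half-open); the per-region statistic is the maximum signal over any base
of the region, with uncovered bases contributing zero. Skewed signal is
mapped to normal scores by a rank-based inverse normal transform before
regression against depletion scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """bedGraph sanity: finite non-negative values, no overlaps per chrom."""
    if not np.isfinite(track["value"]).all() or (track["value"] < 0).any():
        raise ValueError("track values must be finite and >= 0")
    for chrom, grp in track.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["end"] <= g["start"]).any():
            raise ValueError(f"malformed interval on {chrom}")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals on {chrom}")
    return track


def extract_region_signal(
    track: pd.DataFrame, regions: pd.DataFrame
) -> pd.Series:
    """Per-region maximum signal; regions with no coverage get 0."""
    validate_track(track)
    out = {}
    by_chrom = {c: g for c, g in track.groupby("chrom")}
    for _, reg in regions.iterrows():
        grp = by_chrom.get(reg["chrom"])
        if grp is None:
            out[reg["name"]] = 0.0
            continue
        hit = grp[(grp["start"] < reg["end"]) & (grp["end"] > reg["start"])]
        out[reg["name"]] = float(hit["value"].max()) if len(hit) else 0.0
    return pd.Series(out, name="max_signal")


def rank_inverse_normal(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse normal scores: Phi^-1((r_i - 0.5) / n), average
    ranks for ties. All-identical input maps to all zeros (warned)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        import warnings

        warnings.warn("all values identical; transform returns zeros", stacklevel=2)
        return np.zeros(len(x))
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def correlate_depletion_epigenome(
    scores: pd.Series, signal_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Spearman/Pearson correlation of depletion score with each mark, and
    a regression of score on the rank-inverse-normalized signal.

    Significance tiers follow the conventional 0.05 / 0.01 / 0.005 cuts
    (one to three stars).
    """
    common = scores.index.intersection(signal_matrix.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 aligned regions")
    s = scores.loc[common].to_numpy(dtype=float)
    rows = []
    for mark in signal_matrix.columns:
        v = signal_matrix.loc[common, mark].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(s) == 0:
            rows.append(
                {"mark": mark, "spearman_r": np.nan, "spearman_p": np.nan,
                 "pearson_r": np.nan, "pearson_p": np.nan, "slope": np.nan,
                 "slope_p": np.nan, "stars": "", "note": "constant column"}
            )
            continue
        sp = stats.spearmanr(s, v)
        pe = stats.pearsonr(s, v)
        rin = rank_inverse_normal(v)
        model = sm.OLS(s, sm.add_constant(rin)).fit()
        p = float(sp.pvalue)
        stars = "***" if p <= 0.005 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""
        rows.append(
            {
                "mark": mark,
                "spearman_r": float(sp.statistic),
                "spearman_p": p,
                "pearson_r": float(pe.statistic),
                "pearson_p": float(pe.pvalue),
                "slope": float(model.params[1]),
                "slope_p": float(model.pvalues[1]),
                "stars": stars,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# risk-SNP odds-ratio enrichment


def representative_odds_ratios(
    regions: pd.DataFrame, snps: pd.DataFrame, flank: int = 100
) -> pd.Series:
    """Max SNP odds ratio within each region's widened window.

    The widened window is the core region extended by ``flank`` bp on both
    sides (a 400 bp core with the default 100 bp flank spans 600 bp).
    Regions without any OR-bearing SNP are excluded.
    """
    out = {}
    for _, reg in regions.iterrows():
        lo, hi = reg["start"] - flank, reg["end"] + flank
        hit = snps[
            (snps["chrom"] == reg["chrom"])
            & (snps["position"] >= lo)
            & (snps["position"] < hi)
            & snps["odds_ratio"].notna()
        ]
        if len(hit):
            out[reg["name"]] = float(hit["odds_ratio"].max())
    return pd.Series(out, name="representative_or")


def snp_or_enrichment(
    rep_or: pd.Series,
    depletion_scores: Mapping[str, pd.Series],
    top_fraction: float = 0.25,
) -> dict:
    """Compare representative ORs of top-ranked essential regions vs rest.

    Regions are ranked by depletion score per screen (higher = more
    essential); the top ``top_fraction`` per screen and their intersection
    across screens are each compared with the remaining regions by a
    rank-sum test. Returns per-group OR vectors, medians and tests.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    regions = rep_or.index
    results = {"all_or": rep_or, "groups": {}}
    top_sets = {}
    for screen, scores in depletion_scores.items():
        s = scores.loc[scores.index.intersection(regions)]
        k = max(1, int(math.floor(len(s) * top_fraction)))
        top = set(s.sort_values(ascending=False).index[:k])
        top_sets[screen] = top
        results["groups"][f"top_{screen}"] = _or_group(rep_or, top)
    inter = set.intersection(*top_sets.values()) if top_sets else set()
    results["groups"]["top_intersection"] = _or_group(rep_or, inter)
    return results


def _or_group(rep_or: pd.Series, top: set) -> dict:
    top_vals = rep_or.loc[rep_or.index.isin(top)].to_numpy()
    rest_vals = rep_or.loc[~rep_or.index.isin(top)].to_numpy()
    if len(top_vals) == 0 or len(rest_vals) == 0:
        return {"n_top": len(top_vals), "n_rest": len(rest_vals)}
    test = stats.mannwhitneyu(top_vals, rest_vals, alternative="greater")
    return {
        "n_top": int(len(top_vals)),
        "n_rest": int(len(rest_vals)),
        "top_or": top_vals,
        "rest_or": rest_vals,
        "median_top": float(np.median(top_vals)),
        "median_rest": float(np.median(rest_vals)),
        "median_diff": float(np.median(top_vals) - np.median(rest_vals)),
        "ranksum_p": float(test.pvalue),
    }


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass
class PWM:
    """4 x L weight matrix over A, C, G, T with per-column score extrema."""

    matrix: np.ndarray  # shape (4, L)
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM weights must be finite")
        self.col_max = self.matrix.max(axis=0)
        self.col_min = self.matrix.min(axis=0)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[_COMPLEMENT_IDX][:, ::-1], name=self.name + "_rc")

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def read_tsv(cls, path, name: str = "pwm") -> "PWM":
        """Read a 4-row tab-separated matrix; rows A, C, G, T (a leading
        `base` label column is allowed)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.iloc[:, 0].dtype == object:
            df = df.set_index(0)
            df = df.loc[list("ACGT")]
        return cls(df.to_numpy(dtype=float), name=name)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# PWM rows A, C, G, T; columns are motif positions\n")
            for base, row in zip("ACGT", self.matrix):
                fh.write(base + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _scores_one_strand(seq_idx: np.ndarray, pwm: PWM) -> np.ndarray:
    L = pwm.length
    n_win = len(seq_idx) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, L)
    return pwm.matrix[windows, np.arange(L)].sum(axis=1)[:n_win]


def pwm_scan(
    sequence: str, pwm: PWM, threshold: float = 0.75
) -> pd.DataFrame:
    """Scan both strands for windows whose min-max normalized PWM score
    reaches ``threshold``.

    Normalized score = (S - S_min) / (S_max - S_min) where S_min/S_max are
    the per-column extrema sums. Hit coordinates are on the forward
    strand, 0-based half-open.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    seq = sequence.upper()
    if len(seq) < pwm.length:
        return pd.DataFrame(columns=["start", "end", "strand", "score"])
    idx = np.array([_BASE_INDEX[b] for b in seq])
    span = pwm.col_max.sum() - pwm.col_min.sum()
    smin = pwm.col_min.sum()
    rows = []
    fwd = (_scores_one_strand(idx, pwm) - smin) / span
    rev = (_scores_one_strand(idx, pwm.reverse_complement()) - smin) / span
    for pos, score in enumerate(fwd):
        if score >= threshold - 1e-12:
            rows.append((pos, pos + pwm.length, "+", float(score)))
    for pos, score in enumerate(rev):
        if score >= threshold - 1e-12:
            rows.append((pos, pos + pwm.length, "-", float(score)))
    return pd.DataFrame(rows, columns=["start", "end", "strand", "score"]).sort_values(
        ["start", "strand"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylation-binding correlation


def methylation_binding_correlation(
    meth: Sequence[float], binding: Sequence[float], exact_n: int = 10
) -> tuple[float, float]:
    """Spearman correlation between CpG methylation fractions and binding
    signal; the p value is an exact pairing-permutation p for n <= 10 and
    the asymptotic t approximation otherwise."""
    m = np.asarray(meth, dtype=float)
    b = np.asarray(binding, dtype=float)
    if len(m) != len(b) or len(m) < 5:
        raise ValueError("need >= 5 paired observations")
    if ((m < 0) | (m > 1)).any():
        raise ValueError("methylation fractions must lie in [0, 1]")
    if np.ptp(m) == 0 or np.ptp(b) == 0:
        raise ValueError("ties-only input")
    rho = float(stats.spearmanr(m, b).statistic)
    n = len(m)
    if n <= exact_n:
        rm = stats.rankdata(m)
        rb = stats.rankdata(b)
        rm_c = rm - rm.mean()
        perms = np.array(list(_permutations(rb)), dtype=float)
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rm_c**2).sum() * (perms_c**2).sum(axis=1))
        rhos = perms_c @ rm_c / denom
        rb_c = rb - rb.mean()
        obs = abs(float(np.dot(rb_c, rm_c))
                  / math.sqrt((rm_c**2).sum() * (rb_c**2).sum()))
        p = float(np.mean(np.abs(rhos) >= obs - 1e-12))
    else:
        p = float(stats.spearmanr(m, b).pvalue)
    return rho, p
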