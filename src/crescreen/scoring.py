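"""From guide counts to per-region depletion scores.

The scoring contract follows the standard pooled-screen recipe: counts are
normalized by median-of-ratios size factors; each guide gets a
negative-binomial Wald test for depletion between day 0 and day 16; each
region is split into 100 bp sliding windows (50 bp offset, >= 2 guides per
window); windows are scored by alpha-restricted robust rank aggregation
(alpha-RRA) over the guides' library-wide depletion-rank percentiles, with
a permutation p value from re-drawing guide-to-window assignments; and a
region's essentiality is carried by its best window (adjacent sibling
windows from one parent element are merged into the single most essential
window). The region "neg score" is the representative window's RRA score;
`depletion_score = -log10(neg_score)` is used for ranking (higher = more
essential).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import reads_from_source

DEFAULT_WINDOW = 100
DEFAULT_OFFSET = 50
DEFAULT_MIN_GUIDES = 2
DEFAULT_RRA_ALPHA = 0.25
DEFAULT_PERMUTATIONS = 10_000
EXACT_ENUMERATION_LIMIT = 1_000_000
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Guide x sample integer counts with timepoint/replicate metadata."""

    counts: pd.DataFrame  # index guide_id, columns sample names
    meta: pd.DataFrame  # columns: sample, timepoint, replicate
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if set(self.meta["sample"]) != set(self.counts.columns):
            raise ValueError("meta samples do not match count columns")
        for tp in ("day0", "day16"):
            if (self.meta["timepoint"] == tp).sum() < 1:
                raise ValueError(f"need at least one {tp} sample")

    def samples(self, timepoint: str) -> list[str]:
        return list(self.meta.loc[self.meta["timepoint"] == timepoint, "sample"])

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("call normalize_counts first")
        return self.counts / self.size_factors


# ---------------------------------------------------------------------------
# counting


def count_guides(
    sample_reads: Mapping[str, object],
    library: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    offset: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Exact-match read counting against the guide manifest.

    ``sample_reads`` maps sample name -> FASTA/FASTQ path or iterable of
    read sequences. A read is assigned to the single guide whose
    protospacer equals the read subsequence starting at ``offset``;
    anything else is unassigned. Totals are conserved.
    """
    lib = library
    dupes = lib.loc[~lib.get("ambiguous", False).astype(bool), "protospacer"]
    if dupes.duplicated().any():
        raise ValueError("duplicate protospacers in library without ambiguous flag")
    lookup = dict(zip(lib["protospacer"], lib["guide_id"]))
    lengths = sorted({len(p) for p in lib["protospacer"]}, reverse=True)

    counts = {}
    unassigned = {}
    for sample, source in sample_reads.items():
        tally = dict.fromkeys(lib["guide_id"], 0)
        miss = 0
        for read in reads_from_source(source):
            hit = None
            for L in lengths:
                guide = lookup.get(read[offset : offset + L])
                if guide is not None:
                    hit = guide
                    break
            if hit is None:
                miss += 1
            else:
                tally[hit] += 1
        counts[sample] = tally
        unassigned[sample] = miss
    count_df = pd.DataFrame(counts)
    count_df.index.name = "guide_id"
    if meta is None:
        meta = _infer_meta(count_df.columns)
    return CountMatrix(counts=count_df, meta=meta), pd.Series(unassigned)


def _infer_meta(samples: Iterable[str]) -> pd.DataFrame:
    rows = []
    for s in samples:
        tp, _, rep = s.partition("_rep")
        rows.append({"sample": s, "timepoint": tp, "replicate": int(rep or 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normalization


def normalize_counts(cm: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors (guides with any zero count excluded
    from the reference geometric mean)."""
    counts = cm.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    finite = np.isfinite(log_counts).all(axis=1)
    if not finite.any():
        raise ValueError("no guide has nonzero counts in every sample")
    ref = np.exp(log_counts[finite].mean(axis=1))
    ratios = counts[finite] / ref[:, None]
    sf = np.median(ratios, axis=0)
    return CountMatrix(
        counts=cm.counts,
        meta=cm.meta,
        size_factors=pd.Series(sf, index=cm.counts.columns, name="size_factor"),
    )


# ---------------------------------------------------------------------------
# guide-level NB test


def _pooled_dispersion(norm: pd.DataFrame, groups: Sequence[list[str]]) -> float:
    """Moment estimate of the NB dispersion alpha (Var = mu + alpha*mu^2)
    by regressing (s^2 - m) on m^2 through the origin, pooled over guides
    and timepoints with >= 2 replicates; clamped at zero."""
    num = 0.0
    den = 0.0
    used = False
    for cols in groups:
        if len(cols) < 2:
            continue
        used = True
        block = norm[cols].to_numpy()
        m = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        num += float(np.sum((s2 - m) * m**2))
        den += float(np.sum(m**4))
    if not used:
        warnings.warn(
            "single replicate per arm: no replicate scatter to fit dispersion; "
            "falling back to alpha=0 (Poisson)",
            stacklevel=3,
        )
        return 0.0
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def guide_depletion_test(
    cm: CountMatrix, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-guide NB Wald test of day-16 vs day-0 abundance.

    Normalized counts are modeled as NB with a single pooled dispersion
    estimated from replicate scatter. The Wald statistic is the log2 fold
    change over its delta-method standard error; the one-sided depletion p
    is half the two-sided p when the fold change is negative.
    """
    if cm.size_factors is None:
        cm = normalize_counts(cm)
    norm = cm.normalized
    d0, d16 = cm.samples("day0"), cm.samples("day16")
    alpha = _pooled_dispersion(norm, [d0, d16])

    m0 = norm[d0].mean(axis=1).to_numpy()
    m16 = norm[d16].mean(axis=1).to_numpy()
    lfc = np.log2((m16 + pseudocount) / (m0 + pseudocount))

    v0 = (m0 + alpha * m0**2) / len(d0)
    v16 = (m16 + alpha * m16**2) / len(d16)
    ln2 = math.log(2.0)
    se = np.sqrt(v0 / (m0 + pseudocount) ** 2 + v16 / (m16 + pseudocount) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p_two = 2.0 * stats.norm.sf(np.abs(z))
    p_dep = np.where(lfc < 0, p_two / 2.0, 1.0 - p_two / 2.0)

    return pd.DataFrame(
        {
            "guide_id": norm.index,
            "mean_day0": m0,
            "mean_day16": m16,
            "log2fc": lfc,
            "p_two": p_two,
            "p_dep": p_dep,
            "dispersion": alpha,
        }
    ).reset_index(drop=True)


def rank_percentiles(guide_stats: pd.DataFrame) -> pd.Series:
    """Library-wide depletion-rank percentiles (rank by one-sided p,
    average ranks for ties, divided by library size; smaller = more
    depleted)."""
    ranks = stats.rankdata(guide_stats["p_dep"].to_numpy(), method="average")
    return pd.Series(
        ranks / len(ranks), index=guide_stats["guide_id"].to_numpy(), name="percentile"
    )


# ---------------------------------------------------------------------------
# alpha-RRA windows


def _rra_scores(sorted_percentiles: np.ndarray, gate: float) -> np.ndarray:
    """alpha-RRA score for each row of an already-sorted (P, m) matrix.

    Score = min over gated order statistics j of P(Beta(j, m-j+1) <= p_(j));
    rows whose best percentile misses the gate score 1.
    """
    P, m = sorted_percentiles.shape
    j = np.arange(1, m + 1)
    beta_p = stats.beta.cdf(sorted_percentiles, j[None, :], m - j[None, :] + 1)
    beta_p = np.where(sorted_percentiles <= gate, beta_p, np.inf)
    out = beta_p.min(axis=1)
    return np.where(np.isfinite(out), out, 1.0)


def rra_score(percentiles: Sequence[float], gate: float) -> float:
    arr = np.sort(np.asarray(percentiles, dtype=float))[None, :]
    return float(_rra_scores(arr, gate)[0])


def _sample_without_replacement(
    rng: np.random.Generator, n: int, m: int, draws: int
) -> np.ndarray:
    idx = rng.integers(0, n, size=(draws, m))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), m))


def window_permutation_p(
    observed_score: float,
    m: int,
    pool: np.ndarray,
    gate: float,
    n_perm: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | None = None,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> float:
    """P(null window of m library guides scores <= observed).

    Exact enumeration over all C(n, m) guide subsets when that is small
    enough; otherwise seeded Monte Carlo with the +1 correction.
    """
    pool = np.asarray(pool, dtype=float)
    n = len(pool)
    if math.comb(n, m) <= exact_limit:
        null = np.array(
            [*combinations(pool, m)], dtype=float
        )
        null.sort(axis=1)
        scores = _rra_scores(null, gate)
        return float(np.mean(scores <= observed_score + 1e-12))
    if rng is None:
        rng = np.random.default_rng(0)
    idx = _sample_without_replacement(rng, n, m, n_perm)
    null = np.sort(pool[idx], axis=1)
    scores = _rra_scores(null, gate)
    return float((1 + np.sum(scores <= observed_score + 1e-12)) / (n_perm + 1))


def candidate_windows(start: int, end: int, window: int = DEFAULT_WINDOW,
                      offset: int = DEFAULT_OFFSET) -> list[tuple[int, int]]:
    """Sliding windows fully inside [start, end): starts at start + k*offset."""
    return [
        (s, s + window)
        for s in range(start, end - window + 1, offset)
    ]


def window_aggregate(
    region,
    guide_stats: pd.DataFrame,
    percentiles: pd.Series,
    window: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    min_guides: int = DEFAULT_MIN_GUIDES,
    rra_alpha: float = DEFAULT_RRA_ALPHA,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> pd.DataFrame:
    """Score one region's sliding windows.

    ``guide_stats`` must carry ``cut_site`` for the region's guides;
    ``percentiles`` is the library-wide rank-percentile series. Guides are
    assigned to windows by cut-site containment; windows with fewer than
    ``min_guides`` members are dropped. The alpha gate converts the
    guide-level significance cut (one-sided p < rra_alpha) into a
    percentile threshold so observed and permuted windows are scored by the
    same function.
    """
    gate = float(
        (guide_stats["p_dep"] < rra_alpha).mean()
    )  # fraction of the library passing the gate, on the percentile scale
    pool = percentiles.to_numpy()
    in_region = guide_stats[
        (guide_stats["cut_site"] >= region.start)
        & (guide_stats["cut_site"] < region.end)
    ]
    rng = np.random.default_rng(
        [seed, zlib.crc32(region.region_id.encode()) % (2**31)]
    )
    rows = []
    for ws, we in candidate_windows(region.start, region.end, window, offset):
        members = in_region[(in_region["cut_site"] >= ws) & (in_region["cut_site"] < we)]
        if len(members) < min_guides:
            continue
        perc = percentiles.loc[members["guide_id"]].to_numpy()
        score = rra_score(perc, gate)
        p_win = window_permutation_p(
            score, len(perc), pool, gate, n_perm=n_perm, rng=rng,
            exact_limit=exact_limit,
        )
        mean_lfc = float(members["log2fc"].mean())
        rows.append(
            {
                "region_id": region.region_id,
                "chrom": region.chrom,
                "start": ws,
                "end": we,
                "n_guides": len(members),
                "rra_score": score,
                "p_window": p_win,
                "log2fc": mean_lfc,
                "fold_change": 2.0**mean_lfc,
                "guides": ",".join(members["guide_id"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "start", "end", "n_guides", "rra_score",
            "p_window", "log2fc", "fold_change", "guides",
        ],
    )


def summarize_regions(
    windows: pd.DataFrame, regions: Sequence
) -> pd.DataFrame:
    """Best-window summary per region, merging sibling windows of one
    parent element into the single most essential window."""
    parent_of = {}
    for r in regions:
        parent_of[r.region_id] = r.parent_id or r.region_id
    rows = []
    if len(windows):
        windows = windows.assign(
            merged_id=windows["region_id"].map(parent_of)
        )
    groups = windows.groupby("merged_id") if len(windows) else []
    seen = set()
    for merged_id, grp in groups:
        best = grp.sort_values(
            ["p_window", "rra_score", "start"], kind="mergesort"
        ).iloc[0]
        rows.append(
            {
                "region_id": merged_id,
                "neg_score": best["rra_score"],
                "depletion_score": -np.log10(max(best["rra_score"], 1e-300)),
                "p_region": best["p_window"],
                "fold_change": best["fold_change"],
                "representative_window": f"{best['chrom']}:{best['start']}-{best['end']}",
                "merged_parent_id": merged_id,
                "n_windows": len(grp),
                "flagged": False,
            }
        )
        seen.add(merged_id)
    # regions with no qualifying window: p = 1, flagged
    for r in regions:
        mid = parent_of[r.region_id]
        if mid not in seen:
            seen.add(mid)
            rows.append(
                {
                    "region_id": mid,
                    "neg_score": 1.0,
                    "depletion_score": 0.0,
                    "p_region": 1.0,
                    "fold_change": np.nan,
                    "representative_window": "",
                    "merged_parent_id": mid,
                    "n_windows": 0,
                    "flagged": True,
                }
            )
    out = pd.DataFrame(rows).sort_values("region_id").reset_index(drop=True)
    return out


def score_screen(
    cm: CountMatrix,
    manifest: pd.DataFrame,
    regions: Sequence,
    window: int = DEFAULT_WINDOW,
    offset: int = DEFAULT_OFFSET,
    min_guides: int = DEFAULT_MIN_GUIDES,
    rra_alpha: float = DEFAULT_RRA_ALPHA,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> dict:
    """Full scoring pass: normalize, test guides, score windows, summarize.

    Guides flagged ambiguous in the manifest are excluded from window
    statistics. Returns dict with ``guide_stats``, ``windows``,
    ``regions`` DataFrames.
    """
    cm = normalize_counts(cm)
    gstats = guide_depletion_test(cm)
    cols = ["guide_id", "region_id", "cut_site"]
    if "ambiguous" in manifest.columns:
        usable = manifest.loc[~manifest["ambiguous"].astype(bool), cols]
    else:
        usable = manifest[cols]
    gstats = gstats.merge(usable, on="guide_id", how="inner")
    perc = rank_percentiles(gstats)

    window_frames = []
    for region in regions:
        reg_stats = gstats[gstats["region_id"] == region.region_id]
        if reg_stats.empty:
            continue
        wdf = window_aggregate(
            region,
            reg_stats,
            perc,
            window=window,
            offset=offset,
            min_guides=min_guides,
            rra_alpha=rra_alpha,
            n_perm=n_perm,
            seed=seed,
            exact_limit=exact_limit,
        )
        if len(wdf):
            window_frames.append(wdf)
    windows = (
        pd.concat(window_frames, ignore_index=True)
        if window_frames
        else pd.DataFrame(
            columns=[
                "region_id", "chrom", "start", "end", "n_guides", "rra_score",
                "p_window", "log2fc", "fold_change", "guides",
            ]
        )
    )
    region_df = summarize_regions(windows, regions)
    return {"guide_stats": gstats, "windows": windows, "regions": region_df}


# ---------------------------------------------------------------------------
# group ECDF / KS comparison


def group_depletion_comparison(
    groups: Mapping[str, Sequence[float]], grid: Sequence[float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ECDFs of guide depletion p values per group plus pairwise
    two-sample Kolmogorov-Smirnov tests."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 5:
            raise ValueError(f"group {label!r} has fewer than 5 values")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    ecdf_rows = {}
    for label, vals in groups.items():
        arr = np.sort(np.asarray(vals, dtype=float))
        ecdf_rows[label] = np.searchsorted(arr, grid, side="right") / len(arr)
    ecdf = pd.DataFrame({"p": grid, **ecdf_rows})

    ks_rows = []
    labels = list(groups)
    for a, b in combinations(labels, 2):
        res = stats.ks_2samp(groups[a], groups[b], method="asymp")
        ks_rows.append(
            {"group_a": a, "group_b": b, "ks_d": res.statistic, "p": res.pvalue}
        )
    return ecdf, pd.DataFrame(ks_rows)
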