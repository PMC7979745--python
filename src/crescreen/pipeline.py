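"""End-to-end synthetic run: generate, design, screen, score, associate.

One seeded configuration drives every stage, and every stage writes plain
TSV/BED/FASTA tables, so a fixed (config, seed) pair reproduces the output
directory byte-for-byte. This is the entry point the determinism contract
and the worked example are built on.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import design, epigenome, eqtl, scoring, simulate
from .io import write_bed, write_bedgraph, write_fasta, write_tsv


def run_pipeline(
    config: simulate.SimConfig,
    outdir: str | Path,
    n_perm: int = 2000,
    spacing: int = design.DEFAULT_SPACING,
) -> dict:
    """Run every stage on synthetic inputs and write result tables.

    Returns the in-memory results keyed by stage. Files written: genome
    FASTA, regions BED, library manifest TSV, counts TSV, truth TSV, guide
    stats TSV, window stats TSV, region essentiality TSV, signal bedGraph,
    epigenome correlation TSV, cohort TSV, eQTL TSV, co-expression TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, region_bed = simulate.make_genome(config)
    write_fasta(genome, outdir / "genome.fasta")
    write_bed(region_bed, outdir / "regions.bed")

    regions = design.prepare_target_regions(region_bed)
    library, reports = design.design_library(genome, regions, spacing=spacing)
    design.write_library(library, outdir)

    cm, truth = simulate.simulate_screen_counts(library, config)
    write_tsv(cm.counts.reset_index(), outdir / "counts.tsv")
    write_tsv(truth, outdir / "screen_truth.tsv")

    scored = scoring.score_screen(
        cm, library.guides, regions, n_perm=n_perm, seed=config.seed
    )
    write_tsv(_round(scored["guide_stats"]), outdir / "guide_stats.tsv")
    write_tsv(_round(scored["windows"]), outdir / "window_stats.tsv")
    write_tsv(_round(scored["regions"]), outdir / "region_essentiality.tsv")

    region_scores = scored["regions"].set_index("region_id")["depletion_score"]
    aligned = region_scores.reindex(region_bed["name"]).fillna(0.0)
    track = simulate.simulate_signal_track(
        region_bed, aligned.to_numpy(), config.signal_correlation, seed=config.seed
    )
    write_bedgraph(track, outdir / "signal.bedgraph")
    max_sig = epigenome.extract_region_signal(track, region_bed)
    corr = epigenome.correlate_depletion_epigenome(
        aligned.rename(index=dict(zip(region_bed["name"], region_bed["name"]))),
        max_sig.to_frame("signal"),
    )
    write_tsv(_round(corr), outdir / "epigenome_correlation.tsv")

    cohort, cohort_truth = simulate.simulate_cohort(config)
    write_tsv(cohort, outdir / "cohort.tsv")
    eq = eqtl.stratified_eqtl(cohort, "focal")
    eq_df = pd.DataFrame(
        [
            {"stratum": "high", "n": eq["high"].n, "beta": eq["high"].beta,
             "p": eq["high"].p},
            {"stratum": "low", "n": eq["low"].n, "beta": eq["low"].beta,
             "p": eq["low"].p},
            {"stratum": "interaction", "n": len(cohort),
             "beta": eq["interaction"]["beta"], "p": eq["interaction"]["p"]},
        ]
    )
    write_tsv(_round(eq_df), outdir / "eqtl.tsv")
    neighbors = [c for c in cohort.columns if c.startswith("neighbor")]
    coex = eqtl.coexpression_by_stratum(cohort, "focal", neighbors)
    write_tsv(_round(coex), outdir / "coexpression.tsv")

    return {
        "genome": genome,
        "regions": regions,
        "library": library,
        "counts": cm,
        "truth": truth,
        "scored": scored,
        "track": track,
        "epigenome_correlation": corr,
        "cohort": cohort,
        "cohort_truth": cohort_truth,
        "eqtl": eq,
        "coexpression": coex,
    }


def _round(df: pd.DataFrame, digits: int = 10) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(digits)
    return out
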