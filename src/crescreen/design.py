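"""Tiling sgRNA design for cis-regulatory elements.

Candidate discovery scans both strands for 20-nt protospacers adjacent to
an NGG PAM; hard efficiency filters (GC bounds, poly-T, homopolymers) and
exact-match genome-wide specificity counting mark unusable guides; and an
equidistant declustering step picks, for an ideal grid of anchor points
across the region, the passing guide whose predicted cut site lies nearest
each anchor. The goal is uniform coverage of the whole element rather than
clusters at PAM-dense spots — with default 20 bp spacing a saturated
400 bp element yields 20 guides, i.e. five per 100 bp.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import write_fasta, write_tsv

PROTOSPACER_LENGTH = 20
PAM_LENGTH = 3
DEFAULT_SPACING = 20
# vector homology arms flanking the 19-20 nt protospacer in the synthesis oligo
DEFAULT_FLANK5 = "GAAAGGACGAAACACCG"
DEFAULT_FLANK3 = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGC"

REGION_CLASSES = ("rcre", "promoter_control", "insensitive_control")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RiskSNP:
    snp_id: str
    position: int
    odds_ratio: float
    risk_allele: str = "A"

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")


@dataclass
class TargetRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    region_class: str = "rcre"
    locus: str = ""
    snps: list[RiskSNP] = dc_field(default_factory=list)
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.region_id}: end must exceed start")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GuideCandidate:
    protospacer: str
    chrom: str
    start: int  # protospacer interval, 0-based half-open, forward-strand coords
    end: int
    strand: str
    cut_site: int
    region_id: str = ""
    efficiency_pass: bool = True
    fail_reasons: tuple[str, ...] = ()
    genome_matches: int = -1  # -1: not yet counted
    offtarget_annotation_hits: int = 0
    selected: bool = False

    @property
    def passes(self) -> bool:
        return self.efficiency_pass and self.genome_matches == 1


@dataclass
class GuideLibrary:
    guides: pd.DataFrame  # one row per emitted guide (manifest)
    oligos: pd.DataFrame  # guide_id, oligo
    dropped_regions: list[str]
    duplicate_events: list[str]


# ---------------------------------------------------------------------------
# region preparation


def prepare_target_regions(
    intervals: pd.DataFrame,
    tss_table: pd.DataFrame | None = None,
    insensitive_intervals: pd.DataFrame | None = None,
    window: int = 400,
    min_remainder: int = 200,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[TargetRegion]:
    """Split raw elements into tiling windows and add control regions.

    Intervals longer than ``window`` are partitioned into consecutive
    ``window``-bp pieces sharing a parent id (so downstream scoring can
    merge siblings back to the single most essential window). A trailing
    remainder shorter than ``min_remainder`` is absorbed into the previous
    piece; a longer remainder becomes its own short region. Promoter
    controls are ``window`` bp centered on each TSS; insensitive intervals
    pass through as negative controls.
    """
    regions: list[TargetRegion] = []
    for _, row in intervals.iterrows():
        _check_bounds(row, genome_lengths)
        name = row.get("name", f"{row['chrom']}:{row['start']}-{row['end']}")
        locus = str(row.get("locus", ""))
        length = row["end"] - row["start"]
        if length <= window:
            regions.append(
                TargetRegion(
                    region_id=str(name),
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    region_class="rcre",
                    locus=locus,
                )
            )
            continue
        starts = list(range(int(row["start"]), int(row["end"]), window))
        pieces = [[s, min(s + window, int(row["end"]))] for s in starts]
        if len(pieces) > 1 and pieces[-1][1] - pieces[-1][0] < min_remainder:
            pieces[-2][1] = pieces[-1][1]
            pieces.pop()
        for k, (s, e) in enumerate(pieces):
            regions.append(
                TargetRegion(
                    region_id=f"{name}_w{k + 1}",
                    chrom=row["chrom"],
                    start=s,
                    end=e,
                    region_class="rcre",
                    locus=locus,
                    parent_id=str(name),
                )
            )
    if tss_table is not None:
        half = window // 2
        for _, row in tss_table.iterrows():
            tss = int(row["tss"])
            start = tss - half
            if start < 0 or (
                genome_lengths is not None
                and tss + half > genome_lengths.get(row["chrom"], np.inf)
            ):
                raise ValueError(f"TSS {tss} too close to a genome edge")
            regions.append(
                TargetRegion(
                    region_id=f"promoter_{row.get('gene', tss)}",
                    chrom=row["chrom"],
                    start=start,
                    end=tss + half,
                    region_class="promoter_control",
                    locus=str(row.get("locus", "")),
                )
            )
    if insensitive_intervals is not None:
        for i, row in insensitive_intervals.iterrows():
            regions.append(
                TargetRegion(
                    region_id=str(row.get("name", f"insensitive_{i}")),
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    region_class="insensitive_control",
                    locus=str(row.get("locus", "")),
                )
            )
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids after preparation")
    return regions


def _check_bounds(row, genome_lengths) -> None:
    if row["start"] < 0 or row["end"] <= row["start"]:
        raise ValueError(f"malformed interval {dict(row)}")
    if genome_lengths is not None:
        limit = genome_lengths.get(row["chrom"])
        if limit is None or row["end"] > limit:
            raise ValueError(f"interval outside genome bounds: {dict(row)}")


# ---------------------------------------------------------------------------
# candidate discovery


def scan_candidates(region: TargetRegion, genome: Mapping[str, str]) -> list[GuideCandidate]:
    """All protospacer+NGG sites fully inside the region, both strands.

    Cut sites follow the Cas9 blunt cut between protospacer positions 17
    and 18 (3 bp 5' of the PAM); the stored coordinate is the 0-based
    genome position of the base immediately PAM-proximal to the cut.
    """
    seq = genome[region.chrom][region.start : region.end].upper()
    return scan_sequence(seq, offset=region.start, chrom=region.chrom, region_id=region.region_id)


def scan_sequence(
    seq: str, offset: int = 0, chrom: str = "chr", region_id: str = ""
) -> list[GuideCandidate]:
    seq = seq.upper()
    L = PROTOSPACER_LENGTH
    site = L + PAM_LENGTH
    out: list[GuideCandidate] = []
    if len(seq) < site:
        return out
    for i in range(len(seq) - site + 1):
        # forward: [proto 20][N G G]
        if seq[i + L + 1 : i + L + 3] == "GG":
            out.append(
                GuideCandidate(
                    protospacer=seq[i : i + L],
                    chrom=chrom,
                    start=offset + i,
                    end=offset + i + L,
                    strand="+",
                    cut_site=offset + i + L - 3,
                    region_id=region_id,
                )
            )
        # reverse: [C C N][proto 20] on the forward strand
        if seq[i : i + 2] == "CC":
            out.append(
                GuideCandidate(
                    protospacer=reverse_complement(seq[i + 3 : i + site]),
                    chrom=chrom,
                    start=offset + i + 3,
                    end=offset + i + site,
                    strand="-",
                    cut_site=offset + i + 6,
                    region_id=region_id,
                )
            )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# filtering


def _efficiency_check(
    protospacer: str,
    gc_range: tuple[float, float] = (0.20, 0.80),
    max_homopolymer: int = 5,
) -> tuple[bool, tuple[str, ...]]:
    reasons = []
    gc = (protospacer.count("G") + protospacer.count("C")) / len(protospacer)
    if not gc_range[0] <= gc <= gc_range[1]:
        reasons.append("gc_out_of_range")
    if "TTTT" in protospacer:
        reasons.append("polyT")
    if re.search(r"(A{6,}|C{6,}|G{6,}|T{6,})", protospacer):
        reasons.append("homopolymer")
    return (not reasons), tuple(reasons)


def count_genome_matches(protospacer: str, genome: Mapping[str, str]) -> int:
    """Exact (0-mismatch) occurrences of protospacer+NGG, both strands."""
    pat = re.compile("(?=" + re.escape(protospacer) + "[ACGT]GG)")
    total = 0
    for seq in genome.values():
        seq = seq.upper()
        total += len(pat.findall(seq))
        total += len(pat.findall(reverse_complement(seq)))
    return total


def _match_sites(protospacer: str, genome: Mapping[str, str]):
    """Genome intervals (chrom, start, end) of every exact protospacer+NGG site."""
    pat = re.compile("(?=" + re.escape(protospacer) + "[ACGT]GG)")
    site = PROTOSPACER_LENGTH + PAM_LENGTH
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for m in pat.finditer(seq):
            hits.append((chrom, m.start(), m.start() + site))
        rc = reverse_complement(seq)
        n = len(seq)
        for m in pat.finditer(rc):
            hits.append((chrom, n - m.start() - site, n - m.start()))
    return hits


def filter_candidates(
    candidates: Iterable[GuideCandidate],
    genome: Mapping[str, str],
    annotations: pd.DataFrame | None = None,
    gc_range: tuple[float, float] = (0.20, 0.80),
    max_homopolymer: int = 5,
) -> list[GuideCandidate]:
    """Apply efficiency rules and exact-match specificity counting in place.

    A candidate passes overall only if every efficiency rule holds and its
    protospacer+NGG occurs exactly once genome-wide.
    ``offtarget_annotation_hits`` counts non-target exact sites overlapping
    the provided exon/open-chromatin intervals.
    """
    candidates = list(candidates)
    match_cache: dict[str, list] = {}
    for cand in candidates:
        ok, reasons = _efficiency_check(cand.protospacer, gc_range, max_homopolymer)
        cand.efficiency_pass = ok
        cand.fail_reasons = reasons
        if cand.protospacer not in match_cache:
            match_cache[cand.protospacer] = _match_sites(cand.protospacer, genome)
        sites = match_cache[cand.protospacer]
        cand.genome_matches = len(sites)
        if cand.genome_matches == 0:
            raise ValueError(
                f"candidate {cand.protospacer} absent from genome: "
                "genome/index mismatch"
            )
        if annotations is not None:
            own = {(cand.chrom, min(cand.start, cand.end - PROTOSPACER_LENGTH))}
            hits = 0
            for chrom, s, e in sites:
                if cand.chrom == chrom and s <= cand.start < e:
                    continue  # the on-target site itself
                ann = annotations[annotations["chrom"] == chrom]
                if ((ann["start"] < e) & (ann["end"] > s)).any():
                    hits += 1
            cand.offtarget_annotation_hits = hits
    return candidates


# ---------------------------------------------------------------------------
# equidistant declustering


def select_tiling(
    candidates: Sequence[GuideCandidate],
    region: TargetRegion,
    spacing: int = DEFAULT_SPACING,
) -> tuple[list[GuideCandidate], dict]:
    """Pick passing guides nearest an equidistant grid of anchor points.

    Anchors sit at the centers of consecutive ``spacing``-bp bins across
    the region ([start + spacing/2, start + 3*spacing/2, ...)); each anchor
    is matched to the unused passing candidate with the nearest cut site by
    a minimum-total-distance assignment, which makes the result independent
    of candidate input order. Ties are broken toward the smaller genomic
    coordinate, then the lexicographically smaller protospacer.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    passing = [c for c in candidates if c.passes]
    report = {
        "region_id": region.region_id,
        "n_candidates": len(list(candidates)),
        "n_passing": len(passing),
        "spacing": spacing,
    }
    if not passing:
        report["warning"] = "no passing candidates"
        report["n_selected"] = 0
        report["per_100bp"] = 0.0
        return [], report

    n_anchors = max(1, region.length // spacing)
    anchors = np.array(
        [region.start + k * spacing + spacing // 2 for k in range(n_anchors)],
        dtype=float,
    )
    # canonical candidate order implements the tie-break deterministically
    passing.sort(key=lambda c: (c.cut_site, c.protospacer, c.strand))
    cuts = np.array([c.cut_site for c in passing], dtype=float)
    cost = np.abs(anchors[:, None] - cuts[None, :])
    cost = cost + np.arange(len(passing))[None, :] * 1e-9
    rows, cols = linear_sum_assignment(cost)
    selected = sorted((passing[j] for j in cols), key=lambda c: c.cut_site)
    for c in selected:
        c.selected = True
    report["n_selected"] = len(selected)
    report["per_100bp"] = round(len(selected) / region.length * 100.0, 4)
    return selected, report


# ---------------------------------------------------------------------------
# library emission


def emit_library(
    selected_by_region: Mapping[str, Sequence[GuideCandidate]],
    regions: Mapping[str, TargetRegion],
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> GuideLibrary:
    """Assemble the synthesis manifest: oligo = flank5 + protospacer + flank3.

    Protospacers appearing in more than one region are emitted once and
    flagged ambiguous (such guides are excluded from window statistics by
    default); regions left with no guides are reported as dropped.
    """
    for fl in (flank5, flank3):
        if re.fullmatch("[ACGT]+", fl) is None:
            raise ValueError("flanks must be fixed ACGT strings")
    seen: dict[str, int] = {}
    rows = []
    dropped = []
    duplicates = []
    counter = 0
    for region_id in sorted(selected_by_region):
        guides = selected_by_region[region_id]
        region = regions[region_id]
        if not guides:
            dropped.append(region_id)
            continue
        for cand in guides:
            if cand.protospacer in seen:
                duplicates.append(
                    f"{cand.protospacer} in {region_id} duplicates guide "
                    f"#{seen[cand.protospacer]}; emitted once, flagged ambiguous"
                )
                rows[seen[cand.protospacer]]["ambiguous"] = True
                continue
            seen[cand.protospacer] = len(rows)
            counter += 1
            rows.append(
                {
                    "guide_id": f"g{counter:05d}",
                    "region_id": region_id,
                    "region_class": region.region_class,
                    "locus": region.locus,
                    "chrom": cand.chrom,
                    "start": cand.start,
                    "end": cand.end,
                    "strand": cand.strand,
                    "cut_site": cand.cut_site,
                    "protospacer": cand.protospacer,
                    "oligo": flank5 + cand.protospacer + flank3,
                    "ambiguous": False,
                }
            )
    manifest = pd.DataFrame(rows)
    oligos = manifest[["guide_id", "oligo"]].copy() if rows else pd.DataFrame(
        columns=["guide_id", "oligo"]
    )
    return GuideLibrary(
        guides=manifest,
        oligos=oligos,
        dropped_regions=dropped,
        duplicate_events=duplicates,
    )


def design_library(
    genome: Mapping[str, str],
    regions: Sequence[TargetRegion],
    annotations: pd.DataFrame | None = None,
    spacing: int = DEFAULT_SPACING,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> tuple[GuideLibrary, list[dict]]:
    """End-to-end design: scan, filter, decluster and emit for each region."""
    selected = {}
    reports = []
    region_map = {r.region_id: r for r in regions}
    for region in regions:
        cands = scan_candidates(region, genome)
        filter_candidates(cands, genome, annotations=annotations)
        sel, rep = select_tiling(cands, region, spacing=spacing)
        selected[region.region_id] = sel
        reports.append(rep)
    library = emit_library(selected, region_map, flank5=flank5, flank3=flank3)
    return library, reports


# ---------------------------------------------------------------------------
# serialization


def write_library(library: GuideLibrary, outdir: str | Path, stem: str = "library") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = write_tsv(library.guides, outdir / f"{stem}_manifest.tsv")
    fasta_path = write_fasta(
        dict(zip(library.oligos["guide_id"], library.oligos["oligo"])),
        outdir / f"{stem}_oligos.fasta",
    )
    report = {
        "dropped_regions": library.dropped_regions,
        "duplicate_events": library.duplicate_events,
        "n_guides": int(len(library.guides)),
    }
    report_path = outdir / f"{stem}_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return {"manifest": manifest_path, "oligos": fasta_path, "report": report_path}


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protospacer": str, "oligo": str})
    df["ambiguous"] = df["ambiguous"].astype(bool)
    if "locus" in df.columns:
        df["locus"] = df["locus"].fillna("").astype(str)
    return df
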