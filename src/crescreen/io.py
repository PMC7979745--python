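"""Readers and writers for the small text formats the pipeline speaks.

All genomic intervals are 0-based, half-open (BED convention) both in
memory and on disk. FASTA handling is delegated to Biopython; tables are
pandas round-trips with stable column order so outputs are diffable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    """Write ``{name: sequence}`` to an uppercase single-line-wrap FASTA."""
    path = Path(path)
    records = [
        SeqRecord(Seq(str(seq).upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals: pd.DataFrame, path: str | Path) -> Path:
    """Write a 6-column BED. Missing score/strand columns are filled."""
    df = intervals.copy()
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    if "name" not in df.columns:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    df = df[BED_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    _check_intervals(df)
    return df


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> Path:
    track[BEDGRAPH_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BEDGRAPH_COLUMNS, comment="#"
    )
    _check_intervals(df)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return Path(path)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def _check_intervals(df: pd.DataFrame) -> None:
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]]
        raise ValueError(f"malformed intervals (end <= start): {bad.head()}")


def reads_from_source(source) -> Iterable[str]:
    """Yield read sequences from a FASTA/FASTQ path, handle, or iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix in {".fq", ".fastq"} else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    elif isinstance(source, _io.IOBase):
        for rec in SeqIO.parse(source, "fasta"):
            yield str(rec.seq).upper()
    else:
        for read in source:
            yield str(read).upper()
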