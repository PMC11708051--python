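"""Minimal GFF3 / FASTA table access shared by the genome-context modules.

GFF3 files are consumed as plain tab tables (coordinates 1-based inclusive
throughout the package); FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a frame with an extracted ``feature_id`` column
    (the ID attribute) and ``parent_id`` (the Parent attribute, if any)."""
    df = pd.read_csv(
        path, sep="\t", names=GFF_COLUMNS, comment="#", header=None,
        dtype={"seqid": str, "type": str, "attributes": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["feature_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    df["parent_id"] = df["attributes"].str.extract(r"Parent=([^;]+)")
    return df


def contig_lengths_from_fasta(path: str | Path) -> pd.Series:
    """Contig id -> length (bp) from a FASTA file."""
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return pd.Series(lengths, name="length", dtype=int)


def read_contigs_tsv(path: str | Path) -> pd.DataFrame:
    """Contig table alternative to FASTA for worlds where sequence content
    is not materialized: columns contig_id, genome_id, length."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "genome_id": str})
    df["length"] = df["length"].astype(int)
    return df


def bed_to_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED file of intervals, converting 0-based half-open to the
    package's 1-based inclusive convention."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["seqid", "start", "end"], dtype={"seqid": str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df
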