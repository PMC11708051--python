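"""Intron gains in horizontally acquired genes and their native origins.

Prokaryotic donor genes carry no spliceosomal introns, so any intron in a
prokaryote-derived gene is a post-transfer gain.  Three questions are asked
of a call set:

* what fraction of foreign genes gained at least one intron;
* can a gained intron's sequence be traced to the recipient's own genome
  (a seed-and-extend search; a hit covering more than half the intron
  counts as a found origin);
* do intron-bearing foreign genes run higher in expression than intronless
  ones, dataset by dataset.

Coordinates are 1-based inclusive; intron *i* spans
``exon_i.end + 1 .. exon_{i+1}.start − 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FOREIGN_RECIPIENT = "FOREIGN_RECIPIENT"
DONOR_HOMOLOG = "DONOR_HOMOLOG"
NATIVE = "NATIVE"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneStructure:
    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    gene_class: str = NATIVE

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def gene_length(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1

    @property
    def intron_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.introns]


@dataclass
class IntronOriginHit:
    intron_id: str
    target_contig: str
    coverage: float  # fraction of intron length aligned
    identity: float  # percent matches over aligned columns
    strand: str
    score: int = 0

    @property
    def origin_found(self) -> bool:
        return self.coverage > 0.5


# ----------------------------------------------------------- structures

def derive_introns(
    exon_rows: pd.DataFrame,
    gene_class: dict[str, str] | None = None,
) -> tuple[dict[str, GeneStructure], dict]:
    """Build gene structures from exon rows and summarize intron gains.

    ``exon_rows`` needs columns gene_id, contig_id, strand, start, end (one
    row per exon).  Genes with overlapping exons are skipped with a log
    entry.  The gain summary covers FOREIGN_RECIPIENT genes: the fraction
    carrying at least one intron (all introns in prokaryote-derived genes
    being gains by construction) and the total intron count.
    """
    gene_class = gene_class or {}
    structures: dict[str, GeneStructure] = {}
    skipped = []
    for gene_id, grp in exon_rows.groupby("gene_id", sort=True):
        exons = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        ok = all(exons[i][1] < exons[i + 1][0] for i in range(len(exons) - 1))
        if not ok:
            log.warning("gene %s has overlapping exons; skipped", gene_id)
            skipped.append(gene_id)
            continue
        structures[gene_id] = GeneStructure(
            gene_id=str(gene_id),
            contig_id=str(grp["contig_id"].iloc[0]),
            strand=str(grp["strand"].iloc[0]),
            exons=exons,
            gene_class=gene_class.get(gene_id, NATIVE),
        )
    foreign = [s for s in structures.values() if s.gene_class == FOREIGN_RECIPIENT]
    with_introns = sum(1 for s in foreign if s.introns)
    summary = {
        "n_foreign": len(foreign),
        "n_foreign_with_introns": with_introns,
        "gain_fraction": (with_introns / len(foreign)) if foreign else float("nan"),
        "total_introns": sum(len(s.introns) for s in foreign),
        "skipped_genes": skipped,
    }
    return structures, summary


# ------------------------------------------------------- origin search

def _extend(query: str, target: str, qpos: int, tpos: int, k: int,
            match: int, mismatch: int, xdrop: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension around an exact k-mer seed.

    Returns (query_start, query_end_exclusive, score, n_matches)."""
    score = k * match
    matches = k
    # right extension
    best = score
    best_right = qpos + k
    best_m = matches
    i, j, cur, m = qpos + k, tpos + k, score, matches
    while i < len(query) and j < len(target):
        if query[i] == target[j]:
            cur += match
            m += 1
        else:
            cur += mismatch
        if cur > best:
            best, best_right, best_m = cur, i + 1, m
        if cur < best - xdrop:
            break
        i += 1
        j += 1
    # left extension
    score, matches = best, best_m
    best2 = score
    best_left = qpos
    best_m2 = matches
    i, j, cur, m = qpos - 1, tpos - 1, score, matches
    while i >= 0 and j >= 0:
        if query[i] == target[j]:
            cur += match
            m += 1
        else:
            cur += mismatch
        if cur > best2:
            best2, best_left, best_m2 = cur, i, m
        if cur < best2 - xdrop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, best2, best_m2


def _index_kmers(target: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        idx.setdefault(target[i:i + k], []).append(i)
    return idx


def intron_origin_search(
    intron_seq: str,
    genome: dict[str, str] | str,
    intron_id: str = "intron",
    k: int = 7,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 6,
    _index: dict | None = None,
) -> IntronOriginHit | None:
    """Best local ungapped hit of an intron against a native genome.

    Exact k-mer seeds on both strands are extended ungapped under the
    +1/−2 scoring with X-drop; seeds on the same (strand, diagonal) are
    collapsed to their first occurrence.  The best-scoring hit is converted
    to coverage (aligned intron positions / intron length) and identity
    (matches / aligned columns).  Deterministic; returns None when no seed
    matches or the genome is shorter than ``k``.

    ``_index`` may carry a precomputed k-mer index (from
    :func:`build_genome_index`) to amortize repeated searches.
    """
    contigs = {"genome": genome} if isinstance(genome, str) else genome
    intron_seq = intron_seq.upper()
    if len(intron_seq) < k:
        return None
    best_hit: IntronOriginHit | None = None
    for contig_id in sorted(contigs):
        target = contigs[contig_id].upper()
        if len(target) < k:
            continue
        if _index is not None and contig_id in _index:
            idx = _index[contig_id]
        else:
            idx = _index_kmers(target, k)
        for strand, query in (("+", intron_seq), ("-", revcomp(intron_seq))):
            seen_diag: set[int] = set()
            for qpos in range(len(query) - k + 1):
                for tpos in idx.get(query[qpos:qpos + k], ()):
                    diag = tpos - qpos
                    if diag in seen_diag:
                        continue
                    seen_diag.add(diag)
                    qs, qe, score, m = _extend(
                        query, target, qpos, tpos, k, match, mismatch, xdrop
                    )
                    if best_hit is None or score > best_hit.score:
                        aligned = qe - qs
                        best_hit = IntronOriginHit(
                            intron_id=intron_id,
                            target_contig=contig_id,
                            coverage=aligned / len(intron_seq),
                            identity=100.0 * m / aligned,
                            strand=strand,
                            score=score,
                        )
    return best_hit


def build_genome_index(genome: dict[str, str], k: int = 7) -> dict[str, dict]:
    """Precompute per-contig k-mer indexes for repeated origin searches."""
    return {cid: _index_kmers(seq.upper(), k) for cid, seq in genome.items()}


# --------------------------------------------------------- comparisons

def length_statistics(structures: dict[str, GeneStructure]) -> pd.DataFrame:
    """Per-class mean CDS length, gene length and intron length (bp).

    Classes with no genes get NaN means; classes with no introns get a NaN
    intron mean.
    """
    rows = {}
    for cls in (DONOR_HOMOLOG, FOREIGN_RECIPIENT, NATIVE):
        members = [s for s in structures.values() if s.gene_class == cls]
        introns = [l for s in members for l in s.intron_lengths]
        rows[cls] = {
            "n_genes": len(members),
            "mean_cds_length": float(np.mean([s.cds_length for s in members]))
            if members else float("nan"),
            "mean_gene_length": float(np.mean([s.gene_length for s in members]))
            if members else float("nan"),
            "mean_intron_length": float(np.mean(introns)) if introns else float("nan"),
        }
    return pd.DataFrame(rows).T


def expression_compare(
    expression: pd.DataFrame,
    has_intron: dict[str, bool],
) -> tuple[pd.DataFrame, float]:
    """Compare mean expression of intron-bearing vs intronless HGT genes
    within each dataset.

    ``expression`` needs columns gene_id, dataset_id, value (FPKM-like,
    >= 0); only genes present in ``has_intron`` are compared.  A dataset
    missing one of the two groups is excluded (logged) and the denominator
    adjusts.  Returns the per-dataset table and the percentage of datasets
    where the intron-bearing mean is strictly higher.
    """
    expr = expression[expression["gene_id"].isin(has_intron)]
    rows = []
    for ds, grp in expr.groupby("dataset_id", sort=True):
        intron_mask = grp["gene_id"].map(has_intron)
        with_i = grp.loc[intron_mask, "value"]
        without = grp.loc[~intron_mask, "value"]
        if with_i.empty or without.empty:
            log.warning("dataset %s lacks one intron group; excluded", ds)
            continue
        rows.append({
            "dataset_id": ds,
            "mean_with_introns": float(with_i.mean()),
            "mean_without_introns": float(without.mean()),
            "intron_higher": bool(with_i.mean() > without.mean()),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table, float("nan")
    fraction = 100.0 * table["intron_higher"].mean()
    return table, float(fraction)
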