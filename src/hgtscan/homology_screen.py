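"""Similarity-based HGT candidate screening.

Works on taxonomically annotated homology hit tables (the 12-column tabular
hit format plus a ``subject_species`` column).  Three per-gene statistics are
computed:

* **Alien Index (AI)** — ``ln(bbh_in + f) - ln(bbh_out + f)`` where
  ``bbh_in`` / ``bbh_out`` are the best (smallest) E-values among non-self
  ingroup / outgroup hits, ``f`` is a pseudo-count floor, and a missing side
  takes the parse-time E-value cutoff (1.0).  AI > 0 means the best outgroup
  (putative donor) hit is strictly better than the best ingroup hit.
* **outg_pct** — percentage of outgroup species among the top distinct
  non-self subject species (at most ``top_n_species``), walking hits in rank
  order and keeping the first occurrence of each species.
* **LPI** — a lineage-coherence score in [0, 1]: the bitscore-weighted mean,
  over non-self hits within ``bitscore_window`` of the best bitscore, of the
  fraction of lineage ranks each hit species shares with the recipient.
  Genes whose strongest homologs are taxonomically typical for the recipient
  score near 1; genes whose strongest homologs sit in another domain score
  near 0.

A gene is a candidate iff its LPI falls in the lowest ``lpi_percentile`` of
the genome, AI > 0, and outg_pct > 80 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import GroupLabel, TaxonomyDB, classify_species, shared_rank_fraction

#: 12 standard tabular hit columns + subject_species
HIT_COLUMNS = [
    "query_gene_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
    "subject_species",
]

EVALUE_CUTOFF = 1.0


@dataclass
class ScreenConfig:
    """Thresholds and conventions for candidate screening."""

    pseudo_evalue_floor: float = 1e-200
    missing_hit_evalue: float = 1.0
    top_n_species: int = 200
    ai_threshold: float = 0.0
    outg_threshold: float = 80.0  # percent
    lpi_percentile: float = 10.0  # percent, per genome
    bitscore_window: float = 0.10

    def __post_init__(self) -> None:
        if self.top_n_species < 1:
            raise ValueError("top_n_species must be >= 1")
        for name in ("pseudo_evalue_floor", "missing_hit_evalue", "outg_threshold",
                     "lpi_percentile", "bitscore_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class HitTableError(ValueError):
    """Malformed hit-table row."""


def read_hit_table(
    path: str | Path,
    taxonomy: TaxonomyDB,
) -> tuple[pd.DataFrame, int]:
    """Read an extended tabular hit file (gzip accepted by suffix).

    Rows with E-value above the global cutoff of 1 are dropped; the count of
    dropped rows is returned alongside the table.  Hits are sorted per gene
    by ascending E-value then descending bitscore and given a ``rank``
    column.  Every subject species must be present in the taxonomy.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", names=HIT_COLUMNS, header=None, comment="#",
            dtype={"query_gene_id": str, "subject_id": str, "subject_species": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise HitTableError(f"malformed hit table {path}: {exc}") from exc
    if df.empty:
        df = pd.DataFrame(columns=HIT_COLUMNS)
        df["rank"] = pd.Series(dtype=int)
        return df, 0
    if df["evalue"].isna().any() or df["bitscore"].isna().any():
        bad = int(df.index[df["evalue"].isna() | df["bitscore"].isna()][0]) + 1
        raise HitTableError(f"malformed hit table {path}: non-numeric row at line {bad}")
    taxonomy.validate(df["subject_species"].unique())
    n_dropped = int((df["evalue"] > EVALUE_CUTOFF).sum())
    df = df[df["evalue"] <= EVALUE_CUTOFF]
    df = df.sort_values(
        ["query_gene_id", "evalue", "bitscore"],
        ascending=[True, True, False],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("query_gene_id").cumcount()
    return df, n_dropped


# --------------------------------------------------------------------------
# per-gene statistics (operate on the hits of one gene)
# --------------------------------------------------------------------------

def _labels(hits: pd.DataFrame, taxonomy: TaxonomyDB, recipient: str) -> pd.Series:
    return hits["subject_species"].map(
        lambda sp: classify_species(taxonomy, sp, recipient)
    )


def alien_index(
    hits: pd.DataFrame,
    taxonomy: TaxonomyDB,
    recipient: str,
    cfg: ScreenConfig | None = None,
) -> float:
    """Alien Index for one gene's hits; NaN when no hits are retained."""
    cfg = cfg or ScreenConfig()
    if hits.empty:
        return float("nan")
    lab = _labels(hits, taxonomy, recipient)
    f = cfg.pseudo_evalue_floor
    ev_in = hits.loc[lab == GroupLabel.INGROUP, "evalue"].min()
    ev_out = hits.loc[lab == GroupLabel.OUTGROUP, "evalue"].min()
    if np.isnan(ev_in) and np.isnan(ev_out):
        return float("nan")
    bbh_in = cfg.missing_hit_evalue if np.isnan(ev_in) else ev_in
    bbh_out = cfg.missing_hit_evalue if np.isnan(ev_out) else ev_out
    return float(np.log(bbh_in + f) - np.log(bbh_out + f))


def outgroup_percentage(
    hits: pd.DataFrame,
    taxonomy: TaxonomyDB,
    recipient: str,
    cfg: ScreenConfig | None = None,
) -> float:
    """Percent outgroup among the top distinct non-self species; NaN when no
    non-self species occur."""
    cfg = cfg or ScreenConfig()
    if hits.empty:
        return float("nan")
    lab = _labels(hits, taxonomy, recipient)
    sub = hits[lab != GroupLabel.SELF]
    if sub.empty:
        return float("nan")
    sub = sub.sort_values("rank", kind="mergesort").drop_duplicates("subject_species")
    sub = sub.head(cfg.top_n_species)
    is_out = sub["subject_species"].map(
        lambda sp: classify_species(taxonomy, sp, recipient) == GroupLabel.OUTGROUP
    )
    return float(100.0 * is_out.mean())


def lpi_score(
    hits: pd.DataFrame,
    taxonomy: TaxonomyDB,
    recipient: str,
    cfg: ScreenConfig | None = None,
) -> float:
    """Lineage-coherence score in [0, 1]; NaN when no windowed hits exist."""
    cfg = cfg or ScreenConfig()
    if hits.empty:
        return float("nan")
    lab = _labels(hits, taxonomy, recipient)
    sub = hits[lab != GroupLabel.SELF]
    if sub.empty:
        return float("nan")
    best = sub["bitscore"].max()
    win = sub[sub["bitscore"] >= (1.0 - cfg.bitscore_window) * best]
    s = win["subject_species"].map(
        lambda sp: shared_rank_fraction(taxonomy, sp, recipient)
    )
    w = win["bitscore"]
    return float((s * w).sum() / w.sum())


# --------------------------------------------------------------------------
# genome-scale scoring (vectorized; one pass over the whole hit table)
# --------------------------------------------------------------------------

def score_genome(
    hits: pd.DataFrame,
    taxonomy: TaxonomyDB,
    recipient: str,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Compute AI, outg_pct, LPI and n_hits_used for every gene in a
    genome's hit table (as returned by :func:`read_hit_table`).

    Returns a frame indexed by gene_id.  Candidate flags are added later by
    :func:`screen_candidates`, which needs the genome-wise LPI percentile.
    """
    cfg = cfg or ScreenConfig()
    if hits.empty:
        return pd.DataFrame(
            columns=["AI", "outg_pct", "lpi", "n_hits_used"]
        ).rename_axis("gene_id")

    species = pd.unique(hits["subject_species"])
    label_map = {sp: classify_species(taxonomy, sp, recipient) for sp in species}
    sfrac_map = {sp: shared_rank_fraction(taxonomy, sp, recipient) for sp in species}
    lab = hits["subject_species"].map(label_map)

    genes = pd.Index(pd.unique(hits["query_gene_id"]), name="gene_id")
    f = cfg.pseudo_evalue_floor

    bbh_in = (
        hits.loc[lab == GroupLabel.INGROUP]
        .groupby("query_gene_id")["evalue"].min()
        .reindex(genes)
    )
    bbh_out = (
        hits.loc[lab == GroupLabel.OUTGROUP]
        .groupby("query_gene_id")["evalue"].min()
        .reindex(genes)
    )
    has_any = ~(bbh_in.isna() & bbh_out.isna())
    ai = (
        np.log(bbh_in.fillna(cfg.missing_hit_evalue) + f)
        - np.log(bbh_out.fillna(cfg.missing_hit_evalue) + f)
    ).where(has_any)

    nonself = hits[lab != GroupLabel.SELF]
    dedup = nonself.sort_values("rank", kind="mergesort").drop_duplicates(
        ["query_gene_id", "subject_species"]
    )
    dedup = dedup[dedup.groupby("query_gene_id").cumcount() < cfg.top_n_species]
    is_out = dedup["subject_species"].map(label_map) == GroupLabel.OUTGROUP
    outg = (
        100.0
        * is_out.groupby(dedup["query_gene_id"]).mean().reindex(genes)
    )

    best = nonself.groupby("query_gene_id")["bitscore"].transform("max")
    win = nonself[nonself["bitscore"] >= (1.0 - cfg.bitscore_window) * best]
    s = win["subject_species"].map(sfrac_map)
    w = win["bitscore"]
    num = (s * w).groupby(win["query_gene_id"]).sum()
    den = w.groupby(win["query_gene_id"]).sum()
    lpi = (num / den).reindex(genes)

    n_used = hits.groupby("query_gene_id").size().reindex(genes).fillna(0).astype(int)

    return pd.DataFrame(
        {"AI": ai, "outg_pct": outg, "lpi": lpi, "n_hits_used": n_used}
    )


def screen_candidates(
    scores: pd.DataFrame, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Flag candidates over a whole genome's score table.

    ``candidate`` is True iff LPI is at or below the genome-wise
    ``lpi_percentile`` quantile (ties at the boundary included, to err
    toward recall), AI strictly exceeds ``ai_threshold`` and outg_pct
    strictly exceeds ``outg_threshold``.  Genes with undefined scores are
    never candidates.
    """
    cfg = cfg or ScreenConfig()
    out = scores.copy()
    defined = out["lpi"].dropna()
    if defined.empty:
        out["candidate"] = False
        return out
    cut = float(np.percentile(defined, cfg.lpi_percentile))
    out["candidate"] = (
        (out["lpi"] <= cut)
        & (out["AI"] > cfg.ai_threshold)
        & (out["outg_pct"] > cfg.outg_threshold)
    ).fillna(False)
    return out


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-genome score table (gene_id, AI, outg_pct, lpi,
    n_hits_used, candidate) as TSV."""
    scores.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")
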