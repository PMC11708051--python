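"""Contig-scale filters and validation-style distribution comparisons.

Two genome-context rules guard the HGT call set against assembly artifacts:

* only genes on contigs **longer than** ``min_contig_bp`` (default 100 kb)
  enter the analysis at all — small fragments are where contaminant
  sequences concentrate;
* after phylogenetic confirmation, any contig whose gene content is at
  least ``contamination_fraction`` (default 50%) confirmed-HGT is treated
  as a contaminant contig (a stretch of foreign organism in the assembly,
  not transfer) and all its calls are dropped.

The module also provides the rank-sum machinery and descriptive
distribution comparisons used to sanity-check a call set: contig lengths
with vs without HGT, per-contig HGT proportion, and hit-identity
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FilterConfig:
    min_contig_bp: int = 100_000
    contamination_fraction: float = 0.50
    sweep_fractions: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.10, 0.81, 0.10), 2))
    )

    def __post_init__(self) -> None:
        if not (0 < self.contamination_fraction <= 1):
            raise ValueError("contamination_fraction must be in (0, 1]")


class OrphanGeneError(ValueError):
    pass


def filter_genes_by_contig(
    genes: pd.DataFrame,
    contigs: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Retain genes on contigs strictly longer than ``min_contig_bp``.

    ``genes`` needs columns gene_id, contig_id; ``contigs`` needs
    contig_id, length.  Returns the retained gene rows and a summary with
    retained / total counts and their ratio.
    """
    cfg = cfg or FilterConfig()
    lengths = contigs.set_index("contig_id")["length"]
    mapped = genes["contig_id"].map(lengths)
    if mapped.isna().any():
        orphan = genes.loc[mapped.isna(), "gene_id"].iloc[0]
        raise OrphanGeneError(f"gene {orphan!r} maps to no known contig")
    retained = genes[mapped > cfg.min_contig_bp]
    total = len(genes)
    summary = {
        "n_total": total,
        "n_retained": len(retained),
        "ratio": (len(retained) / total) if total else float("nan"),
    }
    return retained, summary


def contamination_filter(
    confirmed: set[str],
    genes: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[set[str], list[str]]:
    """Drop HGT calls on contigs whose confirmed-HGT gene fraction is at
    least ``contamination_fraction`` (inclusive boundary).

    Returns (cleaned confirmed set, discarded contig ids).
    """
    cfg = cfg or FilterConfig()
    is_hgt = genes["gene_id"].isin(confirmed)
    per_contig = genes.assign(is_hgt=is_hgt).groupby("contig_id")["is_hgt"].agg(
        ["sum", "size"]
    )
    frac = per_contig["sum"] / per_contig["size"]
    discarded = sorted(frac.index[frac >= cfg.contamination_fraction])
    bad_genes = set(genes.loc[genes["contig_id"].isin(discarded), "gene_id"])
    return confirmed - bad_genes, discarded


def contamination_sweep(
    confirmed: set[str], genes: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Retained-HGT counts across the configured threshold sweep."""
    cfg = cfg or FilterConfig()
    rows = []
    for f in cfg.sweep_fractions:
        sub = FilterConfig(
            min_contig_bp=cfg.min_contig_bp, contamination_fraction=float(f)
        )
        cleaned, discarded = contamination_filter(confirmed, genes, sub)
        rows.append(
            {"fraction": float(f), "n_retained_hgt": len(cleaned),
             "n_discarded_contigs": len(discarded)}
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- rank tests

def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney by enumerating all assignments, with midranks.

    Two-sided p doubles the smaller tail of the permutation distribution of
    U (capped at 1)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n2 = len(a), len(b)
    n = n1 + n2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = comb(n, n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return float(u_obs), float(min(p, 1.0))


def rank_sum_compare(sample_a, sample_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) with midrank ties.

    Exact enumeration when both samples have at most 8 observations; the
    normal approximation with continuity correction otherwise.  Returns
    (U for sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_compare requires two non-empty samples")
    if a.size <= 8 and b.size <= 8:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------ TE distance

def nearest_te_distance(
    genes: pd.DataFrame, te_intervals: pd.DataFrame
) -> pd.Series:
    """Distance (bp) from each gene to its closest transposable element.

    ``genes``: gene_id, contig_id, start, end (1-based inclusive);
    ``te_intervals``: contig column (``contig_id`` or ``seqid``), start, end.
    Overlap gives 0; otherwise the gap length; genes on TE-free contigs get
    NaN (excluded from comparisons).
    """
    te = te_intervals.rename(columns={"seqid": "contig_id"})
    out = pd.Series(np.nan, index=genes["gene_id"].to_numpy(), name="te_distance")
    te_by_contig = {c: g for c, g in te.groupby("contig_id")}
    for contig, grp in genes.groupby("contig_id"):
        tes = te_by_contig.get(contig)
        if tes is None or tes.empty:
            continue
        ts = tes["start"].to_numpy()[None, :]
        te_ = tes["end"].to_numpy()[None, :]
        gs = grp["start"].to_numpy()[:, None]
        ge = grp["end"].to_numpy()[:, None]
        gap_right = ts - ge - 1  # TE downstream of gene
        gap_left = gs - te_ - 1  # TE upstream of gene
        dist = np.maximum(np.maximum(gap_right, gap_left), 0)
        dist[(ts <= ge) & (te_ >= gs)] = 0
        out.loc[grp["gene_id"].to_numpy()] = dist.min(axis=1)
    return out


# ------------------------------------------------------------- summaries

def validation_summaries(
    confirmed: set[str],
    genes: pd.DataFrame,
    contigs: pd.DataFrame,
    hit_identity: pd.Series | None = None,
) -> dict:
    """Descriptive comparisons supporting a call set.

    Emits contig-length samples for contigs with vs without confirmed HGT,
    the per-contig HGT proportion distribution, and (when best non-ingroup
    hit identities are supplied, indexed by gene_id) the identity
    distribution of HGT vs non-HGT genes — each with its rank-sum p.
    """
    report: dict = {"applicable": bool(confirmed)}
    is_hgt = genes["gene_id"].isin(confirmed)
    hgt_contigs = set(genes.loc[is_hgt, "contig_id"])
    lengths = contigs.set_index("contig_id")["length"]
    with_hgt = lengths[lengths.index.isin(hgt_contigs)]
    without = lengths[~lengths.index.isin(hgt_contigs)]
    report["contig_length"] = {
        "with_hgt": with_hgt.to_numpy(),
        "without_hgt": without.to_numpy(),
    }
    if confirmed and len(with_hgt) and len(without):
        u, p = rank_sum_compare(with_hgt, without)
        report["contig_length"]["p"] = p
        report["contig_length"]["median_with"] = float(np.median(with_hgt))
        report["contig_length"]["median_without"] = float(np.median(without))

    per = genes.assign(is_hgt=is_hgt).groupby("contig_id")["is_hgt"].agg(
        ["sum", "size"]
    )
    per = per[per["sum"] > 0]
    report["per_contig_hgt_proportion"] = (per["sum"] / per["size"]).to_numpy()
    if len(per):
        report["mean_hgt_proportion"] = float(
            (per["sum"] / per["size"]).mean()
        )

    if hit_identity is not None and confirmed:
        ident_hgt = hit_identity[hit_identity.index.isin(confirmed)].dropna()
        ident_other = hit_identity[~hit_identity.index.isin(confirmed)].dropna()
        report["identity"] = {
            "hgt": ident_hgt.to_numpy(),
            "non_hgt": ident_other.to_numpy(),
        }
        if len(ident_hgt) and len(ident_other):
            u, p = rank_sum_compare(ident_hgt, ident_other)
            report["identity"]["p"] = p
            report["identity"]["mean_hgt"] = float(ident_hgt.mean())
    return report
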