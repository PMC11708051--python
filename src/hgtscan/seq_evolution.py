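"""Pairwise Ka/Ks under the Nei–Gojobori (1986) counting model.

For each codon, every single-base change that does not create a stop codon
is classified as synonymous or nonsynonymous; the synonymous site count of
a position is the synonymous fraction of its admissible changes, and site
counts per codon always total 3 (n = 3 − s).  Between two codons differing
at k positions, the k! mutational pathways are averaged; pathways passing
through a stop codon are excluded, and in the degenerate case where every
pathway hits a stop, all pathways are averaged with stop-traversing steps
counted as nonsynonymous.  Proportions are corrected for multiple hits with
the Jukes–Cantor formula d = −¾ ln(1 − 4p/3).

Ka/Ks < 1 indicates purifying selection, ≈1 neutrality, > 1 positive
selection.  Ks = 0 and saturation (p ≥ ¾) are reported as distinct
undefined-ratio cases rather than infinities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"


class StopCodonError(ValueError):
    pass


@lru_cache(maxsize=None)
def _code(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    """codon -> amino acid map and the stop-codon set for a genetic code."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """NG86 (nonsynonymous, synonymous) site counts of one codon.

    At each position the synonymous fraction is computed over single-base
    changes that do not create a stop; n = 3 − s so the counts always
    conserve 3 sites per codon.
    """
    aa_of, stops = _code(table_id)
    codon = codon.upper()
    if codon in stops:
        raise StopCodonError(f"stop codon {codon!r} has no site counts")
    aa = aa_of[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        admissible = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in stops:
                continue
            admissible += 1
            if aa_of[mutant] == aa:
                syn += 1
        if admissible:
            s += syn / admissible
    return 3.0 - s, s


@lru_cache(maxsize=None)
def pair_difference_counts(
    codon_a: str, codon_b: str, table_id: int = 1
) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts
    between two codons."""
    aa_of, stops = _code(table_id)
    a, b = codon_a.upper(), codon_b.upper()
    if a in stops or b in stops:
        raise StopCodonError("difference counts undefined for stop codons")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[bool, float, float]:
        """Follow one mutation order; returns (hits_stop, nd, sd) with
        stop-traversing steps counted as nonsynonymous."""
        cur = a
        nd = sd = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if cur in stops or nxt in stops:
                hits_stop = True
                nd += 1.0
            elif aa_of[cur] == aa_of[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return hits_stop, nd, sd

    paths = [walk(order) for order in itertools.permutations(diff)]
    clean = [(nd, sd) for hit, nd, sd in paths if not hit]
    pool = clean if clean else [(nd, sd) for _, nd, sd in paths]
    nd = sum(p[0] for p in pool) / len(pool)
    sd = sum(p[1] for p in pool) / len(pool)
    return nd, sd


@dataclass
class KaKsResult:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    ratio: float  # NaN when undefined
    undefined: str | None = None  # None | "Ks_zero" | "saturated"
    n_codons: int = 0


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


_AMBIG = set("NRYSWKMBDHV-.")


def _clean_columns(seq_a: str, seq_b: str, stops: frozenset[str]) -> list[tuple[str, str]]:
    """Pairwise codon columns with gap/ambiguity columns removed; trailing
    stop columns dropped, internal stops rejected."""
    cols = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if set(ca) & _AMBIG or set(cb) & _AMBIG:
            continue
        cols.append((ca, cb))
    while cols and (cols[-1][0] in stops or cols[-1][1] in stops):
        cols.pop()
    for ca, cb in cols:
        if ca in stops or cb in stops:
            raise StopCodonError("internal stop codon in coding alignment")
    return cols


def kaks(seq_a: str, seq_b: str, table_id: int = 1) -> KaKsResult:
    """NG86 Ka, Ks and their ratio for an aligned coding-sequence pair.

    Sequences must be equal length and divisible by 3; gapped/ambiguous
    codon columns are dropped pairwise before counting; sites are averaged
    over the two sequences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    _, stops = _code(table_id)
    cols = _clean_columns(seq_a, seq_b, stops)
    if not cols:
        raise ValueError("no codon columns left after filtering")

    n_a = s_a = n_b = s_b = nd = sd = 0.0
    for ca, cb in cols:
        na, sa = codon_site_counts(ca, table_id)
        nb, sb = codon_site_counts(cb, table_id)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = pair_difference_counts(ca, cb, table_id)
        nd += d_n
        sd += d_s

    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pN = nd / N if N > 0 else 0.0
    pS = sd / S if S > 0 else 0.0
    Ka = _jc_correct(pN)
    Ks = _jc_correct(pS)

    undefined = None
    if np.isnan(Ka) or np.isnan(Ks):
        undefined = "saturated"
        ratio = float("nan")
    elif Ks == 0.0:
        undefined = "Ks_zero"
        ratio = float("nan")
    else:
        ratio = Ka / Ks
    return KaKsResult(
        N_sites=N, S_sites=S, Nd=nd, Sd=sd, pN=pN, pS=pS,
        Ka=float(Ka), Ks=float(Ks), ratio=float(ratio),
        undefined=undefined, n_codons=len(cols),
    )


def classify_selection(results: list[KaKsResult]) -> dict[str, int]:
    """Tally selection regimes: ratio < 0.5 strong purifying, > 1 positive,
    the rest intermediate (0.5 and 1.0 fall here under strict bounds);
    undefined ratios counted separately.  Counts sum to the input size."""
    counts = {"purifying_strong": 0, "intermediate": 0, "positive": 0,
              "undefined": 0}
    for r in results:
        if r.undefined is not None or np.isnan(r.ratio):
            counts["undefined"] += 1
        elif r.ratio < 0.5:
            counts["purifying_strong"] += 1
        elif r.ratio > 1.0:
            counts["positive"] += 1
        else:
            counts["intermediate"] += 1
    return counts
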