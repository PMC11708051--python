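"""Independent brute-force oracles used only by the tests.

The NG86 oracle below enumerates every codon column and every mutational
pathway directly from the genetic code, without importing anything from the
package's implementation modules."""

from itertools import permutations
from math import log

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """(n, s) for one codon by direct mutant enumeration."""
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1:]
            if m in _STOPS:
                continue
            tot += 1
            if _AA[m] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return 3.0 - s, s


def oracle_pair_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (nd, sd) by exhaustive pathway enumeration."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    clean = []
    for order in permutations(diff):
        cur = a
        nd = sd = 0.0
        stopped = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in _STOPS or cur in _STOPS:
                stopped = True
                nd += 1
            elif _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((nd, sd))
        if not stopped:
            clean.append((nd, sd))
    pool = clean if clean else results
    nd = sum(x[0] for x in pool) / len(pool)
    sd = sum(x[1] for x in pool) / len(pool)
    return nd, sd


def oracle_kaks(seq_a: str, seq_b: str) -> dict:
    """Full NG86 Ka/Ks recomputed column by column."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    cols = [(seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper())
            for i in range(0, len(seq_a), 3)]
    cols = [c for c in cols if set(c[0] + c[1]) <= set("ACGT")]
    while cols and (cols[-1][0] in _STOPS or cols[-1][1] in _STOPS):
        cols.pop()
    N = S = Nd = Sd = 0.0
    for ca, cb in cols:
        na, sa = oracle_site_counts(ca)
        nb, sb = oracle_site_counts(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = oracle_pair_counts(ca, cb)
        Nd += nd
        Sd += sd
    pN, pS = Nd / N, Sd / S

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)

    return {"N": N, "S": S, "Nd": Nd, "Sd": Sd, "pN": pN, "pS": pS,
            "Ka": jc(pN), "Ks": jc(pS)}


def random_codon_pair(rng, max_codons: int = 30) -> tuple[str, str]:
    """Two related random coding sequences with no stops (for oracle
    equivalence checks)."""
    sense = sorted(set(_AA) - _STOPS)
    n = int(rng.integers(3, max_codons + 1))
    a = [sense[i] for i in rng.integers(0, len(sense), size=n)]
    b = []
    for codon in a:
        c = codon
        for _ in range(int(rng.integers(0, 4))):
            pos = int(rng.integers(0, 3))
            base = "ACGT"[int(rng.integers(0, 4))]
            cand = c[:pos] + base + c[pos + 1:]
            if cand not in _STOPS:
                c = cand
        b.append(c)
    return "".join(a), "".join(b)
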