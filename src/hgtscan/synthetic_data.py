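"""Hermetic synthetic worlds with planted horizontal transfers.

A world is a directory bundle — genomes, annotations, taxonomically
annotated hit tables, gene trees, coding-sequence pairs, expression tables,
lifestyle traits, a species tree — whose statistical structure matches what
the inference pipeline assumes about real fungal genomes:

* a small minority (~2% by default) of genes have prokaryotic best
  homologs, with an E-value gap that makes them Alien-Index positive and
  outgroup-dominant among top hits;
* planted transfers sit on long contigs, near transposable elements, and
  their gene trees nest the query inside a well-supported donor clade;
* donor phyla follow a configurable mix dominated by Proteobacteria and
  Actinobacteria;
* a configurable fraction (44% by default) of planted transfers gained
  introns, copied from the native genome and then point-mutated, and
  intron-bearing transfers run higher in expression by a multiplicative
  factor;
* whole contaminant contigs (blocks of prokaryotic genes) are injected so
  the >=50%-HGT contamination rule has something to remove;
* categorical lifestyle traits modulate the per-genome number of planted
  transfers (parasites > saprotrophs > symbionts).

Sequence content is generated copy-and-mutate, not under an evolutionary
model; genome FASTA is materialized only for genomes where sequence is
consumed (intron origin search), while contig lengths for every genome are
recorded in ``contigs.tsv``.  Identical seeds give byte-identical bundles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim

from .seq_evolution import _code

# donor mix mirrors the observed distribution of prokaryotic donor groups:
# Proteobacteria 45%, Actinobacteria 36%, Firmicutes 7%, Bacteroidetes 6%,
# remainder split across another bacterial phylum, archaea and viruses
DEFAULT_DONOR_MIX = {
    "Proteobacteria": 0.45,
    "Actinobacteria": 0.36,
    "Firmicutes": 0.07,
    "Bacteroidetes": 0.06,
    "Cyanobacteria": 0.04,
    "Archaea": 0.013,
    "Viruses": 0.007,
}

LIFESTYLE_MULT = {"parasite": 1.6, "saprotroph": 1.0, "symbiont": 0.5}
GROWTH_MULT = {"yeast": 1.3, "filamentous": 1.0, "thallus": 0.6}


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world."""

    seed: int = 0
    n_genomes: int = 50
    genes_per_genome: int = 2000
    hgt_fraction: float = 0.02
    decoy_fraction: float = 0.02
    donor_mix: dict = field(default_factory=lambda: dict(DEFAULT_DONOR_MIX))

    # E-value structure (log10 ranges) controlling AI separation
    hgt_out_logev: tuple[float, float] = (-80.0, -30.0)
    hgt_in_logev: tuple[float, float] = (-20.0, -3.0)
    native_in_logev: tuple[float, float] = (-150.0, -40.0)
    native_out_logev: tuple[float, float] = (-5.0, 0.0)

    # gene trees: probability the decision clade is strongly supported
    tree_support_strong: float = 0.97
    hgt_nt_fraction: float = 0.05  # planted transfers with no ingroup in tree

    # intron model
    intron_gain_prob: float = 0.44
    intron_mutation_rate: float = 0.10
    intron_length_range: tuple[int, int] = (60, 250)

    # selection regimes for coding pairs: dN/dS value -> probability
    dnds_regimes: dict = field(
        default_factory=lambda: {0.1: 0.45, 0.3: 0.35, 1.0: 0.15, 2.0: 0.05}
    )
    pair_codons: int = 300

    # expression model
    n_expression_datasets: int = 13
    expression_mu: float = 1.0
    expression_sigma: float = 0.6
    intron_expression_multiplier: float = 1.5

    # genome context
    n_contaminant_contigs: int = 2
    contaminant_genes: tuple[int, int] = (8, 15)
    te_per_40kb: float = 1.0
    hgt_te_max_gap: int = 1500

    # genomes whose sequence content is materialized (intron origin search)
    sequence_genomes: tuple[str, ...] = ()

    def validate(self) -> None:
        if not (0 <= self.hgt_fraction <= 1):
            raise ValueError("hgt_fraction must lie in [0, 1]")
        if abs(sum(self.donor_mix.values()) - 1.0) > 1e-9:
            raise ValueError("donor_mix must sum to 1")
        if abs(sum(self.dnds_regimes.values()) - 1.0) > 1e-9:
            raise ValueError("dnds_regimes probabilities must sum to 1")
        if not (0 <= self.intron_gain_prob <= 1):
            raise ValueError("intron_gain_prob must lie in [0, 1]")


@dataclass
class WorldPaths:
    root: Path

    @property
    def taxonomy(self) -> Path: return self.root / "taxonomy.tsv"
    @property
    def contigs(self) -> Path: return self.root / "contigs.tsv"
    @property
    def genomes_tsv(self) -> Path: return self.root / "genomes.tsv"
    @property
    def annotations_dir(self) -> Path: return self.root / "annotations"
    @property
    def donors_gff(self) -> Path: return self.root / "annotations" / "donors.gff3"
    @property
    def hits_dir(self) -> Path: return self.root / "hits"
    @property
    def trees_dir(self) -> Path: return self.root / "trees"
    @property
    def cds_pairs(self) -> Path: return self.root / "cds_pairs" / "pairs.fasta"
    @property
    def expression_dir(self) -> Path: return self.root / "expression"
    @property
    def traits(self) -> Path: return self.root / "traits.tsv"
    @property
    def species_tree(self) -> Path: return self.root / "species_tree.nwk"
    @property
    def truth(self) -> Path: return self.root / "truth.tsv"
    @property
    def families(self) -> Path: return self.root / "families.tsv"
    @property
    def config(self) -> Path: return self.root / "config.yaml"
    @property
    def genomes_dir(self) -> Path: return self.root / "genomes"
    @property
    def introns_dir(self) -> Path: return self.root / "introns"


# ---------------------------------------------------------------- helpers

_FUNGAL_CLASSES = ["Sordariomycetes", "Dothideomycetes", "Agaricomycetes",
                   "Tremellomycetes", "Eurotiomycetes"]

BASES = np.frombuffer(b"ACGT", dtype="S1")


def _build_taxonomy_rows(cfg: WorldConfig, rng: np.random.Generator):
    """Species pools: recipients (one genus each, plus a congeneric cousin),
    an ingroup pool of other fungi, and donor pools per phylum/domain."""
    rows = []
    recipients = []
    for i in range(cfg.n_genomes):
        genus = f"Recipigenus{i:02d}"
        sp = f"{genus}_typica"
        cls = _FUNGAL_CLASSES[i % len(_FUNGAL_CLASSES)]
        phylum = "Ascomycota" if i % 3 else "Basidiomycota"
        rows.append((sp, "Eukaryota", phylum, cls, f"{cls}_ord{i % 7}",
                     f"{cls}_fam{i % 11}", genus))
        rows.append((f"{genus}_cousina", "Eukaryota", phylum, cls,
                     f"{cls}_ord{i % 7}", f"{cls}_fam{i % 11}", genus))
        recipients.append(sp)

    ingroup_pool = []
    for j in range(40):
        cls = _FUNGAL_CLASSES[j % len(_FUNGAL_CLASSES)]
        phylum = "Ascomycota" if j % 2 else "Basidiomycota"
        sp = f"Fungalius{j:02d}_communis"
        rows.append((sp, "Eukaryota", phylum, cls, f"{cls}_ord{j % 7}",
                     f"{cls}_fam{j % 13}", f"Fungalius{j:02d}"))
        ingroup_pool.append(sp)

    donor_pools: dict[str, list[str]] = {}
    for group in cfg.donor_mix:
        pool = []
        if group == "Archaea":
            dom, phy = "Archaea", "Euryarchaeota"
        elif group == "Viruses":
            dom, phy = "Viruses", "Uroviricota"
        else:
            dom, phy = "Bacteria", group
        n_sp = 8 if dom != "Bacteria" else 30
        for j in range(n_sp):
            sp = f"{group[:6]}{j:02d}_donorii"
            rows.append((sp, dom, phy, f"{group}_cls", f"{group}_ord",
                         f"{group}_fam{j % 5}", f"{group}gen{j:02d}"))
            pool.append(sp)
        donor_pools[group] = pool

    tax = pd.DataFrame(
        rows, columns=["species", "domain", "phylum", "class", "order",
                       "family", "genus"],
    )
    return tax, recipients, ingroup_pool, donor_pools


def _contig_plan(cfg: WorldConfig, rng: np.random.Generator, n_genes: int):
    """Contig lengths (bp) and per-contig gene capacities for one genome.

    ~80% of genes land on contigs longer than 100 kb; planted transfers are
    restricted to those."""
    mean_span = 3200  # gene + intergenic footprint, bp
    lengths = []
    long_genes = int(round(n_genes * 0.8))
    placed = 0
    while placed < long_genes:
        length = int(rng.uniform(110_000, 320_000))
        lengths.append(length)
        placed += length // mean_span
    short_genes = n_genes - min(placed, n_genes)
    placed = 0
    while placed < short_genes:
        length = int(rng.uniform(15_000, 95_000))
        lengths.append(length)
        placed += length // mean_span
    return lengths


def _split_cds(cds_len: int, n_introns: int, rng: np.random.Generator):
    """Split a CDS into n_introns+1 exon pieces (each >= 30 bp)."""
    if n_introns == 0:
        return [cds_len]
    while True:
        cuts = np.sort(rng.integers(30, cds_len - 30, size=n_introns))
        pieces = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (pieces >= 30).all():
            return pieces.tolist()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, float]:
    """Point-mutate a sequence; returns (mutated, realized identity %)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n_mut = 0
    for i in np.nonzero(hit)[0]:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([rng.choice(choices)])
        n_mut += 1
    identity = 100.0 * (len(arr) - n_mut) / len(arr)
    return arr.tobytes().decode(), identity


# ------------------------------------------------------------- CDS pairs

def evolve_codon_pair(
    rng: np.random.Generator, omega: float, n_codons: int,
    proposals_per_codon: float = 0.8,
) -> tuple[str, str]:
    """An ancestor sequence and a copy evolved under a given dN/dS.

    Single-base substitutions are proposed uniformly; synonymous changes are
    accepted with probability min(1, 1/omega) and nonsynonymous ones with
    min(1, omega), which realizes a dN/dS near ``omega`` under NG86-style
    counting.  Changes creating stops are rejected.
    """
    aa_of, stops = _code(1)
    sense = sorted(set(aa_of) - set(stops))
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    ancestor = "".join(codons)
    seq = list(ancestor)
    n_prop = int(proposals_per_codon * n_codons)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    for _ in range(n_prop):
        pos = int(rng.integers(0, 3 * n_codons))
        c0 = pos // 3 * 3
        old_codon = "".join(seq[c0:c0 + 3])
        base = "ACGT"[rng.integers(0, 4)]
        if base == seq[pos]:
            continue
        new_codon = old_codon[:pos - c0] + base + old_codon[pos - c0 + 1:]
        if new_codon in stops:
            continue
        syn = aa_of[old_codon] == aa_of[new_codon]
        if rng.random() < (p_syn if syn else p_non):
            seq[pos] = base
    return ancestor, "".join(seq)


# ----------------------------------------------------------- world build

def generate_world(cfg: WorldConfig, outdir: str | Path) -> pd.DataFrame:
    """Write a world bundle under ``outdir``; returns the truth ledger.

    The ledger covers every emitted gene exactly once (columns gene_id,
    genome_id, contig_id, gene_class, donor_label, event_id, family_id,
    dnds, n_introns, has_tree, intron_identity).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    paths = WorldPaths(Path(outdir))
    paths.root.mkdir(parents=True, exist_ok=True)
    for d in (paths.annotations_dir, paths.hits_dir, paths.trees_dir,
              paths.cds_pairs.parent, paths.expression_dir):
        d.mkdir(parents=True, exist_ok=True)

    tax, recipients, ingroup_pool, donor_pools = _build_taxonomy_rows(cfg, rng)
    tax.to_csv(paths.taxonomy, sep="\t", index=False)
    genome_ids = [f"genome_{i:02d}" for i in range(cfg.n_genomes)]
    species_of_genome = dict(zip(genome_ids, recipients))
    donor_names = list(cfg.donor_mix)
    donor_probs = np.array([cfg.donor_mix[d] for d in donor_names])
    all_bacteria = [sp for g in donor_names if g not in ("Archaea", "Viruses")
                    for sp in donor_pools[g]]

    # lifestyle traits drive planted-transfer counts
    lifestyles = rng.choice(["saprotroph", "parasite", "symbiont"],
                            size=cfg.n_genomes, p=[0.5, 0.3, 0.2])
    growth = rng.choice(["filamentous", "yeast", "thallus"],
                        size=cfg.n_genomes, p=[0.6, 0.25, 0.15])
    noise_traits = {
        "decay_type": rng.choice(["white_rot", "brown_rot", "soft_rot", "mold"],
                                 size=cfg.n_genomes),
        "hymenium_type": rng.choice(["perithecium", "apothecium", "agaricoid"],
                                    size=cfg.n_genomes),
        "fruitbody_type": rng.choice(["closed", "smooth", "gills", "poroid"],
                                     size=cfg.n_genomes),
        "aquatic": rng.choice(["yes", "no"], size=cfg.n_genomes, p=[0.2, 0.8]),
    }

    truth_rows: list[dict] = []
    contig_rows: list[dict] = []
    genome_rows: list[dict] = []

    seq_genomes = set(cfg.sequence_genomes)
    if seq_genomes:
        paths.genomes_dir.mkdir(exist_ok=True)
        paths.introns_dir.mkdir(exist_ok=True)

    # contaminant contigs are assigned to the first genomes, one each
    contam_assignment: dict[str, int] = {}
    for c in range(cfg.n_contaminant_contigs):
        g = genome_ids[c % cfg.n_genomes]
        contam_assignment[g] = contam_assignment.get(g, 0) + 1

    for gi, genome in enumerate(genome_ids):
        recipient = species_of_genome[genome]
        n_genes = int(rng.integers(int(cfg.genes_per_genome * 0.85),
                                   int(cfg.genes_per_genome * 1.15) + 1))
        mult = LIFESTYLE_MULT[lifestyles[gi]] * GROWTH_MULT[growth[gi]]
        n_hgt = int(round(cfg.hgt_fraction * n_genes * mult))
        n_decoy = int(round(cfg.decoy_fraction * n_genes))

        contig_lengths = _contig_plan(cfg, rng, n_genes)
        contigs = [f"{genome}_ctg{ci:03d}" for ci in range(len(contig_lengths))]

        # ---- lay out genes over contigs by capacity
        gene_records = [{"gene_id": f"{genome}_g{k:05d}"} for k in range(n_genes)]
        idx = 0
        contig_of: dict[str, str] = {}
        genes_on: dict[str, list[str]] = {c: [] for c in contigs}
        per_contig_capacity = [length // 3200 for length in contig_lengths]
        for ci, cap in enumerate(per_contig_capacity):
            for _ in range(cap):
                if idx >= n_genes:
                    break
                contig_of[gene_records[idx]["gene_id"]] = contigs[ci]
                genes_on[contigs[ci]].append(gene_records[idx]["gene_id"])
                idx += 1
        # leftovers onto the last contig
        while idx < n_genes:
            contig_of[gene_records[idx]["gene_id"]] = contigs[-1]
            genes_on[contigs[-1]].append(gene_records[idx]["gene_id"])
            idx += 1

        long_contigs = {c for c, L in zip(contigs, contig_lengths) if L > 100_000}
        eligible = [g for c in contigs if c in long_contigs
                    for g in genes_on[c] if len(genes_on[c]) >= 4]
        rng.shuffle(eligible)
        hgt_ids: list[str] = []
        cap_used: dict[str, int] = {}
        for g in eligible:
            if len(hgt_ids) >= n_hgt:
                break
            c = contig_of[g]
            cap = max(1, int(0.3 * len(genes_on[c])))
            if cap_used.get(c, 0) < cap:
                hgt_ids.append(g)
                cap_used[c] = cap_used.get(c, 0) + 1
        hgt_set = set(hgt_ids)
        rest = [r["gene_id"] for r in gene_records if r["gene_id"] not in hgt_set]
        decoy_set = set(rest[:n_decoy])

        # ---- contaminant contigs for this genome
        contam_contigs = []
        for cc in range(contam_assignment.get(genome, 0)):
            cid = f"{genome}_contam{cc:02d}"
            length = int(rng.uniform(110_000, 180_000))
            ng = int(rng.integers(*cfg.contaminant_genes))
            contigs.append(cid)
            contig_lengths.append(length)
            genes_on[cid] = []
            for k in range(ng):
                gid = f"{genome}_c{cc:02d}g{k:03d}"
                contig_of[gid] = cid
                genes_on[cid].append(gid)
                gene_records.append({"gene_id": gid})
            contam_contigs.append(cid)
        contam_genes = {g for cid in contam_contigs for g in genes_on[cid]}

        for c, L in zip(contigs, contig_lengths):
            contig_rows.append({"contig_id": c, "genome_id": genome, "length": L})

        # ---- gene structures (exons/introns) and coordinates
        gff_rows = []
        structures: dict[str, dict] = {}
        contig_cursor = {c: 1 for c in contigs}
        intron_seq_jobs = []  # (gene, idx, length) for sequence genomes
        for rec in gene_records:
            gid = rec["gene_id"]
            contig = contig_of[gid]
            is_hgt = gid in hgt_set or gid in contam_genes
            if is_hgt:
                cds = int(np.clip(rng.normal(1100, 200), 450, 2400)) // 3 * 3
                if gid in hgt_set and rng.random() < cfg.intron_gain_prob:
                    n_introns = int(rng.integers(1, 3))
                else:
                    n_introns = 0
                intron_lens = [int(rng.integers(*cfg.intron_length_range))
                               for _ in range(n_introns)]
            else:
                cds = int(np.clip(rng.normal(1500, 300), 450, 3000)) // 3 * 3
                if rng.random() < 0.6:
                    n_introns = int(rng.integers(1, 4))
                    intron_lens = [int(np.clip(rng.lognormal(5.7, 0.9), 40, 3000))
                                   for _ in range(n_introns)]
                else:
                    n_introns, intron_lens = 0, []
            pieces = _split_cds(cds, n_introns, rng)
            start = contig_cursor[contig] + int(rng.integers(200, 900))
            exons = []
            pos = start
            for e, piece in enumerate(pieces):
                exons.append((pos, pos + piece - 1))
                pos += piece
                if e < len(intron_lens):
                    pos += intron_lens[e]
            end = exons[-1][1]
            length_c = dict(zip(contigs, contig_lengths))[contig]
            if end > length_c - 200:  # fold back: place at a random legal spot
                span = end - start + 1
                start = int(rng.integers(1, max(2, length_c - span - 200)))
                shift = start - exons[0][0]
                exons = [(s + shift, e2 + shift) for s, e2 in exons]
                end = exons[-1][1]
            else:
                contig_cursor[contig] = end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            structures[gid] = {"contig": contig, "exons": exons,
                               "strand": strand, "n_introns": n_introns}
            gff_rows.append((contig, "sim", "gene", exons[0][0], end, ".",
                             strand, ".", f"ID={gid}"))
            for e, (s, e2) in enumerate(exons):
                gff_rows.append((contig, "sim", "exon", s, e2, ".", strand,
                                 ".", f"ID={gid}.exon{e};Parent={gid}"))
            if genome in seq_genomes and gid in hgt_set and n_introns:
                for ii in range(n_introns):
                    intron_seq_jobs.append((gid, ii, intron_lens[ii]))

        # ---- transposable elements: ambient + biased near transfers
        te_rows = []
        te_counter = 0
        for c, L in zip(contigs, contig_lengths):
            n_te = rng.poisson(cfg.te_per_40kb * L / 40_000)
            for _ in range(n_te):
                s = int(rng.integers(1, max(2, L - 2000)))
                te_rows.append((c, "sim", "transposable_element", s,
                                min(L, s + int(rng.integers(300, 2000))), ".",
                                "+", ".", f"ID={genome}_te{te_counter:05d}"))
                te_counter += 1
        for gid in hgt_ids:
            st = structures[gid]
            L = dict(zip(contigs, contig_lengths))[st["contig"]]
            gap = int(rng.integers(0, cfg.hgt_te_max_gap))
            s = min(st["exons"][-1][1] + 1 + gap, L - 500)
            te_rows.append((st["contig"], "sim", "transposable_element", s,
                            min(L, s + 800), ".", "+", ".",
                            f"ID={genome}_te{te_counter:05d}"))
            te_counter += 1

        gff = pd.DataFrame(gff_rows + te_rows)
        gff.to_csv(paths.annotations_dir / f"{genome}.gff3", sep="\t",
                   index=False, header=False)

        # ---- genome sequence + intron origins (sequence genomes only)
        intron_identity: dict[str, float] = {}
        if genome in seq_genomes:
            contig_len_map = dict(zip(contigs, contig_lengths))
            seqs = {c: _random_seq(rng, L) for c, L in contig_len_map.items()}
            intron_fa = []
            for gid, ii, length in intron_seq_jobs:
                src_contig = contigs[int(rng.integers(0, len(contigs)))]
                src_pos = int(rng.integers(0, len(seqs[src_contig]) - length))
                source = seqs[src_contig][src_pos:src_pos + length]
                mutated, ident = _mutate(source, cfg.intron_mutation_rate, rng)
                intron_fa.append((f"{gid}|intron{ii}", mutated))
                intron_identity.setdefault(gid, ident)
            with open(paths.genomes_dir / f"{genome}.fasta", "w") as fh:
                for c in contigs:
                    fh.write(f">{c}\n{seqs[c]}\n")
            with open(paths.introns_dir / f"{genome}.fasta", "w") as fh:
                for name, seq in intron_fa:
                    fh.write(f">{name}\n{seq}\n")

        # ---- per-gene truth bookkeeping (events/families filled later)
        donor_draw = rng.choice(len(donor_names), size=len(hgt_ids) +
                                len(contam_genes), p=donor_probs)
        di = 0
        genome_truth: list[dict] = []
        for rec in gene_records:
            gid = rec["gene_id"]
            if gid in hgt_set or gid in contam_genes:
                donor = donor_names[donor_draw[di]]
                di += 1
                cls = "hgt" if gid in hgt_set else "contaminant"
            else:
                donor = ""
                cls = "decoy" if gid in decoy_set else "native"
            genome_truth.append({
                "gene_id": gid, "genome_id": genome,
                "contig_id": contig_of[gid], "gene_class": cls,
                "donor_label": donor, "event_id": "", "family_id": "",
                "dnds": np.nan,
                "n_introns": structures[gid]["n_introns"],
                "has_tree": cls in ("hgt", "contaminant", "decoy"),
                "intron_identity": intron_identity.get(gid, np.nan),
            })
        truth_rows.extend(genome_truth)
        genome_rows.append({"genome_id": genome, "species": recipient,
                            "n_genes": len(gene_records)})

        # ---- hit table
        _write_hits(cfg, rng, paths, genome, recipient, genome_truth,
                    ingroup_pool, donor_pools, all_bacteria,
                    species_of_genome)

    truth = pd.DataFrame(truth_rows)

    # ---- transfer events: group some planted genes into shared events
    truth = _assign_events(cfg, rng, truth)

    # ---- trees
    _write_trees(cfg, rng, paths, truth, ingroup_pool, donor_pools)

    # ---- coding-sequence pairs per selection regime
    _write_cds_pairs(cfg, rng, paths, truth)

    # ---- expression tables
    _write_expression(cfg, rng, paths, truth, genome_ids)

    # ---- donor homolog gene structures (single exon, shorter CDS)
    donor_rows = []
    hgt_rows = truth[truth["gene_class"] == "hgt"]
    for i, gid in enumerate(hgt_rows["gene_id"]):
        cds = int(np.clip(rng.normal(1000, 150), 300, 2100)) // 3 * 3
        start = 1 + i * 4000
        donor_rows.append(("donor_ctg000", "sim", "gene", start,
                           start + cds - 1, ".", "+", ".", f"ID={gid}|donor"))
        donor_rows.append(("donor_ctg000", "sim", "exon", start,
                           start + cds - 1, ".", "+", ".",
                           f"ID={gid}|donor.exon0;Parent={gid}|donor"))
    pd.DataFrame(donor_rows).to_csv(paths.donors_gff, sep="\t", index=False,
                                    header=False)

    # ---- traits, species tree, tables
    traits = pd.DataFrame({
        "genome_id": genome_ids,
        "primary_lifestyle": lifestyles,
        "growth_form": growth,
        **noise_traits,
    })
    traits.to_csv(paths.traits, sep="\t", index=False)

    pyrng = random.Random(cfg.seed + 1)
    taxa = dendropy.TaxonNamespace(genome_ids)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.2, num_extant_tips=cfg.n_genomes,
        taxon_namespace=taxa, rng=pyrng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = max(edge.length or 0.0, 0.01)
    tree.write(path=str(paths.species_tree), schema="newick",
               suppress_rooting=True)

    pd.DataFrame(contig_rows).to_csv(paths.contigs, sep="\t", index=False)
    pd.DataFrame(genome_rows).to_csv(paths.genomes_tsv, sep="\t", index=False)
    fam = truth.loc[truth["family_id"] != "", ["gene_id", "family_id"]]
    fam.to_csv(paths.families, sep="\t", index=False)
    truth.to_csv(paths.truth, sep="\t", index=False)
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [_plain(v) for v in obj]
        return obj

    with open(paths.config, "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=True)
    return truth


# ------------------------------------------------------------ components

def _write_hits(cfg, rng, paths, genome, recipient, gene_rows, ingroup_pool,
                donor_pools, all_bacteria, species_of_genome):
    """Per-genome extended tabular hit file with the planted E-value gaps."""
    other_recipients = [sp for g, sp in species_of_genome.items() if g != genome]
    ingroup_all = ingroup_pool + other_recipients
    cols = {k: [] for k in ("gene", "species", "logev", "identity")}

    def add(gene, species_list, lo, hi, ident_mu, ident_sd):
        n = len(species_list)
        cols["gene"].extend([gene] * n)
        cols["species"].extend(species_list)
        cols["logev"].extend(rng.uniform(lo, hi, size=n).tolist())
        cols["identity"].extend(
            np.clip(rng.normal(ident_mu, ident_sd, size=n), 15, 99).tolist())

    for r in gene_rows:
        gid = r["gene_id"]
        cls = r["gene_class"]
        if cls in ("hgt", "contaminant"):
            donor = r["donor_label"]
            n_out = int(rng.integers(16, 25))
            n_native_phylum = max(4, int(0.7 * n_out))
            sp_out = (
                list(rng.choice(donor_pools[donor], size=n_native_phylum))
                + list(rng.choice(all_bacteria, size=n_out - n_native_phylum))
            )
            add(gid, sp_out, *cfg.hgt_out_logev, 46, 8)
            n_in = int(rng.integers(0, 3))
            if n_in:
                add(gid, list(rng.choice(ingroup_all, size=n_in)),
                    *cfg.hgt_in_logev, 40, 8)
        elif cls == "decoy":
            add(gid, list(rng.choice(all_bacteria, size=6)), -45.0, -35.0, 35, 6)
            add(gid, list(rng.choice(ingroup_all, size=6)), -40.0, -20.0, 45, 8)
        else:
            n_in = int(rng.integers(5, 11))
            add(gid, list(rng.choice(ingroup_all, size=n_in)),
                *cfg.native_in_logev, 60, 10)
            n_out = int(rng.integers(2, 5))
            add(gid, list(rng.choice(all_bacteria, size=n_out)),
                *cfg.native_out_logev, 32, 6)
            if rng.random() < 0.3:
                add(gid, [recipient.rsplit("_", 1)[0] + "_cousina"],
                    -190.0, -160.0, 92, 3)

    n = len(cols["gene"])
    logev = np.array(cols["logev"])
    bitscore = np.round(-2.2 * logev + 40 + rng.normal(0, 3, size=n), 1)
    alen = rng.integers(80, 400, size=n)
    df = pd.DataFrame({
        "query_gene_id": cols["gene"],
        "subject_id": [f"{sp}|p{i}" for i, sp in enumerate(cols["species"])],
        "percent_identity": np.round(cols["identity"], 1),
        "alignment_length": alen,
        "mismatches": (alen * 0.3).astype(int),
        "gap_opens": rng.integers(0, 5, size=n),
        "q_start": 1, "q_end": alen, "s_start": 1, "s_end": alen,
        "evalue": 10.0 ** logev,
        "bitscore": np.maximum(bitscore, 25.0),
        "subject_species": cols["species"],
    })
    df.to_csv(paths.hits_dir / f"{genome}.tsv", sep="\t", index=False,
              header=False)


def _assign_events(cfg, rng, truth: pd.DataFrame) -> pd.DataFrame:
    """Group planted transfers into events: ~30% of genes join shared
    multi-genome events (2-4 genes), the rest are species-specific."""
    hgt_idx = truth.index[truth["gene_class"] == "hgt"].to_numpy()
    rng.shuffle(hgt_idx)
    n_shared_genes = int(0.3 * len(hgt_idx))
    shared = hgt_idx[:n_shared_genes]
    singles = hgt_idx[n_shared_genes:]
    ev = 0
    pos = 0
    while pos < len(shared):
        size = int(rng.integers(2, 5))
        members = shared[pos:pos + size]
        pos += size
        donor = truth.loc[members[0], "donor_label"]
        truth.loc[members, "donor_label"] = donor
        truth.loc[members, "event_id"] = f"tev_{ev:05d}"
        truth.loc[members, "family_id"] = f"fam_{ev:05d}"
        ev += 1
    for i in singles:
        truth.loc[i, "event_id"] = f"tev_{ev:05d}"
        truth.loc[i, "family_id"] = f"fam_{ev:05d}"
        ev += 1
    contam = truth.index[truth["gene_class"] == "contaminant"]
    for i in contam:
        truth.loc[i, "event_id"] = f"tev_{ev:05d}"
        truth.loc[i, "family_id"] = f"fam_{ev:05d}"
        ev += 1
    return truth


def _write_trees(cfg, rng, paths, truth, ingroup_pool, donor_pools):
    """Newick gene trees: transfers nest the query in a supported donor
    clade; decoys sit with ingroup leaves (vertical topology)."""
    for r in truth.itertuples(index=False):
        if not r.has_tree:
            continue
        gid = r.gene_id
        if r.gene_class in ("hgt", "contaminant"):
            donor = r.donor_label
            pool = donor_pools[donor]
            d = rng.choice(pool, size=4, replace=len(pool) < 4)
            strong = rng.random() < cfg.tree_support_strong
            sup = int(rng.integers(95, 101)) if strong else int(rng.integers(55, 95))
            if r.gene_class == "hgt" and rng.random() < cfg.hgt_nt_fraction:
                nwk = (f"((QUERY__{gid}:0.1,{d[0]}:0.1,{d[1]}:0.1){sup}:0.2,"
                       f"({d[2]}:0.1,{d[3]}:0.1)90:0.2):0.0;")
            else:
                f = rng.choice(ingroup_pool, size=2, replace=False)
                nwk = (f"(((QUERY__{gid}:0.1,{d[0]}:0.1,{d[1]}:0.1){sup}:0.2,"
                       f"({d[2]}:0.1,{d[3]}:0.1)90:0.2)88:0.1,"
                       f"({f[0]}:0.1,{f[1]}:0.1)99:0.3):0.0;")
        else:  # decoy -> vertical topology
            f = rng.choice(ingroup_pool, size=3, replace=False)
            b = rng.choice(donor_pools["Proteobacteria"], size=2, replace=False)
            nwk = (f"(((QUERY__{gid}:0.1,{f[0]}:0.1)97:0.1,"
                   f"({f[1]}:0.1,{f[2]}:0.1)99:0.1)96:0.2,"
                   f"({b[0]}:0.1,{b[1]}:0.1)98:0.3):0.0;")
        (paths.trees_dir / f"{gid}.nwk").write_text(nwk + "\n")


def _write_cds_pairs(cfg, rng, paths, truth):
    """Aligned recipient/donor coding pairs, one per planted transfer,
    evolved under the gene's selection regime."""
    regimes = sorted(cfg.dnds_regimes)
    probs = np.array([cfg.dnds_regimes[w] for w in regimes])
    hgt_idx = truth.index[truth["gene_class"] == "hgt"]
    draws = rng.choice(len(regimes), size=len(hgt_idx), p=probs)
    with open(paths.cds_pairs, "w") as fh:
        for i, idx in enumerate(hgt_idx):
            omega = regimes[draws[i]]
            truth.loc[idx, "dnds"] = omega
            a, b = evolve_codon_pair(rng, omega, cfg.pair_codons)
            gid = truth.loc[idx, "gene_id"]
            fh.write(f">{gid}|recipient dnds={omega}\n{a}\n")
            fh.write(f">{gid}|donor dnds={omega}\n{b}\n")


def _write_expression(cfg, rng, paths, truth, genome_ids):
    """Lognormal expression for planted transfers, one dataset per genome
    for the first ``n_expression_datasets`` genomes, with the intron
    multiplier applied to intron-bearing genes."""
    n_ds = min(cfg.n_expression_datasets, len(genome_ids))
    for d in range(n_ds):
        genome = genome_ids[d]
        sub = truth[(truth["genome_id"] == genome) & (truth["gene_class"] == "hgt")]
        values = rng.lognormal(cfg.expression_mu, cfg.expression_sigma,
                               size=len(sub))
        mult = np.where(sub["n_introns"].to_numpy() > 0,
                        cfg.intron_expression_multiplier, 1.0)
        df = pd.DataFrame({
            "gene_id": sub["gene_id"].to_numpy(),
            "dataset_id": f"dataset_{d:02d}",
            "value": np.round(values * mult, 4),
        })
        df.to_csv(paths.expression_dir / f"dataset_{d:02d}.tsv", sep="\t",
                  index=False)


# -------------------------------------------------------------- scorecard

def scorecard(
    truth: pd.DataFrame,
    candidates: set[str],
    confirmed: set[str],
    final: set[str],
) -> dict:
    """Confusion summaries per pipeline stage against the truth ledger.

    ``candidates`` are genes flagged by similarity screening, ``confirmed``
    those passing tree classification, ``final`` the post-contamination
    call set.  Planted transfers (class ``hgt``) are the positives;
    contaminants calling as HGT in the final set count as false positives.
    """
    known = set(truth["gene_id"])
    for name, s in (("candidates", candidates), ("confirmed", confirmed),
                    ("final", final)):
        stray = s - known
        if stray:
            raise ValueError(f"{name} contains ids absent from the ledger: "
                             f"{sorted(stray)[:5]}")
    planted = set(truth.loc[truth["gene_class"] == "hgt", "gene_id"])
    negatives = known - planted

    def stage(called: set[str]) -> dict:
        tp = len(called & planted)
        fp = len(called - planted)
        return {
            "n_called": len(called),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "specificity": 1 - fp / len(negatives) if negatives else float("nan"),
            "fdr": fp / len(called) if called else 0.0,
        }

    return {
        "n_planted": len(planted),
        "screen": stage(candidates),
        "phylo": stage(confirmed),
        "final": stage(final),
    }
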