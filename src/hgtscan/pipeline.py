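"""End-to-end orchestration over a world bundle, and the report layer.

The funnel runs: all genes -> genes on >100 kb contigs -> similarity-screen
candidates -> tree-confirmed transfers -> post-contamination final calls.
Each later stage only ever shrinks the set.  Downstream characterization
(donor mix, events, Ka/Ks, introns, expression, traits) runs on the final
call set.  Reruns with identical inputs and seed reproduce identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import genome_screen, homology_screen, intron_analysis, phylo_validate
from . import seq_evolution, trait_association
from .gff import contig_lengths_from_fasta, read_contigs_tsv, read_gff3
from .synthetic_data import WorldPaths
from .taxonomy import TaxonomyDB

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    screen: homology_screen.ScreenConfig = field(
        default_factory=homology_screen.ScreenConfig)
    filters: genome_screen.FilterConfig = field(
        default_factory=genome_screen.FilterConfig)
    support_min: float = 95.0
    intron_seed_k: int = 7
    n_perm: int = 1000
    seed: int = 0
    run_kaks: bool = True
    run_introns: bool = True
    run_expression: bool = True
    run_traits: bool = True


def derived_percentages(
    numerator: int, denominator: int, decimals: int = 1
) -> float:
    """Percentage with half-up rounding to the requested decimals.

    Returns NaN for a zero denominator.
    """
    if denominator == 0:
        return float("nan")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    funnel: dict
    donor_percentages: dict
    events: dict
    kaks_classes: dict
    intron: dict
    expression: dict
    traits: dict
    validation: dict

    def to_dict(self) -> dict:
        return {
            "funnel": self.funnel,
            "donor_percentages": self.donor_percentages,
            "events": self.events,
            "kaks_classes": self.kaks_classes,
            "intron": self.intron,
            "expression": self.expression,
            "traits": self.traits,
            "validation": self.validation,
        }

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, default=default, sort_keys=True)
        )


# ------------------------------------------------------------- world load

def _load_world(world_dir: str | Path) -> dict:
    paths = WorldPaths(Path(world_dir))
    taxonomy = TaxonomyDB.from_tsv(paths.taxonomy)
    if paths.contigs.exists():
        contigs = read_contigs_tsv(paths.contigs)
    else:
        frames = []
        for fa in sorted(paths.genomes_dir.glob("*.fasta")):
            lens = contig_lengths_from_fasta(fa)
            frames.append(pd.DataFrame({
                "contig_id": lens.index, "genome_id": fa.stem,
                "length": lens.to_numpy(),
            }))
        contigs = pd.concat(frames, ignore_index=True)
    genomes = pd.read_csv(paths.genomes_tsv, sep="\t")
    species_of_genome = dict(zip(genomes["genome_id"], genomes["species"]))

    gene_frames, exon_frames, te_frames = [], [], []
    for genome in genomes["genome_id"]:
        gff = read_gff3(paths.annotations_dir / f"{genome}.gff3")
        g = gff[gff["type"] == "gene"]
        gene_frames.append(pd.DataFrame({
            "gene_id": g["feature_id"], "genome_id": genome,
            "contig_id": g["seqid"], "start": g["start"], "end": g["end"],
            "strand": g["strand"],
        }))
        e = gff[gff["type"] == "exon"]
        exon_frames.append(pd.DataFrame({
            "gene_id": e["parent_id"], "contig_id": e["seqid"],
            "strand": e["strand"], "start": e["start"], "end": e["end"],
        }))
        t = gff[gff["type"] == "transposable_element"]
        te_frames.append(t[["seqid", "start", "end"]])
    return {
        "paths": paths,
        "taxonomy": taxonomy,
        "contigs": contigs,
        "species_of_genome": species_of_genome,
        "genes": pd.concat(gene_frames, ignore_index=True),
        "exons": pd.concat(exon_frames, ignore_index=True),
        "tes": pd.concat(te_frames, ignore_index=True),
    }


# ---------------------------------------------------------------- stages

def run_pipeline(
    world_dir: str | Path,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[SummaryReport, dict]:
    """Run the full funnel plus characterization on a world bundle.

    Returns (report, artifacts); artifacts carries the intermediate sets
    (candidate/confirmed/final gene ids, per-gene calls, score tables) used
    by the scorecard and the tests.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    world = _load_world(world_dir)
    paths: WorldPaths = world["paths"]
    taxonomy: TaxonomyDB = world["taxonomy"]
    genes: pd.DataFrame = world["genes"]
    contigs: pd.DataFrame = world["contigs"]
    species_of_genome = world["species_of_genome"]

    # stage 1: contig-length restriction
    retained, length_summary = genome_screen.filter_genes_by_contig(
        genes, contigs, cfg.filters)
    retained_ids = set(retained["gene_id"])
    log.info("contig filter: %d/%d genes retained",
             length_summary["n_retained"], length_summary["n_total"])

    # stage 2: similarity screening per genome
    score_frames = []
    for genome, species in species_of_genome.items():
        hit_path = paths.hits_dir / f"{genome}.tsv"
        if not hit_path.exists():
            hit_path = paths.hits_dir / f"{genome}.tsv.gz"
        hits, n_dropped = homology_screen.read_hit_table(hit_path, taxonomy)
        if n_dropped:
            log.info("%s: dropped %d hits above E-value cutoff", genome, n_dropped)
        hits = hits[hits["query_gene_id"].isin(retained_ids)]
        scores = homology_screen.score_genome(hits, taxonomy, species, cfg.screen)
        scores = homology_screen.screen_candidates(scores, cfg.screen)
        scores["genome_id"] = genome
        score_frames.append(scores)
    all_scores = pd.concat(score_frames)
    candidates = set(all_scores.index[all_scores["candidate"]])
    log.info("screen: %d candidates", len(candidates))

    # stage 3: phylogenetic validation
    gene_genome = dict(zip(genes["gene_id"], genes["genome_id"]))
    calls: list[phylo_validate.PhyloCall] = []
    for gid in sorted(candidates):
        tree_path = paths.trees_dir / f"{gid}.nwk"
        if not tree_path.exists():
            calls.append(phylo_validate.PhyloCall(
                gene_id=gid, call=phylo_validate.Call.UNRESOLVED))
            continue
        tree = phylo_validate.load_gene_tree(tree_path)
        recipient = species_of_genome[gene_genome[gid]]
        calls.append(phylo_validate.classify_query(
            tree, taxonomy, recipient, gid, support_min=cfg.support_min))
    confirmed = {c.gene_id for c in calls if c.confirmed}
    donor_of = {c.gene_id: c.donor_label for c in calls if c.confirmed}
    log.info("phylo: %d confirmed", len(confirmed))

    # stage 4: contamination filter
    final, discarded_contigs = genome_screen.contamination_filter(
        confirmed, genes, cfg.filters)
    log.info("contamination: %d contigs discarded, %d calls kept",
             len(discarded_contigs), len(final))

    funnel = {
        "genes_total": int(length_summary["n_total"]),
        "genes_on_long_contigs": int(length_summary["n_retained"]),
        "candidates": len(candidates),
        "confirmed": len(confirmed),
        "final": len(final),
        "long_contig_pct": derived_percentages(
            length_summary["n_retained"], length_summary["n_total"], 1),
        "hgt_fraction_pct": derived_percentages(
            len(final), length_summary["n_total"], 2),
    }

    # donor attribution among final calls
    donor_counts: dict[str, int] = {}
    for gid in final:
        donor_counts[donor_of[gid]] = donor_counts.get(donor_of[gid], 0) + 1
    donor_pct = {
        d: derived_percentages(c, len(final), 1)
        for d, c in sorted(donor_counts.items())
    } if final else {}

    # events
    family_of = {}
    if paths.families.exists():
        fam = pd.read_csv(paths.families, sep="\t", dtype=str)
        family_of = dict(zip(fam["gene_id"], fam["family_id"]))
    species_of_gene = {g: species_of_genome[gm] for g, gm in gene_genome.items()}
    final_calls = [c for c in calls if c.gene_id in final]
    events, event_summary = phylo_validate.cluster_events(
        final_calls, family_of, species_of_gene)

    # Ka/Ks over recipient/donor coding pairs of final calls
    kaks_classes: dict = {}
    kaks_results = []
    if cfg.run_kaks and paths.cds_pairs.exists():
        pairs: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(paths.cds_pairs), "fasta"):
            gid, role = rec.id.rsplit("|", 1)
            pairs.setdefault(gid, {})[role] = str(rec.seq)
        for gid in sorted(final):
            pr = pairs.get(gid)
            if pr and "recipient" in pr and "donor" in pr:
                kaks_results.append(
                    seq_evolution.kaks(pr["recipient"], pr["donor"]))
        kaks_classes = seq_evolution.classify_selection(kaks_results)

    # intron structure, origins, lengths
    intron_report: dict = {}
    has_intron: dict[str, bool] = {}
    if cfg.run_introns:
        gene_class = {
            gid: (intron_analysis.FOREIGN_RECIPIENT if gid in final
                  else intron_analysis.NATIVE)
            for gid in genes["gene_id"]
        }
        structures, gain_summary = intron_analysis.derive_introns(
            world["exons"], gene_class)
        if paths.donors_gff.exists():
            dgff = read_gff3(paths.donors_gff)
            de = dgff[dgff["type"] == "exon"]
            donor_structs, _ = intron_analysis.derive_introns(
                pd.DataFrame({
                    "gene_id": de["parent_id"], "contig_id": de["seqid"],
                    "strand": de["strand"], "start": de["start"],
                    "end": de["end"],
                }),
                {g: intron_analysis.DONOR_HOMOLOG
                 for g in de["parent_id"].unique()},
            )
            structures.update(donor_structs)
        lengths = intron_analysis.length_statistics(structures)
        has_intron = {
            gid: bool(structures[gid].introns)
            for gid in final if gid in structures
        }
        intron_report = {
            "gain_fraction": gain_summary["gain_fraction"],
            "gain_pct": derived_percentages(
                gain_summary["n_foreign_with_introns"],
                gain_summary["n_foreign"], 0)
            if gain_summary["n_foreign"] else float("nan"),
            "total_introns": gain_summary["total_introns"],
            "length_stats": lengths.to_dict(),
        }
        origin = _intron_origins(paths, final, cfg.intron_seed_k)
        intron_report.update(origin)

    # expression comparison across datasets
    expression_report: dict = {}
    if cfg.run_expression and paths.expression_dir.exists() and has_intron:
        frames = [pd.read_csv(p, sep="\t")
                  for p in sorted(paths.expression_dir.glob("*.tsv"))]
        if frames:
            expr = pd.concat(frames, ignore_index=True)
            table, fraction = intron_analysis.expression_compare(
                expr, has_intron)
            expression_report = {
                "n_datasets": int(len(table)),
                "n_intron_higher": int(table["intron_higher"].sum())
                if len(table) else 0,
                "fraction_intron_higher_pct": fraction,
            }

    # trait associations
    traits_report: dict = {}
    if cfg.run_traits and paths.traits.exists():
        traits_report = _trait_stage(
            paths, genes, final, species_of_genome, cfg)

    # validation-style summaries
    identity = _best_outgroup_identity(paths, taxonomy, species_of_genome)
    val = genome_screen.validation_summaries(final, genes, contigs, identity)
    validation = {
        "applicable": val["applicable"],
        "contig_length_p": val.get("contig_length", {}).get("p"),
        "median_len_with_hgt": val.get("contig_length", {}).get("median_with"),
        "median_len_without_hgt": val.get("contig_length", {}).get("median_without"),
        "mean_hgt_proportion": val.get("mean_hgt_proportion"),
        "identity_p": val.get("identity", {}).get("p"),
        "mean_identity_hgt": val.get("identity", {}).get("mean_hgt"),
    }
    te = world["tes"]
    if len(te) and final:
        dist = genome_screen.nearest_te_distance(genes, te)
        d_hgt = dist[dist.index.isin(final)].dropna()
        d_nat = dist[~dist.index.isin(final)].dropna()
        if len(d_hgt) and len(d_nat):
            _, p_te = genome_screen.rank_sum_compare(d_hgt, d_nat)
            validation["te_distance_p"] = p_te
            validation["median_te_dist_hgt"] = float(d_hgt.median())
            validation["median_te_dist_other"] = float(d_nat.median())

    report = SummaryReport(
        funnel=funnel,
        donor_percentages=donor_pct,
        events=event_summary,
        kaks_classes=kaks_classes,
        intron=intron_report,
        expression=expression_report,
        traits=traits_report,
        validation=validation,
    )

    artifacts = {
        "scores": all_scores,
        "calls": calls,
        "candidates": candidates,
        "confirmed": confirmed,
        "final": final,
        "events": events,
        "kaks_results": kaks_results,
        "discarded_contigs": discarded_contigs,
        "elapsed_s": time.time() - t0,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        homology_screen.write_scores(all_scores, out / "scores.tsv")
        pd.DataFrame(
            [{"gene_id": c.gene_id, "call": c.call.value,
              "donor_label": c.donor_label,
              "support": c.support_at_decision} for c in calls]
        ).to_csv(out / "calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"event_id": e.event_id, "family_id": e.family_id,
              "donor_label": e.donor_label,
              "n_genes": len(e.gene_ids),
              "n_species": len(e.recipient_species),
              "species_specific": e.species_specific} for e in events]
        ).to_csv(out / "events.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
    return report, artifacts


def _intron_origins(paths: WorldPaths, final: set[str], k: int) -> dict:
    """Origin search for introns of final calls in sequence-materialized
    genomes; empty dict when no genome FASTA is present."""
    if not paths.genomes_dir.exists():
        return {}
    n_found = 0
    n_total = 0
    identities = []
    per_intron = []
    for fa in sorted(paths.genomes_dir.glob("*.fasta")):
        genome = {rec.id: str(rec.seq)
                  for rec in SeqIO.parse(str(fa), "fasta")}
        intron_fa = paths.introns_dir / fa.name
        if not intron_fa.exists():
            continue
        index = intron_analysis.build_genome_index(genome, k)
        for rec in SeqIO.parse(str(intron_fa), "fasta"):
            gid = rec.id.rsplit("|", 1)[0]
            if gid not in final:
                continue
            n_total += 1
            hit = intron_analysis.intron_origin_search(
                str(rec.seq), genome, intron_id=rec.id, k=k, _index=index)
            found = hit is not None and hit.origin_found
            if found:
                n_found += 1
                identities.append(hit.identity)
            per_intron.append((rec.id, found))
    if n_total == 0:
        return {}
    return {
        "origin_searched": n_total,
        "origin_found": n_found,
        "origin_found_pct": derived_percentages(n_found, n_total, 0),
        "origin_mean_identity": float(np.mean(identities))
        if identities else float("nan"),
    }


def _trait_stage(paths, genes, final, species_of_genome, cfg) -> dict:
    traits = pd.read_csv(paths.traits, sep="\t", dtype=str)
    traits = traits.set_index("genome_id")
    per_genome = (
        genes.assign(is_final=genes["gene_id"].isin(final))
        .groupby("genome_id")["is_final"].sum()
        .reindex(traits.index)
        .fillna(0)
        .astype(int)
    )
    totals = genes.groupby("genome_id").size().reindex(traits.index)
    out: dict = {"per_trait": {}}
    tree = None
    if paths.species_tree.exists():
        import dendropy
        tree = dendropy.Tree.get(path=str(paths.species_tree),
                                 schema="newick", preserve_underscores=True)
    for col in traits.columns:
        entry: dict = {}
        try:
            rda = trait_association.rda_permutation_test(
                per_genome.astype(float), traits[col],
                n_perm=cfg.n_perm, seed=cfg.seed)
            entry["rda_F"] = rda.statistic
            entry["rda_p"] = rda.p_value
        except trait_association.UntestableTraitError as exc:
            entry["rda_error"] = str(exc)
        if tree is not None:
            try:
                pgls = trait_association.pgls_fit(
                    tree, per_genome.astype(float), traits[col])
                entry["pgls_F"] = pgls.statistic
                entry["pgls_p"] = pgls.p_value
            except (trait_association.UntestableTraitError, ValueError) as exc:
                entry["pgls_error"] = str(exc)
        med = trait_association.group_summaries(per_genome, traits[col])
        entry["level_order"] = med["level"].tolist() if len(med) else []
        out["per_trait"][col] = entry
    try:
        r, p = trait_association.hgt_gene_content_correlation(
            per_genome, totals)
        out["gene_content_correlation"] = {"r": r, "p": p}
    except ValueError as exc:
        out["gene_content_correlation"] = {"error": str(exc)}
    out["hgt_counts"] = per_genome.to_dict()
    return out


def _best_outgroup_identity(paths, taxonomy, species_of_genome) -> pd.Series:
    """Best non-ingroup hit identity per gene (for the validation-style
    identity comparison)."""
    from .taxonomy import GroupLabel, classify_species
    series = []
    for genome, species in species_of_genome.items():
        hit_path = paths.hits_dir / f"{genome}.tsv"
        if not hit_path.exists():
            continue
        hits, _ = homology_screen.read_hit_table(hit_path, taxonomy)
        if hits.empty:
            continue
        sp_unique = pd.unique(hits["subject_species"])
        lab = {sp: classify_species(taxonomy, sp, species) for sp in sp_unique}
        mask = hits["subject_species"].map(lab) == GroupLabel.OUTGROUP
        sub = hits[mask]
        best = sub.sort_values("rank").groupby("query_gene_id").first()
        series.append(best["percent_identity"])
    if not series:
        return pd.Series(dtype=float)
    return pd.concat(series)
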