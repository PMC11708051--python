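import numpy as np
import pandas as pd
import pytest

from hgtscan.intron_analysis import (
    DONOR_HOMOLOG, FOREIGN_RECIPIENT, NATIVE, GeneStructure,
    build_genome_index, derive_introns, expression_compare,
    intron_origin_search, length_statistics, revcomp,
)


def exon_rows(spec):
    """spec: {gene: (contig, strand, [(s, e), ...])}"""
    rows = []
    for gid, (contig, strand, exons) in spec.items():
        for s, e in exons:
            rows.append({"gene_id": gid, "contig_id": contig,
                         "strand": strand, "start": s, "end": e})
    return pd.DataFrame(rows)


class TestDeriveIntrons:
    def test_single_exon_no_introns(self):
        structures, summary = derive_introns(
            exon_rows({"g1": ("c1", "+", [(1, 300)])}))
        assert structures["g1"].introns == []
        assert structures["g1"].cds_length == 300

    def test_intron_coordinates(self):
        structures, _ = derive_introns(
            exon_rows({"g1": ("c1", "+", [(1, 100), (151, 300)])}))
        st = structures["g1"]
        assert st.introns == [(101, 150)]
        assert st.intron_lengths == [50]
        assert st.gene_length == 300
        assert st.cds_length == 250

    def test_span_reconstruction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = 1
            exons = []
            for _ in range(int(rng.integers(1, 6))):
                length = int(rng.integers(30, 400))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(20, 500))
            structures, _ = derive_introns(
                exon_rows({"g": ("c", "+", exons)}))
            st = structures["g"]
            assert (st.cds_length + sum(st.intron_lengths)
                    == st.gene_length)

    def test_overlapping_exons_skipped(self):
        structures, summary = derive_introns(
            exon_rows({"bad": ("c1", "+", [(1, 100), (50, 200)]),
                       "good": ("c1", "+", [(1, 90)])}))
        assert "bad" not in structures
        assert summary["skipped_genes"] == ["bad"]

    def test_gain_summary_over_foreign_genes(self):
        spec = {
            "f1": ("c", "+", [(1, 100), (200, 300)]),
            "f2": ("c", "+", [(1, 300)]),
            "n1": ("c", "+", [(1, 100), (500, 700)]),
        }
        classes = {"f1": FOREIGN_RECIPIENT, "f2": FOREIGN_RECIPIENT,
                   "n1": NATIVE}
        _, summary = derive_introns(exon_rows(spec), classes)
        assert summary["n_foreign"] == 2
        assert summary["gain_fraction"] == pytest.approx(0.5)
        assert summary["total_introns"] == 1

    def test_world_gain_fraction_matches_config(self, small_world):
        """~44% of planted transfers gain introns, within sampling error."""
        truth = small_world["truth"]
        hgt = truth[truth["gene_class"] == "hgt"]
        frac = (hgt["n_introns"] > 0).mean()
        n = len(hgt)
        tol = 3 * np.sqrt(0.44 * 0.56 / n)
        assert abs(frac - 0.44) <= tol


class TestOriginSearch:
    def test_verbatim_copy_full_coverage(self):
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        intron = genome[1200:1350]
        hit = intron_origin_search(intron, genome, k=7)
        assert hit is not None
        assert hit.coverage == pytest.approx(1.0)
        assert hit.identity == 100.0
        assert hit.origin_found

    def test_reverse_strand_found(self):
        rng = np.random.default_rng(2)
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        intron = revcomp(genome[800:950])
        hit = intron_origin_search(intron, genome, k=7)
        assert hit is not None and hit.strand == "-"
        assert hit.coverage > 0.9

    def test_mutated_copy_identity_tracks_planted_rate(self):
        rng = np.random.default_rng(3)
        genome = "".join(rng.choice(list("ACGT"), size=20_000))
        found = 0
        for t in range(10):
            start = int(rng.integers(0, 19_800))
            source = list(genome[start:start + 150])
            n_mut = 15  # 10% of 150
            for i in rng.choice(150, size=n_mut, replace=False):
                source[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[source[i]]
            hit = intron_origin_search("".join(source), genome, k=7)
            if hit and hit.origin_found:
                found += 1
                assert hit.identity >= 88.0  # planted 90% minus 2 points
        assert found >= 9

    def test_random_query_rarely_hits_unrelated_genome(self):
        rng = np.random.default_rng(4)
        genome = "".join(rng.choice(list("ACGT"), size=100_000))
        false_hits = 0
        for _ in range(10):
            query = "".join(rng.choice(list("ACGT"), size=100))
            hit = intron_origin_search(query, genome, k=11)
            if hit is not None and hit.origin_found:
                false_hits += 1
        assert false_hits == 0

    def test_short_query_returns_none(self):
        assert intron_origin_search("ACG", "ACGTACGTACGT" * 10, k=7) is None

    def test_world_planted_introns_recovered(self, small_world):
        """Origin search finds planted intron copies with identity within 2
        points of the planted mutation level on >=95% of introns."""
        from Bio import SeqIO
        path = small_world["path"]
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(
            str(path / "genomes" / "genome_00.fasta"), "fasta")}
        index = build_genome_index(genome, k=7)
        truth = small_world["truth"].set_index("gene_id")
        n_total = n_good = 0
        for rec in SeqIO.parse(str(path / "introns" / "genome_00.fasta"),
                               "fasta"):
            gid = rec.id.rsplit("|", 1)[0]
            planted = truth.loc[gid, "intron_identity"]
            hit = intron_origin_search(str(rec.seq), genome, k=7,
                                       _index=index)
            n_total += 1
            if (hit is not None and hit.origin_found
                    and hit.identity >= planted - 2.0):
                n_good += 1
        assert n_total > 0
        assert n_good / n_total >= 0.95


class TestLengthStatistics:
    def test_single_gene(self):
        structures = {"g": GeneStructure("g", "c", "+", [(1, 300)],
                                         FOREIGN_RECIPIENT)}
        stats = length_statistics(structures)
        row = stats.loc[FOREIGN_RECIPIENT]
        assert row["mean_cds_length"] == 300
        assert row["mean_gene_length"] == 300
        assert np.isnan(row["mean_intron_length"])

    def test_toy_trio_hand_computed(self):
        structures = {
            "d": GeneStructure("d", "c", "+", [(1, 900)], DONOR_HOMOLOG),
            "f": GeneStructure("f", "c", "+", [(1, 500), (601, 1200)],
                               FOREIGN_RECIPIENT),
            "n1": GeneStructure("n1", "c", "+", [(1, 1000), (2001, 3000)],
                                NATIVE),
            "n2": GeneStructure("n2", "c", "+", [(1, 2400)], NATIVE),
        }
        stats = length_statistics(structures)
        assert stats.loc[DONOR_HOMOLOG, "mean_cds_length"] == 900
        assert stats.loc[FOREIGN_RECIPIENT, "mean_intron_length"] == 100
        assert stats.loc[NATIVE, "mean_cds_length"] == pytest.approx(2200)
        assert stats.loc[NATIVE, "mean_gene_length"] == pytest.approx(2700)

    def test_world_native_longer_than_foreign(self, small_world_run):
        stats = small_world_run["report"].intron["length_stats"]
        assert (stats["mean_gene_length"][NATIVE]
                > stats["mean_gene_length"][FOREIGN_RECIPIENT])


class TestExpressionCompare:
    def test_identical_groups_not_higher(self):
        expr = pd.DataFrame({
            "gene_id": ["a", "b"], "dataset_id": ["d1", "d1"],
            "value": [5.0, 5.0],
        })
        table, frac = expression_compare(expr, {"a": True, "b": False})
        assert not table["intron_higher"].iloc[0]
        assert frac == 0.0

    def test_two_datasets_half(self):
        expr = pd.DataFrame({
            "gene_id": ["a", "b", "a", "b"],
            "dataset_id": ["d1", "d1", "d2", "d2"],
            "value": [5.0, 3.0, 2.0, 4.0],
        })
        table, frac = expression_compare(expr, {"a": True, "b": False})
        assert frac == 50.0

    def test_missing_group_excluded(self):
        expr = pd.DataFrame({
            "gene_id": ["a", "a2", "b"],
            "dataset_id": ["d1", "d1", "d2"],
            "value": [5.0, 4.0, 3.0],
        })
        table, frac = expression_compare(expr, {"a": True, "a2": True,
                                                "b": False})
        assert len(table) == 0 or not (table["dataset_id"] == "d1").any()

    def test_rescaling_one_dataset_invariant(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        has_intron = {g: i % 2 == 0 for i, g in enumerate(genes)}
        frames = []
        for d in range(4):
            frames.append(pd.DataFrame({
                "gene_id": genes, "dataset_id": f"d{d}",
                "value": rng.lognormal(1, 0.5, 20)}))
        expr = pd.concat(frames, ignore_index=True)
        _, base = expression_compare(expr, has_intron)
        scaled = expr.copy()
        mask = scaled["dataset_id"] == "d2"
        scaled.loc[mask, "value"] *= 37.5
        _, after = expression_compare(scaled, has_intron)
        assert base == after

    def test_world_intron_effect_detected(self, small_world_run):
        rep = small_world_run["report"]
        assert rep.expression["fraction_intron_higher_pct"] >= 60.0
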