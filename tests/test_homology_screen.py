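import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hgtscan.homology_screen import (
    HIT_COLUMNS, ScreenConfig, alien_index, lpi_score, outgroup_percentage,
    read_hit_table, score_genome, screen_candidates,
)

RECIPIENT = "Amanita_recipiens"


def make_hits(rows):
    """rows: (species, evalue, bitscore) -> one-gene hit frame."""
    df = pd.DataFrame(
        [("g1", f"{sp}|p{i}", 50.0, 100, 30, 0, 1, 100, 1, 100, ev, bs, sp)
         for i, (sp, ev, bs) in enumerate(rows)],
        columns=HIT_COLUMNS,
    )
    df = df.sort_values(["evalue", "bitscore"], ascending=[True, False])
    df["rank"] = range(len(df))
    return df


class TestAlienIndex:
    def test_symmetric_evalues_give_zero(self, toy_taxonomy):
        hits = make_hits([("Fusarium_aliud", 1e-30, 120),
                          ("Escherichia_coli", 1e-30, 120)])
        assert alien_index(hits, toy_taxonomy, RECIPIENT) == pytest.approx(0.0)

    def test_outgroup_better_by_50_logs(self, toy_taxonomy):
        hits = make_hits([("Fusarium_aliud", 1e-50, 200),
                          ("Escherichia_coli", 1e-100, 380)])
        # ln(1e-50) - ln(1e-100) = 50 ln 10 ~ 115.13
        assert alien_index(hits, toy_taxonomy, RECIPIENT) == pytest.approx(
            50 * math.log(10), rel=1e-9)

    def test_missing_outgroup_uses_evalue_one(self, toy_taxonomy):
        hits = make_hits([("Fusarium_aliud", 1e-20, 120)])
        expected = math.log(1e-20 + 1e-200) - math.log(1.0 + 1e-200)
        ai = alien_index(hits, toy_taxonomy, RECIPIENT)
        assert ai == pytest.approx(expected)
        assert ai == pytest.approx(-46.0517, abs=1e-3)

    def test_no_hits_is_undefined(self, toy_taxonomy):
        assert math.isnan(alien_index(make_hits([]), toy_taxonomy, RECIPIENT))

    @given(
        e_in=st.floats(1e-180, 1.0), e_out=st.floats(1e-180, 1.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetry_under_swap(self, toy_taxonomy, e_in, e_out):
        a = make_hits([("Fusarium_aliud", e_in, 100),
                       ("Escherichia_coli", e_out, 100)])
        b = make_hits([("Fusarium_aliud", e_out, 100),
                       ("Escherichia_coli", e_in, 100)])
        ai_a = alien_index(a, toy_taxonomy, RECIPIENT)
        ai_b = alien_index(b, toy_taxonomy, RECIPIENT)
        assert ai_a == pytest.approx(-ai_b, abs=1e-9)
        if e_out < e_in:
            assert ai_a > 0


class TestOutgroupPercentage:
    def test_all_outgroup(self, toy_taxonomy):
        hits = make_hits([("Escherichia_coli", 1e-40, 150),
                          ("Pseudomonas_putida", 1e-30, 130)])
        assert outgroup_percentage(hits, toy_taxonomy, RECIPIENT) == 100.0

    def test_mixed_count(self, toy_taxonomy):
        hits = make_hits([("Escherichia_coli", 1e-40, 150),
                          ("Pseudomonas_putida", 1e-35, 140),
                          ("Streptomyces_grisea", 1e-30, 130),
                          ("Fusarium_aliud", 1e-20, 110)])
        assert outgroup_percentage(hits, toy_taxonomy, RECIPIENT) == 75.0

    def test_duplicate_species_deduplicated(self, toy_taxonomy):
        hits = make_hits([("Escherichia_coli", 1e-40, 150),
                          ("Escherichia_coli", 1e-35, 140),
                          ("Escherichia_coli", 1e-30, 130)])
        # one distinct species collected, all outgroup
        assert outgroup_percentage(hits, toy_taxonomy, RECIPIENT) == 100.0

    def test_duplicating_any_row_is_invariant(self, toy_taxonomy):
        base = [("Escherichia_coli", 1e-40, 150),
                ("Fusarium_aliud", 1e-20, 110),
                ("Pseudomonas_putida", 1e-10, 80)]
        ref = outgroup_percentage(make_hits(base), toy_taxonomy, RECIPIENT)
        for row in list(base):
            dup = outgroup_percentage(make_hits(base + [row]),
                                      toy_taxonomy, RECIPIENT)
            assert dup == ref

    def test_self_hits_excluded(self, toy_taxonomy):
        hits = make_hits([("Amanita_cousina", 1e-90, 300),
                          ("Escherichia_coli", 1e-40, 150)])
        assert outgroup_percentage(hits, toy_taxonomy, RECIPIENT) == 100.0

    def test_top_n_cap(self, toy_taxonomy):
        cfg = ScreenConfig(top_n_species=2)
        hits = make_hits([("Escherichia_coli", 1e-40, 150),
                          ("Pseudomonas_putida", 1e-35, 140),
                          ("Fusarium_aliud", 1e-30, 130)])
        # only the 2 best-ranked distinct species are collected
        assert outgroup_percentage(hits, toy_taxonomy, RECIPIENT, cfg) == 100.0


class TestLpi:
    def test_all_congeneric_gives_one(self, toy_taxonomy):
        # non-SELF windowed hits sharing the genus would be SELF; the
        # coherent case is fungal hits of the recipient's class/order
        hits = make_hits([("Coprinus_alter", 1e-60, 200),
                          ("Coprinus_alter", 1e-55, 195)])
        assert lpi_score(hits, toy_taxonomy, RECIPIENT) == pytest.approx(4 / 6)

    def test_all_bacterial_gives_zero(self, toy_taxonomy):
        hits = make_hits([("Escherichia_coli", 1e-60, 200),
                          ("Pseudomonas_putida", 1e-58, 198)])
        assert lpi_score(hits, toy_taxonomy, RECIPIENT) == 0.0

    def test_weighted_mean_by_hand(self, toy_taxonomy):
        # one fully coherent (s=1 via congeneric... SELF excluded), so use
        # equal-weight mix: Coprinus (s=4/6) and E. coli (s=0) at equal
        # bitscore -> mean 2/6
        hits = make_hits([("Coprinus_alter", 1e-60, 100),
                          ("Escherichia_coli", 1e-60, 100)])
        assert lpi_score(hits, toy_taxonomy, RECIPIENT) == pytest.approx(2 / 6)

    def test_window_excludes_weak_hits(self, toy_taxonomy):
        cfg = ScreenConfig(bitscore_window=0.10)
        hits = make_hits([("Escherichia_coli", 1e-60, 200),
                          ("Coprinus_alter", 1e-10, 80)])  # outside window
        assert lpi_score(hits, toy_taxonomy, RECIPIENT, cfg) == 0.0


class TestReadHitTable:
    def test_empty_file(self, tmp_path, toy_taxonomy):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        df, dropped = read_hit_table(p, toy_taxonomy)
        assert df.empty and dropped == 0

    def test_evalue_cutoff_drops_rows(self, tmp_path, toy_taxonomy):
        p = tmp_path / "hits.tsv"
        row = ["g1", "x|p1", "50.0", "100", "30", "0", "1", "100", "1",
               "100", "2.0", "55.0", "Escherichia_coli"]
        p.write_text("\t".join(row) + "\n")
        df, dropped = read_hit_table(p, toy_taxonomy)
        assert len(df) == 0 and dropped == 1

    def test_unknown_species_raises(self, tmp_path, toy_taxonomy):
        p = tmp_path / "hits.tsv"
        row = ["g1", "x|p1", "50.0", "100", "30", "0", "1", "100", "1",
               "100", "1e-10", "80.0", "Martius_incognitus"]
        p.write_text("\t".join(row) + "\n")
        with pytest.raises(KeyError):
            read_hit_table(p, toy_taxonomy)

    def test_world_hit_counts_match_ledger(self, small_world, toy_taxonomy):
        from hgtscan.taxonomy import TaxonomyDB
        tax = TaxonomyDB.from_tsv(small_world["path"] / "taxonomy.tsv")
        df, dropped = read_hit_table(
            small_world["path"] / "hits" / "genome_01.tsv", tax)
        truth = small_world["truth"]
        genes_with_hits = set(df["query_gene_id"])
        ledger_genes = set(
            truth.loc[truth["genome_id"] == "genome_01", "gene_id"])
        assert genes_with_hits == ledger_genes
        assert dropped == 0


class TestScreenCandidates:
    def _scores(self, ai, outg, lpi):
        n = len(ai)
        return pd.DataFrame(
            {"AI": ai, "outg_pct": outg, "lpi": lpi,
             "n_hits_used": [10] * n},
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_strict_ai_boundary(self):
        # gene 0 has AI exactly 0 -> not a candidate despite everything else
        scores = self._scores([0.0, 5.0], [95.0, 95.0], [0.0, 0.0])
        out = screen_candidates(scores, ScreenConfig(lpi_percentile=60))
        assert not out.loc["g0", "candidate"]
        assert out.loc["g1", "candidate"]

    def test_strict_outg_boundary(self):
        scores = self._scores([5.0, 5.0], [80.0, 80.1], [0.0, 0.0])
        out = screen_candidates(scores, ScreenConfig(lpi_percentile=60))
        assert not out.loc["g0", "candidate"]
        assert out.loc["g1", "candidate"]

    def test_undefined_scores_never_candidates(self):
        scores = self._scores([np.nan, 5.0], [95.0, 95.0], [0.0, 0.0])
        out = screen_candidates(scores, ScreenConfig(lpi_percentile=90))
        assert not out.loc["g0", "candidate"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        scores = self._scores(rng.normal(0, 3, 50), rng.uniform(0, 100, 50),
                              rng.uniform(0, 1, 50))
        base = screen_candidates(scores, ScreenConfig())["candidate"]
        stricter_ai = screen_candidates(
            scores, ScreenConfig(ai_threshold=2.0))["candidate"]
        stricter_outg = screen_candidates(
            scores, ScreenConfig(outg_threshold=90.0))["candidate"]
        assert not (stricter_ai & ~base).any()
        assert not (stricter_outg & ~base).any()

    def test_world_screen_separates_planted_transfers(self, small_world):
        """On synthetic data the screen recovers >=95% of planted transfers
        and flags <=5% of native genes."""
        from hgtscan.taxonomy import TaxonomyDB
        tax = TaxonomyDB.from_tsv(small_world["path"] / "taxonomy.tsv")
        truth = small_world["truth"]
        genomes = pd.read_csv(small_world["path"] / "genomes.tsv", sep="\t")
        flagged = set()
        for genome, species in zip(genomes["genome_id"], genomes["species"]):
            hits, _ = read_hit_table(
                small_world["path"] / "hits" / f"{genome}.tsv", tax)
            scores = screen_candidates(score_genome(hits, tax, species))
            flagged |= set(scores.index[scores["candidate"]])
        planted = set(truth.loc[truth["gene_class"] == "hgt", "gene_id"])
        native = set(truth.loc[truth["gene_class"].isin(["native", "decoy"]),
                               "gene_id"])
        recall = len(flagged & planted) / len(planted)
        fpr = len(flagged & native) / len(native)
        assert recall >= 0.95
        assert fpr <= 0.05
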