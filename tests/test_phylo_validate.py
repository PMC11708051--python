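import io
import random

import dendropy
import pytest

from hgtscan.phylo_validate import (
    Call, PhyloCall, TreeStructureError, classify_query, cluster_events,
    load_gene_tree, root_tree,
)

RECIPIENT = "Amanita_recipiens"


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True)


class TestClassifyQuery:
    def test_supported_donor_clade_is_hgt(self, toy_taxonomy):
        nwk = ("(((QUERY__g1:0.1,Escherichia_coli:0.1)95:0.1,"
               "Pseudomonas_putida:0.2)98:0.1,"
               "(Fusarium_aliud:0.1,Coprinus_alter:0.1)99:0.2);")
        call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT, "g1",
                              support_min=95)
        assert call.call == Call.HGT
        assert call.donor_label == "Proteobacteria"
        assert call.support_at_decision == 95

    def test_ingroup_sister_is_vertical(self, toy_taxonomy):
        nwk = ("((QUERY__g1:0.1,Fusarium_aliud:0.1)97:0.1,"
               "(Escherichia_coli:0.1,Pseudomonas_putida:0.1)99:0.2);")
        call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT, "g1",
                              support_min=95)
        assert call.call == Call.VERTICAL
        assert call.donor_label == ""

    def test_no_ingroup_anywhere_is_hgt_nt(self, toy_taxonomy):
        nwk = ("((QUERY__g1:0.1,Escherichia_coli:0.1)96:0.1,"
               "(Pseudomonas_putida:0.1,Streptomyces_grisea:0.1)99:0.2);")
        call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT, "g1",
                              support_min=95)
        assert call.call == Call.HGT_NT
        assert call.donor_label == "Proteobacteria"

    def test_no_supported_ancestor_is_unresolved(self, toy_taxonomy):
        nwk = ("((QUERY__g1:0.1,Escherichia_coli:0.1)60:0.1,"
               "(Fusarium_aliud:0.1,Coprinus_alter:0.1)55:0.2);")
        call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT, "g1",
                              support_min=95)
        assert call.call == Call.UNRESOLVED

    def test_donor_label_set_iff_confirmed(self, toy_taxonomy):
        for nwk, expect_donor in [
            ("((QUERY__g1:0.1,Escherichia_coli:0.1)96:0.1,"
             "(Fusarium_aliud:0.1,Coprinus_alter:0.1)99:0.2);", True),
            ("((QUERY__g1:0.1,Fusarium_aliud:0.1)96:0.1,"
             "(Escherichia_coli:0.1,Coprinus_alter:0.1)99:0.2);", False),
        ]:
            call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT,
                                  "g1", support_min=95)
            assert bool(call.donor_label) is expect_donor

    def test_leaf_order_permutation_invariance(self, toy_taxonomy):
        leaves_inner = ["QUERY__g1:0.1", "Escherichia_coli:0.1",
                        "Pseudomonas_putida:0.1"]
        calls = []
        for seed in range(4):
            rnd = random.Random(seed)
            inner = list(leaves_inner)
            rnd.shuffle(inner)
            nwk = (f"(({','.join(inner)})97:0.1,"
                   "(Fusarium_aliud:0.1,Coprinus_alter:0.1)99:0.2);")
            calls.append(classify_query(tree_from(nwk), toy_taxonomy,
                                        RECIPIENT, "g1", support_min=95))
        assert {c.call for c in calls} == {Call.HGT}
        assert {c.donor_label for c in calls} == {"Proteobacteria"}

    def test_branch_length_rescaling_invariance(self, toy_taxonomy):
        for scale in (0.1, 1.0, 10.0):
            nwk = (f"((QUERY__g1:{0.1*scale},Escherichia_coli:{0.2*scale})96:"
                   f"{0.1*scale},(Fusarium_aliud:{0.1*scale},"
                   f"Coprinus_alter:{0.3*scale})99:{0.2*scale});")
            call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT,
                                  "g1", support_min=95)
            assert call.call == Call.HGT

    def test_raising_support_only_moves_toward_unresolved(self, toy_taxonomy):
        """VERTICAL never flips to HGT as support_min rises."""
        nwk = ("(((QUERY__g1:0.1,Fusarium_aliud:0.1)80:0.1,"
               "Escherichia_coli:0.2)97:0.1,"
               "(Coprinus_alter:0.1,Pseudomonas_putida:0.1)99:0.2);")
        tree = tree_from(nwk)
        order = {Call.HGT: 0, Call.HGT_NT: 0, Call.VERTICAL: 1,
                 Call.UNRESOLVED: 2}
        prev = None
        for smin in (50, 90, 98, 100):
            call = classify_query(tree_from(nwk), toy_taxonomy, RECIPIENT,
                                  "g1", support_min=smin)
            if prev is not None and prev == Call.VERTICAL:
                assert call.call in (Call.VERTICAL, Call.UNRESOLVED)
            prev = call.call


class TestRootTree:
    def test_three_leaf_error(self, toy_taxonomy):
        t = tree_from("(QUERY__g1:0.1,Escherichia_coli:0.1);")
        with pytest.raises(TreeStructureError):
            root_tree(t)

    def test_midpoint_on_long_branch(self):
        # chain with one long branch: midpoint must land on it
        t = tree_from("((a:0.1,b:0.1):0.1,(c:0.1,d:2.0):0.1);")
        root_tree(t)
        # after midpoint rooting, d's path to root is half the diameter
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        diameter = pdm.distance(taxa["d"], taxa["a"])
        depth = {}
        for leaf in t.leaf_node_iter():
            depth[leaf.taxon.label] = leaf.distance_from_root()
        assert depth["d"] == pytest.approx(diameter / 2)

    def test_determinism_under_leaf_permutation(self):
        a = tree_from("((a:0.1,b:0.2):0.1,(c:0.3,d:1.5):0.2);")
        b = tree_from("((d:1.5,c:0.3):0.2,(b:0.2,a:0.1):0.1);")
        root_tree(a)
        root_tree(b)
        assert a.as_string(schema="newick") is not None
        da = {l.taxon.label: l.distance_from_root() for l in a.leaf_node_iter()}
        db = {l.taxon.label: l.distance_from_root() for l in b.leaf_node_iter()}
        for k in da:
            assert da[k] == pytest.approx(db[k])


class TestClusterEvents:
    def _call(self, gid, donor="Proteobacteria", call=Call.HGT):
        return PhyloCall(gene_id=gid, call=call, donor_label=donor,
                         support_at_decision=99)

    def test_shared_event(self):
        calls = [self._call("a1"), self._call("a2"), self._call("a3")]
        fams = {"a1": "famX", "a2": "famX", "a3": "famX"}
        species = {"a1": "spA", "a2": "spB", "a3": "spA"}
        events, summary = cluster_events(calls, fams, species)
        assert summary == {"n_events": 1, "n_species_specific": 0,
                           "n_shared": 1}
        assert sorted(events[0].gene_ids) == ["a1", "a2", "a3"]

    def test_different_families_split(self):
        calls = [self._call("a1"), self._call("a2")]
        fams = {"a1": "famX", "a2": "famY"}
        species = {"a1": "spA", "a2": "spA"}
        _, summary = cluster_events(calls, fams, species)
        assert summary == {"n_events": 2, "n_species_specific": 2,
                           "n_shared": 0}

    def test_conservation_for_singletons(self):
        n = 17
        calls = [self._call(f"g{i}") for i in range(n)]
        fams = {f"g{i}": f"fam{i}" for i in range(n)}
        species = {f"g{i}": f"sp{i % 4}" for i in range(n)}
        _, summary = cluster_events(calls, fams, species)
        assert summary["n_events"] == n
        assert summary["n_species_specific"] + summary["n_shared"] == n

    def test_missing_family_becomes_singleton(self):
        calls = [self._call("a1"), self._call("a2")]
        fams = {"a1": "famX"}
        species = {"a1": "spA", "a2": "spB"}
        events, summary = cluster_events(calls, fams, species)
        assert summary["n_events"] == 2

    def test_unconfirmed_calls_excluded(self):
        calls = [self._call("a1"),
                 PhyloCall(gene_id="a2", call=Call.VERTICAL)]
        events, summary = cluster_events(calls, {"a1": "f"}, {"a1": "spA",
                                                              "a2": "spA"})
        assert summary["n_events"] == 1


def test_load_gene_tree_from_world(small_world):
    truth = small_world["truth"]
    gid = truth.loc[truth["has_tree"], "gene_id"].iloc[0]
    tree = load_gene_tree(small_world["path"] / "trees" / f"{gid}.nwk")
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    assert sum(l.startswith("QUERY") for l in labels) == 1
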