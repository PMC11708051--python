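"""Gene-tree validation of an HGT candidate.

A candidate is confirmed when its query leaf nests inside a well-supported
clade of prokaryotic sequences.  The same taxonomy as in the screening
example classifies each leaf; support_min=95 follows the ultrafast
bootstrap convention."""

import dendropy

from hgtscan import TaxonomyDB, classify_query

lineages = {
    "Amanita_recipiens": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                          "Agaricales", "Amanitaceae", "Amanita"),
    "Fusarium_aliud": ("Eukaryota", "Ascomycota", "Sordariomycetes",
                       "Hypocreales", "Nectriaceae", "Fusarium"),
    "Coprinus_alter": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                       "Agaricales", "Psathyrellaceae", "Coprinus"),
    "Escherichia_coli": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                         "Enterobacterales", "Enterobacteriaceae",
                         "Escherichia"),
    "Pseudomonas_putida": ("Bacteria", "Proteobacteria",
                           "Gammaproteobacteria", "Pseudomonadales",
                           "Pseudomonadaceae", "Pseudomonas"),
}
tax = TaxonomyDB({sp: (*lin, sp) for sp, lin in lineages.items()})

trees = {
    "transfer": ("(((QUERY__g1:0.1,Escherichia_coli:0.1)97:0.1,"
                 "Pseudomonas_putida:0.2)98:0.1,"
                 "(Fusarium_aliud:0.1,Coprinus_alter:0.1)99:0.2);"),
    "vertical": ("((QUERY__g1:0.1,Fusarium_aliud:0.1)97:0.1,"
                 "(Escherichia_coli:0.1,Pseudomonas_putida:0.1)99:0.2);"),
    "no ingroup sampled": ("((QUERY__g1:0.1,Escherichia_coli:0.1)96:0.1,"
                           "Pseudomonas_putida:0.3);"),
}

for name, nwk in trees.items():
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    call = classify_query(tree, tax, "Amanita_recipiens", "g1",
                          support_min=95)
    print(f"{name:20s} -> {call.call.value:10s} donor={call.donor_label or '-':15s}"
          f" support={call.support_at_decision:.0f}")

print("\nHGT and HGT_NT count as confirmed transfers; HGT_NT marks trees")
print("with no fungal (ingroup) sequence sampled at all.")
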