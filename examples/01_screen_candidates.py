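"""Similarity screening on a tiny hand-built hit table.

Builds a taxonomy and a per-gene hit list, then computes the three
screening statistics: the Alien Index (positive when the best prokaryotic
hit beats the best fungal hit), the outgroup percentage among top distinct
species, and the LPI-style lineage-coherence score (low for genes whose
strongest homologs are taxonomically foreign)."""

import pandas as pd

from hgtscan import TaxonomyDB, alien_index, lpi_score, outgroup_percentage
from hgtscan.homology_screen import HIT_COLUMNS

lineages = {
    "Amanita_recipiens": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                          "Agaricales", "Amanitaceae", "Amanita"),
    "Coprinus_alter": ("Eukaryota", "Basidiomycota", "Agaricomycetes",
                       "Agaricales", "Psathyrellaceae", "Coprinus"),
    "Fusarium_aliud": ("Eukaryota", "Ascomycota", "Sordariomycetes",
                       "Hypocreales", "Nectriaceae", "Fusarium"),
    "Escherichia_coli": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                         "Enterobacterales", "Enterobacteriaceae",
                         "Escherichia"),
    "Pseudomonas_putida": ("Bacteria", "Proteobacteria",
                           "Gammaproteobacteria", "Pseudomonadales",
                           "Pseudomonadaceae", "Pseudomonas"),
    "Bacillus_subtilis": ("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                          "Bacillaceae", "Bacillus"),
    "Streptomyces_grisea": ("Bacteria", "Actinobacteria", "Actinomycetia",
                            "Streptomycetales", "Streptomycetaceae",
                            "Streptomyces"),
    "Flavobacterium_aquatile": ("Bacteria", "Bacteroidetes",
                                "Flavobacteriia", "Flavobacteriales",
                                "Flavobacteriaceae", "Flavobacterium"),
}
tax = TaxonomyDB({sp: (*lin, sp) for sp, lin in lineages.items()})


def hits(rows):
    df = pd.DataFrame(
        [("gene1", f"{sp}|p{i}", 48.0, 120, 40, 0, 1, 120, 1, 120, ev, bs, sp)
         for i, (sp, ev, bs) in enumerate(rows)], columns=HIT_COLUMNS)
    df["rank"] = range(len(df))
    return df


# a horizontally acquired gene: strong, taxonomically broad bacterial hits
# and one weak fungal hit (5 of 6 distinct species are outgroup -> 83%)
foreign = hits([("Escherichia_coli", 1e-80, 290),
                ("Pseudomonas_putida", 1e-72, 270),
                ("Bacillus_subtilis", 1e-60, 230),
                ("Streptomyces_grisea", 1e-55, 215),
                ("Flavobacterium_aquatile", 1e-50, 200),
                ("Fusarium_aliud", 1e-6, 52)])
# a vertically inherited gene: strong hits from fungi of the recipient's
# own class, weak bacterial ones
native = hits([("Coprinus_alter", 1e-95, 330),
               ("Fusarium_aliud", 1e-88, 310),
               ("Escherichia_coli", 1e-3, 45)])

for name, h in (("foreign-like", foreign), ("native-like", native)):
    ai = alien_index(h, tax, "Amanita_recipiens")
    outg = outgroup_percentage(h, tax, "Amanita_recipiens")
    lpi = lpi_score(h, tax, "Amanita_recipiens")
    print(f"{name:13s} AI={ai:+8.2f}  outg_pct={outg:5.1f}  lpi={lpi:.2f}")

print("\nAI > 0 with outg_pct > 80 and a low LPI flags the first gene as an")
print("HGT candidate; the second fails all three filters.")
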