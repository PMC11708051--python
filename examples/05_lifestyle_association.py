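"""Lifestyle traits vs HGT abundance: permutation RDA and PGLS.

Builds a small set of genomes whose transfer counts depend on lifestyle
(parasites > saprotrophs > symbionts), then tests the association with the
permutation RDA (no phylogeny) and with PGLS under Brownian motion on a
star tree (no shared history, so it reduces to OLS)."""

import dendropy
import numpy as np
import pandas as pd

from hgtscan import group_summaries, pgls_fit, rda_permutation_test

rng = np.random.default_rng(3)
n = 30
genomes = [f"g{i}" for i in range(n)]
lifestyle = pd.Series(rng.choice(["parasite", "saprotroph", "symbiont"], n),
                      index=genomes, name="primary_lifestyle")
base = {"parasite": 60, "saprotroph": 40, "symbiont": 20}
counts = pd.Series([rng.poisson(base[l]) for l in lifestyle],
                   index=genomes, dtype=float)

rda = rda_permutation_test(counts, lifestyle, n_perm=999, seed=0)
print(f"RDA  : F={rda.statistic:.2f}  p={rda.p_value:.4f}  (999 permutations)")

star = dendropy.Tree.get(
    data="(" + ",".join(f"{g}:1.0" for g in genomes) + ");",
    schema="newick", preserve_underscores=True)
pgls = pgls_fit(star, counts, lifestyle)
print(f"PGLS : F={pgls.statistic:.2f}  p={pgls.p_value:.2e}")

print("\nper-lifestyle medians (ranked):")
print(group_summaries(counts, lifestyle).to_string(index=False))
print("\nBoth tests find the planted lifestyle effect; on real data PGLS")
print("additionally corrects for shared phylogenetic history.")
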