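# hgtscan

Detection and characterization of prokaryote-to-fungus horizontal gene
transfer (HGT), built as a reusable Python library with a thin command-line
layer, and exercised end-to-end on synthetic genomes with planted
transfers.

## The problem

Fungal genomes carry a small minority of genes acquired from bacteria,
archaea and viruses rather than inherited vertically. Finding them from
homology evidence alone is error-prone: contaminant contigs, database
biases and weak trees all masquerade as transfers. The standard defense is
a funnel of increasingly strict evidence:

1. **Similarity screening.** For each gene, three statistics are computed
   from a taxonomically annotated homology hit table:
   - the **Alien Index**, `AI = ln(bbh_in + f) − ln(bbh_out + f)`, where
     `bbh_in`/`bbh_out` are the best E-values among ingroup (fungal) and
     outgroup (prokaryotic/viral) hits, `f = 1e−200`, and a missing side
     takes the parse-time cutoff E-value of 1. `AI > 0` means the best
     outgroup hit beats the best fungal hit;
   - **outg_pct**, the percentage of outgroup species among the top 200
     distinct non-self subject species;
   - an **LPI**-style lineage-coherence score in [0, 1] (bitscore-weighted
     fraction of lineage ranks shared between the strongest hits and the
     recipient), filtered at the lowest 10% per genome.
   A candidate needs a low LPI, `AI > 0` and `outg_pct > 80%`.
2. **Gene-tree validation.** A candidate is confirmed (`HGT`, or `HGT_NT`
   when no ingroup species is sampled at all) only if its query leaf nests
   inside a bootstrap-supported (≥ 95) clade of outgroup sequences;
   otherwise it is vertical or unresolved.
3. **Genome-context filters.** Analysis is restricted to genes on contigs
   longer than 100 kb, and contigs whose gene content is ≥ 50% confirmed
   HGT are discarded as contamination.

Confirmed transfers are then grouped into events by (gene family, donor
group), and characterized: donor-phylum mix, NG86 Ka/Ks selection regimes
(with Jukes–Cantor correction, `d = −¾ ln(1 − 4p/3)`), intron gains and
their native-genome origins (seed-and-extend search, origin = coverage
> 0.5), expression of intron-bearing vs intronless transfers, and
lifestyle-trait association via permutation RDA and phylogenetic GLS under
Brownian motion.

Because the real inputs (hundreds of genomes, an nr-scale homology search)
are not desk-reproducible, the package ships a first-class synthetic-data
generator that plants transfers with controlled E-value gaps, donor mixes,
tree supports, intron copies, selection regimes and lifestyle effects —
every stage is testable against a truth ledger.

## Worked example

```bash
python examples/06_full_pipeline.py
```

generates a compact world (6 genomes × 250 genes, ~2% planted transfers)
and runs the whole funnel. Output from one run:

```
planted transfers: 34

funnel: {
 "genes_total": 1535,
 "genes_on_long_contigs": 1439,
 "candidates": 52,
 "confirmed": 52,
 "final": 34,
 "long_contig_pct": 93.7,
 "hgt_fraction_pct": 2.21
}
recall=1.000 FDR=0.000
events: {'n_events': 28, 'n_species_specific': 24, 'n_shared': 4}
donor mix (%): {'Actinobacteria': 29.4, 'Bacteroidetes': 2.9, 'Cyanobacteria': 2.9,
                'Firmicutes': 5.9, 'Proteobacteria': 52.9, 'Viruses': 5.9}
Ka/Ks classes: {'purifying_strong': 26, 'intermediate': 2, 'positive': 6, 'undefined': 0}
intron gain %: 53.0
intron origins: {'origin_found_pct': 100.0, 'origin_mean_identity': 92.59}
expression intron-higher %: 100.0
```

Reading it: 52 genes passed similarity screening (the 34 planted transfers
plus the planted contaminant-contig genes), tree validation confirmed all
52, and the ≥ 50% contamination rule removed the contaminant contigs,
leaving exactly the 34 planted transfers (recall 1.0, FDR 0). Donor
proportions scatter around the configured mix at this small sample size;
every gained intron traces back to the native genome at ~93% identity, and
intron-bearing transfers ran higher in expression in every dataset.

The other examples each exercise one capability: screening statistics
(`01`), gene-tree classification (`02`), Ka/Ks recovery of planted
selection regimes (`03`), intron origin search (`04`), and lifestyle
association (`05`).

The same funnel is scriptable from the shell:

```bash
hgtscan simulate --seed 1 --outdir world --genomes 10 --genes 400
hgtscan all --world world --outdir results
```

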