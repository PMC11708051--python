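# Methods

This note documents the models, conventions and design choices behind
`hgtscan`, in the order the pipeline runs them.

## Taxonomy and group labels

Every subject species carries a seven-rank lineage (domain, phylum, class,
order, family, genus, species), supplied as a TSV table rather than queried
from a live service, keeping runs hermetic. Relative to a recipient genome
a species is **SELF** (same genus), **INGROUP** (any other fungus) or
**OUTGROUP** (everything else, including non-fungal eukaryotes). The
self-exclusion rank is a package convention: excluding the recipient's own
genus prevents self-hits from masking transfers when the best ingroup hit
is taken, without discarding informative confamilial fungi. Donor
attribution reports the phylum for bacteria and the domain for archaea and
viruses, matching how donor spectra are usually summarized.

## Similarity screening

Hit tables are the 12-column tabular hit format plus a subject-species
column; rows with E-value above 1 are dropped at parse time.

- **Alien Index.** `AI = ln(bbh_in + f) − ln(bbh_out + f)` with
  `f = 1e−200` and a missing best hit set to E-value 1 (the parse cutoff),
  so a gene with no fungal homolog at all is driven strongly positive.
  Natural log and the 1e−200 floor follow the Alien-Index literature. AI is
  antisymmetric under swapping the two best E-values.
- **outg_pct.** Hits are walked in rank order keeping the first occurrence
  of each distinct non-self species until 200 are collected; the statistic
  is the percentage of those that are outgroup. Counting distinct species
  (not raw rows) keeps heavily resequenced taxa from dominating. Whether
  the original tools deduplicate before or after the cap of 200 is not
  documented anywhere we could verify; deduplicating first is our
  convention.
- **LPI surrogate.** The lineage-probability-index pre-filter is
  reimplemented as a lineage-coherence score: over non-self hits within
  10% of the best bitscore, the bitscore-weighted mean of the fraction of
  ranks (domain through genus, top-down, stop at first mismatch) shared
  with the recipient. Congeneric hits score 1, other-domain hits 0. The
  10% filter threshold is applied as a per-genome percentile of defined
  scores, with boundary ties included — erring toward recall is safe
  because phylogenetic validation follows.
- **Candidate rule.** LPI in the lowest 10% AND `AI > 0` AND
  `outg_pct > 80`, both strict as printed. Genes with undefined statistics
  are never candidates. Raising either threshold can only remove
  candidates (monotonicity, property-tested).

## Gene-tree validation

Trees are consumed, not inferred; internal node labels are support values
(absent support counts as 0), and exactly one leaf carries the `QUERY`
prefix. Walking rootward from the query, the first ancestor below the root
with support ≥ `support_min` (default 95, the usual ultrafast-bootstrap
acceptance level) and at least one non-query leaf defines the decision
clade C:

- C entirely outgroup, ingroup elsewhere in the tree → **HGT**;
- C entirely outgroup, no ingroup leaf anywhere → **HGT_NT**;
- any ingroup leaf in C → **VERTICAL**;
- no such ancestor → **UNRESOLVED** (also the fate of candidates with no
  tree file).

The donor label is the majority donor group of C, ties broken by the
best-supported child clade. Non-fungal eukaryote leaves count as outgroup
for clade composition but only become the donor label if they dominate C.
Calls are invariant to leaf order and branch-length rescaling, and raising
`support_min` can only move calls toward UNRESOLVED.

Rooting: midpoint by default; when leaves from a domain that is neither
eukaryotic nor the dominant non-eukaryote domain are present, the tree is
rooted on that extraneous lineage instead. Synthetic trees are generated
pre-rooted, so classification does not depend on rerooting in tests.

**Events.** Confirmed genes sharing (family, donor group) merge into one
transfer event; an event confined to one recipient species is "species
specific". The family assignment is an input contract (the truth ledger in
synthetic worlds; an orthology table in real use) — the event-merging rule
is our explicit convention, and `n_species_specific + n_shared = n_events`
holds by construction.

## Genome-context filters

Coordinates are 1-based inclusive (GFF3 convention) throughout; distances
are gap lengths in bp. "Longer than 100 kb" is strict; "≥ 50% HGT" is
inclusive — both exactly as printed in the sources of these heuristics.
The contamination filter is monotone in its threshold (a lower fraction
discards a superset of contigs) and a sweep helper reports retained-call
counts across 10%–80%.

Rank-sum comparisons (contig lengths with/without HGT, hit identities,
TE distances) use the Mann–Whitney U with midrank ties: exact enumeration
of all assignments when both samples have ≤ 8 observations (two-sided p by
doubling the smaller tail, capped at 1), the normal approximation with
continuity correction otherwise.

## NG86 Ka/Ks

Per codon, each position contributes its synonymous fraction over
single-base changes that do not create a stop; site counts always sum to 3
per codon. Between codons differing at k positions, all k! pathways are
averaged, excluding pathways through stops; if every pathway hits a stop,
all are averaged with stop-traversing steps counted as nonsynonymous (the
counting convention of the NG-model calculators). Sites are averaged over
the two sequences; proportions get the Jukes–Cantor correction
`d = −¾ ln(1 − 4p/3)`. `Ks = 0` and saturation (`p ≥ ¾`) are reported as
distinct undefined-ratio cases. Gapped or ambiguous codon columns are
dropped pairwise, trailing stop columns are dropped, internal stops are an
error. The implementation is table-driven (per-codon and per-codon-pair
caches); an exhaustive pathway-enumeration oracle in the test suite checks
equivalence to 1e−12 on random pairs.

Selection classes use strict bounds: ratio < 0.5 strong purifying, > 1
positive, the rest intermediate; undefined ratios are tallied separately.

## Introns

Intron *i* spans `exon_i.end+1 … exon_{i+1}.start−1`; exon and intron
lengths always reconstruct the gene span. Since prokaryotic donors lack
spliceosomal introns, any intron in a confirmed transfer is treated as a
post-transfer gain structurally, without ancestral-state reconstruction.

The origin search is a deterministic seed-and-extend: exact k-mer seeds
(default k = 7, both strands, one extension per diagonal) extended
ungapped at +1/−2 with X-drop 6; the best hit is converted to coverage
(aligned positions / intron length) and identity (matches / aligned
columns); an origin is "found" iff coverage > 0.5. k = 7 emulates a
short-sequence-tuned search on intron-scale queries; the ungapped
extension keeps the search dependency-free and reproducible. On random
(unrelated) sequence the short seed produces spurious seeds but the −2
mismatch penalty keeps extensions below the coverage bar.

Expression comparisons are made only within a dataset, using arithmetic
means and a strict inequality for the "intron-bearing higher" indicator
(median-based variants would also be defensible; mean is our convention).
The summary fraction is invariant to rescaling any dataset by a positive
constant; datasets missing one group are excluded with the denominator
adjusted.

## Trait association

- **Permutation RDA.** The per-genome response (HGT count by default; a
  donor-composition matrix is equally valid and supported) is
  column-centered and projected onto the one-hot trait design; the
  pseudo-F is compared with its distribution under row permutation,
  `p = (1 + #{F* ≥ F}) / (1 + B)` (add-one, so p is never 0 and never
  below `1/(B+1)`). Deterministic under a fixed seed; invariant to level
  relabelling and response shifts.
- **PGLS.** Brownian-motion covariance `C_ij = shared root-to-tip path
  length`; GLS by Cholesky whitening; the trait's coefficients are tested
  jointly with an F test against the intercept-only GLS model. Counts are
  log1p-transformed by default to stabilize variance. On a star phylogeny
  the fit equals OLS to 1e−10 (tested). Degenerate cases: a constant
  response gives F = 0, p = 1; an exactly collinear response gives the
  smallest representable p rather than 0; a numerically singular C (zero
  branch lengths) gets a tiny ridge.
- Genomes with a missing trait value are dropped per-trait; `n_used` is
  reported.

## The synthetic world

The generator emits, per world: a lineage table; per-genome contig tables,
GFF3 annotations (genes, exons, transposable elements), and hit tables;
gene trees for all genes that can reach the tree stage; aligned coding
pairs; ≥ 13 expression datasets; a lifestyle-trait table; a birth–death
species tree; and a truth ledger covering every gene exactly once.
Identical seeds give byte-identical bundles.

Default study conditions: 50 genomes × ~2,000 genes, 2% planted transfer
fraction modulated by lifestyle (parasite × 1.6, saprotroph × 1.0,
symbiont × 0.5) and growth form (yeast × 1.3, filamentous × 1.0, thallus
× 0.6); donor mix Proteobacteria 45%, Actinobacteria 36%, Firmicutes 7%,
Bacteroidetes 6%, Cyanobacteria 4%, Archaea 1.3%, Viruses 0.7%; intron
gain probability 0.44 with intron copies point-mutated at 10%; selection
regimes dN/dS ∈ {0.1, 0.3, 1.0, 2.0} with probabilities
{0.45, 0.35, 0.15, 0.05}; lognormal(1, 0.6) expression with a ×1.5 intron
multiplier; two injected contaminant contigs per world (8–15 all-prokaryotic
genes each, long enough to pass the 100-kb filter so the contamination rule
has work to do); ~80% of genes on >100-kb contigs; transfers placed only on
long contigs (capped at 30% of a contig's genes so true contigs never trip
the 50% rule), with a transposable element planted within 1.5 kb.

E-value structure: planted transfers draw outgroup log10-E-values in
[−80, −30] and ingroup in [−20, −3] (AI > 0 by construction, with margin);
native genes the converse; "decoy" natives (2%) get a positive AI but a
~50% outgroup share and mid-range coherence, so they pass the LPI
percentile but fail outg_pct — they exercise the screen without inflating
the FDR, and their trees are vertical in any case. Tree decision-clade
support is drawn ≥ 95 with probability 0.97 (else 55–94), so ~3% of
planted transfers are deliberately lost at validation; end-to-end recall
lands near 0.96 against the ≥ 0.90 design target.

Coding pairs are evolved by uniform single-base proposals accepted with
probability min(1, ω) for nonsynonymous and min(1, 1/ω) for synonymous
changes (stops rejected), 0.8 proposals per codon — this realizes a
realized dN/dS close to ω under NG86 counting at moderate divergence
(Ks ≈ 0.3).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: profile-realistic sequence composition (copy-
and-mutate only), indels and recombination, alignment and tree-inference
error (trees are constructed, not inferred), database incompleteness,
taxonomic misannotation of subjects, and expression quantification noise
beyond lognormal scatter. The pipeline's discrimination numbers on
synthetic worlds are design verifications, not field accuracy estimates.

### Problem sizes used in the shipped checks

Module tests run on a 6-genome × 250-gene world with sequence content for
one genome; the detection-recovery check runs on the default 50 × 2,000
world; the contamination-rule check uses 20 independent 4 × 150 worlds;
Ka/Ks recovery uses 50 pairs × 300 codons per regime; PGLS recovery uses a
64-tip tree × 100 replicates; type-I calibrations use 500 replicates with
199 permutations each. Sequence content is materialized only where the
intron origin search consumes it; all other contigs are carried as lengths
in `contigs.tsv` (the FASTA path is equally supported and tested).

## Known limitations

- The LPI surrogate is a coherence score, not the original
  database-frequency model; only its filtering role (lowest-decile
  pre-screen) is preserved.
- Event clustering requires an external family assignment; without one,
  confirmed genes become singleton events.
- The origin search is ungapped; a true origin interrupted by an indel
  larger than the X-drop allowance is reported with reduced coverage.
- PGLS supports only the Brownian covariance (no Pagel's lambda or OU).
- The report layer's percentages use half-up rounding; banker's rounding
  consumers will disagree in the last digit.
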