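# Methods

## Overview

`synstrain` compares strains of a microbial species (bacterium, phage or
plasmid) across genomes or metagenomic assemblies without calling SNPs.
The unit of comparison is a ~5-kbp homologous region; the signal is
microsynteny — whether the region aligns as one uninterrupted colinear
block or has been broken up by insertions, deletions or rearrangements.
The method runs in three parts:

1. **Fragmentation.** Each per-species reference genome is sliced into
   1-kbp *central regions* spaced 4 kbp apart (window period 5 kbp).
   Windows anchor at contig position 0 and partial terminal windows are
   dropped, so region identifiers (`contig:start`) are deterministic.
   Windows with more than 10% ambiguous bases are skipped: they cannot
   seed a meaningful homology search (threshold configurable).
   Coordinates are 0-based half-open everywhere.

2. **Homology search and binning.** Central regions are searched against
   all sample assemblies at high stringency (identity ≥ 97%, query
   coverage ≥ 70%), each passing hit is retrieved together with 2-kbp
   flanks on both sides (hits lacking a full flank are excluded, keeping
   bin members uniformly ~5 kbp), and the retrieved sequences are grouped
   into region-specific bins, at most one sequence per sample (best
   score; ties broken by leftmost coordinate, then contig id). Minus-
   strand hits are reverse-complemented so a bin shares one orientation.

3. **Synteny scoring and APSS.** Within each bin, every sequence pair is
   scored: `score = 1 + log10((Ov/len)/B)` with `B` the number of synteny
   blocks, `len` the shorter sequence's length and `Ov` the accumulated
   block length measured on the shorter sequence. The score is at most 1,
   attained exactly when one block covers the shorter sequence end to
   end. Pairs with `Ov` < 4,800 bp are dropped (scaled as
   `0.96 × (region_length + 2·flank)` for non-default flanks). For each
   sample pair, `n` region scores (default sweep n = 40, 60, 80, 100,
   200) are drawn uniformly without replacement and averaged into the
   APSS; pairs with fewer than `n` scored regions are excluded. An APSS
   strictly above the same-strain threshold (default 0.95, calibrated for
   human-gut species) designates the same strain.

## Search engine

The search uses an exact k-mer position index (word size 11; k-mers
containing ambiguous bases are never indexed) over all contigs of all
samples. Seeds are clustered per contig and diagonal band (half-width
64 bp) on both strands; each cluster's query/target span is extended
ungapped at the ends and re-scored with an optimal edit-distance
alignment (edlib) over the spanned segments, which directly yields the
reported identity (matches / alignment columns) and query coverage
(spanned query bases / region length). At the 97% gate the inputs are
near-identical, so the optimal edit-distance alignment over the chained
span is an exact re-statement of what a banded affine extension would
accept or reject, and it makes the reported identity *equal* to the
full-alignment identity rather than merely close to it. Overlapping hits
on one target locus are merged into the best one. A BLAST tabular file
(outfmt 6, subject ids in `sample|contig` form) can be ingested in place
of the internal engine to reproduce an external front end exactly.

## Block finding

Anchors are maximal exact matches: shared k-mers (k = 11; k-mers
occurring more than 8 times in either sequence are masked as repeats) are
merged along diagonals and extended to maximal length. The
highest-coverage colinear chain is selected by dynamic programming
(crossing anchors are discarded — bins are orientation-normalized, so an
inversion simply loses coverage and splits blocks, which is the intended
penalty). Consecutive chain anchors join the same block iff the
inter-anchor gap is ≤ 15 bp in *both* sequences and the absolute diagonal
shift between them is ≤ 15 bp (`max_gap`/`max_sep`). Consequences of
these semantics, all exercised by tests:

* a lone substitution never splits a block (gap 1 bp on each side);
* two nearby substitutions never split (either an anchor survives
  between them or the combined gap stays ≤ 15);
* three or more substitutions packed within ~15 bp can split;
* indels ≤ 15 bp do not split; longer indels always do.

Blocks span from the first anchor's start to the last anchor's end in
each sequence, so isolated mismatches inside a block do not reduce `Ov`;
sequence before the first anchor and after the last is not counted.

## Threshold calibration

Within-host pairs (same donor, different timepoints) are assumed to be
the same strain; between-host pairs different strains. Per species and
subsampling depth, an ROC is built over candidate thresholds (midpoints
between consecutive distinct APSS values plus sentinels) and the
threshold maximizing Youden's J = sensitivity + specificity − 1 is
selected, ties resolved toward the higher (more specific) threshold —
verified against an exhaustive cutpoint scan. Per-species optima are
averaged over repeated subsampling draws (default 100 iterations), and
the per-depth *threshold APSS* is the unweighted mean over species
(species contribute equally regardless of pair counts). Train/test
splits are always by donor, never by sample, to prevent leakage of a
donor's strain into both sides.

## Dual-metric modes and group contrasts

Given an externally computed SNP-based similarity (popANI, consumed from
a TSV), the most-similar 5% of comparisons under each metric are selected
by rank (ties at the boundary broken by stable input order) and each
species is tested for enrichment in each top set with the upper-tail
hypergeometric probability P(X ≥ k). The point pmf is exposed separately;
enrichment is deliberately the tail probability, since a point
probability cannot order "more enriched than expected". The species map
position is `log10(p_popani / p_apss)` — positive means the species
concentrates in the synteny top set (structural change;
hyper-recombinator), negative in the SNP top set (hypermutator) — with
`min(p)` as the degree of enrichment. Geographic contrasts use a
one-sided Wilcoxon–Mann–Whitney test (exact when the combined group size
is ≤ 20 and untied, normal approximation with tie correction otherwise),
Benjamini–Hochberg correction across species, and Cohen's d with the
conventional bins (negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large).

## Trees and networks

Synteny distances are d = |APSS − 1|. UPGMA is implemented directly so
tie-breaking is deterministic (lexicographically smallest pair of cluster
labels, clusters labeled by their smallest leaf); output is newick.
Tree comparison uses the classic Robinson–Foulds distance (bipartitions
present in exactly one tree, canonicalized so rooted and unrooted
encodings agree); the generalized information-based variant is out of
scope. Significance comes from shuffling the synteny tree's leaf labels
(default 100,000 iterations) with add-one smoothing,
p = (hits + 1)/(iterations + 1), so the attainable floor at the default
is just below 1e-5 and p = 0 is impossible. The p-values are valid but
conservative (the RF statistic is discrete). Networks have hosts as
nodes; sample-pair APSS values aggregate to a host pair by maximum —
a genuinely open design point, resolved toward the strongest evidence
that the two hosts share a strain (a mean would dilute one genuinely
shared strain with unrelated sample pairs). Edges require APSS ≥ 0.75, carry weight −log10(APSS), and
hosts left edgeless are removed.

## Evolution simulator

`popsim.evolve` grows `n_lineages` independent lineages from one random
ancestor (star genealogy). Per generation and lineage, the number of
substitutions is drawn Binomial(L, mu_snp) with uniformly chosen distinct
sites and uniform non-identical replacement bases — exactly equivalent to
independent per-site Bernoulli mutation — and indel events
Binomial(L, mu_indel), insertion/deletion equiprobable, lengths uniform
1–50 bp by default (the generating process behind published comparisons
does not state its length law, so it is configurable; uniform 1–50 spans
both block-preserving ≤ 15 bp and block-splitting > 15 bp lengths).
Defaults are the validation conditions: 20-kbp region, 20 lineages, 3,000
generations, snapshots every 150 generations, mu_snp = 1e-6 or
mu_indel = 1e-7. Percent identity is computed from optimal global
alignments (edlib); synteny scores use the full region as a single
pairwise comparison (190 pairs per timepoint for 20 lineages).

What the star genealogy does **not** model: shared ancestry within the
population (a Wright–Fisher or Moran pedigree), selection, recombination
between lineages, or within-population polymorphism at sampling time. The
main visible consequence is slightly *higher* pairwise divergence than a
coalescent population of the same age (every pair diverges for the full
2T generations), so the simulated minimum mean identity sits at the low
end of the plausible band around the published value (the
independent-lineage expectation at T = 3,000, mu = 1e-6 is ≈ 99.40%).
The substitution-only synteny-score minimum is affected more strongly:
block splits require dense substitution clusters, whose rate grows
roughly cubically with pairwise divergence, and the across-timepoint
minimum selects downward excursions that are correlated across pairs
(one lineage's cluster affects all 19 of its pairs). The simulated
minimum mean score therefore sits visibly below what a shared-ancestry
population of the same age produces. These offsets are a property of
the documented genealogy choice, not of the scoring, and the acceptance
script reports the honestly computed values.

Fixture generators build on the same mutation machinery:
`make_toy_dataset` plants lightly mutated strain copies of a reference
plus decoy contigs into per-sample assemblies for end-to-end tests;
`make_labeled_population` generates donors at between-host divergence
(substitutions ~0.4%/site plus occasional indels) with two longitudinal
samples each at small extra within-host divergence, and scores all
sample pairs region by region. These emulate strain structure, not real
metagenomes: no coverage variation, no chimeric contigs, no
inter-species homology beyond random decoys — so passing calibration
tests demonstrates the statistical machinery recovers a threshold under
clean separation, not field performance on real gut data.

## Numerical and design choices

* Subsampling RNG is seeded per (species, pair, n) by CRC-32 folding of
  the master seed, so adding samples never perturbs existing pairs'
  draws; iteration indices are folded in additively.
* `Ov` is clamped to `len`, and `score == 1` iff B = 1 and Ov = len;
  unscorable pairs (no anchors) are dropped, never given a pseudo-score.
* Anchor chaining allows a few bp of anchor overlap (shared indel
  flanks); overlaps are discounted from chain coverage and trimmed when
  blocks are emitted, keeping blocks mutually non-overlapping.
* Degenerate inputs: empty bins and single-member bins yield no scores;
  a self-pair APSS of an assembly against its duplicate is exactly 1;
  UPGMA refuses incomplete matrices listing the missing pairs.
* Problem sizes in the test suite (5 simulation seeds for the
  substitution-only sweep, 10 replicate pairs for the indel ordering at
  the final generation only, 500 oracle fixtures, 8 donors × 220 regions
  × 2 species for calibration) were chosen as the smallest sets that
  exercise each claim with stable statistics.

## Known limitations

* No inversion- or translocation-aware block typing; inversions are
  penalized via lost coverage only.
* The search engine has no e-value model; stringency comes entirely from
  the identity and coverage gates, as in the underlying method.
* Calibration and the dual-metric analyses are exercised on synthetic
  populations; applying shipped defaults (0.95 same-strain cutoff) to a
  new environment should be preceded by recalibration on longitudinal
  data from that environment.
* popANI is consumed, never computed; no SNP calling of any kind.
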