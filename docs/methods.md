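# Methods

## Scope and model

`radpop` reconstructs a single-enzyme RAD-seq analysis end to end: read
cleaning, de novo stack assembly with hard-threshold genotyping,
cross-accession SNP cataloguing, genotype-distance phylogenetics, PCA,
heterozygosity, within-group diversity and a loss-of-diversity (LOD)
selection scan, plus transcript mapping with synonymous/non-synonymous
classification. Because the target design is a wild/cultivated panel
without a reference genome, every stage is validated against a synthetic
data generator that plants known structure and records it in a truth
table.

Coordinates are 0-based, half-open throughout. All randomness flows from
a single integer seed per simulation; a fixed configuration and seed
reproduce byte-identical reads and truth tables.

## Read cleaning

A read is kept when at most 50% of its bases have Phred quality ≤ 5
(strictly-greater-than-half drops; a 50-nt read with exactly 25 low
bases is kept), it matches no adapter (exact substring screen over a
configurable list; no adapter algorithm beyond that is modelled), its
prefix exactly equals a registered barcode, and the five bases after the
barcode are the EcoRI remnant `AATTC`. Barcode matching is exact:
with pairwise Hamming distance ≥ 2 a single sequencing error is
detectable but not reliably correctable, so error-containing barcodes are
discarded rather than rescued. Variable-length barcode sets are resolved
longest-match-first; generated sets are prefix-free, so at most one
length can match. Assigned reads are trimmed to 41 nt (5-nt remnant +
36-nt variable region); shorter remainders are discarded. Every discard
carries a reason code and `assigned + discarded == input` always holds.

## Stack assembly and genotyping

Identical tags cluster into stacks. Depth filters are inclusive on both
boundaries: depth 10 and depth 300 are retained, 9 ("low") and 301
("repetitive") are not. Retained stacks merge by *star linkage*: stacks
are processed depth-descending (ties broken by sequence for determinism)
and each joins the deepest seed within one mismatch, else founds a new
locus. Star linkage rather than transitive single linkage: chaining can
join arbitrarily distant sequences through intermediates, and the
depth-ordered star rule makes the outcome deterministic and local. One-
mismatch neighbour search uses masked-position dictionary keys, so
assembly is linear in stacks × tag length.

Per-site genotypes use the depth-ratio rule on the two deepest bases
(table in the README). Boundary ratios of exactly 0.05 and 0.1 are
*discarded* — the written rule uses strict inequalities on both sides, so
the closed interval between them is the ambiguous zone. The minimum site
depth of 10 is applied to A1+A2 per site, matching the per-stack minimum.
A third allele deeper than 0.1 of A1 marks the site non-bi-allelic and it
is discarded; shallower third alleles are treated as sequencing error.
When A1 and A2 tie in depth, A1 is the alphabetically first base — this
only affects reporting, since a ratio of 1 is always heterozygous.

## Catalog

Consensus sequences are matched across accessions with the same
depth-ordered, ≤ 1-mismatch star rule; the seed is the deepest locus
overall. An accession contributes at most one locus per entry: deeper
wins, the loser is logged as a putative paralog. A catalog entry becomes
a genotype-matrix row when it is genotyped in ≥ 14 of 18 accessions and
exposes exactly one variant position with exactly two alleles inside the
variable region (positions 5–40). The reference allele is the seed
consensus base at the SNP; calls showing alleles outside the pair become
missing. Monomorphic entries are tallied but never enter the matrix;
variants inside the 5-nt remnant are rejected as corrupt input, since
the remnant is invariant by construction. The completeness and
single-SNP predicates are pure functions of an analysed entry, so
applying them in either order yields the same matrix.

## Distances, trees, PCA

With genotypes coded 0/0.5/1 (alt-allele dosage halved), the pairwise
genotype distance is |g_i − g_j|, which reproduces the 0/0.5/1 rule
including distance 0 between two heterozygotes. D_ij averages over loci
genotyped in both accessions; a pair with no shared loci is an error
naming the pair. The per-SNP normalisation (divide by shared locus
count) is the default; dividing instead by shared nucleotides (41 × loci)
is available and changes only the scale, not the NJ topology.

Neighbor joining is the classical Q-criterion agglomeration with the
standard distance updates and a closed-form three-taxon finish. Negative
branch lengths are clamped to zero with the deficit moved to the sibling
branch, preserving the path length through the join; on additive
matrices clamping never fires and the generating tree is recovered
exactly (tested against a random-additive-tree path-length oracle at
1e-9). Bootstrap resamples loci with replacement, rebuilds distance and
tree per replicate, and reports the percentage of replicates containing
each reference bipartition; replicates with an undefined pair distance
are redrawn and counted. Leaf and near-trivial splits report 100%.

PCA fills missing dosages with the locus mean, centres per locus, and
eigendecomposes the accession × accession covariance matrix; coordinates
are eigenvectors scaled by the square roots of their eigenvalues. Only
cluster membership is asserted in tests — signs and absolute coordinates
are basis-dependent.

## Heterozygosity, π, LOD

Heterozygosity is `H = N_het / (41 × n_genotyped_loci) × 1000` per Kb,
bounded by 1000/41 ≈ 24.39. Within-group π at a locus is the mean
pairwise genotype distance over all unordered pairs of genotyped group
members — the estimator that reproduces the extreme worked examples
16/28 ≈ 0.57 (four vs four opposite homozygotes) and 3.5/28 = 0.125
(seven homozygotes + one heterozygote). π is undefined below 3 genotyped
members, a guard the scan shares. LOD = 1 − π_c/π_w where π_w > 0, else
undefined; the selected set is `π_c == 0 and π_w > 0`, an exact integer
condition needing no floating tolerance. The admixed landrace belongs to
neither group and is excluded from both.

## Transcript mapping and coding effects

Database-scale BLASTN searching is replaced by a deterministic ungapped scan
of the 36-nt variable region (both orientations) over each transcript,
with at most one mismatch, coverage strictly above 80% of the region and
identity strictly above 90%. No E-value is computed — there are no
database statistics in a toy setting, and at these thresholds an
alignment is either near-exact or absent. The best hit (fewest
mismatches, longest overlap) wins; exact ties break by transcript id and
are counted. SNPs inside an annotated CDS are classified by substituting
both alleles into the codon located via the annotated frame and
translating with the standard genetic code; CDS intervals that are not a
whole number of codons after the frame offset raise an error naming the
transcript. Classification is strand-consistent: a reverse-orientation
alignment complements the alleles before codon substitution.

## The synthetic data generator

The generator emulates the study conditions; its defaults are the
conditions under which the acceptance suite runs.

* **Panel.** 18 accessions in six groups — Css (6) and Csa (3)
  cultivated; Ctl (3), Ccc (4), Ctg (1) wild; Ctb (1) admixed.
* **Fragments.** `n_fragments` = 2000 random post-digestion fragments of
  300 nt starting with `AATTC`. A 2% subset is emitted in 10
  near-identical copies (differing only beyond the tag) so that pooled
  stack depth lands near 10 × 40 = 400×, safely above the 300×
  repetitive cut even after error-displaced reads; repeat families carry
  no variants.
* **Variants.** One variant per clean tag, uniform in the variable
  region; 5% of tags carry a second variant to exercise the single-SNP
  filter. Substitutions are transitions with probability 0.6, matching
  the TI share the study design anticipates (~60%).
* **Genotypes.** Per locus an ancestral frequency p ~ U(0.1, 0.9); each
  group's frequency is Beta(pτ_g, (1−p)τ_g) and accessions draw two
  haplotypes binomially (Hardy–Weinberg within group). τ_g is solved
  from the group's target heterozygosity via E[2f(1−f)] =
  E[2p(1−p)]·τ/(τ+1); the defaults (0.07–0.17 per SNP) are
  back-calculated from per-species heterozygosity rates of 1.7–5.2 per
  Kb over 41-nt tags. The admixed accession draws one haplotype from the
  Csa frequency and one from the Ctl frequency, which makes its high
  heterozygosity emergent rather than parameterised.
* **Selection.** A 4.2% subset of single-variant loci is planted with
  both cultivated groups fixed for one allele while wild groups are
  re-drawn around a mid-range ancestral frequency through the same drift
  law. The truth table's `selected` flag is then *recomputed from the
  realized non-missing genotypes* (cultivated fixed and homozygous, wild
  polymorphic, each with ≥ 3 genotyped members — the scan's own guard),
  so loci fixed by drift rather than planting are flagged on equal
  terms.
* **Reads.** Per fragment × accession the read count is Poisson with
  mean 40 by default (negative binomial with a size parameter is
  available; Poisson is its dispersion → ∞ limit and is appropriate for
  a pooled, size-selected single library). Heterozygotes split reads
  binomially between haplotypes. Substitution errors hit each base
  independently at 0.002; 2% of reads receive a low-quality tail (60% of
  bases at Q2) to exercise the quality filter — base errors and quality
  are modelled independently. 5% of locus × accession cells are planted
  missing. Reads are emitted pre-oriented: RAD reads start at the cut
  site, so there is no strand ambiguity by construction.
* **Truth.** Loci are `clean` when single-variant, non-repeat,
  polymorphic in realization and present in ≥ 14 accessions — exactly
  the loci the catalog is allowed to carry. Recovery metrics and the
  selected-set precision/recall are scored on this universe.

What the generator does **not** model: indels, paired ends, PCR
duplicates, chimeras, allele-specific amplification bias, base-quality
mis-calibration, and any correlation between quality and error. Passing
tests therefore demonstrate correctness of the discovery logic under the
stated error model, not robustness to every artefact of real libraries.

## Problem sizes and scenarios used by the test suite

The study-scale scenario runs the generator defaults (2000 tags, 40×,
e = 0.002, fixed seed) and asserts ≥ 95% of clean loci in the catalog,
≥ 95% genotype concordance, six monophyletic groups at ≥ 95% bootstrap
support over 200 replicates, and ≥ 99% precision/recall of the LOD
selected set. The perfect-data scenario (zero error, zero missing, no
quality tail) runs 1000 tags at 70× — the per-tag depth at which RAD tag
loci are typically observed in this design — and requires exact equality
with the truth table. Depth matters here: at 40× a heterozygote's
minor-haplotype stack falls below the hard 10× stack filter with
probability ≈ 1.5% (Poisson, retained-read mean ≈ 18 per haplotype) and
is then called homozygous; at 70× that probability is ~3 × 10⁻⁷, making
exactness a meaningful requirement.

## Known limitations

* The het→hom collapse above is the dominant error mode of the
  hard-threshold genotyper at 40×; it slightly deflates heterozygosity
  and can spuriously add near-fixed cultivated loci to the selected set
  (~1 per 2000 loci per run at default settings). A likelihood-based
  genotyper would mitigate it but is out of scope: the threshold rule is
  the method under study.
* Star-linkage stack merging and deepest-wins catalog seeding are
  deterministic policy choices where pairwise-mismatch language is
  ambiguous under chaining; the brute-force single-linkage alternative
  is kept in the tests to document where the two differ.
* dN/dS is a plain count ratio, not a substitution-rate estimate; with
  random codon placement its neutral expectation is ≈ 3, not 1.
* The one-mismatch transcript scanner is exhaustive (O(transcript ×
  region)); it is meant for toy transcript sets, not 10⁵-unigene
  databases.
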