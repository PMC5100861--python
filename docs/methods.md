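# Methods

This note documents the models, the defaults and why they were chosen, the
behavior of the synthetic-data generators, and the numerical and design
choices that were genuinely open.

## Family-cross model and QC

The family model is a single F1 cross: one mother, one father, and sexed
offspring (defaults 24 daughters, 23 sons). Genotypes are unordered,
unphased diploid allele pairs; the analysis uses only zygosity and allele
content, so phase is never represented and VCF half-calls are treated as
missing.

**Mendelian plausibility.** An offspring genotype is plausible iff it can
be assembled from one allele of each parent. When either parent is missing
the locus is unassessable and passes through QC unmodified (flagged): the
rule is defined relative to both parents and guessing would bias the scan.

**Undercall correction.** Allele dropout converts a heterozygote into one
of its two homozygotes. At a locus with parents A/T × A/A, the dropout
products of a true A/T offspring are A/A (plausible, undetectable) and T/T
(implausible, detectable) with equal probability — so the observable
implausible fraction at such loci is *u*/4 (P(het) = 1/2 × P(dropout) =
*u* × P(detectable homozygote) = 1/2), which the Monte-Carlo tests check.
The correction threshold defaults to 10%: strictly below it, implausible
cells become missing; at or above it the locus is discarded. The boundary
*f* = 0.10 itself discards — the source procedure states "< 10%" for
keeping and "more than 10%" for discarding, leaving the exact boundary
unassigned; discarding there is the conservative completion, and the
threshold is a config field so the alternative is one change away.
The denominator for *f* is offspring with non-missing calls (missing calls
carry no plausibility evidence); counting all offspring instead would only
lower *f*, and the choice is documented here because the original is
ambiguous.

**Call-rate filter.** Default ≥ 90% called over all individuals, parents
included ("90% of individuals" read literally); a toggle restricts the
denominator to offspring. It runs before undercall correction, matching
the narrative order of the procedure it reimplements.

## Sex-linkage scan

"Completely sex-biased" is evaluated over non-missing offspring calls,
with a minimum informative count per sex (default 5) to bound chance hits;
a strict mode (`require_all_offspring`) disqualifies any locus with a
missing offspring call. With ~47 offspring the chance rate per informative
locus is 2·(1/2)⁴⁷, so the scan's false-positive control is essentially
structural rather than statistical.

Classification requires exactly one heterozygous parent. Loci where both
parents are heterozygous (or both homozygous, which cannot produce the
het/hom split) are reported `inconsistent` rather than silently dropped. A
consistency check demotes calls whose offspring genotypes are not the two
Mendelian products expected under sex linkage — the heterozygous sex must
carry {shared allele, parent-specific allele} and the homozygous sex
{shared allele} twice — so isolated genotype errors cannot masquerade as
sex linkage. X/Y patterns are implemented as exact mirrors of W/Z
(swap parents, swap sexes), and the mirror symmetry is property-tested.

## Family simulator

`simulate_family` emulates GBS tag SNPs from a reference-free caller:

- **Autosomal founders** are drawn uniformly from the 7 ordered
  mother×father genotype-class pairs over {hom-ref, het, hom-alt} that
  leave the family polymorphic, because reference-free callers only report
  polymorphic tags. Offspring inherit one random allele per parent.
- **Sex-linked loci** sit in a fully non-recombining region:
  `n_sexlinked` variants ride the sex-limited chromosome (W or Y) and
  `n_sexlinked_shared` ride one copy of the heterogametic parent's shared
  chromosome (one maternal Z, or the paternal X). The second class exists
  because real scans observe both patterns (e.g. 24 W-pattern + 1
  Z-pattern tags); defaults are 0 so it is opt-in.
- **Errors.** Undercall hits heterozygotes with probability
  `undercall_rate` and yields either homozygote with probability 1/2;
  missingness is applied after undercall. Parents get both rates scaled by
  `parent_error_scale` (default 0.1), reflecting their ~10× coverage,
  without modeling reads.
- One `numpy` generator stream drives every draw; a fixed seed reproduces
  the dataset bit-exactly. Locus order is shuffled so position does not
  leak the locus class.

What it does **not** model: read-level coverage, linked loci /
recombination maps, pseudoautosomal behavior, de-novo mutation, genotyping
error other than dropout-and-missingness. Passing tests therefore show the
*logic* of QC + scan is correct under the stated error model, not that the
pipeline is robust to every real-data artifact.

## Gene-family simulator

`simulate_gene_families` evolves sequences under Jukes–Cantor along a gene
tree built from an ultrametric ingroup species tree (default: 5
allotetraploid species, crown depth 1.0) duplicated in whole at
`wgd_stem` = 0.3 time units above the crown, with the outgroup splitting
at depth 2.0 — so the duplication strictly predates all ingroup
speciation, the property the filter exploits. Defaults: `subst_rate` 0.1
substitutions/site/unit (sister-species p-distance ≈ 0.05, homeolog
p-distance ≈ 0.26 — comfortably resolvable yet far from saturation) and
`seq_length` 800 bp, typical of assembled transcript fragments. Homeolog
loss applies per branch (including each copy's stem) with `loss_prob`;
splice variants are gap-truncated exact copies of a surviving tip
(≥ 99% identity), mimicking alternative transcripts or assembly
duplicates. Indels beyond the variant gap block are not modeled, so
"ungapped alignment length" equals sequence length in clean simulated
families.

## Homeolog filter

- **Alignment QC**: ungapped length is the count of columns with no gap in
  *any* retained sequence (the stricter of the two possible readings;
  per-sequence span is available via `ungapped_seq_length`). Default
  minimum 300 bp, i.e. strictly more than 299.
- **Trees**: provided Newick trees are used when attached; otherwise
  neighbor-joining on pairwise-deletion p-distances. NJ is implemented
  in-package (Saitou–Nei, canonical Q criterion) because the contract
  requires full determinism: taxa are name-sorted and Q ties break on the
  first pair in that order, which an off-the-shelf NJ did not guarantee
  under ties. The last three lineages join at a trifurcating root
  (standard unrooted form, three-point branch lengths).
- **Rooting**: on the outgroup when present (its MRCA edge if several
  outgroup tips), else midpoint.
- **Partition search**: internal edges are visited in pre-order from the
  root and the first split of the ingroup tips satisfying (a) ≤ 1 tip per
  species per group, (b) ≥ 1 species in both groups, (c) ≥ 1 group with
  ≥ 3 tips, is accepted. Pre-order matters: a nested clade of one homeolog
  lineage (e.g. four of five species when the fifth branches basally
  within its copy) can also satisfy the criteria, but the true
  duplication-node split is an ancestor of every such edge and is always
  reached first from the root. The search is verified against exhaustive
  clade enumeration on random trees.
- **Prune-and-rebuild**: when no edge qualifies but a species carries tips
  within p-distance ≤ 0.01 of each other (configurable; an arbitrary but
  visible threshold well below the ≈ 0.05 sister-species divergence of
  the simulations), those are reduced to the longest ungapped
  representative and the tree is rebuilt — at most `max_rounds` (default 3)
  build/assess cycles, after which the family is rejected as
  `unresolved_after_rounds`. The original three-round procedure this
  realizes is not specified at the operation level in its source, so this
  concrete prune semantics is this package's own and is isolated behind
  `assess_homeology` for revision.
- **Coalescent selection**: from an accepted family, the lineage covering
  all required species is kept whole, plus exactly one sequence from the
  other lineage — the longest ungapped, with a seeded random choice among
  ties (the divergence of a homeolog from a set of orthologs does not
  depend on which species it comes from).

## Tag-hit classification

E-value comparisons are strict (< 1e−5 by default, matching "below the
threshold"). A "region" is a distinct subject scaffold; multiple HSPs on
one scaffold count once. Two-region tags keep one scaffold by a seeded
random draw (reproducible, unlike an unseeded choice). Chromosome
placement counts aligned bases per chromosome; chromosomes with
≥ `min_span` (default 1 kb) support participate — one means placed, two
means a split alignment, zero or three-plus means unplaced with a reason.
Split calls are restricted to exactly two chromosomes because only
two-chromosome splits are biologically expected from a single fusion.

## Phylogenetic utilities

The harmonic-mean marginal likelihood is computed entirely in log space
(log n − logsumexp(−ℓ)), so traces at any magnitude are safe. The Bayes
factor is reported as 2·ln BF (Kass–Raftery convention) and the CLI also
prints BF = exp(ln BF), because published "BF" values are often ambiguous
between the two scales; no behavior here depends on resolving that
ambiguity. Chronogram rescaling draws the root age from
Normal(65, 4.62) MY truncated at zero by rejection (negligible mass below
zero at these defaults) and multiplies every branch by drawn/current root
age, preserving topology and relative node depths exactly (tested to
1e−12 relative error); input trees must be ultrametric within 1e−9
relative tolerance.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use: 5,000 autosomal + 26
sex-linked loci for parameter recovery (both ZW and XY); 200,000 loci for
the false-positive control; ≥ 10,000 offspring calls for the undercall
Monte-Carlo; 200 gene families (loss 0.2, splice variants 0.1) for filter
recovery; 150 random trees of ≤ 8 ingroup tips for the partition-search
oracle; 2,000 draws for the root-age prior moments. These sizes give the
binomial/Poisson checks 3-sigma resolution while keeping a full run in
tens of seconds on one CPU.

## Known limitations

- The undercall model cannot detect dropout to the Mendelian-plausible
  homozygote; at dropout rate *u*, roughly a (1 − u/2)^(n_het) fraction of
  truly sex-linked loci survive the "completely heterozygous" requirement,
  so the scan's sensitivity decays with error rate (the README's worked
  example shows 24/26 at u = 0.02). This mirrors the real method's
  behavior; it is not recoverable without read-level data.
- Multi-family joint inference, association-style partial sex linkage, and
  recombination-distance estimation are out of scope.
- The homeolog filter assumes the duplication predates ingroup speciation;
  in lineages where that fails, sister-duplicate rejection is the only
  guard.
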