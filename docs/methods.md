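# Methods

This note documents the models, conventions and numerical choices behind
`paraloci`, and what the synthetic-data generators do and do not emulate.

## Coordinate conventions

All positions are gene-local and 1-based. `g.1` is the A of the ATG on the
genomic sequence (which runs from the start codon to the last base of the
stop codon; UTRs are outside the model), and `c.1` is the same base on the
spliced CDS. A `SpliceMap` is the exact bijection between exonic g.
positions and c. positions; intronic queries return the flanking exon
indices. Orientation is always the coding strand in gene-local space;
genome-strand lifting is out of scope.

Inter-paralog correspondence is an alignment-column map (`CoordinateMap`)
from a global pairwise alignment with fixed scoring: match +1, mismatch −1,
gap open −4, gap extend −1 (a length-L gap costs 4 + (L−1)). The gap
penalties were chosen so that the 3-nt length difference between the focal
paralogs' exon 4 (161 vs 164 bp) aligns as a single 3-bp indel — parsimony
of indel events — rather than scattered gaps. The same scheme is used for
every identity computation, so identities are reproducible by construction.

Two rounding conventions coexist deliberately: per-exon identities are
**truncated** to integer percent (floor(100·matches/columns): a 179-bp exon
with one mismatch is 99, a 142-bp exon with two is 98 — only flooring is
consistent with both), while gene-level identities are rounded half-up to
one decimal. Allele and hybrid frequencies are rounded half-up to two
decimals (1/144 → 0.69, 61/144 → 42.36).

## Diploid genotype notation

`GenotypeCall` uses the three-way HET/HOM/MUT notation of diploid Sanger
scoring: HET = two different alleles, HOM = homozygous reference, MUT =
homozygous alternate. Alleles are an unordered pair; transcript-to-gene
consistency is *exact genotype equality* at every assayed position (a HET
transcript against a HOM gene is a mismatch even when alleles overlap),
because that is the observation that separates the two-gene model from the
fused annotation.

## Synthetic focal pair

The generator's defaults are the study conditions, not tunables:

* exon lengths 189, 172, 153, 161, 177, 142, 188, 142, 179 (CDS 1503 nt);
  the donor's exon 4 is 164 bp (one in-frame 3-bp insertion);
* per-exon difference counts 14/0/12/18/6/8/10/2/1, which reproduce the
  published integer identities 92/100/92/87/96/94/94/98/99 under the
  truncation convention, with exons 8–9 differing by exactly 3 nt;
* a fixed diagnostic-site catalogue between intron 7 and exon 9 (31 sites,
  g.3688–g.4240, with the published acceptor/donor bases), one retained
  upstream site at g.3625, and a site-free switching region g.3626–g.3687;
* a donor-fixed T>C polymorphism at donor g.3864 (= acceptor g.3805 via the
  +59 offset), which makes that diagnostic site uninformative;
* donor coordinate offset +59 relative to the acceptor downstream of exon 4,
  built from a 56-bp intron-1 insertion plus the 3-bp exon-4 insertion;
* gene-level focal identity 93.7% (214 substitutions + 59 gap columns over
  4331 alignment columns).

Intron lengths are free parameters of the reconstruction: the published
work fixes none of them, so they were chosen once to place every cited
coordinate consistently (g.92 = c.92 in exon 1, g.2605 = c.805 in exon 5,
g.3328 = c.1127 in exon 7, g.4240 = c.1471 in exon 9, the catalogue sites
in intron 7/exon 8/exon 9, and an intron 8 identical between the paralogs).
The acceptor gene is 4272 bp, compact relative to the real ~22-kb locus;
nothing downstream depends on absolute intron sizes. Specific codons are
planted in the acceptor CDS so that the worked variant set translates to
the published amino-acid changes (codon 31 CGC so G>A at c.92 is R31H,
codon 491 TCT so T>G at c.1471 is S491A, and so on).

## Family simulation on a tree

Gene-level identity targets are realized by placing substitutions along a
neighbor-joining tree: branch substitution counts are fitted by
non-negative least squares to the target distance matrix (in substitution
space, correcting the donor's 59 gap columns), every branch gets a disjoint
set of positions, and each leaf is the acceptor sequence with the mutations
on the symmetric-difference path applied. Realized pairwise distances then
equal path sums exactly, so calibration holds to integer rounding
(±0.07 points in practice against a ±1-point contract).

This construction can only realize **tree-additive** matrices. The
published identity matrix is not additive (its best tree fit leaves a
1.5-point residual on two pairs), so the default target is its closest
additive projection — still inside the published 77–95 band, with the
focal pair pinned at 93.7 by the engineered difference set. A requested
matrix whose tree fit misses by more than the tolerance raises a
generation error rather than silently drifting.

Constraints during mutation placement: the ATG, stop codon, GT/AG splice
dinucleotides, planted codons and engineered sites are never touched;
exonic mutations are restricted to one mutated codon per codon, and each
substitution is chosen to keep that codon a sense codon, so every leaf's
CDS translates without internal stops (asserted at generation time).

## Cohorts, consensus, and calling

Cohorts are diploid: 2n haplotypes in acceptor coordinates. In
`exact_counts` mode each planted variant occupies exactly its requested
number of haplotypes (placement is a seeded draw); `binomial` mode draws
per-haplotype. The default cohort is 72 samples — the published
frequencies all have denominator 144 — with the ten worked missense
variants at their printed allele counts, one in-codon MNV (AAG>GGA), one
11-bp deletion (CCACATGACAT, frameshift at codon 378), and 42 hybrid
alleles. The g.4240 count (61) is a total: 42 hybrid tails plus 19
independent alleles, mirroring how the exon-9 site is both a diagnostic
position and a segregating SNP.

Hybrid haplotypes are tail conversions: every diagnostic site from g.3688
to the gene end takes the donor's **observed** allele (donor reference plus
its fixed polymorphisms), so the confounded site g.3805 stays unconverted.
Carriers default to heterozygous (the published 29.17% < 50% is consistent
with heterozygous carriage; homozygosity was not reported).

Sanger consensus collapses a haplotype pair position-wise: IUPAC two-base
codes at heterozygous substitutions; deletion runs become recorded indel
events rather than bases (a trace shows them as frame disruptions). Variant
calling inverts this exactly — there is deliberately no error model in the
consensus, so recovery tests assert precision = recall = 1; real
chromatogram noise, allele dropout and primer bias are *not* emulated, and
green recovery tests say nothing about those failure modes on real traces.

Same-codon adjacent substitutions with equal zygosity are merged into one
MNV. On unphased consensus data this cannot be distinguished from two
single SNPs on opposite haplotypes in the same codon; the merge is the
convention a Sanger-based study must adopt and is applied per sample.

## Hybrid detection parameters

* `min_run = 2` converted sites: an isolated donor-matching site is
  indistinguishable from a point mutation (the exon-9 site segregates
  independently at 42.36%), while the hybrid evidence is a 31-site run.
* Only tail tracts (reaching the last informative site) get the *hybrid*
  label; interior runs are reported as conversion segments.
* The switching interval is open on both ends: (last non-donor informative
  site, first converted site), printed as "between g.X and g.(first−1)".
  With the g.3805 site masked this yields (3625, 3688); unmasked, the
  acceptor state at 3805 splits the run and misplaces the boundary —
  which is precisely why confounded-site masking exists.
* Unphased diploid calling attributes an uninterrupted run of heterozygous
  diagnostic sites to one hybrid haplotype rather than two reciprocal
  recombinants. This phase assumption is flagged in reports; mixed
  het/hom-donor runs are counted conservatively as one allele with a
  warning.

## Effect classification

SIFT and PROVEAN scores are inputs, never computed. Thresholds: SIFT
deleterious iff score ≤ 0.05, PROVEAN iff score < −2.5. The SIFT boundary
is inclusive although the source methods prose says "below 0.05": the
published score table flags substitutions at exactly 0.05 as deleterious,
and the inclusive rule is the only one that reproduces the flag partition
row for row (the strict PROVEAN boundary is likewise fixed by the
unflagged −2.428 and −2.281 rows). "Clearly deleterious" means deleterious
under both tools. Novel-deleterious counts consider single-nucleotide
missense rows only, matching how the published counts enumerate novel
amino-acid-changing SNPs.

## qPCR model

Standard curves follow Ct = intercept + slope·log₁₀(quantity) with
slope = −1/log₁₀(1+E); perfect efficiency gives |slope| = 3.3219. Sample
quantities are interpolated per assay, normalized to the reference (actin)
per sample, and the two targets are compared as a **ratio of group means**
(stable for n = 4 and standard for the relative-curve workflow, versus the
noisier mean of per-sample ratios). Significance uses Welch's unpaired
t-test with Welch–Satterthwaite degrees of freedom, implemented in closed
form and cross-checked against an independent reference implementation to
1e-10 in tests. The generator plants target-A quantities as
`true_ratio × target-B` per sample, so the noise-free recovered ratio is
exact; with Ct noise of sd 0.2 the recovered ratio stays within 5% in
median over replicate plates. Fig-level per-animal expression values were
not published, so only the ratio (and qualitative significance) is
reproducible.

## Duplication scanning

`self_similarity_scan` seeds with exact 12-mers (long enough to suppress
random hits on a ~20-kb locus, short enough that an 87%-identity exon still
seeds), chains seeds within a 120-diagonal band allowing 600-bp seed gaps,
and refines chained candidates by global alignment, reporting segments
≥ 300 bp at ≥ 85% identity. Only forward-orientation duplications are
sought (the locus is a tandem, same-strand duplication). Exon projection
through the duplication tolerates a 200-bp extrapolation at match edges,
since seeding rarely starts exactly at a copy boundary.

## Problem sizes in the test suite

The default worked cohort is the study-sized 72 samples; end-to-end
pipeline determinism tests use 10–12-sample cohorts, tract-recovery
properties run over 100 seeds on synthetic site maps, and Monte-Carlo qPCR
recovery uses 100 replicate plates. These sizes were chosen as the smallest
that still exercise every code path and every published denominator.

## Known limitations

* The consensus model has no base-calling noise; calling exactness on
  synthetic cohorts does not transfer to noisy traces.
* Mixed-template amplicons (co-amplified paralogs in one reaction) are not
  deconvolved; each consensus is assumed to come from one locus.
* Copy-number variation (gene duplication/deletion alleles) is out of
  scope; diagnostic-site genotypes cannot distinguish a hybrid from some
  CNV configurations.
* Interior (non-tail) conversion tracts are detected but the hybrid
  frequency statistic counts tail conversions only.
* The family simulator realizes identity targets exactly but places
  mutations uniformly (no hotspots, no transition/transversion bias, no
  selection beyond stop-codon avoidance).
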