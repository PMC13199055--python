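# Methods

## Depth-proportion genotyping model

Genotyping of near-identical paralogues proceeds from a single premise:
after masking the confusable copies in the base assembly and appending
one accessory contig per resolved haplotype, reads originating from a
haplotype accumulate depth only on its own contig. At a k-bp
haplotype-diagnostic motif (k = 6 by default: two 3′-UTR SNP windows for
the *DUX4C* alpha/beta pair, the polyadenylation-signal motif and its
syntenic counterparts for *DUX4T*), the expected motif coverage is
proportional to the number of alleles the sample carries.

With diploid chromosomes 4 and 10 and a B motif shared by the 4qB and
10qB haplotypes, the proportion

p(4qA) = Cov(4qA) / (Cov(4qA) + Cov(10qA) + Cov(B))

has a denominator pooling four chromosomal alleles. A euploid 4qA/4qA +
10qA/10qA sample therefore peaks at 0.5, a 4qA/4qB heterozygote at 0.25,
and a 4qB/4qB sample at 0; the two-haplotype *DUX4C* proportion runs
1 / 0.5 / 0. The caller assumes diploidy on both chromosomes; aneuploid
or mosaic samples violate the expected ratios and are out of scope.

**Thresholds.** Observed proportions scatter around the theoretical
values, so calls use permissive intervals: [0.75, 1] / [0.25, 0.75) /
[0, 0.25) for *DUX4C* and [0.375, 1] / [0.125, 0.375) / [0, 0.125) for
each *DUX4T* chromosome. Interval endpoints are closed below and open
above, with the top interval closed at 1 — a deterministic convention
for printed ranges whose endpoints touch. Thresholds are a frozen
dataclass (`ThresholdConfig`) with file-based overrides so other
paralogue systems can reuse the machinery.

**Ambiguity rule.** When p(4qA) ≥ 0.375 and p(B) ≥ 0.05 the B coverage
cannot be attributed between 4qB and 10qB, and a 4qA/4qB heterozygote
can masquerade as 4qA/4qA. Such calls carry an
`ambiguous_B_attribution` flag rather than a corrected genotype —
correction would require haplotype information the depth data do not
contain. Zero pooled coverage yields an explicit no-call, distinct from
any homozygous label.

## Depth and coverage conventions

- Depth counts a read at every position of its aligned reference span:
  CIGAR deletions cover, soft clips do not (the common samtools-style
  semantics). Unmapped, secondary and supplementary records are
  excluded; the MAPQ floor defaults to 10.
- Relative base-depth divides by the mean depth over included
  positions. Masked ('N') positions are excluded from the normaliser by
  default, as are any contigs named in `exclude_contigs` — accessory
  contigs carry inserted extra copies and would otherwise inflate the
  genome-wide average. Whether accessory contigs belong in the
  normaliser is genuinely open; it is exposed as an argument rather
  than decided.
- Specific motif coverage is the exact arithmetic mean of k integer
  depths; no rounding occurs before thresholding.
- Depth may be ingested from SAM/BAM or from a samtools-style 3-column
  TSV (1-based positions, absent rows = 0), decoupling the caller from
  any particular aligner.

## Read simulation

The simulator draws n = ceil(c·L/m) single-end reads of length m from a
template of length L at fold-coverage c, start positions uniform on
[0, L−m] (no read overhangs the end), with independent per-base
substitution errors at rate e, each error uniform over the three
alternative bases. Defaults c=30, m=50, e=0.01 match the conditions
used for breakpoint-mappability simulation. No indels, no quality decay
(quality strings are constant 'I'; nothing downstream reads them), no
paired ends, no PCR duplicates. All randomness flows from a single
`numpy` generator seeded by `ReadSimParams.seed`, so outputs are
byte-reproducible.

`tiled=True` replaces random starts with evenly spaced deterministic
starts. This is the idealized uniform-coverage condition: alleles of
equal template length receive identical start layouts, motif coverages
hit their theoretical ratios exactly, and error-free genotype recovery
is exact. Random starts retain Lander–Waterman-style sampling noise; at
c=30 the observed exact-recovery rate across all nine genotype
combinations is ~98%, with misses concentrated in the 4qA/4qB class
whose proportion (0.25) sits 0.125 from both interval edges.

## Toy locus generator

`default_toy_loci` builds two locus systems that emulate the structural
essentials: haplotype contigs of 426 bp (150 bp flanks, a 3×42 bp
tandem repeat mimicking a repeat array, with the 6-bp motif 40 bp into
the unique 3′ flank — the "breakpoint" junction situation), identical
across haplotypes everywhere except the motif. The *DUX4T*-like system
shares one B haplotype between its chr4 and chr10 loci, reproducing the
pooled-denominator arithmetic. Deliberately absent from the toy model:
real mappability structure (reads are placed at their true origins, so
aligner errors are out of frame), D4Z4-scale repeat copy numbers,
GC/coverage bias, indel errors, and contamination. Passing recovery
tests therefore validates the statistical machinery downstream of
alignment, not alignment itself.

## Two-locus EM and LD

For two biallelic loci the four haplotype frequencies are estimated by
EM over unphased dosage pairs: all genotype classes except the double
heterozygote contribute fixed gamete counts; the double heterozygote is
split between cis (AB/ab) and trans (Ab/aB) resolutions in proportion
to f(AB)f(ab) vs f(Ab)f(aB). Uniform initialisation (0.25 each),
convergence when the largest frequency change is < 1e-8, cap of 1000
iterations, complete-case handling of missing genotypes. With no double
heterozygotes the first M-step already equals direct gamete counting.
The log-likelihood history is retained and is non-decreasing (EM
guarantee; asserted in tests over random datasets). This is exact
maximum likelihood under random union of gametes and replaces a general
phasing engine for the two-allele × two-allele question; it does not
extend to multi-locus haplotypes or imputation.

At n = 100 diploids the binomial sampling noise of a 200-gamete draw
(SD ≈ 0.034 for a frequency of 0.615) exceeds the EM's own error: the
estimator tracks the *realized* phased haplotype frequencies of the
drawn sample to within ~0.005, which is the quantity the recovery tests
assert; convergence to the generating frequencies is asserted at
n = 2000 (±0.02).

r² is always computed from haplotype frequencies, r² = D²/(p_A q_A p_B
q_B) with D = p(AB) − p_A p_B: direct counting for phased input, per-pair
EM for unphased matrices (composite-likelihood style, matching common LD
tools). Monomorphic variants have undefined r² and are reported as
missing, including on the diagonal. LD blocks use single-linkage
chaining at r² > 0.8, numbered deterministically by first variant in
column order. MAF filtering removes variants with MAF strictly below
the cutoff (default 0.1), computed from non-missing calls.

## Isoform curation and ORF classes

A candidate isoform passes iff all four hold: 5′ UTR > 50 bp (strict);
≥1-base overlap of a same-strand CAGE peak with the genomic projection
of the 5′ UTR (peaks are intervals — strict containment would be
fragile); an ATG at the annotated CDS start; and Kozak context with a
purine at −3 and G at +4 (the minimal canonical consensus; the
literature names the consensus without fixing a definition). A start
codon other than ATG forces the Kozak criterion false, since the
context test is anchored on an initiator ATG. Coordinates are 1-based
inclusive in all reports; BED input converts at the parser boundary.
Splice junctions are stored as (last exonic base, first exonic base),
both 1-based.

ORF classification translates frame 1, truncates at the first stop, and
searches each reference domain (HD1, HD2, TAD) by local protein
alignment (match +1, mismatch −1, gap open −2, extend −1), calling a
domain present at ≥80% identity over ≥80% of the domain length (both
configurable). `orf_intact` is false when the first stop precedes 90%
of the expected protein length — the fraction is a configurable default
because no canonical cutoff exists; the expected length defaults to the
input's own frame-1 length and should be set to the canonical protein
length when measuring truncation against a full-length paralogue.
Domain subsets outside the three defined groups (an HD without its
partner, a TAD alone) collapse to group iii with a warning rather than
a fourth group.

## Expression layer

TPM = 1e6·(countᵢ/lengthᵢ)/Σⱼ(countⱼ/lengthⱼ); a complete table sums
to 1e6 (asserted to 1e-3). Gene pooling relabels every transcript whose
gene annotation equals the pool pattern (exact string match by default)
before summing transcript TPM — summation of transcript TPM, not
re-normalisation. Region CPM is 1e6·count/library_size. Group
comparisons use the two-sided Mann–Whitney U: exact distribution when
both groups have ≤8 values and the pooled data are tie-free, otherwise
the normal approximation with continuity correction and mid-rank ties.
Case/control stratification over genotype calls plus expression values
is a pandas query expression, keeping rules like "alpha/alpha ∧ 4qB/4qB
∧ CPM > 1" declarative.

## Problem sizes and determinism

The test and acceptance workloads are sized for interactive runs:
426-bp toy contigs, 900 simulated diploids (100 per genotype
combination) for recovery, 100-diploid EM cohorts with a 2000-diploid
convergence check, ≤10-haplotype exact LD oracles. Every stochastic
step is seeded; the acceptance script's proportion targets are computed
under the tiled (deterministic) layout and are seed-invariant by
construction.

## Known limitations

- Genotyping accuracy against real alignments depends on the masking
  recipe and aligner behaviour, which the truth-placement tests bypass.
- A 10qB carrier shifts the chr4 expected proportions; the toolkit
  flags B-attribution ambiguity but does not attempt corrected
  thresholds.
- D4Z4 repeat copy number, methylation state and PCR validation are
  outside the model.
- The EM layer is strictly two-locus; multi-locus phasing requires a
  dedicated engine.
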