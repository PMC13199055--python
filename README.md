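# dux4kit

Paralog-aware genotyping and transcript toolkit for the *DUX4* family of
subtelomeric loci.

## The problem

The telomeric *DUX4* copy (*DUX4T*) sits inside the D4Z4 macrosatellite
arrays on chromosomes 4q35 and 10q26; its centromeric paralogue *DUX4C*
(*DUX4L9*) lies just upstream between *FRG1* and *FRG2*. The copies are
nearly identical, so short reads from any of them map ambiguously and
standard variant calling fails — yet the haplotypes matter: the 4qA
haplotype carries the polyadenylation signal that stabilises *DUX4*
mRNA in facioscapulohumeral muscular dystrophy (FSHD), and *DUX4C*
haplotypes act as expression QTLs.

`dux4kit` implements the depth-based genotyping strategy for such loci,
for anyone studying genes embedded in near-identical repeats:

1. **Masked reference + accessory contigs** (`refbuild`): hard-mask the
   repeat arrays and endogenous paralogue loci in the base assembly,
   then append one fully resolved sequence per haplotype as an extra
   contig, so every read has exactly one high-identity placement.
2. **Motif coverage** (`covdepth`): per-base depth with a MAPQ ≥ 10
   filter; *specific motif coverage* of a k-bp (default 6) diagnostic
   window, Cov = (Σᵢ₌₁ᵏ depthᵢ)/k; *relative base-depth* (depth /
   genome-wide mean) as a mappability diagnostic.
3. **Threshold genotyping** (`genotyper`): haplotype proportions

   p(4qα) = Cov₄qα / (Cov₄qα + Cov₄qβ)

   p(4qA) = Cov₄qA / (Cov₄qA + Cov₁₀qA + Cov_B)

   with theoretical values 1 / 0.5 / 0 for the *DUX4C* genotypes and
   0.5 / 0.25 / 0 for chr4 *DUX4T* (the denominator pools both
   chromosomes, so a euploid 4qA homozygote peaks at 0.5). Calls use
   permissive intervals ([0.75,1] / [0.25,0.75) / [0,0.25) and
   [0.375,1] / [0.125,0.375) / [0,0.125)), and samples whose B-motif
   signal cannot be attributed between 4qB and 10qB
   (p(4qA) ≥ 0.375 and p(B) ≥ 0.05) are flagged, not guessed.
4. **Population layer** (`haplostats`): MAF filtering, pairwise LD
   (r² = D²/(p_A q_A p_B q_B)), single-linkage LD blocks (r² > 0.8), and
   two-locus haplotype frequencies by EM (double heterozygotes are the
   only phase-ambiguous class), including cross-locus LD between the
   *DUX4C* and *DUX4T* haplotype systems.
5. **Read simulation** (`simreads`): single-end reads (defaults
   c=30, m=50, e=0.01) from breakpoint templates or whole toy diploids
   with recorded truth — the ground-truth generator for every test.
6. **Isoform curation & ORF classes** (`isocurate`): 5′ UTR > 50 bp,
   same-strand CAGE peak in the UTR, initiator ATG, Kozak context
   (purine at −3, G at +4); DUX4-like ORFs classified by HD1/HD2/TAD
   domain content into groups i / ii / iii.
7. **Expression** (`quantify`): TPM from counts, pooling of all
   "DUX4"-annotated transcripts into one gene value, region CPM, and
   Mann–Whitney U group comparisons.

## Worked example

```python
import dux4kit as dk

# toy paralogous loci: two DUX4C-like haplotypes (alpha/beta) and a
# DUX4T-like system (4qA, 10qA, shared B) with 6-bp diagnostic motifs
specs = dk.default_toy_loci()
contigs = dk.toy_reference_contigs(specs)

# simulate a diploid: DUX4C alpha/beta, DUX4T 4qA/4qB, chr10 10qA/10qA
sample = dk.simulate_diploid_sample(
    specs,
    {("DUX4C", "chr4"): ("alpha", "beta"),
     ("DUX4T", "chr4"): ("4qA", "B"),
     ("DUX4T", "chr10"): ("10qA", "10qA")},
    dk.ReadSimParams(coverage=30, read_length=50, error_rate=0.01, seed=1),
)

# depth from true-origin placements, then motif proportions and calls
profile = dk.depth_from_placements(
    sample.placements, 50, {c: len(s) for c, s in contigs.items()})
call = dk.genotype_sample(profile, dk.toy_motif_specs(specs), sample="NA_demo")

print("genotype DUX4C      :", call.genotype_dux4c)
print("genotype DUX4T chr4 :", call.genotype_dux4t_chr4)
print("genotype DUX4T chr10:", call.genotype_dux4t_chr10)
for key, p in sorted(call.proportions.items()):
    print(f"proportion {key:12s}: {p:.3f}")

# linkage between the two locus systems across a cohort
hap, dosages = dk.simulate_two_locus_population(
    [0.615, 0.02, 0.015, 0.35], 100, seed=1)
r2, table = dk.cross_locus_ld(dosages[:, 0], dosages[:, 1])
print("two-locus r^2       :", round(r2, 3))
print(table.to_frame().to_string(index=False))
```

prints

```
genotype DUX4C      : alpha/beta
genotype DUX4T chr4 : 4qA/4qB
genotype DUX4T chr10: 10qA/10qA
proportion DUX4C:alpha : 0.519
proportion DUX4C:beta  : 0.481
proportion DUX4T:10qA  : 0.491
proportion DUX4T:4qA   : 0.282
proportion DUX4T:B     : 0.227
two-locus r^2       : 0.812
haplotype  frequency  count
       AB   0.604402    121
       Ab   0.025598      5
       aB   0.020598      4
       ab   0.349402     70
```

The heterozygous *DUX4C* sample lands near its theoretical proportion of
0.5 and the 4qA/4qB heterozygote near 0.25 (the B and 10qA motifs absorb
the rest of the pooled denominator); both fall inside the calling
intervals and the sample is genotyped correctly. In the cohort half,
the EM recovers the strongly coupled haplotype structure (AB and ab
dominate) and the resulting two-locus r² reflects the simulated linkage.

A CLI mirrors the library for shell pipelines: `dux4kit build-ref`,
`simulate`, `depth`, `genotype`, `ld`, `curate`, `quantify` (see
`dux4kit --help`).

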