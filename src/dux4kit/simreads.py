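"""Synthetic short reads, diploid samples and toy paralogous loci.

This module is the toolkit's ground-truth generator.  It provides three
layers:

1. :func:`simulate_reads` — single-end reads from any template sequence
   under a uniform-start, substitution-only error model (the conditions
   used for breakpoint-mappability simulations: 30-fold coverage, 50-bp
   reads, 1% per-base error, single-end).
2. A toy two-paralogue locus (:class:`ToyLocusSpec` /
   :func:`default_toy_loci`) that emulates the DUX4C / DUX4T situation:
   haplotype contigs that are identical except at a short diagnostic
   motif, with a tandem-repeat tract mimicking the D4Z4 array.
3. :func:`simulate_diploid_sample` / :func:`place_reads_truth` — whole
   diploid samples with recorded genotype truth and true-origin alignment
   records, so depth computation and genotype calling can be tested
   end-to-end without an external aligner.
4. :func:`simulate_two_locus_population` — phased two-locus haplotype
   populations at configurable haplotype frequencies, for exercising the
   EM frequency estimator and LD statistics.

The error model introduces substitutions only (no indels), each erroneous
base replaced uniformly by one of the three alternatives.  Quality strings
are constant 'I' (Q40): downstream depth-based genotyping never consumes
qualities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .covdepth import MotifSpec

__all__ = [
    "ReadSimParams",
    "SimRead",
    "SimulatedSample",
    "ToyLocusSpec",
    "simulate_reads",
    "default_toy_loci",
    "toy_motif_specs",
    "simulate_diploid_sample",
    "place_reads_truth",
    "simulate_two_locus_population",
    "write_fastq",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_QUALITY_CHAR = "I"


@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulation parameters (defaults mirror ``-c 30 -m 50 -e 0.01``).

    With ``tiled=True`` start positions are evenly spaced instead of
    uniform-random — the idealized uniform-coverage condition under
    which depth-proportion genotyping is exact (every allele of equal
    template length receives byte-identical start layouts, so motif
    coverages hit their theoretical ratios with no sampling noise).
    """

    coverage: float = 30.0
    read_length: int = 50
    error_rate: float = 0.01
    seed: int = 0
    tiled: bool = False

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimRead:
    """One simulated single-end read with its true origin."""

    id: str
    sequence: str
    quality: str
    template: str  # contig/template name of origin
    start: int  # 0-based true start on the template


@dataclass
class SimulatedSample:
    """A diploid sample with genotype truth and true read placements."""

    truth: dict[tuple[str, str], tuple[str, str]]  # (system, locus) -> allele pair
    reads: list[SimRead] = field(default_factory=list)

    @property
    def placements(self) -> list[tuple[str, str, int]]:
        return [(r.id, r.template, r.start) for r in self.reads]


def _simulate_onto(
    template: str,
    params: ReadSimParams,
    rng: np.random.Generator,
    template_name: str,
    id_prefix: str,
    coverage: float | None = None,
) -> list[SimRead]:
    c = params.coverage if coverage is None else coverage
    L, m = len(template), params.read_length
    if L < m:
        raise ValueError(
            f"template {template_name!r} (length {L}) shorter than read length {m}"
        )
    n = math.ceil(c * L / m)
    if params.tiled:
        starts = np.floor(np.linspace(0, L - m, n)).astype(np.int64)
    else:
        starts = rng.integers(0, L - m + 1, size=n)
    arr = np.frombuffer(template.upper().encode("ascii"), dtype=np.uint8)
    reads = arr[starts[:, None] + np.arange(m)].copy()
    if params.error_rate > 0:
        err = rng.random(reads.shape) < params.error_rate
        if err.any():
            # replace each erroneous base by one of the 3 other bases, uniformly
            shift = rng.integers(1, 4, size=int(err.sum()))
            code = np.searchsorted(_BASES, reads[err])
            # non-ACGT (e.g. 'N') bases get a uniform random base instead
            known = code < 4
            newcode = np.where(known, (code + shift) % 4, shift - 1)
            reads[err] = _BASES[newcode]
    qual = DEFAULT_QUALITY_CHAR * m
    return [
        SimRead(
            id=f"{id_prefix}{i}",
            sequence=reads[i].tobytes().decode("ascii"),
            quality=qual,
            template=template_name,
            start=int(starts[i]),
        )
        for i in range(n)
    ]


def simulate_reads(
    template: str,
    params: ReadSimParams,
    template_name: str = "template",
    id_prefix: str = "read",
) -> list[SimRead]:
    """Simulate single-end reads from one template.

    Read count is ``ceil(coverage * len(template) / read_length)``; start
    positions are uniform on ``[0, len - m]`` so no read overhangs the
    template end.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    return _simulate_onto(template, params, rng, template_name, id_prefix + "_")


# ---------------------------------------------------------------------------
# Toy paralogous locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyLocusSpec:
    """Layout of a toy locus system with haplotype-diagnostic motifs.

    ``contigs`` maps haplotype label -> full haplotype contig sequence;
    within a system the sequences are identical except inside the k-bp
    motif window.  ``loci`` maps a locus name (one diploid chromosome
    pair, e.g. ``"chr4"``) to the haplotype labels its alleles may take.
    ``motifs`` maps haplotype label -> (contig_name, start0, allele) for
    the diagnostic window.
    """

    system: str
    contigs: dict[str, str]
    loci: dict[str, tuple[str, ...]]
    motifs: dict[str, tuple[str, int, str]]
    motif_k: int = 6

    def contig_name(self, haplotype: str) -> str:
        return f"{self.system}-{haplotype}"

    def __post_init__(self) -> None:
        for hap, (contig, start0, allele) in self.motifs.items():
            if len(allele) != self.motif_k:
                raise ValueError(
                    f"motif for {hap!r} has length {len(allele)}, expected {self.motif_k}"
                )
            seq = self.contigs[hap]
            if seq[start0 : start0 + self.motif_k] != allele:
                raise ValueError(f"motif allele for {hap!r} does not match its contig")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(list("ACGT"), size=n).tobytes().decode("ascii") if False else "".join(
        "ACGT"[i] for i in rng.integers(0, 4, size=n)
    )


def default_toy_loci(
    seed: int = 20,
    flank: int = 150,
    repeat_unit_len: int = 42,
    repeat_copies: int = 3,
    motif_k: int = 6,
) -> list[ToyLocusSpec]:
    """Build the default toy DUX4C-like and DUX4T-like locus systems.

    Each haplotype contig is ``left flank + tandem repeat + right flank``
    with a k-bp diagnostic motif placed a short distance into the right
    flank — mimicking a junction ("breakpoint") between the last repeat
    unit and the unique 3' sequence where the polyadenylation-signal motif
    sits.  The DUX4C-like system has two haplotypes (alpha, beta) on one
    chromosome; the DUX4T-like system has haplotypes 4qA and 10qA plus a
    shared B haplotype that serves both the chr4 and chr10 loci, exactly
    the pooled-denominator situation the proportion formulas address.
    """
    rng = np.random.default_rng(seed)
    motif_offset = 40  # into the right flank

    def build_system(system: str, hap_alleles: dict[str, str], loci: dict[str, tuple[str, ...]]):
        left = _random_seq(rng, flank)
        unit = _random_seq(rng, repeat_unit_len)
        right = _random_seq(rng, flank)
        backbone = left + unit * repeat_copies + right
        pos = flank + repeat_unit_len * repeat_copies + motif_offset
        contigs, motifs = {}, {}
        for hap, allele in hap_alleles.items():
            contigs[hap] = backbone[:pos] + allele + backbone[pos + motif_k :]
            motifs[hap] = (f"{system}-{hap}", pos, allele)
        return ToyLocusSpec(system=system, contigs=contigs, loci=loci, motifs=motifs, motif_k=motif_k)

    def distinct_motifs(n: int) -> list[str]:
        out: set[str] = set()
        while len(out) < n:
            out.add(_random_seq(rng, motif_k))
        return sorted(out)

    m_c = distinct_motifs(2)
    dux4c = build_system(
        "DUX4C",
        {"alpha": m_c[0], "beta": m_c[1]},
        {"chr4": ("alpha", "beta")},
    )
    m_t = distinct_motifs(3)
    dux4t = build_system(
        "DUX4T",
        {"4qA": m_t[0], "10qA": m_t[1], "B": m_t[2]},
        {"chr4": ("4qA", "B"), "chr10": ("10qA", "B")},
    )
    return [dux4c, dux4t]


def toy_motif_specs(specs: list[ToyLocusSpec]) -> list[MotifSpec]:
    """Motif table (one row per haplotype-diagnostic window) for genotyping."""
    out = []
    for spec in specs:
        for hap, (contig, start0, allele) in spec.motifs.items():
            out.append(
                MotifSpec(
                    contig=contig,
                    start=start0,
                    k=spec.motif_k,
                    system=spec.system,
                    haplotype=hap,
                    allele=allele,
                )
            )
    return out


def toy_reference_contigs(specs: list[ToyLocusSpec]) -> dict[str, str]:
    """All haplotype contigs of the toy systems, keyed by contig name."""
    return {
        spec.contig_name(hap): seq
        for spec in specs
        for hap, seq in spec.contigs.items()
    }


def simulate_diploid_sample(
    specs: list[ToyLocusSpec],
    genotypes: dict[tuple[str, str], tuple[str, str]],
    params: ReadSimParams,
) -> SimulatedSample:
    """Simulate one diploid sample with known genotype truth.

    ``genotypes`` maps ``(system, locus)`` to an unordered allele pair of
    haplotype labels valid for that locus.  Each allele contributes reads
    from its haplotype contig at half the total coverage, so a homozygote
    reaches full coverage on one contig and a heterozygote half coverage
    on each.  Fully reproducible from ``params.seed``.
    """
    by_system = {s.system: s for s in specs}
    rng = np.random.default_rng(params.seed)
    reads: list[SimRead] = []
    for (system, locus), pair in sorted(genotypes.items()):
        if system not in by_system:
            raise KeyError(f"unknown locus system {system!r}")
        spec = by_system[system]
        if locus not in spec.loci:
            raise KeyError(f"unknown locus {locus!r} in system {system!r}")
        allowed = spec.loci[locus]
        if len(pair) != 2:
            raise ValueError(f"genotype at {system}:{locus} must be an allele pair")
        for k, allele in enumerate(pair):
            if allele not in allowed:
                raise KeyError(
                    f"haplotype {allele!r} not valid at {system}:{locus} "
                    f"(allowed: {allowed})"
                )
            reads.extend(
                _simulate_onto(
                    spec.contigs[allele],
                    params,
                    rng,
                    template_name=spec.contig_name(allele),
                    id_prefix=f"{system}_{locus}_{allele}_{k}_",
                    coverage=params.coverage / 2.0,
                )
            )
    return SimulatedSample(truth=dict(genotypes), reads=reads)


# ---------------------------------------------------------------------------
# Truth placements as alignment records
# ---------------------------------------------------------------------------

def place_reads_truth(
    sample: SimulatedSample,
    reference: dict[str, str],
    mark_multimappers: bool = False,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Emit one ungapped alignment record per read at its true origin.

    Records are MAPQ 60; with ``mark_multimappers`` a read whose
    error-free source window is byte-identical at the same coordinate on
    another contig is demoted to MAPQ 0, emulating the ambiguity a real
    aligner would report for reads that do not overlap a diagnostic
    motif.
    """
    if not sample.reads:
        raise ValueError("sample has no reads/placements")
    header = pysam.AlignmentHeader.from_references(
        list(reference.keys()), [len(s) for s in reference.values()]
    )
    records = []
    for r in sample.reads:
        if r.template not in reference:
            raise KeyError(f"read {r.id} placed on unknown contig {r.template!r}")
        m = len(r.sequence)
        if r.start + m > len(reference[r.template]):
            raise ValueError(f"read {r.id} placement exceeds contig bounds")
        a = pysam.AlignedSegment(header)
        a.query_name = r.id
        a.query_sequence = r.sequence
        a.query_qualities = pysam.qualitystring_to_array(r.quality)
        a.reference_id = header.get_tid(r.template)
        a.reference_start = r.start
        a.mapping_quality = 60
        a.cigarstring = f"{m}M"
        a.flag = 0
        if mark_multimappers:
            window = reference[r.template][r.start : r.start + m]
            for name, seq in reference.items():
                if name != r.template and seq[r.start : r.start + m] == window:
                    a.mapping_quality = 0
                    break
        records.append(a)
    return header, records


def write_sam(header: pysam.AlignmentHeader, records, path: str) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_fastq(reads: list[SimRead], path) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    close = fh is not path
    try:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Two-locus haplotype populations
# ---------------------------------------------------------------------------

def simulate_two_locus_population(
    freqs,
    n_diploids: int,
    seed: int = 0,
):
    """Draw a phased two-locus population and pair haplotypes into diploids.

    ``freqs`` are the four haplotype frequencies in the order
    (AB, Ab, aB, ab), where allele code 1 denotes A (locus 1) / B
    (locus 2).  Returns ``(haplotypes, dosages)``: a (2n, 2) 0/1 array of
    phased haplotypes and the (n, 2) diploid dosage matrix obtained by
    pairing consecutive haplotypes (random union of gametes).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or (freqs < 0).any():
        raise ValueError("freqs must be 4 non-negative haplotype frequencies")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("haplotype frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    draw = rng.choice(4, size=2 * n_diploids, p=freqs)
    haplotypes = alleles[draw]
    dosages = haplotypes.reshape(n_diploids, 2, 2).sum(axis=1)
    return haplotypes, dosages
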