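"""Custom genotyping-reference construction.

Near-identical paralogous loci (here the centromeric DUX4C and telomeric
DUX4T copies of DUX4 embedded in / adjacent to the D4Z4 macrosatellite)
defeat short-read genotyping because reads from either paralogue map to
both. The remedy implemented here is the "masked genome + accessory
contig" recipe: hard-mask the repeat arrays and endogenous paralogue loci
in the base assembly with 'N', then append one fully resolved sequence per
haplotype as an extra contig, so that every read has exactly one
high-identity placement.

Coordinate conventions
----------------------
Printed genomic coordinates (and :class:`GenomicInterval`) are 1-based
inclusive, matching how loci are reported in the literature.  BED input is
0-based half-open and is converted at the parser boundary.  Masking is
hard-masking with ``N`` so contig lengths — and hence every downstream
coordinate — are preserved.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "AccessoryContig",
    "MaskedReference",
    "mask_regions",
    "append_contigs",
    "build_reference",
    "read_fasta",
    "read_bed",
    "write_fasta",
]

_VALID_BASES = frozenset("ACGTN")
FASTA_WRAP = 60


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    @classmethod
    def from_bed_row(cls, chrom: str, start0: int, end0: int) -> "GenomicInterval":
        """Build from a BED (0-based half-open) row."""
        return cls(chrom, int(start0) + 1, int(end0))

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


@dataclass(frozen=True)
class AccessoryContig:
    """A haplotype sequence to be appended to a masked assembly."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("accessory contig name must be non-empty")
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise ValueError(f"accessory contig {self.name!r} has empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"accessory contig {self.name!r} contains invalid characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class MaskedReference:
    """A genome with hard-masked intervals plus appended accessory contigs.

    ``contigs`` preserves insertion order (originals first, accessories
    appended).  ``mask_log`` records, for each merged mask interval, how
    many bases were newly converted to 'N'.
    """

    contigs: dict[str, str]
    mask_log: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    accessory_names: list[str] = field(default_factory=list)

    def total_masked(self) -> int:
        return sum(n for _, n in self.mask_log)

    def contig_length(self, name: str) -> int:
        return len(self.contigs[name])


def _merge_intervals(regions: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping/adjacent intervals per chromosome (sorted output)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(regions):
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end + 1:
            prev = merged[-1]
            merged[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
        else:
            merged.append(iv)
    return merged


def mask_regions(
    genome: dict[str, str], regions: list[GenomicInterval]
) -> MaskedReference:
    """Hard-mask ``regions`` of ``genome`` with 'N'.

    Overlapping intervals are merged before masking, so masked-base counts
    never double-count a position and the operation is idempotent.  Input
    sequence case is normalised to uppercase.

    Raises
    ------
    KeyError
        If a region names a contig absent from the genome.
    ValueError
        If a region extends beyond its contig.
    """
    contigs = {name: seq.upper() for name, seq in genome.items()}
    for name, seq in contigs.items():
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"contig {name!r} contains invalid characters: {sorted(bad)}")

    merged = _merge_intervals(list(regions))
    mask_log: list[tuple[GenomicInterval, int]] = []
    for iv in merged:
        if iv.chrom not in contigs:
            raise KeyError(f"mask interval references unknown contig {iv.chrom!r}")
        seq = contigs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"mask interval {iv} exceeds contig length {len(seq)}"
            )
        lo, hi = iv.start - 1, iv.end  # to 0-based half-open
        masked_count = hi - lo
        contigs[iv.chrom] = seq[:lo] + "N" * masked_count + seq[hi:]
        mask_log.append((iv, masked_count))
    return MaskedReference(contigs=contigs, mask_log=mask_log)


def append_contigs(
    ref: MaskedReference, accessories: list[AccessoryContig]
) -> MaskedReference:
    """Append accessory haplotype contigs, preserving order.

    Raises
    ------
    ValueError
        On a name collision with an existing contig or within the batch.
    """
    contigs = dict(ref.contigs)
    names = list(ref.accessory_names)
    for acc in accessories:
        if acc.name in contigs:
            raise ValueError(f"accessory contig name collides with existing contig: {acc.name!r}")
        contigs[acc.name] = acc.sequence
        names.append(acc.name)
    return MaskedReference(contigs=contigs, mask_log=list(ref.mask_log), accessory_names=names)


# ---------------------------------------------------------------------------
# File-level plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ mask intervals (0-based half-open → 1-based inclusive)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            out.append(GenomicInterval.from_bed_row(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_fasta(contigs: dict[str, str], path, wrap: int = FASTA_WRAP) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    close = fh is not path
    try:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
    finally:
        if close:
            fh.close()


def build_reference(
    genome_fasta: str,
    mask_bed: str | None,
    accessory_fasta: str | None,
    out_fasta: str,
    report_tsv: str | None = None,
) -> MaskedReference:
    """Compose mask + append from files, writing the reference and a report.

    The report lists one row per merged mask interval:
    ``chrom  start  end  bases_masked`` (1-based inclusive coordinates).
    """
    genome = read_fasta(genome_fasta)
    regions = read_bed(mask_bed) if mask_bed else []
    ref = mask_regions(genome, regions)
    if accessory_fasta:
        acc = [AccessoryContig(n, s) for n, s in read_fasta(accessory_fasta).items()]
        ref = append_contigs(ref, acc)
    write_fasta(ref.contigs, out_fasta)
    if report_tsv:
        fh = sys.stdout if report_tsv == "-" else open(report_tsv, "w")
        try:
            fh.write("chrom\tstart\tend\tbases_masked\n")
            for iv, n in ref.mask_log:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{n}\n")
        finally:
            if fh is not sys.stdout:
                fh.close()
    return ref
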