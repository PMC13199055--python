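"""Transcript-isoform curation and DUX4-like ORF classification.

Candidate full-length isoforms (e.g. reconstructed from long-read RNA-seq)
are accepted only when four structural criteria all hold:

1. a 5' UTR longer than 50 bp;
2. a same-strand CAGE peak (a transcription-start-site tag cluster)
   overlapping the genomic projection of the 5' UTR by at least one base;
3. an initiating methionine (ATG) at the annotated CDS start;
4. a Kozak consensus context at the start codon — purine at -3 and G at
   +4, counting the A of ATG as +1 (the minimal canonical rule).

Separately, DUX4-like coding sequences are classified by the presence of
the two homeodomains (HD1, HD2) and the C-terminal transcriptional
activation domain (TAD):

* group i   — HD1, HD2 and TAD all present (intact DUX4-type ORFs);
* group ii  — HD1 and HD2 present, TAD absent (the DUX4C situation,
  whose C-terminus is an intrinsically disordered region instead);
* group iii — HD1 and HD2 absent (pseudogenised copies).

Domain presence is decided by local protein alignment of a reference
domain against the frame-1 translation truncated at the first stop
codon, at configurable identity/coverage floors.  Subsets not covered by
the three definitions (e.g. HD1 without HD2) fall into group iii with a
warning.

All printed coordinates are 1-based inclusive; BED input is converted at
the parser boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "CagePeak",
    "CurationResult",
    "DomainRef",
    "ORFClassification",
    "utr5_length",
    "kozak_check",
    "curate_isoforms",
    "classify_dux4l_orf",
    "group_from_domains",
    "read_bed12",
]

_VALID_CDS = frozenset("ACGTN")
MIN_UTR5 = 50  # "longer than 50 bp" — strict
DOMAIN_NAMES = ("HD1", "HD2", "TAD")


@dataclass(frozen=True)
class TranscriptModel:
    """An exon/CDS transcript structure on a genome contig.

    ``exons`` are 1-based inclusive genomic intervals in ascending
    genomic order and must not overlap; ``cds`` is the genomic
    (min, max) span of the coding sequence, or ``None`` for a
    non-coding model.
    """

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = 0
        for s, e in self.exons:
            if s < 1 or e < s:
                raise ValueError(f"bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons must be ascending and non-overlapping")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not any(s <= cs <= e for s, e in self.exons) or not any(
                s <= ce <= e for s, e in self.exons
            ):
                raise ValueError("CDS boundaries must lie within exons")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int:
        """1-based transcript coordinate (5'->3') of a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                plus_coord = offset + (pos - s) + 1
                return plus_coord if self.strand == "+" else self.length - plus_coord + 1
            offset += e - s + 1
        raise ValueError(f"position {pos} is not exonic in transcript {self.id}")

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        if self.contig not in genome:
            raise KeyError(f"transcript {self.id} on unknown contig {self.contig!r}")
        chrom = genome[self.contig]
        if self.exons[-1][1] > len(chrom):
            raise ValueError(f"transcript {self.id} extends past contig end")
        seq = "".join(chrom[s - 1 : e] for s, e in self.exons).upper()
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def cds_start_transcript(self) -> int:
        """1-based transcript coordinate of the first coding base."""
        if self.cds is None:
            raise ValueError(f"transcript {self.id} has no CDS")
        genomic_start = self.cds[0] if self.strand == "+" else self.cds[1]
        return self.genomic_to_transcript(genomic_start)

    def utr5_genomic_intervals(self) -> list[tuple[int, int]]:
        """Genomic projection (1-based inclusive intervals) of the 5' UTR."""
        n = utr5_length(self)
        if n == 0:
            return []
        out = []
        remaining = n
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for s, e in exons:
            size = e - s + 1
            take = min(size, remaining)
            if self.strand == "+":
                out.append((s, s + take - 1))
            else:
                out.append((e - take + 1, e))
            remaining -= take
            if remaining == 0:
                break
        return sorted(out)


@dataclass(frozen=True)
class CagePeak:
    """A CAGE tag cluster (1-based inclusive interval, stranded)."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad peak interval ({self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError("peak strand must be '+' or '-'")

    @classmethod
    def from_bed_row(cls, chrom, start0, end0, strand) -> "CagePeak":
        return cls(chrom, int(start0) + 1, int(end0), strand)


@dataclass
class CurationResult:
    """Per-transcript pass/fail verdicts for the four curation criteria."""

    transcript_id: str
    criteria: dict[str, bool] = field(default_factory=dict)
    passed: bool = False
    reasons: list[str] = field(default_factory=list)
    error: str | None = None


def utr5_length(t: TranscriptModel) -> int:
    """Number of transcript bases upstream of the first coding base."""
    return t.cds_start_transcript() - 1


def kozak_check(sequence: str, atg_offset: int) -> tuple[bool, str]:
    """Kozak context at an ATG (0-based ``atg_offset`` into ``sequence``).

    True iff position -3 (3 bases upstream of the A) is a purine and
    position +4 (the base after the codon) is G.  Returns the
    7-base context ``[-3..+4]``, or ``"context_truncated"`` (and False)
    when fewer than 3 upstream or 1 downstream bases exist.
    """
    seq = sequence.upper()
    if seq[atg_offset : atg_offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {atg_offset}")
    if atg_offset < 3 or atg_offset + 4 > len(seq):
        return False, "context_truncated"
    context = seq[atg_offset - 3 : atg_offset + 4]
    ok = context[0] in "AG" and context[6] == "G"
    return ok, context


def curate_isoforms(
    models: list[TranscriptModel],
    genome: dict[str, str],
    cage_peaks: list[CagePeak],
    min_utr5: int = MIN_UTR5,
) -> list[CurationResult]:
    """Apply the four curation criteria to each transcript model.

    A model that cannot be resolved on the genome yields an error entry
    rather than aborting the batch.
    """
    results = []
    for t in models:
        res = CurationResult(transcript_id=t.id)
        try:
            if t.cds is None:
                raise ValueError("no CDS annotated")
            n_utr = utr5_length(t)
            seq = t.spliced_sequence(genome)
            cds_start0 = t.cds_start_transcript() - 1

            utr_ivals = t.utr5_genomic_intervals()
            cage_hit = any(
                p.contig == t.contig
                and p.strand == t.strand
                and any(p.start <= e and p.end >= s for s, e in utr_ivals)
                for p in cage_peaks
            )
            start_codon = seq[cds_start0 : cds_start0 + 3]
            has_met = start_codon == "ATG"
            kozak = kozak_check(seq, cds_start0)[0] if has_met else False

            res.criteria = {
                "utr5_gt_50": n_utr > min_utr5,
                "cage_in_utr5": cage_hit,
                "has_start_met": has_met,
                "kozak_ok": kozak,
            }
            res.passed = all(res.criteria.values())
            res.reasons = [k for k, v in res.criteria.items() if not v]
        except (KeyError, ValueError) as exc:
            res.error = str(exc)
            res.passed = False
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# ORF domain classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainRef:
    """A reference protein domain with its detection floors."""

    name: str
    sequence: str
    min_identity: float = 0.8
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"domain {self.name!r} has empty sequence")


@dataclass
class ORFClassification:
    sequence_id: str
    orf_intact: bool
    domains_present: frozenset
    group: str
    warning: str | None = None


def group_from_domains(present) -> tuple[str, str | None]:
    """Map a set of detected domains to group i / ii / iii.

    Combinations outside the three definitions (an HD without its
    partner, or a TAD without HDs) collapse to group iii with a warning
    rather than inventing a fourth class.
    """
    present = frozenset(present)
    if {"HD1", "HD2"} <= present:
        return ("i", None) if "TAD" in present else ("ii", None)
    if present:
        return "iii", f"domain combination {sorted(present)} outside defined groups"
    return "iii", None


def _domain_present(translation: str, ref: DomainRef, aligner: PairwiseAligner) -> bool:
    if not translation:
        return False
    alns = aligner.align(ref.sequence, translation)
    if len(alns) == 0:
        return False
    counts = alns[0].counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return False
    coverage = aligned / len(ref.sequence)
    identity = counts.identities / aligned
    return coverage >= ref.min_coverage and identity >= ref.min_identity


def classify_dux4l_orf(
    cds: str,
    domain_refs: list[DomainRef],
    sequence_id: str = "orf",
    premature_frac: float = 0.9,
    expected_aa_len: int | None = None,
) -> ORFClassification:
    """Translate a candidate CDS (frame 1) and classify by domain content.

    ``orf_intact`` is False when a stop codon appears before
    ``premature_frac`` of the expected protein length (default: the
    frame-1 length of the input itself; pass the canonical protein
    length to measure truncation against a full-length paralogue).
    Domain search runs on the translation truncated at the first stop,
    so a premature stop upstream of a domain removes it.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    bad = set(seq) - _VALID_CDS
    if bad:
        raise ValueError(f"CDS contains non-ACGTN characters: {sorted(bad)}")

    aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    expected = expected_aa_len if expected_aa_len is not None else len(aa.rstrip("*"))
    stop_idx = aa.find("*")
    effective = aa if stop_idx == -1 else aa[:stop_idx]
    orf_intact = stop_idx == -1 or stop_idx >= premature_frac * expected

    aligner = PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    present = frozenset(
        ref.name for ref in domain_refs if _domain_present(effective, ref, aligner)
    )
    group, warning = group_from_domains(present)
    if warning:
        warnings.warn(f"{sequence_id}: {warning}", stacklevel=2)
    return ORFClassification(
        sequence_id=sequence_id,
        orf_intact=orf_intact,
        domains_present=present,
        group=group,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# File plumbing
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def read_bed12(path) -> list[TranscriptModel]:
    """Read transcript models from BED12 (0-based half-open; thick = CDS)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_BED12_COLS)
    models = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(row.block_count) or len(offsets) != int(row.block_count):
            raise ValueError(f"malformed BED12 blocks for {row.name}")
        exons = tuple(
            (int(row.start) + off + 1, int(row.start) + off + size)
            for off, size in zip(offsets, sizes)
        )
        cds = None
        if int(row.thick_end) > int(row.thick_start):
            cds = (int(row.thick_start) + 1, int(row.thick_end))
        models.append(
            TranscriptModel(
                id=str(row.name),
                contig=str(row.chrom),
                strand=str(row.strand),
                exons=exons,
                cds=cds,
            )
        )
    return models


def read_cage_bed(path) -> list[CagePeak]:
    """Read CAGE peaks from BED6 (needs the strand column)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"CAGE BED needs 6 columns, got: {line!r}")
            peaks.append(CagePeak.from_bed_row(f[0], int(f[1]), int(f[2]), f[5]))
    return peaks
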