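"""Per-base depth, relative base-depth and specific motif coverage.

Depth-based paralogue genotyping reduces to three quantities:

* a per-base **depth profile** from alignments, after discarding
  low-confidence placements (default MAPQ < 10, the filter applied
  throughout the genotyping pipeline);
* the **relative base-depth**, per-base coverage divided by the
  genome-wide average — values near 1 indicate uniquely mapped,
  non-redundant alignment, so the statistic doubles as a mappability
  diagnostic for candidate motif windows;
* the **specific motif coverage**, the arithmetic mean of depth across
  the k (default 6) bases of a haplotype-diagnostic motif:
  ``sum(depth_i, i=1..k) / k``.

Depth counts a read at every reference position of its aligned span
(CIGAR deletions therefore count as covering, soft clips do not), the
behaviour of the usual samtools-style depth tools.  Unmapped, secondary
and supplementary records are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MotifSpec",
    "MotifCoverage",
    "DepthProfile",
    "RelativeDepthProfile",
    "per_base_depth",
    "depth_from_placements",
    "relative_base_depth",
    "motif_coverage",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_motif_tsv",
]

DEFAULT_MAPQ_MIN = 10
DEFAULT_MOTIF_K = 6


@dataclass(frozen=True)
class MotifSpec:
    """A k-bp haplotype-diagnostic window on a contig (0-based start)."""

    contig: str
    start: int
    k: int = DEFAULT_MOTIF_K
    system: str = ""
    haplotype: str = ""
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("motif length k must be >= 1")
        if self.start < 0:
            raise ValueError("motif start must be >= 0")
        if self.allele is not None and len(self.allele) != self.k:
            raise ValueError("motif allele string must have length k")

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.k


@dataclass(frozen=True)
class MotifCoverage:
    """Mean read depth across a motif window."""

    motif: MotifSpec
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("motif coverage cannot be negative")


@dataclass
class DepthProfile:
    """Per-contig integer depth vectors (one entry per base)."""

    depths: dict[str, np.ndarray]
    mapq_min: int = 0
    total_aligned_bases: int = 0

    def __post_init__(self) -> None:
        self.depths = {c: np.asarray(v, dtype=np.int64) for c, v in self.depths.items()}
        for c, v in self.depths.items():
            if (v < 0).any():
                raise ValueError(f"negative depth on contig {c!r}")


@dataclass
class RelativeDepthProfile:
    """Depth divided by a genome-wide mean-depth normaliser."""

    relative: dict[str, np.ndarray]
    normalizer: float


def _zero_profile(contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    return {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}


def _accumulate_span(diff: np.ndarray, start: int, end: int) -> None:
    diff[start] += 1
    diff[end] -= 1


def per_base_depth(
    alignments,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    contig_lengths: dict[str, int] | None = None,
) -> DepthProfile:
    """Pileup depth from alignments with a MAPQ floor.

    ``alignments`` may be a SAM/BAM path, an open
    :class:`pysam.AlignmentFile`, or a ``(header, records)`` pair as
    produced by :func:`dux4kit.simreads.place_reads_truth`.  Contig
    lengths come from the header unless overridden.
    """
    close = False
    if isinstance(alignments, (str, bytes)):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    if isinstance(alignments, pysam.AlignmentFile):
        header, records = alignments.header, alignments
    else:
        header, records = alignments

    if contig_lengths is None:
        contig_lengths = {
            header.get_reference_name(i): header.get_reference_length(
                header.get_reference_name(i)
            )
            for i in range(header.nreferences)
        }
    # difference arrays (length + 1) turned into depth by cumsum at the end
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
    total = 0
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            name = rec.reference_name
            if name not in diffs:
                raise KeyError(f"alignment references unknown contig {name!r}")
            start, end = rec.reference_start, rec.reference_end
            if end is None or end > contig_lengths[name]:
                raise ValueError(
                    f"alignment {rec.query_name!r} extends past contig {name!r}"
                )
            _accumulate_span(diffs[name], start, end)
            total += end - start
    finally:
        if close:
            records.close()
    depths = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return DepthProfile(depths=depths, mapq_min=mapq_min, total_aligned_bases=total)


def depth_from_placements(
    placements,
    read_length: int,
    contig_lengths: dict[str, int],
) -> DepthProfile:
    """Depth directly from true-origin placements ``(read_id, contig, start)``.

    Equivalent to :func:`per_base_depth` on the corresponding ungapped
    MAPQ-60 records; used as the fast path for simulated samples.
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
    total = 0
    for _, contig, start in placements:
        if contig not in diffs:
            raise KeyError(f"placement references unknown contig {contig!r}")
        end = start + read_length
        if start < 0 or end > contig_lengths[contig]:
            raise ValueError(f"placement at {contig}:{start} out of bounds")
        _accumulate_span(diffs[contig], start, end)
        total += read_length
    depths = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return DepthProfile(depths=depths, mapq_min=0, total_aligned_bases=total)


def relative_base_depth(
    profile: DepthProfile,
    reference: dict[str, str] | None = None,
    exclude_masked: bool = True,
    exclude_contigs=(),
) -> RelativeDepthProfile:
    """Normalise depth to the genome-wide average.

    The normaliser is the mean depth over included positions: contigs in
    ``exclude_contigs`` (typically the accessory haplotype contigs, whose
    inserted copies would inflate the average) contribute nothing, and
    with ``exclude_masked`` any position that is 'N' in ``reference`` is
    skipped.  All contigs — included or not — are then divided by that
    single normaliser.
    """
    total = 0.0
    n_pos = 0
    for contig, depth in profile.depths.items():
        if contig in exclude_contigs:
            continue
        if exclude_masked and reference is not None and contig in reference:
            seq = np.frombuffer(reference[contig].upper().encode("ascii"), dtype=np.uint8)
            keep = seq != ord("N")
            total += float(depth[keep].sum())
            n_pos += int(keep.sum())
        else:
            total += float(depth.sum())
            n_pos += depth.size
    if n_pos == 0:
        raise ValueError("no positions available to compute the genome-wide mean")
    mean = total / n_pos
    if mean <= 0:
        raise ValueError("genome-wide mean depth is zero; no usable coverage")
    return RelativeDepthProfile(
        relative={c: d / mean for c, d in profile.depths.items()},
        normalizer=mean,
    )


def motif_coverage(profile: DepthProfile, motif: MotifSpec) -> MotifCoverage:
    """Specific motif coverage: mean depth over the motif's k bases."""
    if motif.contig not in profile.depths:
        raise KeyError(f"motif contig {motif.contig!r} absent from depth profile")
    depth = profile.depths[motif.contig]
    if motif.end > depth.size:
        raise ValueError(
            f"motif window {motif.contig}:{motif.start}-{motif.end} exceeds "
            f"contig length {depth.size}"
        )
    value = float(depth[motif.start : motif.end].mean())
    return MotifCoverage(motif=motif, value=value)


# ---------------------------------------------------------------------------
# TSV plumbing (aligner-independent ingestion)
# ---------------------------------------------------------------------------

def read_depth_tsv(path, contig_lengths: dict[str, int] | None = None) -> DepthProfile:
    """Read a 3-column depth table ``contig  pos(1-based)  depth``.

    The samtools-depth convention: positions are 1-based, absent
    positions have depth 0.  Contig lengths default to the maximum
    position seen per contig.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["contig", "pos", "depth"]
    )
    if contig_lengths is None:
        contig_lengths = df.groupby("contig")["pos"].max().astype(int).to_dict()
    depths = _zero_profile(contig_lengths)
    for contig, sub in df.groupby("contig"):
        if contig not in depths:
            raise KeyError(f"depth table references unknown contig {contig!r}")
        pos = sub["pos"].to_numpy(dtype=np.int64) - 1
        if (pos < 0).any() or (pos >= depths[contig].size).any():
            raise ValueError(f"depth position out of bounds on contig {contig!r}")
        depths[contig][pos] = sub["depth"].to_numpy(dtype=np.int64)
    total = int(sum(d.sum() for d in depths.values()))
    return DepthProfile(depths=depths, mapq_min=0, total_aligned_bases=total)


def write_depth_tsv(profile: DepthProfile, path, skip_zero: bool = True) -> None:
    fh = path if hasattr(path, "write") else open(path, "w")
    close = fh is not path
    try:
        for contig, depth in profile.depths.items():
            idx = np.nonzero(depth)[0] if skip_zero else np.arange(depth.size)
            for i in idx:
                fh.write(f"{contig}\t{i + 1}\t{depth[i]}\n")
    finally:
        if close:
            fh.close()


def read_motif_tsv(path) -> list[MotifSpec]:
    """Read a motif table ``contig  start  end  system  haplotype [allele]``.

    Coordinates are BED-style 0-based half-open; ``k = end - start``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 5:
        raise ValueError("motif TSV needs >= 5 columns: contig start end system haplotype")
    out = []
    for row in df.itertuples(index=False):
        contig, start, end, system, hap = row[:5]
        allele = str(row[5]) if df.shape[1] > 5 and not pd.isna(row[5]) else None
        out.append(
            MotifSpec(
                contig=str(contig),
                start=int(start),
                k=int(end) - int(start),
                system=str(system),
                haplotype=str(hap),
                allele=allele,
            )
        )
    return out
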