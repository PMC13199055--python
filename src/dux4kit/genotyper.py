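"""Threshold-based diploid genotype calls from motif-coverage proportions.

The caller converts specific-motif coverages into haplotype proportions
and bins them into diploid genotypes.

DUX4C (one locus, two haplotypes alpha/beta)::

    p_alpha = cov_alpha / (cov_alpha + cov_beta)

with theoretical values 1 (alpha/alpha), 0.5 (alpha/beta), 0 (beta/beta)
and permissive call intervals [0.75, 1.0] / [0.25, 0.75) / [0, 0.25).

DUX4T (two chromosomes sharing a pooled denominator; the B motif is
common to the 4qB and 10qB haplotypes)::

    p_4qA  = cov_4qA  / (cov_4qA + cov_10qA + cov_B)
    p_10qA = cov_10qA / (cov_4qA + cov_10qA + cov_B)

Because the denominator pools four chromosomal alleles (two chr4 + two
chr10), a euploid 4qA homozygote peaks at p_4qA = 0.5, not 1; the
theoretical values are 0.5 / 0.25 / 0 for 4qA/4qA, 4qA/4qB, 4qB/4qB and
the call intervals are [0.375, 1] / [0.125, 0.375) / [0, 0.125), applied
identically to chr10.  Interval bounds are closed below, open above, with
the top interval closed at 1 — a deterministic convention for the
printed overlapping endpoints.

When p_4qA >= 0.375 and p_B >= 0.05 the B coverage cannot be attributed
between 4qB and 10qB (a 4qA/4qB heterozygote may masquerade as 4qA/4qA);
such calls carry the ``ambiguous_B_attribution`` flag and should be
excluded from downstream haplotype analyses.  The caller assumes diploidy
on both chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .covdepth import DepthProfile, MotifCoverage, MotifSpec, motif_coverage

__all__ = [
    "LocusThresholds",
    "ThresholdConfig",
    "ProportionSet",
    "GenotypeCall",
    "dux4c_proportion",
    "dux4t_proportions",
    "call_dux4c",
    "call_dux4t",
    "genotype_sample",
]

FLAG_OK = "ok"
FLAG_NO_CALL = "no_call"
FLAG_AMBIGUOUS_B = "ambiguous_B_attribution"


@dataclass(frozen=True)
class LocusThresholds:
    """Proportion intervals [hom_hi, 1] / [het_lo, hom_hi) / [0, het_lo)."""

    hom_hi: float
    het_lo: float

    def __post_init__(self) -> None:
        if not (0.0 < self.het_lo < self.hom_hi <= 1.0):
            raise ValueError("need 0 < het_lo < hom_hi <= 1")

    def classify(self, p: float, major: str, minor: str) -> str:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"proportion {p} outside [0, 1]")
        if p >= self.hom_hi:
            return f"{major}/{major}"
        if p >= self.het_lo:
            return f"{major}/{minor}"
        return f"{minor}/{minor}"


@dataclass(frozen=True)
class ThresholdConfig:
    """Default thresholds for the DUX4C / DUX4T systems (configurable)."""

    dux4c: LocusThresholds = LocusThresholds(hom_hi=0.75, het_lo=0.25)
    dux4t: LocusThresholds = LocusThresholds(hom_hi=0.375, het_lo=0.125)
    ambiguity_p4qa_min: float = 0.375
    ambiguity_pb_min: float = 0.05
    # haplotype labels as they appear in the motif table
    dux4c_haplotypes: tuple[str, str] = ("alpha", "beta")
    dux4t_haplotypes: tuple[str, str, str] = ("4qA", "10qA", "B")
    # display labels for the untyped minor haplotypes per chromosome
    dux4t_minor_labels: tuple[str, str] = ("4qB", "10qB")

    @classmethod
    def from_file(cls, path) -> "ThresholdConfig":
        """Load ``key = value`` overrides of the numeric thresholds."""
        vals: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                vals[key.strip()] = float(raw)
        cfg = cls()
        if {"dux4c_hom_hi", "dux4c_het_lo"} & vals.keys():
            cfg = replace(
                cfg,
                dux4c=LocusThresholds(
                    vals.get("dux4c_hom_hi", cfg.dux4c.hom_hi),
                    vals.get("dux4c_het_lo", cfg.dux4c.het_lo),
                ),
            )
        if {"dux4t_hom_hi", "dux4t_het_lo"} & vals.keys():
            cfg = replace(
                cfg,
                dux4t=LocusThresholds(
                    vals.get("dux4t_hom_hi", cfg.dux4t.hom_hi),
                    vals.get("dux4t_het_lo", cfg.dux4t.het_lo),
                ),
            )
        return replace(
            cfg,
            ambiguity_p4qa_min=vals.get("ambiguity_p4qa_min", cfg.ambiguity_p4qa_min),
            ambiguity_pb_min=vals.get("ambiguity_pb_min", cfg.ambiguity_pb_min),
        )


@dataclass(frozen=True)
class ProportionSet:
    """Motif coverages and derived proportions for one locus system.

    ``proportions`` is ``None`` when the pooled coverage is zero
    (no-call); otherwise the proportions sum to 1.
    """

    system: str
    coverages: dict[str, float]
    proportions: dict[str, float] | None
    total: float

    @property
    def defined(self) -> bool:
        return self.proportions is not None


def _as_value(cov) -> float:
    v = cov.value if isinstance(cov, MotifCoverage) else float(cov)
    if v < 0:
        raise ValueError(f"negative motif coverage: {v}")
    return v


def dux4c_proportion(cov_alpha, cov_beta, haplotypes=("alpha", "beta")) -> ProportionSet:
    """p_alpha = cov_alpha / (cov_alpha + cov_beta); zero total -> no-call."""
    a, b = _as_value(cov_alpha), _as_value(cov_beta)
    total = a + b
    props = None if total == 0 else {haplotypes[0]: a / total, haplotypes[1]: b / total}
    return ProportionSet(
        system="DUX4C",
        coverages={haplotypes[0]: a, haplotypes[1]: b},
        proportions=props,
        total=total,
    )


def dux4t_proportions(
    cov_4qa, cov_10qa, cov_b, haplotypes=("4qA", "10qA", "B")
) -> ProportionSet:
    """Pooled-denominator proportions over the 4qA, 10qA and shared B motifs."""
    vals = [_as_value(cov_4qa), _as_value(cov_10qa), _as_value(cov_b)]
    total = sum(vals)
    props = None if total == 0 else {h: v / total for h, v in zip(haplotypes, vals)}
    return ProportionSet(
        system="DUX4T",
        coverages=dict(zip(haplotypes, vals)),
        proportions=props,
        total=total,
    )


@dataclass
class GenotypeCall:
    """Per-sample genotypes with full provenance."""

    sample: str
    coverages: dict[str, float] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)
    genotype_dux4c: str | None = None
    genotype_dux4t_chr4: str | None = None
    genotype_dux4t_chr10: str | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return self.flags == {FLAG_OK}


def call_dux4c(p: ProportionSet, t: ThresholdConfig | None = None):
    """Classify a DUX4C proportion set: (genotype label | None, flags)."""
    t = t or ThresholdConfig()
    if not p.defined:
        return None, {FLAG_NO_CALL}
    major, minor = t.dux4c_haplotypes
    return t.dux4c.classify(p.proportions[major], major, minor), {FLAG_OK}


def call_dux4t(p: ProportionSet, t: ThresholdConfig | None = None):
    """Classify a DUX4T proportion set.

    Returns ``(chr4 label | None, chr10 label | None, flags)``.  Labels
    are still reported when the B-attribution is ambiguous, but the call
    carries the ``ambiguous_B_attribution`` flag and must not be treated
    as a confident genotype.
    """
    t = t or ThresholdConfig()
    if not p.defined:
        return None, None, {FLAG_NO_CALL}
    h4, h10, hb = t.dux4t_haplotypes
    m4, m10 = t.dux4t_minor_labels
    g4 = t.dux4t.classify(p.proportions[h4], h4, m4)
    g10 = t.dux4t.classify(p.proportions[h10], h10, m10)
    flags = {FLAG_OK}
    if (
        p.proportions[h4] >= t.ambiguity_p4qa_min
        and p.proportions[hb] >= t.ambiguity_pb_min
    ):
        flags = {FLAG_AMBIGUOUS_B}
    return g4, g10, flags


def genotype_sample(
    depth: DepthProfile,
    motifs: list[MotifSpec],
    thresholds: ThresholdConfig | None = None,
    sample: str = "sample",
) -> GenotypeCall:
    """End-to-end call: motif coverages -> proportions -> genotypes.

    ``motifs`` must carry ``system`` in {"DUX4C", "DUX4T"} and
    ``haplotype`` labels matching the threshold config.
    """
    t = thresholds or ThresholdConfig()
    cov: dict[str, MotifCoverage] = {}
    for spec in motifs:
        key = f"{spec.system}:{spec.haplotype}"
        if key in cov:
            raise ValueError(f"duplicate motif for {key}")
        cov[key] = motif_coverage(depth, spec)

    call = GenotypeCall(sample=sample)
    call.coverages = {k: c.value for k, c in cov.items()}

    a, b = t.dux4c_haplotypes
    pc = dux4c_proportion(
        cov[f"DUX4C:{a}"], cov[f"DUX4C:{b}"], haplotypes=t.dux4c_haplotypes
    )
    gc, flags_c = call_dux4c(pc, t)
    call.genotype_dux4c = gc

    h4, h10, hb = t.dux4t_haplotypes
    pt = dux4t_proportions(
        cov[f"DUX4T:{h4}"],
        cov[f"DUX4T:{h10}"],
        cov[f"DUX4T:{hb}"],
        haplotypes=t.dux4t_haplotypes,
    )
    g4, g10, flags_t = call_dux4t(pt, t)
    call.genotype_dux4t_chr4 = g4
    call.genotype_dux4t_chr10 = g10

    if pc.defined:
        call.proportions.update({f"DUX4C:{k}": v for k, v in pc.proportions.items()})
    if pt.defined:
        call.proportions.update({f"DUX4T:{k}": v for k, v in pt.proportions.items()})
    call.flags = (flags_c | flags_t) - ({FLAG_OK} if (flags_c | flags_t) != {FLAG_OK} else set())
    return call
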