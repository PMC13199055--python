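"""Population-genetic layer: MAF filtering, LD (r²), blocks, two-locus EM.

Works on sample × variant matrices of biallelic dosage codes {0, 1, 2}
(NaN = missing), held as pandas DataFrames.  Linkage disequilibrium is
always derived from haplotype frequencies::

    D  = p_AB - p_A * p_B
    r² = D² / (p_A * (1 - p_A) * p_B * (1 - p_B))

For phased input the haplotype frequencies are direct counts; for
unphased genotypes they come from the two-locus EM estimator, in which
only double heterozygotes carry phase ambiguity.  The EM replaces a
full phasing engine for the two-allele × two-allele question asked
here (which haplotype of the centromeric locus travels with which
haplotype of the telomeric locus); it is exact maximum likelihood under
random union of gametes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "HaplotypeFreqTable",
    "filter_maf",
    "pairwise_r2",
    "ld_blocks",
    "em_haplotype_freq",
    "cross_locus_ld",
    "r2_from_freqs",
    "read_vcf_dosages",
]

DEFAULT_MAF_MIN = 0.1
DEFAULT_BLOCK_R2 = 0.8
EM_TOL = 1e-8
EM_MAX_ITER = 1000

# haplotype order used throughout: (AB, Ab, aB, ab); allele code 1 = A / B
_HAP_ALLELES = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])


@dataclass
class HaplotypeFreqTable:
    """Estimated two-locus haplotype frequencies.

    ``freqs`` follows the order (AB, Ab, aB, ab).  ``counts`` are
    ``freq * 2n`` rounded to integers, mirroring the way haplotype
    tallies are reported in cohort studies.
    """

    freqs: np.ndarray
    n_samples: int
    log_likelihood: float
    iterations: int
    labels: tuple[str, str, str, str] = ("AB", "Ab", "aB", "ab")
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or (self.freqs < -1e-12).any():
            raise ValueError("freqs must be 4 non-negative values")
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-6):
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.freqs * 2 * self.n_samples).astype(int)

    def r2(self) -> float:
        return r2_from_freqs(self.freqs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"haplotype": list(self.labels), "frequency": self.freqs, "count": self.counts}
        )


def r2_from_freqs(freqs) -> float:
    """r² from four haplotype frequencies in (AB, Ab, aB, ab) order."""
    f = np.asarray(freqs, dtype=float)
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return float("nan")
    d = f[0] - p_a * p_b
    return float(d * d / denom)


def filter_maf(genotypes: pd.DataFrame, maf_min: float = DEFAULT_MAF_MIN) -> pd.DataFrame:
    """Drop variants with minor allele frequency strictly below ``maf_min``.

    MAF is computed from non-missing dosages; a variant with no calls at
    all is treated as MAF 0 and removed.
    """
    g = genotypes.astype(float)
    p = g.mean(axis=0, skipna=True) / 2.0
    p = p.fillna(0.0)
    maf = np.minimum(p, 1.0 - p)
    return genotypes.loc[:, maf >= maf_min]


def _phased_pair_freqs(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) from two phased 0/1 columns."""
    n = h1.size
    f_ab = np.sum((h1 == 1) & (h2 == 1)) / n
    f_a = np.sum(h1 == 1) / n
    f_b = np.sum(h2 == 1) / n
    return np.array([f_ab, f_a - f_ab, f_b - f_ab, 1 - f_a - f_b + f_ab])


def pairwise_r2(data, phased: bool = False) -> pd.DataFrame:
    """Symmetric variant × variant r² matrix.

    ``data``: DataFrame of dosages (unphased; r² per pair via the EM
    estimator on complete cases) or, with ``phased=True``, a
    haplotype × variant 0/1 matrix (r² by direct haplotype counting).
    Monomorphic variants yield NaN against every partner, including
    themselves.
    """
    df = pd.DataFrame(data)
    cols = list(df.columns)
    v = len(cols)
    if v < 2:
        raise ValueError("need at least two variants")
    arr = df.to_numpy(dtype=float)
    out = np.full((v, v), np.nan)
    for i in range(v):
        for j in range(i, v):
            if i == j:
                col = arr[:, i]
                col = col[~np.isnan(col)]
                mono = col.size == 0 or np.all(col == col[0])
                out[i, i] = np.nan if mono else 1.0
                continue
            pair = arr[:, [i, j]]
            pair = pair[~np.isnan(pair).any(axis=1)]
            if pair.shape[0] < 2:
                continue
            if phased:
                freqs = _phased_pair_freqs(pair[:, 0], pair[:, 1])
                r2 = r2_from_freqs(freqs)
            else:
                try:
                    r2 = em_haplotype_freq(pair).r2()
                except ValueError:
                    r2 = float("nan")
            out[i, j] = out[j, i] = r2
    return pd.DataFrame(out, index=cols, columns=cols)


def ld_blocks(r2_matrix: pd.DataFrame, r2_min: float = DEFAULT_BLOCK_R2) -> pd.Series:
    """Single-linkage block assignment: chains of pairs with r² > ``r2_min``.

    Blocks are numbered 0, 1, ... by the first (column-order) variant
    they contain, so the assignment is deterministic.
    """
    m = r2_matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("LD matrix must be square")
    adj = np.nan_to_num(m, nan=0.0) > r2_min
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # renumber components in order of first appearance
    order: dict[int, int] = {}
    renum = [order.setdefault(lab, len(order)) for lab in labels]
    return pd.Series(renum, index=r2_matrix.index, name="block")


# ---------------------------------------------------------------------------
# Two-locus EM
# ---------------------------------------------------------------------------

def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """3×3 table of genotype-pair counts; rows = locus 1 dosage."""
    counts = np.zeros((3, 3))
    for g1 in range(3):
        for g2 in range(3):
            counts[g1, g2] = np.sum((dosages[:, 0] == g1) & (dosages[:, 1] == g2))
    return counts


# fixed expected haplotype counts (AB, Ab, aB, ab) per unambiguous genotype
_FIXED_HAPS = {
    (0, 0): (0, 0, 0, 2),
    (0, 1): (0, 0, 1, 1),
    (0, 2): (0, 0, 2, 0),
    (1, 0): (0, 1, 0, 1),
    (1, 2): (1, 0, 1, 0),
    (2, 0): (0, 2, 0, 0),
    (2, 1): (1, 1, 0, 0),
    (2, 2): (2, 0, 0, 0),
}


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3×3 genotype-pair probabilities under random union of gametes."""
    p = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            g1 = _HAP_ALLELES[i, 0] + _HAP_ALLELES[j, 0]
            g2 = _HAP_ALLELES[i, 1] + _HAP_ALLELES[j, 1]
            p[g1, g2] += f[i] * f[j]
    return p


def em_haplotype_freq(
    dosages,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeFreqTable:
    """Two-locus haplotype-frequency EM from unphased dosages.

    ``dosages`` is an (n, 2) array-like with codes {0, 1, 2}; rows with
    missing (NaN) values at either locus are dropped (complete-case).
    Only the double-heterozygote class (1, 1) is phase-ambiguous; all
    other classes contribute fixed haplotype counts, so in the absence
    of double heterozygotes the EM reduces to direct gamete counting in
    a single iteration.  Uniform initialisation, convergence when the
    largest frequency change drops below ``tol``.
    """
    arr = np.asarray(pd.DataFrame(dosages).to_numpy(), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("dosages must be an (n, 2) two-locus matrix")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] == 0:
        raise ValueError("no complete-case samples for EM")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("dosage codes must be 0, 1 or 2")
    counts = _genotype_counts(arr)
    n = arr.shape[0]

    fixed = np.zeros(4)
    for (g1, g2), haps in _FIXED_HAPS.items():
        fixed += counts[g1, g2] * np.asarray(haps)
    n_dh = counts[1, 1]

    f = np.full(4, 0.25)
    history: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        probs = _genotype_probs(f)
        with np.errstate(divide="ignore"):
            ll = float(np.sum(counts * np.log(np.where(counts > 0, probs, 1.0))))
        history.append(ll)
        # E-step: split double heterozygotes between the two phase resolutions
        expect = fixed.copy()
        if n_dh > 0:
            cis = f[0] * f[3]
            trans = f[1] * f[2]
            w = 0.5 if cis + trans == 0 else cis / (cis + trans)
            expect += n_dh * np.array([w, 1 - w, 1 - w, w])
        new_f = expect / (2 * n)
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            break
        f = new_f
    probs = _genotype_probs(f)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(counts * np.log(np.where(counts > 0, probs, 1.0))))
    history.append(ll)
    return HaplotypeFreqTable(
        freqs=f,
        n_samples=n,
        log_likelihood=ll,
        iterations=iterations,
        loglik_history=history,
    )


def _labels_to_dosage(labels, focal: str) -> np.ndarray:
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        alleles = str(lab).split("/")
        if len(alleles) != 2:
            raise ValueError(f"genotype label {lab!r} is not of the form x/y")
        out[i] = sum(a == focal for a in alleles)
    return out


def cross_locus_ld(
    geno1,
    geno2,
    focal1: str | None = None,
    focal2: str | None = None,
) -> tuple[float, HaplotypeFreqTable]:
    """LD between two locus systems from per-sample diploid genotypes.

    ``geno1`` / ``geno2`` are either dosage arrays {0, 1, 2} or
    sequences of ``"x/y"`` genotype labels, in which case ``focalN``
    names the haplotype counted as allele 1 (e.g. focal1="alpha",
    focal2="B" to measure the alpha–B association).  Returns the r²
    computed from EM haplotype frequencies together with the frequency
    table itself.
    """
    d1 = _labels_to_dosage(geno1, focal1) if focal1 is not None else np.asarray(geno1, float)
    d2 = _labels_to_dosage(geno2, focal2) if focal2 is not None else np.asarray(geno2, float)
    if d1.shape != d2.shape:
        raise ValueError("locus systems have different sample counts")
    table = em_haplotype_freq(np.column_stack([d1, d2]))
    if focal1 and focal2:
        other1, other2 = "~" + focal1, "~" + focal2
        table.labels = (
            f"{focal1}-{focal2}",
            f"{focal1}-{other2}",
            f"{other1}-{focal2}",
            f"{other1}-{other2}",
        )
    return table.r2(), table


def read_vcf_dosages(path) -> pd.DataFrame:
    """Sample × variant dosage matrix from a biallelic VCF (alt-allele count)."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        data: dict[str, list[float]] = {}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"variant {rec.id or rec.pos} is not biallelic")
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(np.nan)
                else:
                    col.append(float(sum(gt)))
            data[vid] = col
    return pd.DataFrame(data, index=samples)
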