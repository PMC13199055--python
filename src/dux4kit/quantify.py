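"""Expression aggregation (TPM / CPM) and genotype-stratified comparison.

Transcript-level quantification is length-normalised to transcripts per
million (TPM = 1e6 * (count/length) / sum(count/length)), transcripts
pooled to genes by annotation label — all entries annotated with the
pooled gene label (default exact string "DUX4") are combined into one
gene-level value, the way the many near-identical D4Z4-embedded DUX4
entries of a comprehensive annotation are collapsed to a single DUX4T
readout.  Region-level CPM (1e6 * count / library size) supports
genotype stratification rules such as "case: CPM > 1, control: CPM = 0".
Two-group comparisons use the Mann–Whitney U test: exact for small
tie-free groups, normal approximation with continuity correction and
mid-rank ties otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "tpm_from_counts",
    "aggregate_gene",
    "region_cpm",
    "compare_groups",
    "select_samples",
]

EXACT_MAX_N = 8


def tpm_from_counts(counts, lengths, ids=None) -> pd.DataFrame:
    """Transcript table with TPM from raw counts and effective lengths.

    Returns columns ``transcript_id, length, count, tpm``; TPM sums to
    1e6 unless every count is zero (then all-zero with a warning).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if ids is None:
        ids = [f"tx{i}" for i in range(counts.size)]
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM undefined, reporting zeros", stacklevel=2)
        tpm = np.zeros_like(rate)
    else:
        tpm = 1e6 * rate / total
    return pd.DataFrame(
        {"transcript_id": list(ids), "length": lengths, "count": counts, "tpm": tpm}
    )


def aggregate_gene(
    table: pd.DataFrame,
    t2g: dict[str, str] | pd.Series,
    pool_match: str | None = None,
    pool_label: str | None = None,
    allow_unmapped: bool = False,
) -> pd.DataFrame:
    """Sum transcript TPM to gene level.

    ``t2g`` maps transcript id -> gene label.  With ``pool_match``, every
    gene whose label equals it is re-labelled ``pool_label`` (default:
    the match itself) before summing, e.g. pool_match="DUX4",
    pool_label="DUX4T" combines all DUX4-annotated entries into one
    DUX4T row while leaving DUX4C separate.  Unmapped transcripts keep
    their own id as gene label when ``allow_unmapped``; otherwise they
    raise.
    """
    t2g = dict(t2g) if not isinstance(t2g, dict) else t2g
    genes = []
    for tx in table["transcript_id"]:
        if tx in t2g:
            genes.append(t2g[tx])
        elif allow_unmapped:
            genes.append(tx)
        else:
            raise KeyError(f"transcript {tx!r} has no gene annotation")
    genes = pd.Series(genes, index=table.index, name="gene")
    if pool_match is not None:
        genes = genes.where(genes != pool_match, pool_label or pool_match)
    out = (
        table.assign(gene=genes)
        .groupby("gene", sort=False)["tpm"]
        .sum()
        .reset_index()
    )
    if pool_match is not None:
        label = pool_label or pool_match
        if label not in set(out["gene"]):
            out = pd.concat(
                [out, pd.DataFrame({"gene": [label], "tpm": [0.0]})],
                ignore_index=True,
            )
    return out


def region_cpm(read_count: float, library_size: float) -> float:
    """Counts per million over a region: 1e6 * count / library size."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return 1e6 * read_count / library_size


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann–Whitney U comparison of two value groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: str  # "a>b", "b>a" or "none"
    method: str  # "exact" or "asymptotic"


def compare_groups(
    values_a,
    values_b,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when both groups have <= 8 values and the
    pooled data carry no ties; otherwise normal approximation with
    continuity correction (mid-ranks for ties).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    mid = a.size * b.size / 2.0
    if res.statistic > mid:
        direction = "a>b"
    elif res.statistic < mid:
        direction = "b>a"
    else:
        direction = "none"
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        method=method,
    )


def select_samples(frame: pd.DataFrame, query: str) -> pd.DataFrame:
    """Declarative case/control stratification over a merged call/expression
    table, e.g. ``genotype_dux4c == 'alpha/alpha' and cpm > 1``."""
    return frame.query(query)
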