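"""Shared fixtures: toy loci, synthetic domain references, label helpers."""

import numpy as np
import pytest

from dux4kit import default_toy_loci, toy_motif_specs, toy_reference_contigs
from dux4kit.isocurate import DomainRef


@pytest.fixture(scope="session")
def toy_specs():
    return default_toy_loci()


@pytest.fixture(scope="session")
def toy_contigs(toy_specs):
    return toy_reference_contigs(toy_specs)


@pytest.fixture(scope="session")
def toy_lengths(toy_contigs):
    return {c: len(s) for c, s in toy_contigs.items()}


@pytest.fixture(scope="session")
def toy_motifs(toy_specs):
    return toy_motif_specs(toy_specs)


# synthetic stand-ins for the two homeodomains and the activation domain;
# arbitrary sequences long enough for unambiguous local alignment
@pytest.fixture(scope="session")
def domain_refs():
    rng = np.random.default_rng(99)
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def protein(n):
        return "".join(aa[i] for i in rng.integers(0, len(aa), size=n))

    return {
        "HD1": DomainRef("HD1", protein(60)),
        "HD2": DomainRef("HD2", protein(60)),
        "TAD": DomainRef("TAD", protein(50)),
    }


_REVERSE_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}


def reverse_translate(protein: str) -> str:
    """One fixed codon per residue — deterministic CDS for a protein."""
    return "".join(_REVERSE_CODON[a] for a in protein)


@pytest.fixture(scope="session")
def rt():
    return reverse_translate


def expected_genotype_labels(gc, gt4, gt10=("10qA", "10qA")):
    """Map toy-locus truth allele pairs to the caller's genotype labels."""
    lab = {
        ("alpha", "alpha"): "alpha/alpha",
        ("alpha", "beta"): "alpha/beta",
        ("beta", "beta"): "beta/beta",
        ("4qA", "4qA"): "4qA/4qA",
        ("4qA", "B"): "4qA/4qB",
        ("B", "B"): "4qB/4qB",
        ("10qA", "10qA"): "10qA/10qA",
        ("10qA", "B"): "10qA/10qB",
    }
    lab[("B", "B"), "chr10"] = "10qB/10qB"
    g10 = "10qB/10qB" if gt10 == ("B", "B") else lab[gt10]
    return lab[gc], lab[gt4], g10
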