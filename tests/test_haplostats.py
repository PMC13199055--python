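"""MAF filter, r² against a brute-force oracle, blocks, two-locus EM."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import dux4kit as dk
from dux4kit.haplostats import r2_from_freqs


def brute_force_r2(haps: np.ndarray) -> float:
    """Exhaustive haplotype-counting r² with exact rational arithmetic."""
    n = len(haps)
    p_ab = Fraction(int(np.sum((haps[:, 0] == 1) & (haps[:, 1] == 1))), n)
    p_a = Fraction(int(np.sum(haps[:, 0] == 1)), n)
    p_b = Fraction(int(np.sum(haps[:, 1] == 1)), n)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return float("nan")
    d = p_ab - p_a * p_b
    return float(d * d / denom)


class TestFilterMaf:
    def _matrix(self, freqs, n=100):
        rng = np.random.default_rng(0)
        cols = {
            f"v{i}": rng.binomial(2, p, size=n).astype(float)
            for i, p in enumerate(freqs)
        }
        return pd.DataFrame(cols)

    def test_low_maf_variant_removed(self):
        g = pd.DataFrame({"keep": [0, 1, 1, 2], "drop": [0, 0, 0, 1]})
        # drop: allele freq 1/8 = 0.125 kept; make a truly rare one
        g["rare"] = [0, 0, 0, 0]
        out = dk.filter_maf(g, 0.1)
        assert "rare" not in out.columns
        assert "keep" in out.columns

    def test_boundary_exactly_at_threshold_retained(self):
        g = pd.DataFrame({"v": [1, 0, 0, 0, 0]})  # MAF = 1/10 = 0.1
        assert "v" in dk.filter_maf(g, 0.1).columns

    def test_monomorphic_removed(self):
        g = pd.DataFrame({"v": [2, 2, 2]})
        assert dk.filter_maf(g, 0.1).shape[1] == 0

    def test_maf_uses_non_missing_calls_only(self):
        g = pd.DataFrame({"v": [1.0, 1.0, np.nan, np.nan, np.nan, np.nan]})
        # among 2 called samples: freq 2/4 = 0.5
        assert "v" in dk.filter_maf(g, 0.4).columns


class TestPairwiseR2:
    def test_variant_vs_itself_is_one(self):
        h = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 1, 0, 0]})
        r2 = dk.pairwise_r2(h, phased=True)
        assert r2.loc["a", "a"] == 1.0

    def test_worked_four_haplotype_case(self):
        # haplotypes {AB, AB, ab, aB}: D = 1/8, r² = 1/3 exactly
        h = pd.DataFrame([[1, 1], [1, 1], [0, 0], [0, 1]])
        r2 = dk.pairwise_r2(h, phased=True)
        assert r2.iloc[0, 1] == pytest.approx(1 / 3, abs=1e-15)

    def test_equilibrium_haplotypes_give_zero(self):
        h = pd.DataFrame([[1, 1], [1, 0], [0, 1], [0, 0]])
        r2 = dk.pairwise_r2(h, phased=True)
        assert r2.iloc[0, 1] == 0.0

    def test_monomorphic_reported_missing(self):
        h = pd.DataFrame({"mono": [1, 1, 1, 1], "poly": [1, 0, 1, 0]})
        r2 = dk.pairwise_r2(h, phased=True)
        assert np.isnan(r2.loc["mono", "poly"])
        assert np.isnan(r2.loc["mono", "mono"])

    def test_matches_brute_force_oracle_on_random_phased_data(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(10, 2))
            expected = brute_force_r2(haps)
            got = dk.pairwise_r2(pd.DataFrame(haps), phased=True).iloc[0, 1]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_label_swap_invariance(self):
        rng = np.random.default_rng(32)
        haps = rng.integers(0, 2, size=(40, 3))
        r2 = dk.pairwise_r2(pd.DataFrame(haps), phased=True)
        assert np.allclose(r2.to_numpy(), r2.to_numpy().T, equal_nan=True)
        flipped = haps.copy()
        flipped[:, 0] = 1 - flipped[:, 0]  # swap allele labels at locus 0
        r2f = dk.pairwise_r2(pd.DataFrame(flipped), phased=True)
        assert np.allclose(r2.to_numpy(), r2f.to_numpy(), equal_nan=True)

    def test_unphased_em_route_close_to_phased_truth(self):
        hap, dos = dk.simulate_two_locus_population([0.4, 0.1, 0.1, 0.4], 300, seed=33)
        r2_phased = dk.pairwise_r2(pd.DataFrame(hap), phased=True).iloc[0, 1]
        r2_em = dk.pairwise_r2(pd.DataFrame(dos)).iloc[0, 1]
        assert r2_em == pytest.approx(r2_phased, abs=0.05)


class TestLdBlocks:
    def _matrix(self, values):
        return pd.DataFrame(values)

    def test_two_clusters(self):
        m = np.full((4, 4), 0.1)
        m[np.ix_([0, 1], [0, 1])] = 0.95
        m[np.ix_([2, 3], [2, 3])] = 0.95
        np.fill_diagonal(m, 1.0)
        blocks = dk.ld_blocks(self._matrix(m), 0.8)
        assert list(blocks) == [0, 0, 1, 1]

    def test_all_linked_single_block(self):
        blocks = dk.ld_blocks(self._matrix(np.ones((3, 3))), 0.8)
        assert blocks.nunique() == 1

    def test_threshold_above_everything_splits_all(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        blocks = dk.ld_blocks(self._matrix(m), 0.9)
        assert list(blocks) == [0, 1, 2]

    def test_chain_linkage_merges_transitively(self):
        # 0-1 and 1-2 linked, 0-2 not: single-linkage puts all in one block
        m = np.array([[1, 0.9, 0.1], [0.9, 1, 0.9], [0.1, 0.9, 1]])
        blocks = dk.ld_blocks(self._matrix(m), 0.8)
        assert blocks.nunique() == 1


class TestEmHaplotypeFreq:
    def test_double_homozygotes_equal_direct_counts(self):
        # no phase ambiguity: EM = gamete counting in one pass
        dos = np.array([[2, 2]] * 3 + [[0, 0]] * 5 + [[2, 0]] * 2)
        t = dk.em_haplotype_freq(dos)
        assert np.allclose(t.freqs, [6 / 20, 4 / 20, 0, 10 / 20])
        assert t.iterations <= 2

    def test_monomorphic_second_locus_degenerates_to_allele_freq(self):
        dos = np.array([[2, 2], [1, 2], [0, 2], [1, 2]])
        t = dk.em_haplotype_freq(dos)
        # locus 2 fixed for allele B -> f(AB) = p_A, f(aB) = 1 - p_A
        assert t.freqs[0] == pytest.approx(4 / 8)
        assert t.freqs[2] == pytest.approx(4 / 8)
        assert t.freqs[1] == pytest.approx(0.0) and t.freqs[3] == pytest.approx(0.0)

    def test_recovers_realized_phased_truth(self):
        truth = [0.615, 0.02, 0.015, 0.35]
        hap, dos = dk.simulate_two_locus_population(truth, 100, seed=34)
        realized = np.array(
            [np.mean((hap[:, 0] == a) & (hap[:, 1] == b)) for a, b in
             [(1, 1), (1, 0), (0, 1), (0, 0)]]
        )
        t = dk.em_haplotype_freq(dos)
        assert np.abs(t.freqs - realized).max() < 0.03

    def test_converges_to_population_truth_at_large_n(self):
        truth = np.array([0.615, 0.02, 0.015, 0.35])
        _, dos = dk.simulate_two_locus_population(truth, 2000, seed=35)
        t = dk.em_haplotype_freq(dos)
        assert np.abs(t.freqs - truth).max() < 0.02

    def test_loglik_non_decreasing(self):
        rng = np.random.default_rng(36)
        for _ in range(50):
            dos = rng.integers(0, 3, size=(rng.integers(5, 60), 2))
            t = dk.em_haplotype_freq(dos)
            assert np.all(np.diff(t.loglik_history) >= -1e-9)

    def test_missing_rows_dropped_complete_case(self):
        dos = np.array([[2, 2], [np.nan, 1], [0, 0], [1, np.nan]])
        t = dk.em_haplotype_freq(dos)
        assert t.n_samples == 2
        assert np.allclose(t.freqs, [0.5, 0, 0, 0.5])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="complete-case"):
            dk.em_haplotype_freq(np.full((3, 2), np.nan))

    def test_counts_mirror_frequency_times_2n(self):
        dos = np.array([[2, 2]] * 3 + [[0, 0]] * 7)
        t = dk.em_haplotype_freq(dos)
        assert list(t.counts) == [6, 0, 0, 14]


class TestCrossLocusLd:
    def test_perfect_association_r2_one(self):
        g1 = ["alpha/alpha"] * 3 + ["beta/beta"] * 3
        g2 = ["4qB/4qB"] * 3 + ["4qA/4qA"] * 3
        r2, table = dk.cross_locus_ld(g1, g2, focal1="alpha", focal2="4qB")
        assert r2 == pytest.approx(1.0)
        assert table.labels[0] == "alpha-4qB"
        assert table.counts[0] == 6

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(37)
        hap1 = rng.integers(0, 2, size=1000)
        hap2 = rng.integers(0, 2, size=1000)
        d1 = hap1[:500] + hap1[500:]
        d2 = hap2[:500] + hap2[500:]
        r2, _ = dk.cross_locus_ld(d1, d2)
        assert r2 < 0.05

    def test_r2_from_freqs_bounds(self):
        rng = np.random.default_rng(38)
        for _ in range(50):
            f = rng.dirichlet(np.ones(4))
            r2 = r2_from_freqs(f)
            assert 0.0 <= r2 <= 1.0 + 1e-12

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="sample counts"):
            dk.cross_locus_ld([0, 1], [0, 1, 2])
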