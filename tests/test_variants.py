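"""Variant triage cascade, codon annotation and haplotype tests."""

import itertools

import pytest
from Bio.Seq import Seq

from siderosig.variants import (
    CascadeReport,
    ContingencyTable2x2,
    ReferenceMismatchError,
    SNPCatalog,
    TranscriptModel,
    VariantRecord,
    annotate_amino_acid_change,
    call_haplotypes,
    classify_coding,
    compare_carrier_frequencies,
    filter_known_snps,
    run_cascade,
)

SITE_DEFS = (("T", "C"), ("C", "T"))


def V(pos, ref, alt, chrom="chrT", sample="S1", vid=None):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         sample=sample, id=vid)


class TestVariantRecord:
    def test_indels_rejected(self):
        with pytest.raises(ValueError, match="single-nucleotide"):
            VariantRecord(chrom="c", pos=5, ref="AT", alt="A", sample="s")

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError, match="ref == alt"):
            VariantRecord(chrom="c", pos=5, ref="A", alt="A", sample="s")


class TestKnownSnpFilter:
    def test_split_arithmetic(self):
        variants = [V(100 + i, "A", "G") for i in range(10)]
        catalog = SNPCatalog(keys={("chrT", 100 + i, "G") for i in range(4)})
        kept, discarded = filter_known_snps(variants, catalog)
        assert (len(kept), len(discarded)) == (6, 4)
        assert set(kept) | set(discarded) == set(variants)
        assert not set(kept) & set(discarded)

    def test_empty_catalog_keeps_everything(self):
        variants = [V(100, "A", "G"), V(200, "C", "T")]
        kept, discarded = filter_known_snps(variants, SNPCatalog())
        assert kept == variants and discarded == []

    def test_id_match_suffices(self):
        v = V(100, "A", "G", vid="rs123")
        kept, discarded = filter_known_snps([v], SNPCatalog(ids={"rs123"}))
        assert discarded == [v]


class TestClassifyCoding:
    def test_boundaries_inclusive(self, toy_model):
        assert classify_coding(V(101, "A", "G"), [toy_model]) == "coding"
        assert classify_coding(V(112, "A", "G"), [toy_model]) == "coding"
        assert classify_coding(V(113, "A", "G"), [toy_model]) == "non_coding"
        assert classify_coding(V(100, "A", "G"), [toy_model]) == "non_coding"

    def test_unknown_chromosome_is_non_coding(self, toy_model):
        assert classify_coding(V(105, "A", "G", chrom="chrX"),
                               [toy_model]) == "non_coding"

    def test_spliced_model_intron_is_non_coding(self):
        m = TranscriptModel(gene="SPL", chrom="c", strand="+",
                            cds_intervals=[(10, 15), (100, 105)],
                            cds_sequence="ATGGTTCGTTAA")
        assert classify_coding(V(50, "A", "G", chrom="c"), [m]) == "non_coding"
        assert classify_coding(V(100, "C", "T", chrom="c"), [m]) == "coding"


class TestAminoAcidAnnotation:
    def test_valine_to_alanine(self, toy_model):
        # codon 2 GTT, second base T>C -> GCT: V -> A missense
        ann = annotate_amino_acid_change(V(105, "T", "C"), toy_model)
        assert (ann.codon_index, ann.ref_aa, ann.alt_aa) == (2, "V", "A")
        assert ann.consequence == "missense"

    def test_arginine_to_cysteine(self, toy_model):
        # codon 3 CGT, first base C>T -> TGT: R -> C missense
        ann = annotate_amino_acid_change(V(107, "C", "T"), toy_model)
        assert (ann.codon_index, ann.ref_aa, ann.alt_aa) == (3, "R", "C")
        assert ann.consequence == "missense"

    def test_wobble_synonymous(self, toy_model):
        # GTT -> GTC, still valine
        ann = annotate_amino_acid_change(V(106, "T", "C"), toy_model)
        assert ann.consequence == "synonymous"
        assert ann.ref_aa == ann.alt_aa == "V"

    def test_start_loss_and_nonsense(self, toy_model):
        ann = annotate_amino_acid_change(V(102, "T", "C"), toy_model)  # ATG->ACG
        assert ann.consequence == "start_loss"
        # CGT -> CGA? no: make codon 3 C>A? CGT first base -> AGT is Ser.
        # nonsense: codon 2 GTT: G>T -> TTT is Phe (missense); use codon 3
        # CGT: second base G>A? CAT is His. Build stop via codon 3 C->T? TGT.
        # TGA stop needs TGT third base T>A -> codon 3 TGA if first base were T;
        # instead mutate codon 3 CGT entirely impossible in one hit, so test
        # a dedicated model whose codon 2 is TAC (Tyr): T A C -> TAA by C>A.
        m = TranscriptModel(gene="STP", chrom="c", strand="+",
                            cds_intervals=[(1, 9)], cds_sequence="ATGTACTAA")
        ann = annotate_amino_acid_change(V(6, "C", "A", chrom="c"), m)
        assert ann.consequence == "nonsense"
        assert ann.alt_aa == "*"

    def test_reference_mismatch_reported(self, toy_model):
        with pytest.raises(ReferenceMismatchError, match="105"):
            annotate_amino_acid_change(V(105, "G", "C"), toy_model)

    def test_minus_strand_mirrors_plus_strand(self, toy_model, toy_model_minus):
        # genomic sequence of the minus model is revcomp(CDS); the base at
        # genomic position 201+k is complement(cds[L-1-k]).
        L = len(toy_model_minus.cds_sequence)
        genomic = str(Seq(toy_model_minus.cds_sequence).reverse_complement())
        for plus_off, alt in [(4, "C"), (6, "T"), (5, "C")]:
            # mirror of the three plus-strand cases above
            plus_ann = annotate_amino_acid_change(
                V(101 + plus_off, toy_model.cds_sequence[plus_off], alt),
                toy_model,
            )
            gpos = 201 + (L - 1 - plus_off)
            gref = genomic[L - 1 - plus_off]
            galt = str(Seq(alt).complement())
            minus_ann = annotate_amino_acid_change(
                V(gpos, gref, galt, chrom="chrM"), toy_model_minus
            )
            assert minus_ann == plus_ann

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_single_base_mutations_match_translation_oracle(
        self, strand
    ):
        cds = "ATGGTTCGT" + "TGCTATCAA" "TAA"  # several codon types
        cds = cds[: (len(cds) // 3) * 3]
        if strand == "+":
            model = TranscriptModel(gene="X", chrom="c", strand="+",
                                    cds_intervals=[(1, len(cds))],
                                    cds_sequence=cds)
        else:
            model = TranscriptModel(gene="X", chrom="c", strand="-",
                                    cds_intervals=[(1, len(cds))],
                                    cds_sequence=cds)
        genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
        prot = str(Seq(cds).translate())
        for gpos0, alt in itertools.product(range(len(cds)), "ACGT"):
            gref = genomic[gpos0]
            if alt == gref:
                continue
            ann = annotate_amino_acid_change(
                V(gpos0 + 1, gref, alt, chrom="c"), model
            )
            # oracle: rebuild the whole CDS with the substitution and translate
            if strand == "+":
                off = gpos0
                cds_alt = alt
            else:
                off = len(cds) - 1 - gpos0
                cds_alt = str(Seq(alt).complement())
            mutated = cds[:off] + cds_alt + cds[off + 1:]
            prot_mut = str(Seq(mutated).translate())
            ci = ann.codon_index - 1
            assert ann.ref_aa == prot[ci]
            assert ann.alt_aa == prot_mut[ci]
            if prot == prot_mut:
                assert ann.consequence == "synonymous"
            elif prot_mut[ci] == "*":
                assert ann.consequence == "nonsense"
            elif ci == 0:
                assert ann.consequence == "start_loss"
            else:
                assert ann.consequence == "missense"


class TestCascade:
    def _fixture(self, toy_model):
        """20 variants: 5 known; 8 of the rest non-coding; 4 of the coding
        rest synonymous; 3 survivors."""
        variants = []
        catalog_keys = set()
        # 5 known SNPs (non-coding positions; stage 1 removes them first)
        for i in range(5):
            v = V(500 + i, "A", "G")
            variants.append(v)
            catalog_keys.add(v.key)
        # 8 novel non-coding
        variants += [V(600 + i, "C", "T") for i in range(8)]
        # 4 coding synonymous: GTT->GTC (pos 106), CGT->CGC (pos 109 3rd base
        # of codon 3? codon3 = 107-109 CGT; 109 T>C -> CGC Arg), and two on
        # the stop codon TAA (110-112): TAA->TGA (111 A>G), TAA->TAG (112 A>G)
        variants += [V(106, "T", "C"), V(109, "T", "C"),
                     V(111, "A", "G"), V(112, "A", "G")]
        # 3 amino-acid changing: V97A-like, R174C-like, start loss
        variants += [V(105, "T", "C"), V(107, "C", "T"), V(102, "T", "C")]
        assert len(variants) == 20
        return variants, SNPCatalog(keys=catalog_keys)

    def test_hand_built_fixture_report(self, toy_model):
        variants, catalog = self._fixture(toy_model)
        survivors, report = run_cascade(variants, catalog, [toy_model])
        assert (report.n_input, report.n_after_snp_filter,
                report.n_after_coding_filter,
                report.n_after_nonsyn_filter) == (20, 15, 7, 3)
        assert len(survivors) == 3
        assert all(
            annotate_amino_acid_change(v, toy_model).consequence
            in ("missense", "nonsense", "start_loss")
            for v in survivors
        )

    def test_conservation_at_every_stage(self, toy_model):
        variants, catalog = self._fixture(toy_model)
        _, report = run_cascade(variants, catalog, [toy_model])
        disc = report.discarded
        assert report.n_input - disc["known_snp"] == report.n_after_snp_filter
        assert report.n_after_snp_filter - disc["non_coding"] \
            == report.n_after_coding_filter
        assert report.n_after_coding_filter - disc["synonymous"] \
            == report.n_after_nonsyn_filter

    def test_all_known_short_circuits(self, toy_model):
        variants = [V(500 + i, "A", "G") for i in range(4)]
        catalog = SNPCatalog(keys={v.key for v in variants})
        survivors, report = run_cascade(variants, catalog, [toy_model])
        assert survivors == []
        assert (report.n_after_snp_filter, report.n_after_nonsyn_filter) == (0, 0)

    def test_report_rejects_increasing_counts(self):
        with pytest.raises(ValueError, match="monotone"):
            CascadeReport(10, 12, 5, 3)


class TestHaplotypes:
    def test_paper_haplotype_classes(self):
        calls = call_haplotypes(
            {
                "variant_sample": ("TC", "CT"),   # variant allele at both
                "common_sample": ("TT", "CC"),    # at neither
                "discordant": ("TC", "CC"),       # at one only
            },
            SITE_DEFS,
        )
        by = {c.sample: c.haplotype_class for c in calls}
        assert by == {"variant_sample": "variant",
                      "common_sample": "common",
                      "discordant": "other"}

    def test_missing_genotype_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            calls = call_haplotypes(
                {"ok": ("TC", "CT"), "missing": (None, "CT")}, SITE_DEFS
            )
        assert len(calls) == 1

    def test_classes_partition_samples(self):
        genotypes = {f"s{i}": ("TC" if i % 3 else "TT",
                               "CT" if i % 2 else "CC") for i in range(30)}
        genotypes["gone"] = (None, None)
        with pytest.warns(UserWarning):
            calls = call_haplotypes(genotypes, SITE_DEFS)
        classes = [c.haplotype_class for c in calls]
        assert len(calls) + 1 == len(genotypes)
        assert set(classes) <= {"common", "variant", "other"}

    def test_carrier_comparison_published_counts(self):
        cases = [call for i in range(100)
                 for call in [("TC", "CT") if i < 12 else ("TT", "CC")]]
        controls = [("TC", "CT") if i < 5 else ("TT", "CC") for i in range(100)]
        case_calls = call_haplotypes(
            {f"c{i}": g for i, g in enumerate(cases)}, SITE_DEFS)
        ctrl_calls = call_haplotypes(
            {f"k{i}": g for i, g in enumerate(controls)}, SITE_DEFS)
        table, or_, chi_p, fisher_p = compare_carrier_frequencies(
            case_calls, ctrl_calls)
        assert (table.a, table.b, table.c, table.d) == (12, 88, 5, 95)
        assert chi_p == pytest.approx(0.0759, abs=0.0005)
        assert 0.06 <= fisher_p <= 0.08
        assert or_ == pytest.approx(12 * 95 / (88 * 5), rel=1e-12)

    def test_equal_proportions_give_zero_chi_square(self):
        from siderosig.setstats import chi_square_2x2

        stat, _ = chi_square_2x2(ContingencyTable2x2(5, 45, 5, 45))
        assert stat == pytest.approx(0.0)
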