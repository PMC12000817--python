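"""Gene-table arithmetic, composition, CDS extraction and translation."""

import pytest

from mitovulture.genome_profile import (
    STANDARD_CODE,
    VERTEBRATE_MITO,
    composition,
    extract_cds,
    genome_length_of,
    get_code,
    normalize_feature,
    pcg_span_stats,
    profile_genome,
    round_half_up,
    translate,
    validate_feature_table,
)
from mitovulture.io_formats import Feature, FeatureTable, GenomeRecord


class TestNormalizeFeature:
    @pytest.mark.parametrize(
        "a,b,expected_span",
        [(4076, 2934, 1143), (5903, 4089, 1815), (7, 7, 1)],
    )
    def test_high_low_coordinates_normalize(self, a, b, expected_span):
        f = normalize_feature(a, b, "-", "CDS", name="X")
        assert f.start == min(a, b) and f.end == max(a, b)
        assert f.length == expected_span

    def test_coordinate_below_one_rejected(self):
        with pytest.raises(ValueError):
            normalize_feature(0, 10, "+", "CDS", name="X")


class TestValidation:
    def test_packaged_table_single_documented_length_mismatch(self, vulture_table):
        # The published table itself prints ND3 with declared length 354 over
        # a 351 bp span; every other row is internally consistent.
        mismatches = [
            f for f in validate_feature_table(vulture_table) if f.kind == "length_mismatch"
        ]
        assert [m.feature for m in mismatches] == ["ND3"]

    def test_cox3_flagged_as_incomplete_codon_multiple(self, vulture_table):
        flagged = [
            f.feature
            for f in validate_feature_table(vulture_table)
            if f.kind == "cds_not_codon_multiple"
        ]
        assert flagged == ["COX3"]  # 784 bp, truncated stop

    def test_declared_length_mismatch_reported_not_raised(self):
        t = FeatureTable(
            [Feature("X", "CDS", 1, 99, "+", declared_length=100)]
        )
        findings = validate_feature_table(t)
        assert any(f.kind == "length_mismatch" for f in findings)

    def test_known_gene_overlaps_reported(self, vulture_table):
        overlaps = {
            (f.feature, f.message.split()[1])
            for f in validate_feature_table(vulture_table)
            if f.kind == "overlap"
        }
        assert ("ATP6", "ATP8") in overlaps
        assert ("ND4", "ND4L") in overlaps


class TestGenomeLength:
    def test_packaged_table_without_sequence(self, vulture_table):
        assert genome_length_of(vulture_table) == 17750

    def test_sequence_wins_over_feature_extent(self):
        t = FeatureTable([Feature("X", "CDS", 1, 60, "+")])
        g = GenomeRecord("g", "A" * 100)
        assert genome_length_of(t, g) == 100

    def test_single_feature(self):
        t = FeatureTable([Feature("X", "tRNA", 1, 10, "+")])
        assert genome_length_of(t) == 10


class TestComposition:
    @pytest.mark.parametrize(
        "seq,at,gc", [("ATAT", 100.0, 0.0), ("ACGT", 50.0, 50.0), ("GGCC", 0.0, 100.0)]
    )
    def test_simple_sequences(self, seq, at, gc):
        assert composition(GenomeRecord("x", seq)) == (at, gc)

    def test_n_excluded_from_denominator(self):
        assert composition(GenomeRecord("x", "ATNN")) == (100.0, 0.0)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            composition(GenomeRecord("x", "NNNN"))

    def test_strand_invariance(self):
        seq = "ATGCCGTAAATTTGCA"
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert composition(GenomeRecord("f", seq)) == composition(GenomeRecord("r", comp))

    def test_rounding_is_half_up(self):
        assert round_half_up(0.15, 1) == 0.2
        assert round_half_up(54.05, 1) == 54.1


class TestPcgSpan:
    def test_packaged_table_reproduces_printed_span(self, vulture_table):
        assert pcg_span_stats(vulture_table, 17750) == (11407, 64.26)

    def test_single_cds_half_genome(self):
        t = FeatureTable([Feature("X", "CDS", 1, 300, "+")])
        assert pcg_span_stats(t, 600) == (300, 50.00)

    def test_two_cds_plain_sum(self):
        t = FeatureTable(
            [Feature("A", "CDS", 1, 150, "+"), Feature("B", "CDS", 200, 349, "+")]
        )
        assert pcg_span_stats(t, 600) == (300, 50.00)

    def test_no_cds_rejected(self):
        t = FeatureTable([Feature("X", "tRNA", 1, 70, "+")])
        with pytest.raises(ValueError):
            pcg_span_stats(t, 100)


class TestExtractCds:
    def test_plus_strand_boundary_codons(self):
        g = GenomeRecord("g", "ATGAAATAA")
        f = Feature("X", "CDS", 1, 9, "+")
        ext = extract_cds(g, f)
        assert ext.observed_start_codon == "ATG"
        assert ext.observed_stop_codon == "TAA" and ext.stop_complete

    def test_minus_strand_reverse_complement(self):
        # reverse complement of GTGAAAAGG written on the minus strand
        cds = "GTGAAAAGG"
        genomic = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        g = GenomeRecord("g", "CC" + genomic + "TT")
        f = Feature("X", "CDS", 3, 11, "-")
        ext = extract_cds(g, f)
        assert ext.sequence == cds
        assert ext.observed_start_codon == "GTG"

    def test_incomplete_stop_flagged(self):
        g = GenomeRecord("g", "ATGAAAT")
        ext = extract_cds(g, Feature("X", "CDS", 1, 7, "+"))
        assert not ext.stop_complete
        assert ext.observed_stop_codon == "T"

    def test_out_of_bounds_rejected(self):
        g = GenomeRecord("g", "ATGAAA")
        with pytest.raises(ValueError):
            extract_cds(g, Feature("X", "CDS", 4, 9, "+"))


class TestTranslate:
    def test_vertebrate_mito_specifics(self):
        # TGA = Trp, AGA = stop under the vertebrate mitochondrial code
        t = translate("ATGTGAAGA", VERTEBRATE_MITO)
        assert t.protein == "MW"
        assert t.terminal_stop == "AGA"
        assert t.internal_stop_positions == ()

    def test_ata_is_methionine(self):
        assert translate("ATAAAA", VERTEBRATE_MITO).protein.startswith("M")

    def test_standard_code_differs_on_aga(self):
        assert translate("AGAAAA", STANDARD_CODE).protein.startswith("R")

    def test_internal_stop_is_finding_not_error(self):
        t = translate("ATGTAAAAATAA", VERTEBRATE_MITO)
        assert t.internal_stop_positions == (2,)
        assert t.protein == "M*K"

    def test_trailing_partial_codon_flagged(self):
        t = translate("ATGAAAT", VERTEBRATE_MITO)
        assert t.incomplete_tail and t.protein == "MK"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")


class TestGeneticCodes:
    def test_vertebrate_mito_code_contract(self):
        code = get_code("vertebrate_mito")
        assert len(code.codon_map) == 64
        assert code.stop_codons == frozenset({"TAA", "TAG", "AGA", "AGG"})
        assert {"ATG", "GTG"} <= code.start_codons
        assert code.amino_acid("TGA") == "W" and code.amino_acid("ATA") == "M"

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            get_code("martian")


class TestProfile:
    def test_profile_of_packaged_table_without_sequence(self, vulture_table):
        prof = profile_genome(vulture_table)
        assert prof.genome_length == 17750
        assert prof.pcg_total_bp == 11407 and prof.pcg_fraction == 64.26
        assert prof.at_fraction is None
        assert len(prof.per_feature) == 39
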