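"""Group-conserved substitution detection, chemical classing and summaries."""

import random

import pytest

from mitovulture.io_formats import AlignmentBlock, GroupPartition
from mitovulture.substitution_sites import (
    DEFAULT_SCHEME,
    STANDARD_RESIDUES,
    classify_residue,
    effective_class,
    find_group_conserved_sites,
    focal_vs_group_sites,
    sites_from_frame,
    summarize_sites,
)


def brute_force_sites(block, partition, group_a, group_b):
    """Independent per-column oracle (set of (column, res_a, res_b))."""
    rows_a = [block.rows[t] for t in block.taxa if partition.assignment.get(t) == group_a]
    rows_b = [block.rows[t] for t in block.taxa if partition.assignment.get(t) == group_b]
    out = set()
    for col in range(block.n_columns):
        col_a = {r[col] for r in rows_a}
        col_b = {r[col] for r in rows_b}
        if len(col_a) != 1 or len(col_b) != 1:
            continue
        (a,), (b,) = col_a, col_b
        if a == b or a not in STANDARD_RESIDUES or b not in STANDARD_RESIDUES:
            continue
        out.add((col, a, b))
    return out


def random_alignment(seed, n_a=4, n_b=5, length=80, alphabet="ANTSPCG-"):
    rng = random.Random(seed)
    taxa = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    rows = {t: "".join(rng.choice(alphabet) for _ in range(length)) for t in taxa}
    part = GroupPartition({t: ("GA" if t.startswith("A") else "GB") for t in taxa})
    return AlignmentBlock(gene="g", rows=rows), part


class TestClassification:
    @pytest.mark.parametrize(
        "residue,label",
        [
            ("H", "Positive"),
            ("Y", "Hydrophobic"),
            ("Q", "Polar uncharged"),
            ("E", "Negative"),
            ("P", "Special case"),
            ("C", "Special case"),
            ("G", "Special case"),
        ],
    )
    def test_default_scheme_labels(self, residue, label):
        assert classify_residue(residue) == label

    def test_all_twenty_residues_mapped(self):
        assert set(DEFAULT_SCHEME.mapping) == set(STANDARD_RESIDUES)

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            classify_residue("B")

    def test_special_residues_are_singleton_effective_classes(self):
        # a Cys-to-Gly swap is cross-class even though both print "Special case"
        assert effective_class("C") != effective_class("G")
        assert effective_class("A") == effective_class("V")


class TestReferenceSiteLists:
    def test_owv_nwv_list_reproduces_all_printed_labels(self, owv_nwv_sites):
        for row in owv_nwv_sites.itertuples():
            assert classify_residue(row.residue_owv) == row.class_owv
            assert classify_residue(row.residue_nwv) == row.class_nwv

    def test_owv_nwv_counts_and_special_tallies(self, owv_nwv_sites):
        sites = sites_from_frame(owv_nwv_sites)
        summary = summarize_sites(sites)
        assert summary.total == 67
        assert summary.max_genes == frozenset({"ND1"})
        assert summary.per_gene["ND1"] == 11
        assert summary.special_residue_tallies["P"] == 7
        assert summary.special_residue_tallies["C"] == 5

    def test_focal_list_reproduces_labels_except_documented_one(self, calvus_sites):
        mismatches = []
        for row in calvus_sites.itertuples():
            if classify_residue(row.residue_group) != row.class_group:
                mismatches.append((row.gene, row.position, "group"))
            if classify_residue(row.residue_focal) != row.class_focal:
                mismatches.append((row.gene, row.position, "focal"))
        # the source prints Thr at ND3 108 as hydrophobic; Thr is polar uncharged
        assert mismatches == [("ND3", 108, "group")]

    def test_focal_list_shape(self, calvus_sites):
        assert len(calvus_sites) == 43
        per_gene = calvus_sites.groupby("gene").size()
        assert per_gene.idxmax() == "CYTB" and per_gene.max() == 9


class TestDetector:
    def test_fully_conserved_differing_column_is_a_site(self):
        rows = {f"A{i}": "A" for i in range(5)} | {f"B{i}": "N" for i in range(6)}
        block = AlignmentBlock(gene="ATP8", rows={t: r for t, r in rows.items()})
        part = GroupPartition({t: ("GA" if t.startswith("A") else "GB") for t in rows})
        (site,) = find_group_conserved_sites(block, part, "GA", "GB")
        assert (site.residue_a, site.residue_b) == ("A", "N")
        assert (site.class_a, site.class_b) == ("Hydrophobic", "Polar uncharged")
        assert site.cross_class and not site.special_involved

    def test_within_group_polymorphism_disqualifies(self):
        block = AlignmentBlock(
            gene="g",
            rows={"A1": "A", "A2": "V", "B1": "N", "B2": "N"},
        )
        part = GroupPartition({"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"})
        assert find_group_conserved_sites(block, part, "GA", "GB") == []

    def test_gap_in_qualifying_row_disqualifies(self):
        block = AlignmentBlock(
            gene="g", rows={"A1": "A-", "A2": "AA", "B1": "NN", "B2": "NN"}
        )
        part = GroupPartition({"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"})
        sites = find_group_conserved_sites(block, part, "GA", "GB")
        assert [s.position for s in sites] == [1]

    def test_positions_in_ungapped_reference_numbering(self):
        block = AlignmentBlock(
            gene="g",
            rows={"A1": "-MAK", "A2": "-MAK", "B1": "-MSK", "B2": "AMSK"},
        )
        part = GroupPartition({"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"})
        (site,) = find_group_conserved_sites(block, part, "GA", "GB")
        # column 3 of the alignment is ungapped position 2 of the first GA row
        assert site.position == 2

    def test_empty_group_rejected(self):
        block = AlignmentBlock(gene="g", rows={"A1": "A", "B1": "N"})
        part = GroupPartition({"A1": "GA", "B1": "GB"})
        with pytest.raises((ValueError, KeyError)):
            find_group_conserved_sites(block, part, "GA", "GC")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_column_oracle_on_random_alignments(self, seed):
        block, part = random_alignment(seed)
        got = {
            (s.residue_a, s.residue_b)
            for s in find_group_conserved_sites(block, part, "GA", "GB")
        }
        expected = {(a, b) for _, a, b in brute_force_sites(block, part, "GA", "GB")}
        assert got == expected
        assert len(find_group_conserved_sites(block, part, "GA", "GB")) == len(
            brute_force_sites(block, part, "GA", "GB")
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_group_swap_symmetry(self, seed):
        block, part = random_alignment(50 + seed)
        fwd = find_group_conserved_sites(block, part, "GA", "GB")
        rev = find_group_conserved_sites(block, part, "GB", "GA")
        assert {(s.position, s.residue_a, s.residue_b, s.cross_class) for s in fwd} == {
            (s.position, s.residue_b, s.residue_a, s.cross_class) for s in rev
        }


class TestFocal:
    def test_focal_private_residue_with_unique_class(self):
        rows = {"F": "P", "A2": "S", "A3": "S", "B1": "S"}
        block = AlignmentBlock(gene="ATP8", rows=rows)
        part = GroupPartition(
            {"F": "GA", "A2": "GA", "A3": "GA", "B1": "GB"}, focal="F"
        )
        (site,) = focal_vs_group_sites(block, part, "GA")
        assert (site.residue_a, site.residue_b) == ("S", "P")
        assert site.unique_class is True

    def test_focal_identical_to_group_is_no_site(self):
        block = AlignmentBlock(gene="g", rows={"F": "SS", "A2": "SS", "A3": "SS"})
        part = GroupPartition({"F": "GA", "A2": "GA", "A3": "GA"}, focal="F")
        assert focal_vs_group_sites(block, part, "GA") == []

    def test_polymorphic_rest_group_is_no_site(self):
        block = AlignmentBlock(gene="g", rows={"F": "P", "A2": "S", "A3": "T"})
        part = GroupPartition({"F": "GA", "A2": "GA", "A3": "GA"}, focal="F")
        assert focal_vs_group_sites(block, part, "GA") == []

    def test_missing_focal_rejected(self):
        block = AlignmentBlock(gene="g", rows={"A2": "S", "A3": "S"})
        part = GroupPartition({"A2": "GA", "A3": "GA"})
        with pytest.raises(ValueError):
            focal_vs_group_sites(block, part, "GA")


class TestSummary:
    def test_empty_input_all_zero(self):
        s = summarize_sites([])
        assert s.total == 0 and s.cross_class_total == 0
        assert s.max_genes == frozenset()
        assert s.special_residue_tallies == {"C": 0, "G": 0, "P": 0}

    def test_special_residue_counted_once_per_site_per_residue(self, owv_nwv_sites):
        # the C->G site contributes once to the Cys tally and once to Gly
        sites = sites_from_frame(owv_nwv_sites)
        cg = [s for s in sites if {s.residue_a, s.residue_b} == {"C", "G"}]
        assert len(cg) == 1
        summary = summarize_sites(cg)
        assert summary.special_residue_tallies == {"C": 1, "G": 1, "P": 0}
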