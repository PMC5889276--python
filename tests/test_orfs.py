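import pytest

from phagekit import GenomeRecord, find_orfs, packing_profile, translate_cds
from phagekit.orfs import (
    CdsError,
    CdsFeature,
    coordinate_inconsistencies,
    load_reference_cds_table,
)

from oracles import orf_oracle


class TestTranslateCds:
    def test_canonical(self):
        g = GenomeRecord("g", "ATGGCTTAA")
        assert translate_cds(g, 1, 9, "+") == "MA"

    def test_gtg_initiator_is_met(self):
        g = GenomeRecord("g", "GTGGCTTAA")
        assert translate_cds(g, 1, 9, "+") == "MA"

    def test_ttg_initiator_is_met(self):
        g = GenomeRecord("g", "TTGGCTTAA")
        assert translate_cds(g, 1, 9, "+") == "MA"

    def test_reverse_strand(self):
        g = GenomeRecord("g", "TTAAGCCAT")  # rc = ATGGCTTAA
        assert translate_cds(g, 1, 9, "-") == "MA"

    def test_internal_stop_reports_codon_index(self):
        g = GenomeRecord("g", "ATGTAAGCTTAA")
        with pytest.raises(CdsError, match="codon index 1"):
            translate_cds(g, 1, 12, "+")

    def test_non_stop_final_codon(self):
        g = GenomeRecord("g", "ATGGCTGCT")
        with pytest.raises(CdsError, match="not a stop"):
            translate_cds(g, 1, 9, "+")

    def test_length_not_codon_multiple(self):
        g = GenomeRecord("g", "ATGGCTTAAC")
        with pytest.raises(CdsError, match="divisible"):
            translate_cds(g, 1, 10, "+")


class TestFindOrfs:
    def test_hand_enumerated_example(self):
        g = GenomeRecord("g", "AAATGGCTGCTTAATT")
        (orf,) = find_orfs(g, min_mass_kda=0)
        assert (orf.start, orf.end, orf.strand) == (3, 14, "+")
        assert orf.protein == "MAA"
        assert orf.aa_length == 3
        assert orf.nt_length == 12

    def test_all_a_sequence_is_empty(self):
        g = GenomeRecord("g", "A" * 300)
        assert find_orfs(g, min_mass_kda=0) == []

    def test_stop_codon_inside_interval(self):
        g = GenomeRecord("g", "AAATGGCTGCTTAATT")
        (orf,) = find_orfs(g, min_mass_kda=0)
        assert g.slice(orf.end - 2, orf.end) == "TAA"
        assert orf.aa_length == orf.nt_length // 3 - 1

    def test_mass_filter_monotone(self, make_genome):
        g = make_genome(seed=9, length=1500)
        thresholds = [0.0, 1.0, 2.0, 4.0]
        results = [
            {(f.start, f.end, f.strand) for f in find_orfs(g, min_mass_kda=t)}
            for t in thresholds
        ]
        for loose, tight in zip(results, results[1:]):
            assert tight <= loose

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_sequences(self, seed, make_genome):
        g = make_genome(seed=seed, length=1200)
        called = {(f.start, f.end, f.strand) for f in find_orfs(g, min_mass_kda=1.0)}
        expected = set(orf_oracle(g.seq, min_mass_kda=1.0))
        assert called == expected

    def test_forward_only(self, make_genome):
        g = make_genome(seed=3, length=1000)
        fwd = find_orfs(g, min_mass_kda=0.5, strands="forward")
        assert all(f.strand == "+" for f in fwd)
        both = find_orfs(g, min_mass_kda=0.5, strands="both")
        assert {(f.start, f.end) for f in fwd} <= {(f.start, f.end) for f in both}

    def test_invariants(self, make_genome):
        g = make_genome(seed=5, length=2000)
        for f in find_orfs(g, min_mass_kda=2.0):
            assert f.aa_length == f.nt_length // 3 - 1
            assert f.product_mass >= 2.0
            assert "*" not in f.protein


class TestPackingProfile:
    def test_overlap_arithmetic(self):
        feats = [CdsFeature("a", 1, 9, "+"), CdsFeature("b", 7, 15, "+")]
        strand_counts, gaps, n_overlaps, max_gap = packing_profile(feats)
        assert gaps[0].gap_nt == -3
        assert n_overlaps == 1
        assert strand_counts == {"+": 2}

    def test_max_gap(self):
        feats = [
            CdsFeature("a", 1, 9, "+"),
            CdsFeature("b", 20, 28, "+"),
            CdsFeature("c", 40, 48, "+"),
        ]
        _, gaps, n_overlaps, max_gap = packing_profile(feats)
        assert [g.gap_nt for g in gaps] == [10, 11]
        assert n_overlaps == 0
        assert (max_gap.upstream_label, max_gap.downstream_label, max_gap.gap_nt) == ("b", "c", 11)

    def test_tie_prefers_smaller_start(self):
        feats = [
            CdsFeature("a", 1, 9, "+"),
            CdsFeature("b", 15, 23, "+"),
            CdsFeature("c", 29, 37, "+"),
        ]
        _, _, _, max_gap = packing_profile(feats)
        assert max_gap.upstream_label == "a"

    def test_requires_features(self):
        with pytest.raises(CdsError):
            packing_profile([])


class TestReferenceTable:
    def test_row_count_and_strands(self):
        rows = load_reference_cds_table()
        assert len(rows) == 81
        assert {f.strand for f in rows} == {"+"}

    def test_aa_rule_on_printed_lengths(self):
        for f in load_reference_cds_table():
            assert f.aa_length == f.nt_length // 3 - 1, f.label

    def test_known_single_coordinate_typo(self):
        # one printed row's length disagrees with its coordinate span by 1 nt
        bad = coordinate_inconsistencies(load_reference_cds_table())
        assert bad == ["TP84_43"]

    def test_largest_coordinate_gap(self):
        _, gaps, n_overlaps, max_gap = packing_profile(load_reference_cds_table())
        assert (max_gap.upstream_label, max_gap.downstream_label) == ("TP84_55", "TP84_56")
        assert max_gap.gap_nt == 365
        assert n_overlaps > 0
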