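import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthlr import (
    AdapterSpec,
    SequenceRecord,
    collapse_hamming,
    extract_barcode,
    filter_groups,
    group_by_barcode,
    merge_read_pair,
    quality_trim,
)
from synthlr.barcodes import (
    REJECT_ANCHOR,
    REJECT_INDEX,
    REJECT_N_IN_BARCODE,
    REJECT_SHORT,
    BarcodeGroup,
    build_groups,
)
from synthlr.io import reverse_complement


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        rec = SequenceRecord("r", "A" * 100, [40] * 100)
        assert quality_trim(rec) is rec

    def test_low_quality_tail_removed(self):
        # hand-scan: the most 3' window of mean >= 20 ends at position 80
        rec = SequenceRecord("r", "A" * 100, [40] * 80 + [2] * 20)
        trimmed = quality_trim(rec)
        assert len(trimmed.sequence) == 80

    def test_hopeless_read_rejected(self):
        rec = SequenceRecord("r", "A" * 100, [2] * 100)
        assert quality_trim(rec) is None

    def test_five_prime_end_untouched(self):
        rec = SequenceRecord("r", "ACGT" * 25, [2] * 10 + [40] * 90)
        trimmed = quality_trim(rec)
        assert trimmed.sequence.startswith("ACGT")
        assert len(trimmed.sequence) == 100

    def test_missing_qualities_is_a_contract_error(self):
        with pytest.raises(ValueError):
            quality_trim(SequenceRecord("r", "ACGT"))


class TestMergeReadPair:
    def test_exact_six_base_overlap(self):
        # r1 suffix "ACGTAC" overlaps rc(r2) prefix; merged length 10+10-6
        r1 = SequenceRecord("p", "ACGTACGTAC", [30] * 10)
        rc2 = "ACGTAC" + "GGTT"
        r2 = SequenceRecord("p", reverse_complement(rc2), [30] * 10)
        merged = merge_read_pair(r1, r2, min_overlap=6)
        assert isinstance(merged, SequenceRecord)
        assert merged.sequence == "ACGTACGTACGGTT"
        assert len(merged.sequence) == 14

    def test_disjoint_pair_returned_unmerged(self):
        r1 = SequenceRecord("p", "AAAACCCCAAAACCCC", [30] * 16)
        r2 = SequenceRecord("p", "AAAACCCCAAAACCCC", [30] * 16)  # rc is all G/T
        out = merge_read_pair(r1, r2, min_overlap=10)
        assert isinstance(out, tuple) and out == (r1, r2)

    def test_full_overlap_reproduces_forward_read(self):
        r1 = SequenceRecord("p", "ACGGTTACGGATCCTAGGAC", [30] * 20)
        r2 = r1.reverse_complement()
        merged = merge_read_pair(r1, r2)
        assert merged.sequence == r1.sequence

    def test_overlap_conflict_resolved_by_higher_quality(self):
        r1 = SequenceRecord("p", "AACCGGTTAACCGGTTCGAT", [10] * 20)
        rc2_seq = "AACCGGTTAACCGGTTCGAA"  # disagrees at the last base
        r2 = SequenceRecord("p", reverse_complement(rc2_seq), [35] * 20)
        merged = merge_read_pair(r1, r2, min_overlap=10)
        assert merged.sequence == rc2_seq  # r2 wins on quality


class TestExtractBarcode:
    SPEC = AdapterSpec(barcode_length=8, anchor="CC")

    def test_simple_extraction(self):
        rec = SequenceRecord("r", "ACGTACGT" + "CC" + "TTTTTTTT")
        out = extract_barcode(rec, self.SPEC)
        assert out.ok
        assert out.barcode == "ACGTACGT"
        assert out.payload.sequence == "TTTTTTTT"

    def test_anchor_beyond_tolerance_rejected(self):
        rec = SequenceRecord("r", "ACGTACGT" + "GG" + "TTTTTTTT")
        out = extract_barcode(rec, self.SPEC)
        assert not out.ok and out.reject_reason == REJECT_ANCHOR

    def test_anchor_single_mismatch_tolerated(self):
        rec = SequenceRecord("r", "ACGTACGT" + "CG" + "TTTTTTTT")
        assert extract_barcode(rec, self.SPEC).ok

    def test_n_in_barcode_rejected(self):
        rec = SequenceRecord("r", "ACGTNCGT" + "CC" + "TTTTTTTT")
        assert extract_barcode(rec, self.SPEC).reject_reason == REJECT_N_IN_BARCODE

    def test_short_read_rejected(self):
        rec = SequenceRecord("r", "ACGTACGTCC")
        assert extract_barcode(rec, self.SPEC).reject_reason == REJECT_SHORT

    def test_index_single_mismatch_assigned_to_unique_best(self):
        spec = AdapterSpec(
            barcode_length=8,
            index_length=6,
            anchor="CC",
            index_table={"AAAAAA": "s1", "TTTTTT": "s2"},
        )
        rec = SequenceRecord("r", "ACGTACGT" + "AAAAAT" + "CC" + "GGGGGGGG")
        out = extract_barcode(rec, spec)
        assert out.ok and out.sample == "s1"

    def test_ambiguous_index_rejected(self):
        spec = AdapterSpec(
            barcode_length=8,
            index_length=6,
            anchor="CC",
            index_table={"AAAAAA": "s1", "AAAATT": "s2"},
        )
        rec = SequenceRecord("r", "ACGTACGT" + "AAAATA" + "CC" + "GGGGGGGG")
        assert extract_barcode(rec, spec).reject_reason == REJECT_INDEX


class TestGrouping:
    def test_partition_property(self):
        items = [
            ("A" * 8, "", [SequenceRecord("r1", "ACGT")]),
            ("A" * 8, "", [SequenceRecord("r2", "ACGT"), SequenceRecord("r2b", "AAAA")]),
            ("C" * 8, "", [SequenceRecord("r3", "ACGT")]),
        ]
        groups = group_by_barcode(items)
        assert {bc: g.read_pair_count for bc, g in groups.items()} == {
            "A" * 8: 2,
            "C" * 8: 1,
        }
        assert sum(g.read_pair_count for g in groups.values()) == len(items)
        assert sum(len(g.reads) for g in groups.values()) == 4

    def test_empty_input(self):
        assert group_by_barcode([]) == {}

    def test_filter_threshold_is_inclusive_at_fifty(self):
        groups = {
            "A": BarcodeGroup("A", read_pair_count=49),
            "B": BarcodeGroup("B", read_pair_count=50),
        }
        kept = filter_groups(groups, 50)
        assert set(kept) == {"B"}
        assert filter_groups(groups, 0) == groups
        assert filter_groups(groups, 1000) == {}


class TestCollapseHamming:
    def test_shorter_neighbor_discarded(self):
        assert collapse_hamming({"AAAA": 3000, "AAAT": 500}) == ["AAAA"]

    def test_distant_barcodes_both_kept(self):
        assert set(collapse_hamming({"AAAA": 3000, "TTTT": 2000})) == {"AAAA", "TTTT"}

    def test_chain_collapses_onto_longest(self):
        # brute-force over the greedy order: AAAT and AATT are both within
        # distance 2 of AAAA, which is processed first
        assert collapse_hamming({"AAAA": 3000, "AAAT": 2000, "AATT": 1000}) == ["AAAA"]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            collapse_hamming({"AAAA": 1, "AAAAA": 2})

    @settings(deadline=None, max_examples=50)
    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            st.integers(min_value=1, max_value=10_000),
            min_size=1,
            max_size=30,
        )
    )
    def test_idempotent_and_pairwise_distant(self, items):
        kept = collapse_hamming(items)
        assert collapse_hamming({bc: items[bc] for bc in kept}) == kept
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) > 2


class TestGroupingOnSimulation:
    def test_zero_error_grouping_has_perfect_recall_and_purity(self, zero_error_library):
        lib = zero_error_library
        from synthlr import PipelineConfig

        spec = PipelineConfig(simulate=lib.config).adapter_spec()
        groups, stats = build_groups(lib.iter_read_pairs(), spec)
        # no quality- or adapter-based rejections; the only losses are reads
        # too short to carry a payload (junctions at the barcoded end)
        assert stats.rejections == {}
        assert stats.accepted == stats.pairs_in - stats.pairs_trimmed_away
        truth_of_bc = {}
        for t in lib.truths:
            truth_of_bc[t.barcode_left] = t.molecule_id
            truth_of_bc[t.barcode_right] = t.molecule_id
        assert set(groups) <= set(truth_of_bc)
        for bc, group in groups.items():
            for read in group.reads:
                assert read.id.split("|")[0] == truth_of_bc[bc]

    def test_largest_group_purity_with_default_errors(self, small_library):
        from synthlr import PipelineConfig

        spec = PipelineConfig(simulate=small_library.config).adapter_spec()
        groups, _ = build_groups(small_library.iter_read_pairs(), spec)
        truth_of_bc = {}
        for t in small_library.truths:
            truth_of_bc[t.barcode_left] = t.molecule_id
            truth_of_bc[t.barcode_right] = t.molecule_id
        largest = max(groups.values(), key=lambda g: g.read_pair_count)
        mol = truth_of_bc[largest.barcode]
        same = sum(1 for r in largest.reads if r.id.split("|")[0] == mol)
        assert same / len(largest.reads) >= 0.947

    def test_collapse_removes_spurious_barcodes_from_simulation(self, small_library):
        from synthlr import PipelineConfig

        spec = PipelineConfig(simulate=small_library.config).adapter_spec()
        groups, _ = build_groups(small_library.iter_read_pairs(), spec)
        truth_bcs = set()
        for t in small_library.truths:
            truth_bcs.update((t.barcode_left, t.barcode_right))
        spurious = set(groups) - truth_bcs
        assert spurious, "expected sequencing errors to create spurious barcodes"
        kept = set(collapse_hamming({bc: g.read_pair_count for bc, g in groups.items()}))
        removed = spurious - kept
        assert len(removed) / len(spurious) >= 0.95
        assert truth_bcs <= kept | (truth_bcs - set(groups))
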