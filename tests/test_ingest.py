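"""Eligibility filters and substitution record extraction."""

import numpy as np
import pytest

from ctxsub.ingest import (
    FilterTally,
    TripletAlignment,
    _eligibility,
    count_table_from_alignments,
    extract_site_records,
    read_triplet_alignments,
    site_eligible,
)
from ctxsub.matrices import accumulate_counts

SEQ = "ACGTACGTACGTACGTACGTACGT"  # 24 columns


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestReadTripletAlignments:
    def test_reads_role_tagged_records(self, tmp_path):
        seq = SEQ * 4  # 96 columns, passes the length filter
        write_fasta(
            tmp_path / "r.fasta",
            [("r1|ingroup1", seq), ("r1|ingroup2", seq), ("r1|outgroup", seq)],
        )
        trips = read_triplet_alignments(tmp_path / "r.fasta")
        assert len(trips) == 1 and trips[0].region_id == "r1"

    def test_missing_role_named_in_error(self, tmp_path):
        write_fasta(tmp_path / "r.fasta", [("r1|ingroup1", SEQ), ("r1|outgroup", SEQ)])
        with pytest.raises(ValueError, match="ingroup2"):
            read_triplet_alignments(tmp_path / "r.fasta")

    def test_untagged_record_rejected(self, tmp_path):
        write_fasta(tmp_path / "r.fasta", [("r1", SEQ)])
        with pytest.raises(ValueError, match="tag"):
            read_triplet_alignments(tmp_path / "r.fasta")

    def test_short_region_skipped_and_tallied(self, tmp_path):
        short = SEQ * 2 + SEQ[:12]  # 60 columns
        good = SEQ * 4
        write_fasta(
            tmp_path / "r.fasta",
            [("s|ingroup1", short), ("s|ingroup2", short), ("s|outgroup", short),
             ("g|ingroup1", good), ("g|ingroup2", good), ("g|outgroup", good)],
        )
        tally = FilterTally()
        trips = read_triplet_alignments(tmp_path / "r.fasta", tally=tally)
        assert [t.region_id for t in trips] == ["g"]
        assert tally.regions_too_short == 1 and tally.regions_read == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            TripletAlignment("x", SEQ, SEQ[:-1], SEQ)


class TestSiteEligible:
    def test_identical_gapfree_interior_column(self, identical_triplet):
        assert site_eligible(identical_triplet, 12, radius=3)

    def test_all_interior_columns_eligible_when_identical(self, identical_triplet):
        L = identical_triplet.length
        for col in range(L):
            expected = 5 <= col <= L - 6
            assert site_eligible(identical_triplet, col, radius=2) == expected

    def test_three_window_gaps_fail_eight_of_ten(self):
        """Gaps in 3 of the 10 surrounding columns leave only 7 base pairs."""
        in2 = list(SEQ)
        for c in (9, 10, 11):
            in2[c] = "-"
        trip = TripletAlignment("x", SEQ, "".join(in2), SEQ)
        assert not site_eligible(trip, 12, radius=1)
        assert site_eligible(trip, 12 + 5, radius=1)  # only 2 gaps in that window

    def test_window_similarity_seventy_percent(self):
        """4 ingroup mismatches among the 10 window columns fail the filter."""
        in2 = list(SEQ)
        for c in (7, 8, 15, 16):  # keep context columns 11-13 intact
            in2[c] = {"A": "C", "C": "A", "G": "T", "T": "G"}[in2[c]]
        trip = TripletAlignment("x", SEQ, "".join(in2), SEQ)
        assert not site_eligible(trip, 12, radius=1)
        in2[16] = SEQ[16]  # back to 3 mismatches: exactly 7 of 10 match
        assert site_eligible(TripletAlignment("x", SEQ, "".join(in2), SEQ), 12, radius=1)

    def test_outgroup_context_mismatch_fails(self):
        """A flanking base differing in the outgroup breaks context conservation."""
        og = list(SEQ)
        og[11] = "A" if og[11] != "A" else "C"
        trip = TripletAlignment("x", SEQ, SEQ, "".join(og))
        assert not site_eligible(trip, 12, radius=1)
        assert not site_eligible(trip, 12, radius=3)
        assert site_eligible(trip, 12 + 6, radius=1)

    def test_column_out_of_range(self, identical_triplet):
        with pytest.raises(IndexError):
            site_eligible(identical_triplet, 99, radius=1)

    def test_ambiguity_code_makes_column_ineligible(self):
        og = SEQ[:12] + "N" + SEQ[13:]
        trip = TripletAlignment("x", SEQ, SEQ, og)
        assert not site_eligible(trip, 12, radius=1)

    def test_gap_monotonicity(self, random_gappy_triplets):
        """Adding a gap to a surrounding column never makes a site eligible."""
        for trip in random_gappy_triplets[:3]:
            base = [site_eligible(trip, c, 2) for c in range(trip.length)]
            mid = trip.length // 2
            in1 = trip.ingroup1[:mid] + "-" + trip.ingroup1[mid + 1 :]
            worse = TripletAlignment(trip.region_id, in1, trip.ingroup2, trip.outgroup)
            for c in range(trip.length):
                if c != mid and site_eligible(worse, c, 2):
                    assert base[c]


class TestExtractRecords:
    def _triplet_with(self, og_base, in1_base, in2_base):
        og = SEQ[:12] + og_base + SEQ[13:]
        in1 = SEQ[:12] + in1_base + SEQ[13:]
        in2 = SEQ[:12] + in2_base + SEQ[13:]
        return TripletAlignment("x", in1, in2, og)

    def test_one_substitution_one_conserved(self):
        trip = self._triplet_with("A", "A", "G")
        recs = [r for r in extract_site_records(trip, 3) if r.column == 12]
        assert [(r.ancestral, r.derived, r.ingroup_index) for r in recs] == [
            ("A", "A", 1),
            ("A", "G", 2),
        ]

    def test_both_ingroups_changed(self):
        trip = self._triplet_with("C", "T", "T")
        recs = [r for r in extract_site_records(trip, 3) if r.column == 12]
        assert [(r.ancestral, r.derived) for r in recs] == [("C", "T"), ("C", "T")]

    def test_double_difference_counts_two_substitutions(self):
        """Outgroup differing from both ingroups yields two records, no consensus."""
        trip = self._triplet_with("A", "C", "G")
        recs = [r for r in extract_site_records(trip, 3) if r.column == 12]
        assert [(r.ancestral, r.derived) for r in recs] == [("A", "C"), ("A", "G")]

    def test_record_count_is_twice_eligible_columns(self, gappy_dataset):
        aligns, _ = gappy_dataset
        trip = aligns[0]
        eligible, *_ = _eligibility(trip, 3)
        recs = list(extract_site_records(trip, 3))
        assert len(recs) == 2 * int(eligible.sum())

    def test_context_taken_from_conserved_flanks(self):
        trip = self._triplet_with("A", "A", "G")
        rec = next(iter(extract_site_records(trip, 3)))
        first_eligible = 5
        assert rec.column == first_eligible
        assert rec.context.left == SEQ[first_eligible - 3 : first_eligible]
        assert rec.context.right == SEQ[first_eligible + 1 : first_eligible + 4]


class TestVectorizedAgainstScalarOracle:
    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_eligibility_mask_matches_scalar(self, random_gappy_triplets, radius):
        for trip in random_gappy_triplets:
            mask, *_ = _eligibility(trip, radius)
            expected = [site_eligible(trip, c, radius) for c in range(trip.length)]
            assert mask.tolist() == expected

    def test_count_table_matches_record_accumulation(self, gappy_dataset):
        aligns, _ = gappy_dataset
        fast = count_table_from_alignments(aligns, 2)
        records = [r for t in aligns for r in extract_site_records(t, 2)]
        slow = accumulate_counts(records, 2)
        assert np.array_equal(fast.counts, slow.counts)
        assert fast.total() == len(records)


def test_filter_tally_accounting_identity(gappy_dataset):
    """Columns scanned = eligible + sum of per-filter exclusions, exactly."""
    aligns, _ = gappy_dataset
    tally = FilterTally()
    count_table_from_alignments(aligns, 3, tally=tally)
    assert tally.columns_scanned == tally.eligible + tally.excluded_total
    assert tally.eligible > 0
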