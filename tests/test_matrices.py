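"""Count matrices, complement combining, transition matrices, rates, folds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ctxsub.contexts import BASES, ContextKey, canonical_index_mask, rc_permutation
from ctxsub.ingest import count_table_from_alignments
from ctxsub.matrices import (
    ContextCountTable,
    RateSummary,
    accumulate_counts,
    fold_variation_table,
    rate_ci,
    rate_summaries,
    rate_summary,
    slice_by_outer_pair,
    to_transition_matrix,
)


class Rec:
    def __init__(self, context, ancestral, derived):
        self.context, self.ancestral, self.derived = context, ancestral, derived


class TestAccumulateCounts:
    def test_two_records_one_context(self):
        key = ContextKey("AGC", "TGA")
        table = accumulate_counts([Rec(key, "A", "A"), Rec(key, "A", "G")], 3)
        m = table[key]
        assert m[0, 0] == 1 and m[0, 2] == 1 and m.sum() == 2
        assert table.counts.sum() == 2

    def test_empty_stream(self):
        assert accumulate_counts([], 3).total() == 0

    def test_mixed_radii_rejected(self):
        with pytest.raises(ValueError):
            accumulate_counts([Rec(ContextKey("A", "C"), "A", "A")], 3)

    def test_count_conservation_from_simulation(self, uniform_dataset):
        """Sum over all matrices equals the number of records (2 per site)."""
        from ctxsub.ingest import FilterTally

        aligns, _ = uniform_dataset
        tally = FilterTally()
        table = count_table_from_alignments(aligns, 3, tally=tally)
        assert table.total() == 2 * tally.eligible > 0


class TestCombineComplements:
    def test_known_pair_pools(self):
        table = ContextCountTable(3)
        table.add(("AGC", "TGA"), "A", "G", 5)
        table.add(("TCA", "GCT"), "T", "C", 7)  # reverse-complement partner
        combined = table.combine_complements()
        # T->C in the partner becomes A->G after complementation
        assert combined[("AGC", "TGA")][0, 2] == 12

    def test_ttt_to_aaa_complementation(self):
        """A T->C count in TTT|TTT lands as A->G in canonical AAA|AAA."""
        table = ContextCountTable(3)
        table.add(("TTT", "TTT"), "T", "C", 3)
        combined = table.combine_complements()
        assert combined[("AAA", "AAA")][0, 2] == 3

    def test_self_complementary_kept_once(self):
        key = ContextKey("AAA", "TTT")
        assert key.is_self_complementary
        table = ContextCountTable(3)
        table.add(key, "C", "T", 4)
        combined = table.combine_complements()
        assert combined[key][1, 3] == 4
        assert combined[key].sum() == 4

    def test_conservation_over_canonical_subset(self, uniform_dataset):
        aligns, _ = uniform_dataset
        raw = count_table_from_alignments(aligns, 2)
        combined = raw.combine_complements()
        mask = canonical_index_mask(2)
        assert combined.counts[mask].sum() == raw.total()

    def test_complement_transform_is_involution(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(256, 4, 4))
        perm = rc_permutation(2)
        once = counts[perm][:, ::-1, ::-1]
        twice = once[perm][:, ::-1, ::-1]
        assert np.array_equal(twice, counts)

    def test_double_combining_rejected(self):
        with pytest.raises(ValueError):
            ContextCountTable(2).combine_complements().combine_complements()


class TestTransitionMatrix:
    def test_row_normalization_example(self):
        # T row: 900 conserved, 60 T->C, 25 T->A, 15 T->G
        counts = np.zeros((4, 4), dtype=int)
        counts[3] = [25, 60, 15, 900]
        tm = to_transition_matrix(counts, ContextKey("A", "A"))
        assert tm.probs[3].tolist() == [0.025, 0.060, 0.015, 0.900]
        assert tm.empty_rows.tolist() == [True, True, True, False]
        assert not np.isnan(tm.probs).any()

    @given(hnp.arrays(np.int64, (4, 4), elements=st.integers(0, 1000)))
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, counts):
        tm = to_transition_matrix(counts, ContextKey("A", "A"))
        for i in range(4):
            if tm.row_n[i] > 0:
                assert abs(tm.probs[i].sum() - 1.0) < 1e-12
            else:
                assert tm.probs[i].sum() == 0.0


class TestRateCI:
    @pytest.mark.parametrize(
        "p,n,lo,hi",
        [(0.1, 100, 0.0412, 0.1588), (0.0, 50, 0.0, 0.0), (0.5, 4, 0.01, 0.99)],
    )
    def test_wald_examples(self, p, n, lo, hi):
        got = rate_ci(p, n)
        assert got[0] == pytest.approx(lo, abs=1e-4)
        assert got[1] == pytest.approx(hi, abs=1e-4)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            rate_ci(0.5, 0)


class TestRateSummary:
    def _tm(self, t_row):
        counts = np.zeros((4, 4), dtype=int)
        counts[3] = t_row  # A, C, G, T order
        return to_transition_matrix(counts, ContextKey("AA", "AA"))

    def test_ts_tv_split_from_t_row(self):
        # T row probs (A, C, G, T) = (0.025, 0.060, 0.015, 0.900)
        s = rate_summary(self._tm([25, 60, 15, 900]), "T")
        assert s.ts_rate == pytest.approx(0.060)
        assert s.tv_rate == pytest.approx(0.040)
        assert s.total_rate == pytest.approx(0.100)
        assert s.ts_tv == pytest.approx(1.5)
        assert (s.n_ts, s.n_tv, s.n_row) == (60, 40, 1000)

    def test_zero_transversions_flagged_undefined(self):
        s = rate_summary(self._tm([0, 60, 0, 940]), "T")
        assert s.ts_tv is None

    def test_purine_rows_rejected(self):
        with pytest.raises(ValueError):
            rate_summary(self._tm([1, 1, 1, 1]), "A")

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            rate_summary(self._tm([1, 1, 1, 1]), "C")

    def test_uniform_simulation_ts_tv_near_half(self, uniform_dataset):
        """One transition vs two transversions at equal rates gives Ts:Tv = 0.5."""
        aligns, _ = uniform_dataset
        table = count_table_from_alignments(aligns, 1).combine_complements()
        summaries = rate_summaries(table)
        n_ts = sum(s.n_ts for s in summaries)
        n_tv = sum(s.n_tv for s in summaries)
        ratio = n_ts / n_tv
        se = ratio * math.sqrt(1 / n_ts + 1 / n_tv)
        assert abs(ratio - 0.5) < 3 * se


def _summary(ctx, base, ts, tv, n_row):
    return RateSummary(
        context=ContextKey.from_string(ctx),
        from_base=base,
        ts_rate=ts,
        tv_rate=tv,
        total_rate=ts + tv,
        ts_tv=ts / tv if tv else None,
        n_ts=int(ts * n_row),
        n_tv=int(tv * n_row),
        n_row=n_row,
    )


class TestFoldVariation:
    def test_two_contexts_fold(self):
        summaries = [
            _summary("AA|AA", "T", 0.02, 0.04, 10000),
            _summary("CC|CC", "T", 0.02, 0.01, 10000),
        ]
        frame = fold_variation_table(summaries, mode="ts50tv50")
        tv = frame[(frame.statistic == "tv_rate") & (frame["from"] == "T")].iloc[0]
        assert tv.fold == pytest.approx(4.0)
        assert tv.max_context == "AA|AA" and tv.min_context == "CC|CC"

    def test_single_context_fold_is_one(self):
        frame = fold_variation_table([_summary("AA|AA", "C", 0.02, 0.01, 10000)])
        assert (frame.fold == 1.0).all()

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        summaries = []
        for i, ctx in enumerate(["AA|AA", "AC|GT", "CC|CC", "GA|TC", "TT|TT"]):
            for base in ("T", "C"):
                ts, tv = rng.uniform(0.01, 0.1, 2)
                summaries.append(_summary(ctx, base, ts, tv, 20000))
        frame = fold_variation_table(summaries, mode="row100", min_row=100)
        for stat in ("ts_rate", "tv_rate", "total_rate", "ts_tv"):
            for scope in ("T", "C", "T+C"):
                pool = [
                    getattr(s, stat)
                    for s in summaries
                    if scope == "T+C" or s.from_base == scope
                ]
                expect = max(pool) / min(pool)
                got = frame[(frame.statistic == stat) & (frame["from"] == scope)].fold.iloc[0]
                assert got == pytest.approx(expect)

    def test_threshold_filters_low_count_rows(self):
        summaries = [
            _summary("AA|AA", "T", 0.02, 0.04, 10000),
            _summary("CC|CC", "T", 0.5, 0.4, 20),  # fails both thresholds
        ]
        frame = fold_variation_table(summaries, mode="ts50tv50")
        assert (frame.fold == 1.0).all()
        with pytest.raises(ValueError):
            fold_variation_table([_summary("AA|AA", "T", 0.5, 0.5, 10)])


class TestSliceByOuterPair:
    def test_key_construction(self):
        table = ContextCountTable(3)
        table.add(("CAA", "AAG"), "T", "C", 9)
        sliced = slice_by_outer_pair(table, ContextKey("AA", "AA"))
        assert sliced[("C", "G")][3, 1] == 9
        assert sliced[("A", "A")].sum() == 0

    def test_sixteen_slices_sum_to_internal_marginal(self, uniform_dataset):
        """The 16 outer-pair slices partition the internal context's counts."""
        from ctxsub.contexts import BASES as B

        aligns, _ = uniform_dataset
        t3 = count_table_from_alignments(aligns, 3)
        internal = ContextKey("AC", "GT")
        sliced = slice_by_outer_pair(t3, internal)
        assert len(sliced) == 16
        total = sum(m.sum() for m in sliced.values())
        marginal = sum(
            t3[ContextKey(x + internal.left, internal.right + y)].sum()
            for x in B
            for y in B
        )
        assert total == marginal > 0

    def test_radius_mismatch_rejected(self):
        with pytest.raises(ValueError):
            slice_by_outer_pair(ContextCountTable(3), ContextKey("AAA", "AAA"))


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, uniform_dataset):
        aligns, _ = uniform_dataset
        table = count_table_from_alignments(aligns[:5], 2)
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = ContextCountTable.from_tsv(path)
        assert np.array_equal(back.counts, table.counts)
        assert back.radius == table.radius

    def test_empty_table_needs_radius(self):
        with pytest.raises(ValueError):
            ContextCountTable.from_frame(pd.DataFrame(columns=["context_left"]))
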