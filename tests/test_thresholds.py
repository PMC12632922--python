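"""Threshold computation, verification and row mapping."""

import numpy as np
import pytest

from moveindex import (
    build_suffix_bundle,
    compute_thresholds,
    map_thresholds_to_rows,
    run_length_encode,
    text_from_string,
    verify_threshold,
)
from moveindex.core_text import RowPartition
from moveindex.thresholds import ThresholdSet


@pytest.fixture(scope="module")
def acacgt_parts(acacgt_bundle):
    rlbwt = run_length_encode(acacgt_bundle)
    return acacgt_bundle, rlbwt, compute_thresholds(acacgt_bundle, rlbwt)


class TestCompute:
    def test_c_pair_leftmost_minimum(self, acacgt_parts):
        _, _, ts = acacgt_parts
        # single C-run pair (runs 2 and 4), candidates lcp[3..5]=(0,1,0): t=3
        assert ts.pairs[2].tolist() == [[2, 4, 3]]

    def test_single_run_symbols_have_no_pairs(self, acacgt_parts):
        _, _, ts = acacgt_parts
        for c in (1, 3, 4):  # A, G, T each occur in one run
            assert ts.pairs[c].shape == (0, 3)

    def test_pair_count_bounded_by_r(self, small_corpus):
        for _, b in small_corpus:
            rlbwt = run_length_encode(b)
            ts = compute_thresholds(b, rlbwt)
            assert ts.total_pairs <= rlbwt.r

    def test_flat_lcp_gap_takes_leftmost_offset(self):
        # T=AATAA$: the two A-runs in BWT "AAT$AA" straddle a gap whose LCP
        # minimum is attained twice; the tie must break to the leftmost.
        b = build_suffix_bundle(text_from_string("AATAA$"))
        rlbwt = run_length_encode(b)
        ts = compute_thresholds(b, rlbwt)
        for c, pairs in ts.pairs.items():
            for i, j, t in pairs.tolist():
                lo = int(rlbwt.tail[i]) + 1
                hi = int(rlbwt.head[j])
                window = b.lcp[lo : hi + 1]
                assert t == lo + int(np.argmin(window))
                assert verify_threshold(b, rlbwt, i, j, t)


class TestVerify:
    def test_chosen_candidate_valid(self, acacgt_parts):
        b, rlbwt, _ = acacgt_parts
        assert verify_threshold(b, rlbwt, 2, 4, 3)

    def test_other_candidates_may_also_be_valid(self, acacgt_parts):
        b, rlbwt, _ = acacgt_parts
        assert verify_threshold(b, rlbwt, 2, 4, 5)  # 1-based offset 6

    def test_threshold_outside_interval_rejected(self, acacgt_parts):
        b, rlbwt, _ = acacgt_parts
        with pytest.raises(ValueError, match="outside the legal interval"):
            verify_threshold(b, rlbwt, 2, 4, int(rlbwt.tail[2]))

    def test_non_adjacent_pair_rejected(self, small_corpus):
        for _, b in small_corpus:
            rlbwt = run_length_encode(b)
            idx = np.flatnonzero(rlbwt.sym == rlbwt.sym[0])
            if idx.size >= 3:
                with pytest.raises(ValueError, match="not adjacent"):
                    verify_threshold(b, rlbwt, int(idx[0]), int(idx[2]), int(rlbwt.head[idx[2]]))
                return

    def test_all_computed_thresholds_verify(self, small_corpus):
        for _, b in small_corpus[:8]:
            rlbwt = run_length_encode(b)
            ts = compute_thresholds(b, rlbwt)
            for c, pairs in ts.pairs.items():
                for i, j, t in pairs.tolist():
                    assert verify_threshold(b, rlbwt, i, j, t)


def _manual_threshold_set(pairs_c, tails_c, heads_c):
    empty = np.zeros((0, 3), dtype=np.int64)
    none = np.zeros(0, dtype=np.int64)
    pairs = {c: empty for c in range(1, 5)}
    tails = {c: none for c in range(1, 5)}
    heads = {c: none for c in range(1, 5)}
    pairs[2] = np.array(pairs_c, dtype=np.int64).reshape(-1, 3)
    tails[2] = np.array(tails_c, dtype=np.int64)
    heads[2] = np.array(heads_c, dtype=np.int64)
    return ThresholdSet(pairs=pairs, run_tail=tails, run_head=heads)


class TestRowMapping:
    def test_clamp_cases(self):
        # C runs at [0,2) and [15,20); pair threshold configurable.
        rows = RowPartition(
            sym=np.array([2, 1, 3, 4, 2]),
            head=np.array([0, 2, 7, 10, 15]),
            length=np.array([2, 5, 3, 5, 5]),
        )
        for t, expected in [(12, [5, 3, 2]), (20, [5, 3, 5]), (3, [1, 0, 0])]:
            ts = _manual_threshold_set([(0, 1, t)], [1, 19], [0, 15])
            theta = map_thresholds_to_rows(ts, rows)[:, 1]  # symbol C column
            assert theta[[1, 2, 3]].tolist() == expected

    def test_before_first_and_after_last_run(self):
        rows = RowPartition(
            sym=np.array([1, 2, 1]),
            head=np.array([0, 4, 6]),
            length=np.array([4, 2, 3]),
        )
        ts = _manual_threshold_set([], [5], [4])  # single C run at [4,6)
        theta = map_thresholds_to_rows(ts, rows)[:, 1]
        assert theta[0] == 0  # before the first C run: always down
        assert theta[2] == 3  # after the last C run: always up (= row length)

    def test_fixture_a_row_threshold_trivial(self, acacgt_parts):
        b, rlbwt, ts = acacgt_parts
        rows = RowPartition.from_rlbwt(rlbwt)
        theta = map_thresholds_to_rows(ts, rows)
        # A-run row (head 3, l=2) with C-pair threshold t=3: clamp -> 0
        assert theta[3, 1] == 0

    def test_interior_thresholds_round_trip(self, small_corpus):
        for _, b in small_corpus[:6]:
            rlbwt = run_length_encode(b)
            ts = compute_thresholds(b, rlbwt)
            rows = RowPartition.from_rlbwt(rlbwt)
            theta = map_thresholds_to_rows(ts, rows)
            for c in range(1, 5):
                for _, _, t in ts.pairs[c].tolist():
                    u = int(np.searchsorted(rows.head, t, side="right")) - 1
                    if rows.sym[u] != c and 0 < t - rows.head[u] < rows.length[u]:
                        assert theta[u, c - 1] == t - rows.head[u]
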