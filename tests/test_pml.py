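"""Pseudo matching length queries against the naive matching-statistics and
step-by-step repositioning oracles."""

import numpy as np
import pytest

from moveindex import (
    Pattern,
    build_move_table,
    build_suffix_bundle,
    compute_pml,
    compute_pml_batch,
    compute_thresholds,
    generate_reads,
    matching_statistics_naive,
    run_length_encode,
    text_from_string,
)

from conftest import random_dna
from oracles import pml_oracle


def _pat(seq, name="p"):
    return Pattern.from_string(name, seq)


class TestMicroTrace:
    def test_worked_example_ca(self, acacgt, acacgt_bundle):
        table = build_move_table(acacgt, bundle=acacgt_bundle)
        assert compute_pml(table, _pat("CA")).pml.tolist() == [1, 0]

    def test_worked_example_matches_independent_oracle(self, acacgt, acacgt_bundle):
        table = build_move_table(acacgt, bundle=acacgt_bundle)
        ts = compute_thresholds(acacgt_bundle, run_length_encode(acacgt_bundle))
        p = _pat("CA")
        assert np.array_equal(
            compute_pml(table, p).pml, pml_oracle(acacgt_bundle, ts, p.codes)
        )

    def test_exact_substring_counts_down(self, acacgt, acacgt_bundle):
        table = build_move_table(acacgt, bundle=acacgt_bundle)
        assert compute_pml(table, _pat("ACACG")).pml.tolist() == [4, 3, 2, 1, 0]

    def test_absent_symbols_give_zero_without_moving(self):
        text = text_from_string("AACCAACC$")  # no G, no T
        table = build_move_table(text)
        assert compute_pml(table, _pat("GTGT")).pml.tolist() == [0, 0, 0, 0]
        mixed = compute_pml(table, _pat("AAGAA")).pml
        assert mixed[2] == 0  # the G position resets

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _pat("")


class TestNaiveMatchingStatistics:
    def test_worked_example(self, acacgt):
        assert matching_statistics_naive(acacgt, _pat("CA")).ms.tolist() == [2, 1]

    def test_absent_symbol(self, acacgt):
        t = text_from_string("AAAA$")
        assert matching_statistics_naive(t, _pat("G")).ms.tolist() == [0]

    def test_full_match_prefix(self, acacgt):
        assert matching_statistics_naive(acacgt, _pat("ACACG")).ms[0] == 5


@pytest.fixture(scope="module")
def fixtures(small_corpus):
    rng = np.random.default_rng(17)
    out = []
    for text, b in small_corpus[:8]:
        table = build_move_table(text, bundle=b)
        ts = compute_thresholds(b, run_length_encode(b))
        reads = [_pat(random_dna(rng, int(rng.integers(5, 40))), f"r{i}") for i in range(4)]
        out.append((text, b, ts, table, reads))
    return out


class TestProperties:

    def test_pml_lower_bounds_matching_statistics(self, fixtures):
        for text, _, _, table, reads in fixtures:
            for p in reads:
                pml = compute_pml(table, p).pml
                ms = matching_statistics_naive(text, p).ms
                assert (pml <= ms).all()

    def test_substring_witness(self, fixtures):
        for text, _, _, table, reads in fixtures:
            t = str(text)
            for p in reads:
                seq = "".join("ACGT"[c] for c in p.codes)
                pml = compute_pml(table, p).pml
                for k, l in enumerate(pml.tolist()):
                    if l > 0:
                        assert seq[k : k + l] in t

    def test_structural_recurrence(self, fixtures):
        for _, _, _, table, reads in fixtures:
            for p in reads:
                pml = compute_pml(table, p).pml
                assert pml[-1] == 0
                for k in range(p.m - 1):
                    assert pml[k] in (0, pml[k + 1] + 1)
                assert (pml < p.m).all() and (pml >= 0).all()

    def test_agrees_with_step_by_step_oracle(self, fixtures):
        for _, b, ts, table, reads in fixtures:
            for p in reads:
                assert np.array_equal(
                    compute_pml(table, p).pml, pml_oracle(b, ts, p.codes)
                )


class TestVariantAgreement:
    def test_identical_pmls_across_variants(self, small_corpus):
        rng = np.random.default_rng(23)
        for text, b in small_corpus[:5]:
            reads = [_pat(random_dna(rng, 30), f"r{i}") for i in range(3)]
            tables = [build_move_table(text, bundle=b)]
            tables += [
                build_move_table(text, variant="blocked", block_size=bs, bundle=b)
                for bs in (8, 2048)
            ]
            tables += [
                build_move_table(text, variant="sampled", sample_rate=s, bundle=b)
                for s in (2, 50, 200)
            ]
            for p in reads:
                ref = compute_pml(tables[0], p).pml
                for t in tables[1:]:
                    assert np.array_equal(compute_pml(t, p).pml, ref)


class TestBatch:
    def test_empty_stream(self, acacgt):
        table = build_move_table(acacgt)
        assert list(compute_pml_batch(table, [])) == []

    def test_duplicates_and_order(self, acacgt):
        table = build_move_table(acacgt)
        reads = [_pat("CAC", "a"), _pat("GTA", "b"), _pat("CAC", "c")]
        out = list(compute_pml_batch(table, reads))
        assert [r.name for r in out] == ["a", "b", "c"]
        assert np.array_equal(out[0].pml, out[2].pml)

    def test_batch_equals_single_calls(self, small_corpus):
        text, b = small_corpus[5]
        table = build_move_table(text, bundle=b)
        rng = np.random.default_rng(31)
        reads = [_pat(random_dna(rng, 20), f"r{i}") for i in range(20)]
        batch = list(compute_pml_batch(table, reads))
        for p, res in zip(reads, batch):
            assert np.array_equal(res.pml, compute_pml(table, p).pml)


class TestClassificationSanity:
    def test_indexed_reads_score_higher_than_unrelated(self, pangenome_small):
        records, text, bundle = pangenome_small
        table = build_move_table(text, bundle=bundle)
        own = generate_reads(records, n_reads=15, read_length=120, error_rate=0.0, seed=7)
        rng = np.random.default_rng(1234)
        other = [(f"bg{i}", random_dna(rng, 120)) for i in range(15)]
        mean_own = np.mean([
            compute_pml(table, _pat(seq, n)).pml.mean() for n, seq in own
        ])
        mean_other = np.mean([
            compute_pml(table, _pat(seq, n)).pml.mean() for n, seq in other
        ])
        assert mean_own > 4 * mean_other
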