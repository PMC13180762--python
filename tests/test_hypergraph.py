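"""Data model, I/O, filtering, splitting and incidence construction."""

import json

import numpy as np
import pytest

from hypertrail.hypergraph import (HypergraphParseError, filter_by_size,
                                   incidence, read_hyperedges,
                                   remove_split_leakage, split_by_period,
                                   subgraph, write_hyperedges)

from conftest import make_edge, make_hypergraph


def write_jsonl(path, records):
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


class TestReadWrite:
    def test_basic_jsonl(self, tmp_path):
        p = tmp_path / "h.jsonl"
        write_jsonl(p, [
            {"id": "a", "year": 2000, "concepts": ["X", "Y"]},
            {"id": "b", "year": 2001, "concepts": ["Y", "Z"]},
            {"id": "c", "year": 2001, "concepts": ["X", "Z"]},
        ])
        th = read_hyperedges(p)
        assert th.num_hyperedges == 3
        assert th.num_steps == 2 and max(th.snapshots) == 1
        assert th.year_origin == 2000

    def test_duplicate_concepts_collapse(self, tmp_path):
        p = tmp_path / "h.jsonl"
        write_jsonl(p, [{"id": "a", "year": 2000,
                         "concepts": ["TP53", "EGFR", "TP53"]}])
        (edge,) = read_hyperedges(p).hyperedges()
        assert edge.size == 2

    def test_zero_concepts_is_parse_error(self, tmp_path):
        p = tmp_path / "h.jsonl"
        write_jsonl(p, [{"id": "a", "year": 2000, "concepts": []}])
        with pytest.raises(HypergraphParseError, match="line 1"):
            read_hyperedges(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "h.jsonl"
        with open(p, "w") as fh:
            fh.write('{"id": "a", "year": 2000, "concepts": ["X"]}\n')
            fh.write("not json\n")
        with pytest.raises(HypergraphParseError, match="line 2"):
            read_hyperedges(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "h.jsonl"
        p.write_text("")
        with pytest.raises(HypergraphParseError):
            read_hyperedges(p)

    def test_nonconsecutive_years_remap_preserving_order(self, tmp_path):
        p = tmp_path / "h.jsonl"
        write_jsonl(p, [
            {"id": "a", "year": 1995, "concepts": ["X"]},
            {"id": "b", "year": 2005, "concepts": ["Y"]},
        ])
        th = read_hyperedges(p)
        assert sorted(th.snapshots) == [0, 1]
        assert th.years == (1995, 2005)

    @pytest.mark.parametrize("dialect", ["jsonl", "tsv"])
    def test_round_trip(self, tmp_path, dialect, small_hypergraph):
        p = tmp_path / f"h.{dialect}"
        write_hyperedges(small_hypergraph, p, dialect)
        th = read_hyperedges(p, dialect)
        orig = {(e.source_id or str(e.id), e.timestamp,
                 frozenset(small_hypergraph.vocabulary.labels[j] for j in e.members))
                for e in small_hypergraph.hyperedges()}
        back = {(e.source_id, e.timestamp,
                 frozenset(th.vocabulary.labels[j] for j in e.members))
                for e in th.hyperedges()}
        assert orig == back


class TestFilterBySize:
    def test_size_window(self):
        th = make_hypergraph(
            [(i, 0, set(range(s))) for i, s in enumerate([4, 5, 11, 30, 31])],
            n_concepts=31,
        )
        out = filter_by_size(th, 5, 30, compact_vocabulary=False)
        assert sorted(e.size for e in out.hyperedges()) == [5, 11, 30]

    def test_empty_hypergraph_passes_through(self):
        th = make_hypergraph([(0, 0, {0})], n_concepts=1)
        out = filter_by_size(th, 5, 30)
        assert out.num_hyperedges == 0

    def test_identity_when_all_in_range(self, small_hypergraph):
        out = filter_by_size(small_hypergraph, 1, 10, compact_vocabulary=False)
        assert {e.id for e in out.hyperedges()} == set(range(6))

    def test_idempotent(self, small_hypergraph):
        once = filter_by_size(small_hypergraph, 3, 3)
        twice = filter_by_size(once, 3, 3)
        assert [(e.id, e.members) for e in once.hyperedges()] == \
               [(e.id, e.members) for e in twice.hyperedges()]

    def test_vocabulary_compaction_drops_orphans(self):
        th = make_hypergraph([(0, 0, {0, 1}), (1, 0, {2, 3, 4})], n_concepts=5)
        out = filter_by_size(th, 3, 10, compact_vocabulary=True)
        assert out.vocabulary.size == 3
        (edge,) = out.hyperedges()
        assert edge.members == frozenset({0, 1, 2})

    def test_invalid_bounds(self, small_hypergraph):
        with pytest.raises(ValueError):
            filter_by_size(small_hypergraph, 5, 4)


class TestSplit:
    def _th(self, n_val):
        specs = [(i, 0, {0, i % 3 + 1}) for i in range(4)]
        specs += [(10 + i, 1, {1, i % 3 + 2}) for i in range(n_val)]
        specs += [(50 + i, 2, {2, i % 3 + 3}) for i in range(3)]
        return make_hypergraph(specs, n_concepts=8)

    BOUNDS = {"train": (2000, 2000), "val": (2001, 2001), "test": (2002, 2002)}

    def test_even_halving(self):
        splits = split_by_period(self._th(10), self.BOUNDS, val_half_seed=3)
        assert len(splits.val_opt) == 5 and len(splits.val_trail) == 5

    def test_odd_halving_favors_val_opt(self):
        splits = split_by_period(self._th(7), self.BOUNDS, val_half_seed=3)
        assert len(splits.val_opt) == 4 and len(splits.val_trail) == 3

    def test_deterministic_under_seed(self):
        a = split_by_period(self._th(9), self.BOUNDS, val_half_seed=11)
        b = split_by_period(self._th(9), self.BOUNDS, val_half_seed=11)
        assert [e.id for e in a.val_opt] == [e.id for e in b.val_opt]
        assert [e.id for e in a.val_trail] == [e.id for e in b.val_trail]

    def test_halves_partition_validation_period(self):
        splits = split_by_period(self._th(9), self.BOUNDS, val_half_seed=5)
        ids = {e.id for e in splits.val_opt} | {e.id for e in splits.val_trail}
        assert ids == {10 + i for i in range(9)}
        assert not ({e.id for e in splits.val_opt}
                    & {e.id for e in splits.val_trail})

    def test_empty_split_warns_not_errors(self):
        th = make_hypergraph([(0, 0, {0}), (1, 2, {1})], n_concepts=2)
        with pytest.warns(UserWarning):
            split_by_period(th, self.BOUNDS, val_half_seed=0)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            split_by_period(self._th(4), {"train": (2000, 2001),
                                          "val": (2001, 2001),
                                          "test": (2002, 2002)}, 0)


class TestLeakageRemoval:
    def _splits(self, test_members):
        th = self_th = make_hypergraph(
            [(0, 0, {0, 1, 2, 3, 4}), (1, 1, {5, 6}), (2, 2, test_members)],
            n_concepts=9)
        return split_by_period(self_th, TestSplit.BOUNDS, 0)

    def test_equal_member_set_removed_across_years(self):
        splits = remove_split_leakage(self._splits({0, 1, 2, 3, 4}))
        assert splits.test == []

    def test_partial_overlap_retained(self):
        splits = remove_split_leakage(self._splits({0, 1, 2, 3, 8}))
        assert len(splits.test) == 1

    def test_train_unchanged_and_empty_test_ok(self):
        before = self._splits({7, 8})
        after = remove_split_leakage(before)
        assert [e.id for e in after.train] == [e.id for e in before.train]
        empty = remove_split_leakage(
            type(after)(train=after.train, val_opt=[], val_trail=[], test=[],
                        boundaries=after.boundaries))
        assert empty.test == []

    def test_exhaustive_no_equal_pairs_after_removal(self, rng):
        # random fixture: check the postcondition pairwise
        specs = []
        for i in range(30):
            t = int(rng.integers(3))
            members = set(int(x) for x in rng.choice(6, size=3, replace=False))
            specs.append((i, t, members))
        th = make_hypergraph(specs, n_concepts=6)
        splits = remove_split_leakage(split_by_period(th, TestSplit.BOUNDS, 0))
        train_sets = [e.members for e in splits.train]
        for e in splits.val_opt + splits.val_trail + splits.test:
            assert all(e.members != m for m in train_sets)


class TestIncidence:
    def test_small_example(self, small_hypergraph):
        edges = [make_edge(0, 0, {0, 1}), make_edge(1, 0, {1, 2})]
        th = make_hypergraph([(0, 0, {0, 1}), (1, 0, {1, 2})], n_concepts=3)
        H = incidence(edges, th.vocabulary)
        assert H.entries.tolist() == [[1, 0], [1, 1], [0, 1]]

    def test_empty_list_gives_n_by_zero(self, small_hypergraph):
        H = incidence([], small_hypergraph.vocabulary)
        assert H.shape == (6, 0)

    def test_full_edge_gives_all_ones_column(self, small_hypergraph):
        e = make_edge(9, 0, set(range(6)))
        H = incidence([e], small_hypergraph.vocabulary)
        assert np.all(H.entries == 1.0)

    def test_column_sums_equal_sizes(self, small_hypergraph):
        edges = list(small_hypergraph.hyperedges())
        H = incidence(edges, small_hypergraph.vocabulary)
        assert np.array_equal(H.entries.sum(axis=0),
                              np.array([e.size for e in edges], dtype=float))

    def test_out_of_range_member_errors(self, small_hypergraph):
        with pytest.raises(ValueError):
            incidence([make_edge(0, 0, {99})], small_hypergraph.vocabulary)


def test_subgraph_preserves_time_axis(small_hypergraph):
    edges = [e for e in small_hypergraph.hyperedges() if e.timestamp < 2]
    sub = subgraph(small_hypergraph, edges)
    assert sorted(sub.snapshots) == sorted(small_hypergraph.snapshots)
    assert sub.num_hyperedges == 4
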