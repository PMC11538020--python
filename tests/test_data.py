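"""Knowledge-graph containers, I/O, reverses, splits, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kgelp import data
from kgelp.data import KnowledgeGraph, RelationSchema
from tests.conftest import random_kg


def write_lines(path, lines):
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


class TestReadTriples:
    def test_duplicates_collapse(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["a\tDDI\tb", "b\tPPI\tc", "a\tDDI\tb"])
        kg = data.read_triples(f)
        assert len(kg) == 2
        assert kg.duplicates_dropped == 1

    def test_vocab_first_appearance_order(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["a\tDDI\tb", "b\tPPI\tc"])
        kg = data.read_triples(f)
        assert kg.entities == ["a", "b", "c"]
        assert kg.relations == ["DDI", "PPI"]
        assert len(kg) == 2

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["a\tDDI\tb", "broken line"])
        with pytest.raises(ValueError, match="line 2"):
            data.read_triples(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("\n\n", encoding="utf-8")
        with pytest.raises(ValueError):
            data.read_triples(f)

    def test_blank_lines_ignored(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, ["a\tDDI\tb", "", "b\tDDI\tc"])
        assert len(data.read_triples(f)) == 2


class TestWriteRoundTrip:
    @pytest.mark.parametrize("dialect", ["label-tsv", "index-tsv"])
    def test_round_trip_identity(self, tmp_path, rng, dialect):
        kg = random_kg(rng, n_entities=30, n_relations=4, n_triples=1000)
        f = tmp_path / "out.tsv"
        data.write_triples(kg, f, dialect)
        back = data.read_triples(f, dialect)
        if dialect == "index-tsv":
            assert back.triple_set() == kg.triple_set()
        else:
            # map labels back to original indices
            remap = {
                (back.entities[s], back.relations[p], back.entities[o])
                for s, p, o in back.triples
            }
            orig = {
                (kg.entities[s], kg.relations[p], kg.entities[o])
                for s, p, o in kg.triples
            }
            assert remap == orig

    def test_deterministic_order(self, tmp_path, rng):
        kg = random_kg(rng, n_triples=200)
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        data.write_triples(kg, f1)
        data.write_triples(kg, f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestAddReverses:
    def _kg(self, triples, schema=None, classes=None):
        return KnowledgeGraph(
            ["a", "b", "c", "d"], ["DDI", "PPI", "DPI"],
            np.array(triples), schema, classes,
        )

    def test_reverse_added(self):
        kg = self._kg([[0, 0, 1]])
        out = data.add_reverses(kg, {0})
        assert out.triple_set() == {(0, 0, 1), (1, 0, 0)}

    def test_idempotent(self):
        kg = self._kg([[0, 0, 1], [1, 0, 0]])
        out = data.add_reverses(kg, {0})
        assert len(out) == 2
        twice = data.add_reverses(out, {0})
        assert twice.triple_set() == out.triple_set()

    def test_counts_and_untouched_relations(self):
        # 5 DDI, 3 PPI, 4 DPI without pre-existing reverses
        rows = (
            [[0, 0, 1], [0, 0, 2], [0, 0, 3], [1, 0, 2], [1, 0, 3]]
            + [[0, 1, 1], [0, 1, 2], [1, 1, 2]]
            + [[0, 2, 1], [0, 2, 2], [1, 2, 2], [2, 2, 3]]
        )
        kg = self._kg(rows)
        out = data.add_reverses(kg, {0, 1})
        assert len(out) == len(rows) + 5 + 3
        dpi = out.triples[out.triples[:, 1] == 2]
        assert len(dpi) == 4

    def test_cross_class_relation_refused(self):
        schema = {
            "DDI": RelationSchema("drug", "drug", True),
            "PPI": RelationSchema("protein", "protein", True),
            "DPI": RelationSchema("drug", "protein", False),
        }
        classes = {"a": "drug", "b": "drug", "c": "protein", "d": "protein"}
        kg = KnowledgeGraph(
            ["a", "b", "c", "d"], ["DDI", "PPI", "DPI"],
            np.array([[0, 2, 2]]), schema, classes,
        )
        with pytest.raises(ValueError, match="same-class"):
            data.add_reverses(kg, {2})


class TestSplit:
    def test_80_10_10_sizes(self, rng):
        kg = random_kg(rng, n_entities=200, n_relations=5, n_triples=1100)
        kg = kg.replace_triples(kg.triples[:1000])
        sp = data.split(kg, (0.8, 0.1, 0.1), seed=0)
        assert (len(sp.train), len(sp.valid), len(sp.test)) == (800, 100, 100)

    def test_floor_arithmetic_small(self):
        kg = KnowledgeGraph(
            [f"e{i}" for i in range(11)], ["r"],
            np.array([[i, 0, i + 1] for i in range(10)]),
        )
        sp = data.split(kg, (0.8, 0.1, 0.1), seed=1)
        assert (len(sp.train), len(sp.valid), len(sp.test)) == (8, 1, 1)

    def test_deterministic_and_seed_sensitive(self, rng):
        kg = random_kg(rng, n_entities=100, n_triples=400)
        a = data.split(kg, (0.8, 0.1, 0.1), seed=7)
        b = data.split(kg, (0.8, 0.1, 0.1), seed=7)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)
        diffs = sum(
            not np.array_equal(
                data.split(kg, (0.8, 0.1, 0.1), seed=s).train, a.train
            )
            for s in range(1, 21)
        )
        assert diffs >= 19  # different seeds give different partitions

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_disjoint_exhaustive(self, seed):
        rng = np.random.default_rng(99)
        kg = random_kg(rng, n_entities=40, n_relations=3, n_triples=120)
        sp = data.split(kg, (0.8, 0.1, 0.1), seed=seed)
        parts = [set(map(tuple, p.tolist())) for p in (sp.train, sp.valid, sp.test)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert parts[0] | parts[1] | parts[2] == kg.triple_set()

    def test_empty_partition_rejected(self):
        kg = KnowledgeGraph(
            ["a", "b", "c"], ["r"], np.array([[0, 0, 1], [1, 0, 2]])
        )
        with pytest.raises(ValueError, match="empty"):
            data.split(kg, (0.8, 0.1, 0.1), seed=0)

    def test_train_reverses_leak_free(self, rng):
        kg = random_kg(rng, n_entities=30, n_relations=2, n_triples=200)
        sp = data.split(kg, (0.8, 0.1, 0.1), seed=0)
        aug = sp.with_train_reverses(kg, {0})
        train_set = set(map(tuple, aug.train.tolist()))
        for s, p, o in aug.valid.tolist() + aug.test.tolist():
            assert (s, p, o) not in train_set
        # every reverse of an r0 training triple is present, unless that
        # reverse is itself a held-out triple (kept out on purpose)
        held = set(map(tuple, sp.valid.tolist())) | set(map(tuple, sp.test.tolist()))
        for s, p, o in sp.train.tolist():
            if p == 0 and (o, p, s) not in held:
                assert (o, p, s) in train_set


class TestRelationStats:
    def test_counts_single_relation(self):
        kg = KnowledgeGraph(
            [f"e{i}" for i in range(6)], ["r"],
            np.array([[i, 0, i + 1] for i in range(5)]),
        )
        stats = data.relation_stats(kg)
        assert stats.counts == {0: 5}

    def test_mean_in_degree_hand_count(self):
        # 4 triples of r, objects {b, b, c, c} -> 4 / 2 distinct = 2.0
        kg = KnowledgeGraph(
            ["a", "b", "c", "d"], ["r"],
            np.array([[0, 0, 1], [3, 0, 1], [0, 0, 2], [3, 0, 2]]),
        )
        stats = data.relation_stats(kg)
        assert stats.mean_in_degree[0] == 2.0
        assert stats.mean_out_degree[0] == 2.0

    def test_counts_conserved_under_reverses(self, rng):
        kg = random_kg(rng, n_entities=25, n_relations=3, n_triples=150)
        before = data.relation_stats(kg).counts
        after = data.relation_stats(data.add_reverses(kg, {1})).counts
        assert after[0] == before[0] and after[2] == before[2]
        assert before[1] <= after[1] <= 2 * before[1]
        assert sum(after.values()) == len(data.add_reverses(kg, {1}))
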