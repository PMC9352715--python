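"""Ontology parsing, information content, MICA metrics, cosine, tables."""

import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from seenrec import (
    OntologyDAG,
    SimilarityTable,
    aggregate_features,
    build_similarity_table,
    cosine_similarity,
    information_content,
    mica,
    parse_obo,
    read_similarity_table,
    semantic_similarity,
    write_similarity_table,
)

OBO_HEADER = "format-version: 1.2\nontology: test\n\n"


def obo(*stanzas: str) -> io.StringIO:
    return io.StringIO(OBO_HEADER + "\n".join(stanzas))


class TestParseObo:
    def test_two_term_edge(self):
        dag = parse_obo(obo("[Term]\nid: A\nname: a\n",
                            "[Term]\nid: B\nname: b\nis_a: A\n"))
        assert dag.roots == {"A"}
        assert dag.parents["B"] == ("A",)

    def test_obsolete_term_dropped(self):
        dag = parse_obo(obo("[Term]\nid: A\nname: a\n",
                            "[Term]\nid: B\nname: b\nis_a: A\nis_obsolete: true\n"))
        assert "B" not in dag.terms

    def test_edge_to_obsolete_dropped(self):
        dag = parse_obo(obo("[Term]\nid: A\nname: a\n",
                            "[Term]\nid: X\nname: x\nis_obsolete: true\n",
                            "[Term]\nid: B\nname: b\nis_a: A\nis_a: X\n"))
        assert dag.parents["B"] == ("A",)

    def test_diamond_ancestors(self):
        dag = parse_obo(obo("[Term]\nid: A\nname: a\n",
                            "[Term]\nid: B\nname: b\nis_a: A\n",
                            "[Term]\nid: C\nname: c\nis_a: A\n",
                            "[Term]\nid: D\nname: d\nis_a: B\nis_a: C\n"))
        assert dag.ancestors("D", inclusive=False) == {"B", "C", "A"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(obo("[Term]\nid: A\nname: a\nis_a: B\n",
                          "[Term]\nid: B\nname: b\nis_a: A\n"))

    def test_dangling_target_rejected(self):
        with pytest.raises(ValueError, match="dangling"):
            parse_obo(obo("[Term]\nid: B\nname: b\nis_a: NOPE\n"))


class TestInformationContent:
    def test_root_ic_zero(self, toy_dag, toy_ic):
        assert toy_ic["R"] == 0.0

    def test_toy_hand_values(self, toy_ic):
        assert toy_ic["A"] == pytest.approx(math.log(2), abs=1e-12)
        assert toy_ic["B"] == pytest.approx(math.log(4), abs=1e-12)
        assert toy_ic["C"] == pytest.approx(math.log(4), abs=1e-12)

    def test_children_at_least_parents(self, toy_dag, toy_ic):
        for child, parents in toy_dag.parents.items():
            for p in parents:
                assert toy_ic[child] >= toy_ic[p]

    def test_corpus_uniform_siblings_equal(self, toy_dag):
        ic = information_content(toy_dag, mode="corpus",
                                 annotations={"B": 5, "C": 5})
        assert ic["B"] == pytest.approx(ic["C"])
        assert ic["R"] == 0.0

    def test_corpus_requires_counts(self, toy_dag):
        with pytest.raises(ValueError):
            information_content(toy_dag, mode="corpus", annotations={})


class TestSemanticSimilarity:
    def test_lin_self_is_one(self, toy_dag, toy_ic):
        for t in "ABC":
            assert semantic_similarity(toy_dag, toy_ic, t, t, "lin") == pytest.approx(1.0)

    def test_lin_hand_value(self, toy_dag, toy_ic):
        expected = 2 * math.log(2) / (math.log(2) + math.log(4))
        got = semantic_similarity(toy_dag, toy_ic, "A", "C", "lin")
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(2 / 3, abs=1e-12)

    def test_lin_root_mica_zero(self, toy_dag, toy_ic):
        assert semantic_similarity(toy_dag, toy_ic, "B", "C", "lin") == 0.0

    def test_symmetry_and_ranges(self, toy_dag, toy_ic):
        for a, b in itertools.combinations("RABC", 2):
            for metric in ("resnik", "lin", "jc"):
                x = semantic_similarity(toy_dag, toy_ic, a, b, metric)
                y = semantic_similarity(toy_dag, toy_ic, b, a, metric)
                assert x == pytest.approx(y)
            lin = semantic_similarity(toy_dag, toy_ic, a, b, "lin")
            assert 0.0 <= lin <= 1.0
            res = semantic_similarity(toy_dag, toy_ic, a, b, "resnik")
            assert res <= min(toy_ic[a], toy_ic[b]) + 1e-12

    def test_jc_is_one_iff_zero_distance(self, toy_dag, toy_ic):
        assert semantic_similarity(toy_dag, toy_ic, "C", "C", "jc") == pytest.approx(1.0)
        assert semantic_similarity(toy_dag, toy_ic, "B", "C", "jc") < 1.0

    def test_unknown_term_named(self, toy_dag, toy_ic):
        with pytest.raises(KeyError, match="ZZ"):
            semantic_similarity(toy_dag, toy_ic, "A", "ZZ", "lin")

    def test_lin_monotone_along_chain(self):
        """On a chain ontology, moving b away from a never increases lin."""
        for length in range(2, 9):
            terms = [f"T{i}" for i in range(length)]
            parents = {terms[0]: ()}
            for i in range(1, length):
                parents[terms[i]] = (terms[i - 1],)
            dag = OntologyDAG(parents=parents)
            ic = information_content(dag)
            a = terms[-1]
            sims = [semantic_similarity(dag, ic, a, b, "lin") for b in reversed(terms)]
            assert all(x >= y - 1e-12 for x, y in zip(sims, sims[1:]))

    def test_mica_matches_brute_force_on_random_dags(self):
        """Declared MICA algorithm == brute-force max over ancestor intersections."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            terms = [f"T{i}" for i in range(n)]
            parents = {terms[0]: ()}
            for i in range(1, n):
                k = int(rng.integers(1, min(i, 2) + 1))
                ps = rng.choice(i, size=k, replace=False)
                parents[terms[i]] = tuple(sorted(terms[j] for j in ps))
            dag = OntologyDAG(parents=parents)
            ic = information_content(dag)
            a, b = (terms[int(i)] for i in rng.integers(0, n, size=2))
            common = dag.ancestors(a) & dag.ancestors(b)
            brute = max(ic[t] for t in common)
            assert ic[mica(dag, ic, a, b)] == pytest.approx(brute)


class TestFeatures:
    def test_single_member_mean(self):
        df = pd.DataFrame({"item": ["x"], "f1": [3.0], "f2": [4.0]})
        fm = aggregate_features(df)
        assert fm.vector("x") == pytest.approx([3.0, 4.0])

    def test_two_member_mean(self):
        df = pd.DataFrame({"item": ["x", "x"], "f1": [0.0, 2.0], "f2": [0.0, 4.0]})
        assert aggregate_features(df).vector("x") == pytest.approx([1.0, 2.0])

    def test_mean_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(100, 3))
        df = pd.DataFrame(vals, columns=["f1", "f2", "f3"])
        df.insert(0, "item", "c")
        fm = aggregate_features(df)
        # two-pass compensated mean oracle
        oracle = vals.sum(axis=0) / 100
        oracle = oracle + (vals - oracle).sum(axis=0) / 100
        assert np.allclose(fm.vector("c"), oracle, atol=1e-12)

    def test_non_finite_mean_dropped(self, caplog):
        df = pd.DataFrame({"item": ["x", "y"], "f1": [1.0, np.nan]})
        fm = aggregate_features(df)
        assert "y" not in fm
        assert "x" in fm


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1, 1, 0], [1, 1, 0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(math.sqrt(0.5), abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.normal(size=(2, 4))
            c = float(rng.uniform(0.1, 10))
            assert cosine_similarity(c * x, y) == pytest.approx(
                cosine_similarity(x, y), abs=1e-12)

    def test_range(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            x, y = rng.normal(size=(2, 5))
            assert -1.0 - 1e-12 <= cosine_similarity(x, y) <= 1.0 + 1e-12


class TestSimilarityTable:
    def test_top1_neighbours(self):
        scores = {("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.5}
        table = build_similarity_table("ABC", lambda a, b: scores[tuple(sorted((a, b)))], 1)
        assert table.top_neighbors("A", 1) == [("B", 0.9)]
        assert table.top_neighbors("B", 1) == [("A", 0.9)]
        assert table.top_neighbors("C", 1) == [("B", 0.5)]

    def test_full_lists_when_top_n_large(self):
        scores = {("A", "B"): 0.9, ("A", "C"): 0.1, ("B", "C"): 0.5}
        table = build_similarity_table("ABC", lambda a, b: scores[tuple(sorted((a, b)))], 2)
        assert [b for b, _ in table.top_neighbors("A", 10)] == ["B", "C"]

    def test_tie_breaks_by_id(self):
        table = build_similarity_table("ABC", lambda a, b: 0.5, 2)
        assert [b for b, _ in table.top_neighbors("A", 2)] == ["B", "C"]

    def test_symmetry(self, compound_table):
        assert compound_table.similarity("monoamine", "noradrenaline") == 0.836

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            build_similarity_table("AB", lambda a, b: 1.0, 0)

    def test_agrees_with_brute_force_full_ranking(self):
        rng = np.random.default_rng(8)
        items = [f"i{k}" for k in range(12)]
        scores = {tuple(sorted((a, b))): float(rng.random())
                  for i, a in enumerate(items) for b in items[i + 1:]}
        table = build_similarity_table(items, lambda a, b: scores[tuple(sorted((a, b)))],
                                       top_n=len(items) - 1)
        for a in items:
            brute = sorted(((b, scores[tuple(sorted((a, b)))]) for b in items if b != a),
                           key=lambda t: (-t[1], t[0]))
            assert table.top_neighbors(a, len(items) - 1) == brute


class TestTableIO:
    def test_single_line(self):
        table = read_similarity_table(io.StringIO("A\tB\t0.836\n"))
        assert table.similarity("A", "B") == 0.836
        assert table.similarity("B", "A") == 0.836

    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValueError, match="line 2"):
            read_similarity_table(io.StringIO("A\tB\t0.8\nB\tA\t0.7\n"))

    def test_non_numeric_score_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            read_similarity_table(io.StringIO("A\tB\thigh\n"))

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        table = SimilarityTable()
        items = [f"x{k}" for k in range(8)]
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                if rng.random() < 0.4:
                    table.add(a, b, float(rng.random()))
        buf = io.StringIO()
        write_similarity_table(table, buf)
        buf.seek(0)
        back = read_similarity_table(buf)
        assert back.pairs() == table.pairs()
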