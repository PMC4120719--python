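"""Consistency matrix, summaries, and hierarchy integration."""

import re

import pytest

from classalign.instalign import ClassPairScore, annotate_best_pairs, classify_pairs
from classalign.lexalign import LexicalMatch
from classalign.model import DrugClass, build_hierarchy_index
from classalign.report import (
    IntegratedHierarchy,
    consistency_matrix,
    integrate_hierarchies,
    summarize_relations,
)


def _rels(triples):
    return classify_pairs([ClassPairScore(a, b, am, ao, mo) for a, b, am, ao, mo in triples])


class TestConsistencyMatrix:
    @pytest.fixture
    def planted(self):
        a_eligible = {f"A{i}" for i in range(5)}
        b_eligible = {f"B{i}" for i in range(6)}
        rels = _rels(
            [
                ("A0", "B0", 9, 1, 1),   # EQ+, lexically matched  -> consistent
                ("A1", "B1", 10, 2, 2),  # EQ+, lexically matched  -> consistent
                ("A2", "B2", 9, 0, 1),   # EQ+, no lexical match   -> EQ-only
                ("A3", "B3", 2, 5, 5),   # EQ-
            ]
        )
        lex = [
            LexicalMatch("A0", "B0", "exact"),
            LexicalMatch("A1", "B1", "normalized"),
            LexicalMatch("A4", "B4", "exact"),  # lexical-only pair
        ]
        return lex, rels, a_eligible, b_eligible

    def test_cells_match_fixture_ground_truth(self, planted):
        lex, rels, a_el, b_el = planted
        m = consistency_matrix(lex, rels, a_el, b_el)
        assert (m.lex_eq, m.lex_noeq, m.nolex_eq) == (2, 1, 1)
        assert m.nolex_noeq == 30 - 4
        assert m.no_data == 0

    def test_cells_reconcile_with_universe(self, planted):
        lex, rels, a_el, b_el = planted
        m = consistency_matrix(lex, rels, a_el, b_el)
        assert m.cells_total == m.universe_size == len(a_el) * len(b_el)

    def test_empty_lexical_input_zeroes_lex_cells(self, planted):
        _, rels, a_el, b_el = planted
        m = consistency_matrix([], rels, a_el, b_el)
        assert m.lex_eq == 0 and m.lex_noeq == 0

    def test_match_outside_eligible_sets_counts_as_no_data(self, planted):
        lex, rels, a_el, b_el = planted
        lex = lex + [LexicalMatch("A9", "B0", "exact")]  # A9 has no eligible drugs
        m = consistency_matrix(lex, rels, a_el, b_el)
        assert m.no_data == 1
        assert m.cells_total == m.universe_size


class TestSummaries:
    @pytest.fixture
    def tagged_world(self):
        classes = [
            DrugClass("A0", "a0", "A"), DrugClass("A1", "a1", "A"), DrugClass("A2", "a2", "A"),
            DrugClass("B0", "b0", "B", kind="structural"),
            DrugClass("B1", "b1", "B", kind="functional"),
            DrugClass("B2", "b2", "B", kind="structural"),
        ]
        rels = annotate_best_pairs(
            _rels(
                [
                    ("A0", "B0", 9, 1, 1),    # EQ+ to structural
                    ("A1", "B1", 6, 0, 18),   # IN+ (A1 in functional B1)
                    ("A1", "B2", 5, 1, 14),   # IN+ (A1 in structural B2), lower ES
                    ("A2", "B2", 2, 6, 6),    # weak
                ]
            )
        )
        return rels, classes

    def test_counts_equal_hand_tally(self, tagged_world):
        rels, classes = tagged_world
        t = summarize_relations(rels, classes)["relations"].set_index("relation")
        assert t.loc["equivalence (all)", "n_relations"] == 1
        assert t.loc["equivalence (B structural)", "n_relations"] == 1
        assert t.loc["equivalence (B functional)", "n_relations"] == 0
        assert t.loc["inclusion A-in-B (all)", "n_relations"] == 2
        # best inclusion is selected per target kind: one structural, one functional
        assert t.loc["best inclusion A-in-B (all)", "n_relations"] == 2
        assert t.loc["best inclusion A-in-B (B functional)", "n_relations"] == 1
        assert t.loc["best inclusion A-in-B (B structural)", "n_relations"] == 1

    def test_no_functional_classes_zero_rows(self):
        classes = [DrugClass("A0", "a0", "A"), DrugClass("B0", "b0", "B", kind="structural")]
        rels = annotate_best_pairs(_rels([("A0", "B0", 9, 1, 1)]))
        t = summarize_relations(rels, classes)["relations"].set_index("relation")
        assert t.loc["equivalence (B functional)", "n_relations"] == 0

    def test_class_with_equivalence_and_both_inclusion_kinds(self):
        classes = [
            DrugClass("A0", "a0", "A"),
            DrugClass("Beq", "beq", "B", kind="structural"),
            DrugClass("Bst", "bst", "B", kind="structural"),
            DrugClass("Bfn", "bfn", "B", kind="functional"),
        ]
        rels = annotate_best_pairs(
            _rels(
                [
                    ("A0", "Beq", 10, 1, 1),   # best equivalence
                    ("A0", "Bst", 8, 3, 30),   # IS -0.60 -> structural inclusion
                    ("A0", "Bfn", 6, 2, 40),   # IS -0.68 -> functional inclusion
                ]
            )
        )
        cross = summarize_relations(rels, classes)["equivalence_vs_inclusion"]
        row = cross.set_index(["relation", "inclusion_target_kind"]).loc[
            ("equivalence and best inclusion", "both")
        ]
        assert int(row["n_classes"]) == 1


def _class_set():
    a_classes = [
        DrugClass("L01", "Antineoplastic agents", "A", addresses=("L01",)),
        DrugClass("L01A", "Alkylating agents", "A", addresses=("L01A",)),
        DrugClass("L01AA", "Nitrogen mustards", "A", addresses=("L01AA",)),
        DrugClass("L01AB", "Alkyl sulfonates", "A", addresses=("L01AB",)),
    ]
    b_classes = [
        DrugClass("AntineoB", "Antineoplastic Agents", "B", addresses=("D27.505",)),
        DrugClass("AlkB", "Antineoplastic Agents, Alkylating", "B", addresses=("D27.505.100",)),
    ]
    return a_classes, b_classes


class TestIntegration:
    @pytest.fixture
    def merged(self):
        a_classes, b_classes = _class_set()
        rels = _rels(
            [
                ("L01A", "AlkB", 9, 1, 1),     # equivalence (and more)
                ("L01AA", "AlkB", 4, 0, 6),    # inclusion into the B class
                ("L01AB", "AlkB", 3, 0, 7),    # inclusion into the B class
            ]
        )
        h = integrate_hierarchies(
            rels,
            build_hierarchy_index(a_classes),
            build_hierarchy_index(b_classes),
            scope=["L01A", "L01AA", "L01AB"],
        )
        return h

    def test_level4_classes_bridge_into_parent_class(self, merged):
        inc = {(b["from"], b["to"]) for b in merged.bridges if b["type"] == "inclusion"}
        assert ("L01AA", "AlkB") in inc and ("L01AB", "AlkB") in inc

    def test_ancestors_pulled_into_node_set(self, merged):
        assert "L01" in merged.nodes and "AntineoB" in merged.nodes

    def test_bridges_connect_sources_only(self, merged):
        src = {n: attrs["source"] for n, attrs in merged.nodes.items()}
        for b in merged.bridges:
            assert src[b["from"]] != src[b["to"]]

    def test_empty_relations_yield_disconnected_hierarchies(self):
        a_classes, b_classes = _class_set()
        h = integrate_hierarchies(
            [], build_hierarchy_index(a_classes), build_hierarchy_index(b_classes),
            scope=["L01AA", "AlkB"],
        )
        assert h.bridges == []
        assert {"L01AA", "L01A", "L01", "AlkB", "AntineoB"} <= set(h.nodes)

    def test_unknown_scope_id_raises(self):
        a_classes, b_classes = _class_set()
        with pytest.raises(KeyError, match="nope"):
            integrate_hierarchies(
                [], build_hierarchy_index(a_classes), build_hierarchy_index(b_classes),
                scope=["nope"],
            )

    def test_dot_round_trips_through_json(self, merged):
        json_obj = merged.to_json_obj()
        rebuilt = IntegratedHierarchy.from_json_obj(json_obj)
        assert rebuilt.to_json_obj() == json_obj
        dot = merged.to_dot()
        # same node and edge multiset in the DOT rendering
        nodes = re.findall(r'^  "([^"]+)" \[label=', dot, flags=re.M)
        edges = re.findall(r'^  "([^"]+)" -> "([^"]+)"', dot, flags=re.M)
        assert sorted(nodes) == sorted(n["id"] for n in json_obj["nodes"])
        assert len(edges) == len(json_obj["intra_edges"]) + len(json_obj["bridges"])
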