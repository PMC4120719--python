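"""Consistency assessment, summary tables, and hierarchy integration.

The lexical and instance-based alignments are contrasted over the
cross-product of the two instance-eligible class sets: a pair can be
LEX+/EQ+ (consistent), LEX+/EQ- or LEX-/EQ+ (inconsistent), or LEX-/EQ-
(consistent by absence).  Lexical matches involving a class with no
eligible drug cannot be assessed by the instance-based side and are
tallied separately as *no data*.

The equivalence/inclusion bridges can also be materialized as a merged
graph over both hierarchies, for rendering (DOT) or downstream use (JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .instalign import AlignmentRelation
from .lexalign import LexicalMatch
from .model import DrugClass, HierarchyIndex

__all__ = [
    "ConsistencyMatrix",
    "IntegratedHierarchy",
    "consistency_matrix",
    "summarize_relations",
    "integrate_hierarchies",
]


@dataclass
class ConsistencyMatrix:
    """2x2 contingency of lexical vs instance-based equivalence.

    ``lex_eq`` .. ``nolex_noeq`` partition the evaluated universe;
    ``no_data`` counts lexical matches excluded because a side had no
    eligible drugs.  ``nolex_noeq`` is the arithmetic remainder of the
    cross-product, never enumerated.
    """

    lex_eq: int
    lex_noeq: int
    nolex_eq: int
    nolex_noeq: int
    no_data: int
    universe_size: int

    @property
    def cells_total(self) -> int:
        return self.lex_eq + self.lex_noeq + self.nolex_eq + self.nolex_noeq

    def to_dict(self) -> dict:
        return {
            "LEX+/EQ+": self.lex_eq,
            "LEX+/EQ-": self.lex_noeq,
            "LEX-/EQ+": self.nolex_eq,
            "LEX-/EQ-": self.nolex_noeq,
            "no_data": self.no_data,
            "universe_size": self.universe_size,
        }


def consistency_matrix(
    lex: Iterable[LexicalMatch],
    rels: Iterable[AlignmentRelation],
    a_eligible: set[str],
    b_eligible: set[str],
) -> ConsistencyMatrix:
    """Classify every cross-product pair LEX+/- x EQ+/-.

    The universe is ``|a_eligible| * |b_eligible|``.  Lexical matches where
    either class is outside the instance-eligible sets go to ``no_data``.
    """
    eq_pairs = {
        (r.pair.a_class_id, r.pair.b_class_id)
        for r in rels
        if r.eq_flag and r.pair.a_class_id in a_eligible and r.pair.b_class_id in b_eligible
    }
    lex_pairs: set[tuple[str, str]] = set()
    no_data = 0
    for m in lex:
        if m.a_class_id in a_eligible and m.b_class_id in b_eligible:
            lex_pairs.add((m.a_class_id, m.b_class_id))
        else:
            no_data += 1
    universe = len(a_eligible) * len(b_eligible)
    lex_eq = len(lex_pairs & eq_pairs)
    lex_noeq = len(lex_pairs) - lex_eq
    nolex_eq = len(eq_pairs) - lex_eq
    nolex_noeq = universe - lex_eq - lex_noeq - nolex_eq
    return ConsistencyMatrix(lex_eq, lex_noeq, nolex_eq, nolex_noeq, no_data, universe)


def _kind_of(class_id: str, kinds: Mapping[str, str]) -> str:
    return kinds.get(class_id, "unspecified")


def summarize_relations(
    rels: Sequence[AlignmentRelation],
    classes: Iterable[DrugClass],
    config: "AlignConfig | None" = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables over the classified relations.

    ``relations``: strong-relation counts and unique classes per side,
    split by relation type, direction, and the second source's
    structural/functional kind.  Because the second source distinguishes
    structural from functional classes, the best inclusion for a
    first-source class is selected *per target kind* — a class may have
    both a best structural container and a best functional one.

    ``equivalence_vs_inclusion``: for first-source classes with any strong
    relation, the cross of having an equivalence with having concomitant
    best inclusions into structural and/or functional classes.
    """
    from .instalign import AlignConfig, best_inclusion

    config = config or AlignConfig()
    kinds = {c.class_id: c.kind for c in classes}
    rows = []

    def _row(label: str, sel: list[AlignmentRelation]) -> dict:
        return {
            "relation": label,
            "n_relations": len(sel),
            "n_unique_a": len({r.pair.a_class_id for r in sel}),
            "n_unique_b": len({r.pair.b_class_id for r in sel}),
        }

    eq = [r for r in rels if r.eq_flag]
    rows.append(_row("equivalence (all)", eq))
    for kind in ("structural", "functional"):
        rows.append(_row(f"equivalence (B {kind})", [r for r in eq if _kind_of(r.pair.b_class_id, kinds) == kind]))
    inc_a = [r for r in rels if r.in_flag and r.direction == "A_in_B"]
    inc_b = [r for r in rels if r.in_flag and r.direction == "B_in_A"]
    rows.append(_row("inclusion A-in-B (all)", inc_a))
    rows.append(_row("inclusion B-in-A (all)", inc_b))

    # per-kind best inclusion selection for A-side classes
    by_rel = {(r.pair.a_class_id, r.pair.b_class_id): r for r in rels}
    scores_by_kind: dict[str, list] = {}
    for r in rels:
        scores_by_kind.setdefault(_kind_of(r.pair.b_class_id, kinds), []).append(r.pair)
    a_ids_all = sorted({r.pair.a_class_id for r in rels})
    best_a_by_kind: dict[str, list[AlignmentRelation]] = {}
    best_inc_kinds_per_a: dict[str, set[str]] = {}
    for kind, kind_scores in sorted(scores_by_kind.items()):
        for a_id in a_ids_all:
            s = best_inclusion(a_id, kind_scores, config)
            if s is not None and s.a_class_id == a_id:
                best_a_by_kind.setdefault(kind, []).append(by_rel[(s.a_class_id, s.b_class_id)])
                best_inc_kinds_per_a.setdefault(a_id, set()).add(kind)
    best_a = sorted(
        {id(r): r for sel in best_a_by_kind.values() for r in sel}.values(),
        key=lambda r: (r.pair.a_class_id, r.pair.b_class_id),
    )
    best_b = [
        by_rel[(s.a_class_id, s.b_class_id)]
        for b_id in sorted({r.pair.b_class_id for r in rels})
        if (s := best_inclusion(b_id, [r.pair for r in rels], config)) is not None
        and s.b_class_id == b_id
    ]
    rows.append(_row("best inclusion A-in-B (all)", best_a))
    for kind in ("structural", "functional"):
        rows.append(_row(f"best inclusion A-in-B (B {kind})", best_a_by_kind.get(kind, [])))
    rows.append(_row("best inclusion B-in-A (all)", best_b))
    relations_df = pd.DataFrame(rows)

    # equivalence vs concomitant best-inclusion kinds, per A-side class
    a_ids = {r.pair.a_class_id for r in rels if r.eq_flag or r.in_flag}
    cross: dict[tuple[str, str], int] = {}
    for a_id in sorted(a_ids):
        has_eq = any(r.eq_flag for r in rels if r.pair.a_class_id == a_id)
        inc_kinds = best_inc_kinds_per_a.get(a_id, set())
        if not has_eq and not inc_kinds:
            continue
        if has_eq and inc_kinds:
            row_label = "equivalence and best inclusion"
        elif has_eq:
            row_label = "equivalence only"
        else:
            row_label = "best inclusion only"
        if {"structural", "functional"} <= inc_kinds:
            col = "both"
        elif "structural" in inc_kinds:
            col = "structural only"
        elif "functional" in inc_kinds:
            col = "functional only"
        else:
            col = "none"
        cross[(row_label, col)] = cross.get((row_label, col), 0) + 1
    cross_df = (
        pd.Series(cross).rename_axis(["relation", "inclusion_target_kind"]).reset_index(name="n_classes")
        if cross
        else pd.DataFrame(columns=["relation", "inclusion_target_kind", "n_classes"])
    )
    return {"relations": relations_df, "equivalence_vs_inclusion": cross_df}


@dataclass
class IntegratedHierarchy:
    """Both hierarchies plus typed cross-source bridge edges.

    ``nodes`` maps node id to attributes (source, label); ``intra_edges``
    are child -> parent within a source; ``bridges`` are cross-source
    edges typed ``equivalence`` (undirected, stored once with sorted
    endpoints) or ``inclusion`` (directed contained -> container), each
    carrying the pair's scores.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    intra_edges: list[tuple[str, str]] = field(default_factory=list)
    bridges: list[dict] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        return {
            "nodes": [{"id": n, **attrs} for n, attrs in sorted(self.nodes.items())],
            "intra_edges": [{"child": c, "parent": p} for c, p in sorted(self.intra_edges)],
            "bridges": sorted(self.bridges, key=lambda b: (b["type"], b["from"], b["to"])),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "IntegratedHierarchy":
        h = cls()
        for n in obj["nodes"]:
            attrs = dict(n)
            h.nodes[attrs.pop("id")] = attrs
        h.intra_edges = [(e["child"], e["parent"]) for e in obj["intra_edges"]]
        h.bridges = [dict(b) for b in obj["bridges"]]
        return h

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_obj(), indent=indent, sort_keys=True)

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the same node and edge multiset."""
        obj = self.to_json_obj()
        lines = ["digraph integrated {", "  rankdir=BT;"]
        for n in obj["nodes"]:
            label = n.get("label", n["id"]).replace('"', r"\"")
            lines.append(
                f'  "{n["id"]}" [label="{label}", source="{n.get("source", "")}"];'
            )
        for e in obj["intra_edges"]:
            lines.append(f'  "{e["child"]}" -> "{e["parent"]}" [kind="intra"];')
        for b in obj["bridges"]:
            style = "dashed" if b["type"] == "equivalence" else "bold"
            extra = ", dir=none" if b["type"] == "equivalence" else ""
            lines.append(
                f'  "{b["from"]}" -> "{b["to"]}" '
                f'[kind="{b["type"]}", style={style}{extra}, es="{b["es"]:.2f}", is="{b["is"]:.2f}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def integrate_hierarchies(
    rels: Sequence[AlignmentRelation],
    a_index: HierarchyIndex,
    b_index: HierarchyIndex,
    scope: Iterable[str] | None = None,
) -> IntegratedHierarchy:
    """Merged hierarchy over the scope classes, their ancestors, and the
    classes bridged to them by strong relations.

    Bridge edges are added for every EQ+ pair (undirected equivalence) and
    IN+ pair (directed contained -> container) with both endpoints in the
    induced node set.  Unknown scope ids raise ``KeyError``.
    """
    known = set(a_index.ancestors) | set(b_index.ancestors)
    if scope is None:
        scope_set = {r.pair.a_class_id for r in rels} | {r.pair.b_class_id for r in rels}
    else:
        scope_set = set(scope)
        unknown = scope_set - known
        if unknown:
            raise KeyError(f"unknown scope class ids: {sorted(unknown)}")

    strong = [r for r in rels if r.eq_flag or r.in_flag]
    # pull in bridged partners of scoped classes before closing over ancestors
    for r in strong:
        if r.pair.a_class_id in scope_set or r.pair.b_class_id in scope_set:
            scope_set.update((r.pair.a_class_id, r.pair.b_class_id))

    h = IntegratedHierarchy()

    def _add_side(index: HierarchyIndex, side_ids: set[str]) -> None:
        closed = set(side_ids)
        for cid in side_ids:
            closed |= index.ancestor_ids(cid)
        for cid in closed:
            h.nodes[cid] = {"source": index.source, "label": index.labels.get(cid, cid)}
        for cid in closed:
            for p in index.parent_ids(cid):
                if p in closed:
                    h.intra_edges.append((cid, p))

    _add_side(a_index, {c for c in scope_set if c in a_index.ancestors})
    _add_side(b_index, {c for c in scope_set if c in b_index.ancestors})

    for r in strong:
        a_id, b_id = r.pair.a_class_id, r.pair.b_class_id
        if a_id not in h.nodes or b_id not in h.nodes:
            continue
        if r.eq_flag:
            u, v = sorted((a_id, b_id))
            h.bridges.append(
                {"from": u, "to": v, "type": "equivalence", "es": r.pair.es, "is": r.pair.is_}
            )
        if r.in_flag:
            contained, container = (a_id, b_id) if r.direction == "A_in_B" else (b_id, a_id)
            h.bridges.append(
                {
                    "from": contained,
                    "to": container,
                    "type": "inclusion",
                    "es": r.pair.es,
                    "is": r.pair.is_,
                }
            )
    return h
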