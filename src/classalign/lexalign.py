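"""Lexical alignment of class names.

Three matching techniques, tried in order of strictness per class:

1. **exact** — case-folded label identity;
2. **normalized** — identity of normalized keys (case, punctuation and
   hyphen variation, possessives, rule-based singularization, word order);
3. **cosynonymy** — both names are synonyms of the same concept in a
   concept-keyed synonym table, without being identical strings.

Normalization approximates the behaviour of biomedical lexical-variant
normalizers: it handles inflectional variation only — no derivational
morphology and no abbreviation expansion (``HMG CoA`` will not match
``Hydroxymethylglutaryl-CoA``); the synonym table is expected to carry
such equivalences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import DrugClass

__all__ = ["SynonymTable", "LexicalMatch", "normalize_term", "lexical_align"]

_NON_WORD = re.compile(r"[^0-9a-z']+")

# tokens never singularized: endings that look plural but are not
_SINGULARIZE_EXCEPTIONS = frozenset(
    {
        "is", "as", "us", "its", "this", "has", "was", "gas", "plus", "virus",
        "lens", "series", "species", "bis", "tris", "mumps", "herpes",
        "diabetes", "rabies", "scabies", "measles",
    }
)


def _singularize(token: str) -> str:
    if token in _SINGULARIZE_EXCEPTIONS or len(token) <= 2:
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "shes", "ches", "xes", "zes")):
        return token[:-2]
    if token.endswith("ss") or token.endswith("us"):
        return token
    if token.endswith("s"):
        return token[:-1]
    return token


def normalize_term(term: str) -> str:
    """Normalized key for a class name or synonym term.

    Lowercase; hyphens and punctuation become spaces; possessives are
    stripped; tokens are singularized by suffix rules; tokens are sorted
    and joined with single spaces, making the key word-order invariant.
    Idempotent by construction.  An empty result never matches anything.
    """
    s = term.lower().replace("’", "'")
    tokens = []
    for raw in _NON_WORD.split(s):
        if not raw:
            continue
        if raw.endswith("'s"):
            raw = raw[:-2]
        raw = raw.strip("'")
        if not raw:
            continue
        tokens.append(_singularize(raw))
    return " ".join(sorted(tokens))


@dataclass
class SynonymTable:
    """Concept-keyed synonyms with an inverted index under the normalizer."""

    concept_terms: dict[str, set[str]] = field(default_factory=dict)
    _exact: dict[str, set[str]] = field(default_factory=dict)
    _norm: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SynonymTable":
        t = cls()
        for concept_id, term in pairs:
            t.add(concept_id, term)
        return t

    def add(self, concept_id: str, term: str) -> None:
        self.concept_terms.setdefault(concept_id, set()).add(term)
        self._exact.setdefault(term.casefold(), set()).add(concept_id)
        key = normalize_term(term)
        if key:
            self._norm.setdefault(key, set()).add(concept_id)

    def concepts_exact(self, label: str) -> set[str]:
        return set(self._exact.get(label.casefold(), set()))

    def concepts_normalized(self, label: str) -> set[str]:
        key = normalize_term(label)
        return set(self._norm.get(key, set())) if key else set()


@dataclass(frozen=True)
class LexicalMatch:
    """A matched cross-source class-name pair.

    ``concept_id`` is set iff the match was established through cosynonymy
    (a shared concept rather than string identity); ``ambiguous`` marks
    matches reached through more than one concept.
    """

    a_class_id: str
    b_class_id: str
    method: str  # exact | normalized | cosynonym
    concept_id: str | None = None
    ambiguous: bool = False


def _index_by(classes: Iterable[DrugClass], keyfn) -> dict[str, list[DrugClass]]:
    out: dict[str, list[DrugClass]] = {}
    for c in classes:
        k = keyfn(c.label)
        if k:
            out.setdefault(k, []).append(c)
    return out


def lexical_align(
    a_classes: Iterable[DrugClass],
    b_classes: Iterable[DrugClass],
    syn: SynonymTable | None = None,
) -> list[LexicalMatch]:
    """Match every A-side class against B-side labels and synonyms.

    Per A-class, the exact technique is tried first (against B labels and,
    through the synonym table, against concept terms); only when it yields
    nothing is the normalized technique tried.  Matches established through
    a shared concept are tagged ``cosynonym``.  One-to-many matches are
    all returned.
    """
    a_classes = list(a_classes)
    b_classes = list(b_classes)
    syn = syn or SynonymTable()
    b_exact = _index_by(b_classes, lambda s: s.casefold())
    b_norm = _index_by(b_classes, normalize_term)
    # B classes keyed by the concepts their labels belong to
    b_by_concept: dict[str, list[DrugClass]] = {}
    for b in b_classes:
        for cid in syn.concepts_exact(b.label) | syn.concepts_normalized(b.label):
            b_by_concept.setdefault(cid, []).append(b)

    out: list[LexicalMatch] = []
    for a in a_classes:
        found = _match_stage(
            a, b_exact.get(a.label.casefold(), []), syn.concepts_exact(a.label), b_by_concept
        )
        if not found:
            key = normalize_term(a.label)
            found = _match_stage(
                a,
                b_norm.get(key, []) if key else [],
                syn.concepts_normalized(a.label),
                b_by_concept,
                normalized=True,
            )
        out.extend(found)
    return out


def _match_stage(
    a: DrugClass,
    direct_hits: list[DrugClass],
    a_concepts: set[str],
    b_by_concept: Mapping[str, list[DrugClass]],
    normalized: bool = False,
) -> list[LexicalMatch]:
    method = "normalized" if normalized else "exact"
    matches: dict[str, LexicalMatch] = {}
    for b in direct_hits:
        matches[b.class_id] = LexicalMatch(a.class_id, b.class_id, method)
    concept_hits: dict[str, set[str]] = {}  # b_class_id -> concepts
    for cid in a_concepts:
        for b in b_by_concept.get(cid, []):
            concept_hits.setdefault(b.class_id, set()).add(cid)
    for b_id, cids in concept_hits.items():
        if b_id in matches:  # string identity wins over the concept route
            continue
        cid = sorted(cids)[0]
        matches[b_id] = LexicalMatch(
            a.class_id, b_id, "cosynonym", concept_id=cid, ambiguous=len(cids) > 1
        )
    # ambiguity across concepts when the a-label itself is ambiguous
    if len(a_concepts) > 1:
        matches = {
            k: (
                m
                if m.method != "cosynonym" or m.ambiguous
                else LexicalMatch(m.a_class_id, m.b_class_id, m.method, m.concept_id, True)
            )
            for k, m in matches.items()
        }
    return list(matches.values())
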