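"""Instance-based alignment: pairwise scoring, classification, best pairs.

Two classes are compared through the eligible drugs they share.  For a
class A (first source) and a class M (second source) with ``am`` shared
members, ``a`` members specific to A and ``m`` members specific to M:

* the **equivalence score** is a modified Jaccard coefficient that damps
  the similarity of pairs sharing few drugs::

      ES(A, M) = sqrt(am * (am - 0.8)) / (a + m + am)

  It satisfies ``0 <= ES < 1`` and ``ES < JC`` wherever ``am >= 1``.

* the **inclusion score** combines the one-sidedness of the non-shared
  drugs with the coverage of the smaller class by the larger::

      IS(A, M) = ((a - m) / (a + m)) * (am / min(am + a, am + m))

  with ``IS = 0`` when ``a = m = 0`` (identical member sets).  The sign is
  directional: ``IS = -1`` means A is strictly contained in M, ``+1`` the
  reverse.

Pairs with ``ES`` at or above the threshold (default 0.5) are flagged
equivalent (EQ+); pairs with ``|IS|`` at or above the threshold are
flagged inclusions (IN+).  For each class the best equivalence partner is
the pair with the highest ES; the best inclusion partner is the *first*
pair in descending-ES order whose inclusion score points the right way —
not the pair with the highest |IS|, which would favour the broadest
possible container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .membership import MembershipSet

__all__ = [
    "ClassPairScore",
    "AlignConfig",
    "AlignmentRelation",
    "equivalence_score",
    "inclusion_score",
    "round_score",
    "score_all_pairs",
    "classify_pairs",
    "best_equivalence",
    "best_inclusion",
    "annotate_best_pairs",
]


def equivalence_score(am: int, a_only: int, m_only: int) -> float:
    """Modified Jaccard coefficient penalizing small intersections.

    ``sqrt(am * max(am - 0.8, 0)) / (am + a_only + m_only)``; the clamp
    only matters at ``am = 0`` where the score is 0.
    """
    if am < 0 or a_only < 0 or m_only < 0:
        raise ValueError("counts must be non-negative")
    total = am + a_only + m_only
    if total == 0:
        raise ValueError("equivalence score undefined for two empty classes")
    return math.sqrt(am * max(am - 0.8, 0.0)) / total


def inclusion_score(am: int, a_only: int, m_only: int) -> float:
    """Signed one-sidedness times coverage.

    Negative values mean the first-source class is contained in the
    second-source class; positive the reverse.  Undefined (raises) for
    disjoint classes; 0 for identical member sets.
    """
    if am < 1:
        raise ValueError("inclusion score undefined for disjoint classes (am = 0)")
    if a_only < 0 or m_only < 0:
        raise ValueError("counts must be non-negative")
    if a_only == 0 and m_only == 0:
        return 0.0
    one_sided = (a_only - m_only) / (a_only + m_only)
    coverage = am / min(am + a_only, am + m_only)
    return one_sided * coverage


def round_score(x: float, ndigits: int = 2) -> float:
    """Round half-up (away from zero) to ``ndigits``, for report output."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassPairScore:
    """Counts and scores for one cross-source class pair (am >= 1)."""

    a_class_id: str
    b_class_id: str
    am: int
    a_only: int
    m_only: int

    @property
    def jc(self) -> float:
        return self.am / (self.am + self.a_only + self.m_only)

    @property
    def es(self) -> float:
        return equivalence_score(self.am, self.a_only, self.m_only)

    @property
    def is_(self) -> float:
        return inclusion_score(self.am, self.a_only, self.m_only)


@dataclass(frozen=True)
class AlignConfig:
    es_threshold: float = 0.5
    is_threshold: float = 0.5
    rounding: int = 2

    def __post_init__(self) -> None:
        for name in ("es_threshold", "is_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class AlignmentRelation:
    """A classified pair: equivalence and/or directed inclusion flags.

    ``direction`` is ``A_in_B`` when the inclusion score is negative
    (first-source class contained), ``B_in_A`` when positive, ``none``
    when the pair is not a strong inclusion.
    """

    pair: ClassPairScore
    eq_flag: bool
    in_flag: bool
    direction: str  # A_in_B | B_in_A | none
    best_equivalence_for: set[str] = field(default_factory=set)
    best_inclusion_for: set[str] = field(default_factory=set)


def score_all_pairs(a_sets: MembershipSet, b_sets: MembershipSet) -> list[ClassPairScore]:
    """All cross-source pairs sharing at least one eligible drug.

    Uses an inverted drug -> classes index so the cost is proportional to
    actual co-membership rather than to the full cross-product.
    """
    drug_to_b: dict[str, list[str]] = {}
    for b_id, members in b_sets.members_eligible.items():
        for d in members:
            drug_to_b.setdefault(d, []).append(b_id)

    shared: dict[tuple[str, str], int] = {}
    for a_id, members in a_sets.members_eligible.items():
        for d in members:
            for b_id in drug_to_b.get(d, ()):
                key = (a_id, b_id)
                shared[key] = shared.get(key, 0) + 1

    out: list[ClassPairScore] = []
    for (a_id, b_id), am in sorted(shared.items()):
        na = len(a_sets.members_eligible[a_id])
        nb = len(b_sets.members_eligible[b_id])
        out.append(ClassPairScore(a_id, b_id, am, na - am, nb - am))
    return out


def classify_pairs(
    scores: Iterable[ClassPairScore], config: AlignConfig | None = None
) -> list[AlignmentRelation]:
    """Flag each pair EQ+/EQ- and IN+/IN- at the configured thresholds.

    Threshold comparisons use >=.  A pair can be both EQ+ and IN+.
    """
    config = config or AlignConfig()
    out = []
    for s in scores:
        eq = s.es >= config.es_threshold
        inc = abs(s.is_) >= config.is_threshold
        if not inc:
            direction = "none"
        else:
            direction = "A_in_B" if s.is_ < 0 else "B_in_A"
        out.append(AlignmentRelation(s, eq, inc, direction))
    return out


def _candidate_order(class_id: str, scores: Iterable[ClassPairScore]):
    """This class's pairs in descending-ES order; ties broken by larger
    shared count, then lexicographically smaller partner id."""
    mine = []
    for s in scores:
        if s.a_class_id == class_id:
            mine.append((s, s.b_class_id))
        elif s.b_class_id == class_id:
            mine.append((s, s.a_class_id))
    mine.sort(key=lambda t: (-t[0].es, -t[0].am, t[1]))
    return mine


def best_equivalence(
    class_id: str,
    scores: Sequence[ClassPairScore],
    config: AlignConfig | None = None,
) -> ClassPairScore | None:
    """Max-ES pair involving ``class_id`` with ES at or above threshold."""
    config = config or AlignConfig()
    for s, _partner in _candidate_order(class_id, scores):
        if s.es >= config.es_threshold:
            return s
        break  # sorted by ES: the first pair below threshold ends the search
    return None


def best_inclusion(
    class_id: str,
    scores: Sequence[ClassPairScore],
    config: AlignConfig | None = None,
) -> ClassPairScore | None:
    """First pair (descending ES) whose inclusion makes ``class_id`` the
    contained side with |IS| at or above threshold.

    The best container is the *smallest* class covering the contained class
    well, which is why candidates are ranked by ES — the pair with the
    highest |IS| would typically name the broadest class.
    """
    config = config or AlignConfig()
    for s, _partner in _candidate_order(class_id, scores):
        if abs(s.is_) < config.is_threshold:
            continue
        contained_is_a = s.is_ < 0
        if contained_is_a and s.a_class_id == class_id:
            return s
        if not contained_is_a and s.b_class_id == class_id:
            return s
    return None


def annotate_best_pairs(
    relations: Sequence[AlignmentRelation], config: AlignConfig | None = None
) -> list[AlignmentRelation]:
    """Mark, on each relation, the classes for which it is the best
    equivalence and/or best inclusion pair."""
    config = config or AlignConfig()
    scores = [r.pair for r in relations]
    by_key = {(r.pair.a_class_id, r.pair.b_class_id): r for r in relations}
    class_ids = {s.a_class_id for s in scores} | {s.b_class_id for s in scores}
    for cid in sorted(class_ids):
        be = best_equivalence(cid, scores, config)
        if be is not None:
            by_key[(be.a_class_id, be.b_class_id)].best_equivalence_for.add(cid)
        bi = best_inclusion(cid, scores, config)
        if bi is not None:
            by_key[(bi.a_class_id, bi.b_class_id)].best_inclusion_for.add(cid)
    return list(relations)
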