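"""Asserted and inferred drug-class membership.

Coded (ATC-style) sources: a level-5 drug code asserts membership to its
level-4 chemical class, and membership is inferred upward to the level-3
and level-2 classes by prefix arithmetic; level-1 classes are ignored.

Tree-numbered (MeSH-style) sources: membership is asserted through three
kinds of edges — a *pharmacologic action* edge from a drug to a functional
class, a *heading mapped to* edge from a supplementary-record drug to a
structural class, and a *direct parent* edge from a descriptor-level drug
to its parent descriptor.  When a supplementary record is heading-mapped
to another *drug* (a drug descriptor) rather than a class, it inherits that
descriptor's structural classes instead (one indirection step).  Membership
is then inferred to every ancestor of each asserted class via tree numbers,
within the same channel; top-level classes are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import Drug, DrugClass, HierarchyIndex, is_atc_code, parse_atc_code

logger = logging.getLogger(__name__)

__all__ = [
    "MembershipPair",
    "MembershipSet",
    "MembershipLink",
    "atc_memberships",
    "mesh_memberships",
    "materialize_membership",
]

ASSERTED = "asserted"
INFERRED = "inferred"


@dataclass(frozen=True)
class MembershipPair:
    """One (ingredient, class) membership with its provenance and channel.

    Channel is ``coded`` for prefix-derived sources, ``structural`` or
    ``functional`` for tree-numbered sources.
    """

    ingredient_id: str
    class_id: str
    provenance: str  # asserted | inferred
    channel: str  # structural | functional | coded


@dataclass(frozen=True)
class MembershipLink:
    """A raw membership edge from the interchange table.

    relation: ``pa`` (pharmacologic action), ``hm`` (heading mapped to),
    ``parent`` (descriptor drug -> direct parent), ``level5`` (coded drug ->
    asserted class).
    """

    drug_id: str
    target_id: str
    relation: str


@dataclass
class MembershipSet:
    """Per-class member-ingredient sets, with a restriction to the eligible
    universe used by the instance-based scorer."""

    members_all: dict[str, set[str]] = field(default_factory=dict)
    members_eligible: dict[str, set[str]] = field(default_factory=dict)
    n_asserted: int = 0
    n_inferred: int = 0

    def members(self, class_id: str) -> set[str]:
        return self.members_all.get(class_id, set())

    def eligible_members(self, class_id: str) -> set[str]:
        return self.members_eligible.get(class_id, set())


def _dedupe(pairs: Iterable[MembershipPair]) -> list[MembershipPair]:
    """One pair per (ingredient, class); asserted wins over inferred."""
    best: dict[tuple[str, str], MembershipPair] = {}
    for p in pairs:
        key = (p.ingredient_id, p.class_id)
        prev = best.get(key)
        if prev is None or (prev.provenance == INFERRED and p.provenance == ASSERTED):
            best[key] = p
    return list(best.values())


def atc_memberships(
    drugs: Sequence[Drug],
    classes: Sequence[DrugClass],
    index: HierarchyIndex,
    links: Sequence[MembershipLink] = (),
) -> list[MembershipPair]:
    """Membership pairs for a coded source.

    Asserted pairs link each level-5 drug to its level-4 prefix class;
    inferred pairs link it to the level-3 and level-2 prefix classes.
    Level-1 classes and excluded (combination/top-level) classes receive no
    pairs.  Explicit ``level5`` edges in ``links`` are honoured as asserted
    input and deduplicated against the derived pairs.  A level-5 code with
    no class above it is logged as an orphan.
    """
    eligible_ids = {c.class_id for c in classes if c.is_eligible}
    by_addr = index.address_to_class
    by_id = {c.class_id: c for c in classes}
    pairs: list[MembershipPair] = []

    explicit: dict[str, set[str]] = {}
    for ln in links:
        if ln.relation == "level5":
            explicit.setdefault(ln.drug_id, set()).add(ln.target_id)

    for d in drugs:
        if d.ingredient_id is None:
            continue
        code = d.drug_id.upper()
        targets: list[tuple[str, str]] = []  # (class_id, provenance)
        if is_atc_code(code) and parse_atc_code(code)["level"] == 5:
            prefixes = parse_atc_code(code)["ancestors"]  # [l1, l2, l3, l4]
            # walk specific -> general; a combination class blocks both its
            # own membership and any inference through it (a drug asserted
            # into a combination class is a combination drug)
            for pre, prov in zip(reversed(prefixes[1:]), (ASSERTED, INFERRED, INFERRED)):
                cid = by_addr.get(pre)
                if cid is not None and by_id[cid].is_combination:
                    break  # nothing above a combination class either
                if cid is not None:
                    targets.append((cid, prov))
        for cid in explicit.get(d.drug_id, ()):
            targets.append((cid, ASSERTED))
            for anc in index.ancestor_ids(cid):
                targets.append((anc, INFERRED))
        if not targets:
            if is_atc_code(code) and parse_atc_code(code)["level"] == 5:
                logger.info("orphan coded drug %s: no class above it", d.drug_id)
            continue
        for cid, prov in targets:
            cls = by_id.get(cid)
            if cls is not None and cls.level == 1:
                continue
            if cid in eligible_ids:
                pairs.append(MembershipPair(d.ingredient_id, cid, prov, "coded"))
    return _dedupe(pairs)


def mesh_memberships(
    drugs: Sequence[Drug],
    classes: Sequence[DrugClass],
    index: HierarchyIndex,
    links: Sequence[MembershipLink],
) -> list[MembershipPair]:
    """Membership pairs for a tree-numbered source.

    See the module docstring for the assertion rules.  Inference adds every
    ancestor (via all tree numbers) of each asserted class, preserving the
    structural/functional channel; excluded classes are skipped.  Edges to
    ids that are neither a class nor a drug are logged as dangling.
    """
    by_id = {c.class_id: c for c in classes}
    eligible_ids = {c.class_id for c in classes if c.is_eligible}
    drug_ids = {d.drug_id for d in drugs}
    ingredient_of = {d.drug_id: d.ingredient_id for d in drugs}

    # direct structural parents of each descriptor drug (relation=parent)
    parent_classes: dict[str, set[str]] = {}
    for ln in links:
        if ln.relation == "parent":
            parent_classes.setdefault(ln.drug_id, set()).add(ln.target_id)

    asserted: list[tuple[str, str, str]] = []  # (drug_id, class_id, channel)
    for ln in links:
        if ln.relation == "pa":
            asserted.append((ln.drug_id, ln.target_id, "functional"))
        elif ln.relation == "hm":
            if ln.target_id in by_id:
                asserted.append((ln.drug_id, ln.target_id, "structural"))
            elif ln.target_id in drug_ids:
                # SCR mapped to a drug descriptor: substitute that
                # descriptor's structural classes (one indirection step)
                for cid in parent_classes.get(ln.target_id, ()):
                    asserted.append((ln.drug_id, cid, "structural"))
            else:
                logger.warning("dangling heading-mapped-to target %r", ln.target_id)
        elif ln.relation == "parent":
            asserted.append((ln.drug_id, ln.target_id, "structural"))
        elif ln.relation == "level5":
            pass  # coded-source edge, not ours
        else:
            raise ValueError(f"unknown membership relation {ln.relation!r}")

    pairs: list[MembershipPair] = []
    for drug_id, cid, channel in asserted:
        ing = ingredient_of.get(drug_id)
        if ing is None:
            if drug_id not in drug_ids:
                logger.warning("dangling membership edge from unknown drug %r", drug_id)
            continue
        if cid not in by_id:
            logger.warning("dangling membership edge to unknown class %r", cid)
            continue
        if cid in eligible_ids:
            pairs.append(MembershipPair(ing, cid, ASSERTED, channel))
        for anc in index.ancestor_ids(cid):
            if anc in eligible_ids:
                pairs.append(MembershipPair(ing, anc, INFERRED, channel))
    return _dedupe(pairs)


def materialize_membership(
    pairs: Iterable[MembershipPair],
    universe: set[str],
) -> MembershipSet:
    """Per-class member sets plus their restriction to the eligible universe."""
    ms = MembershipSet()
    for p in pairs:
        ms.members_all.setdefault(p.class_id, set()).add(p.ingredient_id)
        if p.ingredient_id in universe:
            ms.members_eligible.setdefault(p.class_id, set()).add(p.ingredient_id)
        if p.provenance == ASSERTED:
            ms.n_asserted += 1
        else:
            ms.n_inferred += 1
    return ms
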