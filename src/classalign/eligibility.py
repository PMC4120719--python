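"""Drug normalization and class eligibility filtering.

The common reference for the alignment is built in three steps: drugs from
each source are normalized to base-form ingredients through a normalization
map (salts and esters collapse onto their base ingredient), the drug
universe is restricted to clinically relevant ingredients present in *both*
sources, and classes are filtered by three rules — top-level classes are
dropped, combination classes are dropped (a literal, case-insensitive
substring test on the class label and on all ancestor labels), and classes
with no eligible member drug, directly or through a subclass, are dropped.

Two nested class sets result: the *lexical-eligible* set (top-level and
combination exclusions only) used by name matching, and the smaller
*instance-eligible* set (additionally requiring a non-empty eligible member
set) used by instance-based scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, TYPE_CHECKING

from .model import Drug, DrugClass, HierarchyIndex

if TYPE_CHECKING:  # pragma: no cover
    from .membership import MembershipSet

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationMap",
    "EligibleUniverse",
    "EligibilityConfig",
    "normalize_drugs",
    "restrict_clinical",
    "mark_combination_classes",
    "mark_top_level_classes",
    "eligible_classes",
    "build_universe",
]


@dataclass
class NormalizationMap:
    """Maps precise drug forms to base ingredients and records clinical status.

    ``precise_to_ingredient`` is functional: each source-local drug id maps
    to exactly one reference ingredient id.  Drugs absent from the map are
    base forms and normalize to their own id.
    """

    precise_to_ingredient: dict[str, str] = field(default_factory=dict)
    clinical_ingredients: set[str] = field(default_factory=set)
    source_to_ingredients: dict[str, set[str]] = field(default_factory=dict)

    def ingredient_for(self, drug_id: str) -> str:
        return self.precise_to_ingredient.get(drug_id, drug_id)


@dataclass
class EligibilityConfig:
    """Knobs for the class filters.

    ``excluded_top_addresses`` lists, per source, additional address roots
    (beyond depth-1 addresses) whose owning classes are treated as
    top-level — e.g. the roots of a pharmacologic-action branch.
    """

    combination_token: str = "combination"
    excluded_top_addresses: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class EligibleUniverse:
    """The common reference: shared clinical ingredients and eligible classes."""

    eligible_drugs: set[str]
    lexical_classes: dict[str, set[str]] = field(default_factory=dict)
    instance_classes: dict[str, set[str]] = field(default_factory=dict)


def normalize_drugs(drugs: Iterable[Drug], nmap: NormalizationMap) -> list[Drug]:
    """Assign each drug its reference ingredient id; merge duplicates.

    Precise forms (salts/esters) are mapped through ``nmap``; base forms
    keep their own id.  Two records of one source collapsing onto the same
    ingredient are merged into a single record (clinical if any of them
    was).  A precise form with no mapping is unmappable: it is excluded
    and the count is logged.
    """
    merged: dict[tuple[str, str], Drug] = {}
    unmappable = 0
    for d in drugs:
        if d.is_precise_form and d.drug_id not in nmap.precise_to_ingredient:
            unmappable += 1
            continue
        ing = nmap.ingredient_for(d.drug_id)
        key = (d.source, ing)
        prev = merged.get(key)
        if prev is None:
            merged[key] = d.replace(ingredient_id=ing)
        elif d.is_clinical and not prev.is_clinical:
            merged[key] = prev.replace(is_clinical=True)
    if unmappable:
        logger.warning("excluded %d precise-form drugs with no ingredient mapping", unmappable)
    return list(merged.values())


def restrict_clinical(drugs: Iterable[Drug], nmap: NormalizationMap) -> set[str]:
    """Ingredient ids of normalized drugs flagged clinically relevant."""
    out = set()
    for d in drugs:
        if d.ingredient_id is not None and d.is_clinical:
            out.add(d.ingredient_id)
    if nmap.clinical_ingredients:
        out &= nmap.clinical_ingredients
    return out


def mark_combination_classes(
    classes: Iterable[DrugClass],
    index: HierarchyIndex,
    token: str = "combination",
) -> list[DrugClass]:
    """Flag classes whose label, or any ancestor's label, contains ``token``.

    The test is a literal case-insensitive substring match — no
    tokenization — so e.g. a label containing "non-combination" is flagged.
    """
    token = token.lower()
    by_id = {c.class_id: c for c in classes}
    flagged: list[DrugClass] = []
    for c in by_id.values():
        hit = token in c.label.lower()
        if not hit:
            for anc in index.ancestor_ids(c.class_id):
                anc_label = index.labels.get(anc, by_id[anc].label if anc in by_id else "")
                if token in anc_label.lower():
                    hit = True
                    break
        flagged.append(c.replace(is_combination=hit) if hit != c.is_combination else c)
    return flagged


def mark_top_level_classes(
    classes: Iterable[DrugClass],
    config: EligibilityConfig | None = None,
) -> list[DrugClass]:
    """Flag depth-1 classes and classes at configured excluded root addresses.

    Multi-parentage rule: a class is top-level if *any* of its addresses is
    at depth 1 (or configured as an excluded root).
    """
    config = config or EligibilityConfig()
    out: list[DrugClass] = []
    for c in classes:
        roots = set(config.excluded_top_addresses.get(c.source, ()))
        # c.level == 1 <=> some address sits at depth 1 (level is the min depth)
        top = (not c.addresses) or c.level == 1 or any(a in roots for a in c.addresses)
        out.append(c.replace(is_top_level=top) if top != c.is_top_level else c)
    return out


def eligible_classes(
    classes: Iterable[DrugClass],
    memberships: "MembershipSet | None",
    universe_drugs: set[str],
    config: EligibilityConfig | None = None,
    *,
    require_members: bool = True,
) -> set[str]:
    """Class ids surviving the exclusion rules.

    With ``require_members=False`` only the top-level and combination rules
    apply (the lexical-eligible set); with the default, a class must also
    have at least one member ingredient from ``universe_drugs`` in its
    direct-or-descendant member set (the instance-eligible set).  The
    filter is idempotent.
    """
    out: set[str] = set()
    for c in classes:
        if c.is_top_level or c.is_combination:
            continue
        if require_members:
            if memberships is None:
                raise ValueError("memberships required when require_members=True")
            members = memberships.members(c.class_id) & universe_drugs
            if not members:
                continue
        out.add(c.class_id)
    return out


def build_universe(
    drugs_a: Iterable[Drug],
    drugs_b: Iterable[Drug],
    nmap: NormalizationMap,
) -> set[str]:
    """Shared clinical ingredient universe: the intersection of both
    sources' clinical ingredient sets after normalization."""
    a = restrict_clinical(normalize_drugs(drugs_a, nmap), nmap)
    b = restrict_clinical(normalize_drugs(drugs_b, nmap), nmap)
    return a & b
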