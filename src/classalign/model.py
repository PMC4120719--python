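"""Domain types and hierarchy parsing for drug classifications.

Two addressing styles are supported:

* **Coded** (ATC-style): a class address is the code itself, e.g. ``C10AA``.
  Codes have five levels with fixed lengths — 1 character (anatomical),
  3 (therapeutic), 4 (pharmacological), 5 (chemical), 7 (substance) — and a
  class's ancestors are exactly its proper prefixes of valid lengths.
* **Tree-numbered** (MeSH-style): a class owns one or more dot-separated
  tree numbers, e.g. ``D03.438.810.835``; ancestors are the classes owning
  every proper dot-prefix.  A descriptor may appear at several locations
  (multi-parentage), in which case its level is the minimum depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "DrugClass",
    "Drug",
    "HierarchyIndex",
    "AddressError",
    "HierarchyError",
    "parse_atc_code",
    "atc_level",
    "address_ancestors",
    "address_depth",
    "build_hierarchy_index",
    "mesh_ancestor_closure",
]

# valid ATC code lengths -> level
_ATC_LEVEL_BY_LEN = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
# proper-prefix lengths used for ancestor derivation (level 1..4 codes)
_ATC_PREFIX_LENS = (1, 3, 4, 5)

_ATC_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    2: re.compile(r"^[A-Z]\d{2}$"),
    3: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
}


class AddressError(ValueError):
    """Raised for a malformed or unresolvable hierarchy address."""


class HierarchyError(ValueError):
    """Raised for structural defects: duplicate addresses, cycles."""


@dataclass(frozen=True)
class DrugClass:
    """One drug class in either classification source.

    ``addresses`` carries the ATC code itself for coded sources, or the
    tree numbers for tree-numbered sources.  ``kind`` distinguishes
    structural (chemical-structure) from functional (mechanism / effect /
    therapeutic-use) classes where the source makes that distinction.
    """

    class_id: str
    label: str
    source: str
    kind: str = "unspecified"  # structural | functional | unspecified
    addresses: tuple[str, ...] = ()
    is_combination: bool = False
    is_top_level: bool = False
    is_asserted_class: bool = True
    style: str = "auto"  # coded | tree | auto

    def __post_init__(self) -> None:
        if self.kind not in ("structural", "functional", "unspecified"):
            raise ValueError(f"unknown class kind {self.kind!r}")
        if self.style not in ("coded", "tree", "auto"):
            raise ValueError(f"unknown addressing style {self.style!r}")

    @property
    def level(self) -> int:
        """Depth in the hierarchy: ATC level for codes, minimum dot-depth
        over tree numbers (multi-parentage takes the shallowest).

        A dotless address is ambiguous between the styles ("D03" is both a
        valid code and a tree root), so a class owning any dotted address
        is treated as tree-numbered throughout; ``style`` pins the reading
        for single dotless addresses.
        """
        if not self.addresses:
            return 1
        tree = self.style == "tree" or (
            self.style == "auto" and any("." in a for a in self.addresses)
        )
        if tree:
            return min(a.count(".") + 1 for a in self.addresses)
        return min(address_depth(a) for a in self.addresses)

    @property
    def is_eligible(self) -> bool:
        return not self.is_top_level and not self.is_combination

    def replace(self, **kw) -> "DrugClass":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class Drug:
    """One substance with a source-local identifier.

    ``ingredient_id`` is the normalized reference identifier (shared across
    sources, base form); it is null until normalization has run.
    ``is_precise_form`` marks salts/esters of a base ingredient.
    """

    drug_id: str
    label: str
    source: str
    ingredient_id: str | None = None
    is_precise_form: bool = False
    is_clinical: bool = True

    def replace(self, **kw) -> "Drug":
        from dataclasses import replace

        return replace(self, **kw)


def parse_atc_code(code: str) -> dict:
    """Parse an ATC-style code into its level and ancestor codes.

    >>> parse_atc_code("C10AA05")
    {'level': 5, 'ancestors': ['C', 'C10', 'C10A', 'C10AA']}

    Ancestors are ordered general -> specific.  Raises :class:`AddressError`
    for an invalid length or a malformed character pattern.
    """
    if not code:
        raise AddressError("empty ATC code")
    code = code.strip().upper()
    level = _ATC_LEVEL_BY_LEN.get(len(code))
    if level is None:
        raise AddressError(
            f"invalid ATC code {code!r}: length {len(code)} is not one of 1, 3, 4, 5, 7"
        )
    if not _ATC_PATTERNS[level].match(code):
        raise AddressError(f"malformed ATC code {code!r} for level {level}")
    ancestors = [code[:n] for n in _ATC_PREFIX_LENS if n < len(code)]
    return {"level": level, "ancestors": ancestors}


def atc_level(code: str) -> int:
    return parse_atc_code(code)["level"]


def is_atc_code(address: str) -> bool:
    try:
        parse_atc_code(address)
    except AddressError:
        return False
    return True


def address_depth(address: str) -> int:
    """Depth of an address: ATC level for codes, dot-segment count otherwise."""
    if "." in address:
        return address.count(".") + 1
    if is_atc_code(address):
        return atc_level(address)
    return 1  # opaque single-segment address: a root


def address_ancestors(address: str) -> list[str]:
    """Proper-prefix addresses of ``address``, ordered general -> specific."""
    if "." in address:
        parts = address.split(".")
        return [".".join(parts[:i]) for i in range(1, len(parts))]
    if is_atc_code(address):
        return parse_atc_code(address)["ancestors"]
    return []


@dataclass
class HierarchyIndex:
    """Address and ancestry lookup for one classification source.

    ``ancestors`` is the transitive closure of ``parents``; by construction
    (prefix arithmetic) the relation is acyclic.
    """

    source: str
    address_to_class: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    ancestors: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def ancestor_ids(self, class_id: str) -> set[str]:
        return set(self.ancestors.get(class_id, set()))

    def parent_ids(self, class_id: str) -> set[str]:
        return set(self.parents.get(class_id, set()))


def build_hierarchy_index(classes: Iterable[DrugClass], source: str | None = None) -> HierarchyIndex:
    """Build parent/ancestor maps from class addresses.

    The parent of each address is the class owning its longest resolvable
    proper prefix (missing intermediate nodes are skipped); ancestors are
    the classes owning any proper prefix.  Duplicate addresses raise
    :class:`HierarchyError`.
    """
    classes = list(classes)
    if source is None:
        source = classes[0].source if classes else ""
    idx = HierarchyIndex(source=source)
    for c in classes:
        idx.labels[c.class_id] = c.label
        for addr in c.addresses:
            owner = idx.address_to_class.get(addr)
            if owner is not None and owner != c.class_id:
                raise HierarchyError(
                    f"duplicate address {addr!r} owned by {owner!r} and {c.class_id!r}"
                )
            idx.address_to_class[addr] = c.class_id
    for c in classes:
        parents: set[str] = set()
        ancs: set[str] = set()
        for addr in c.addresses:
            chain = address_ancestors(addr)  # general -> specific
            resolved = [idx.address_to_class[a] for a in chain if a in idx.address_to_class]
            resolved = [cid for cid in resolved if cid != c.class_id]
            ancs.update(resolved)
            if resolved:
                parents.add(resolved[-1])
        idx.parents.setdefault(c.class_id, set()).update(parents)
        idx.ancestors.setdefault(c.class_id, set()).update(ancs)
    _check_acyclic(idx)
    return idx


def _check_acyclic(idx: HierarchyIndex) -> None:
    # prefix-derived ancestry cannot cycle (prefixes strictly shorten), but
    # the check guards against future non-prefix index builders
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(idx.parents)
    for child, ps in idx.parents.items():
        for p in ps:
            g.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise HierarchyError(f"cycle in hierarchy: {cyc}")


def mesh_ancestor_closure(tree_numbers: Iterable[str], index: HierarchyIndex) -> set[str]:
    """Classes owning every proper dot-prefix of each tree number.

    The union is taken over all tree numbers; the owning class itself is
    excluded.  An address that does not resolve in the index raises
    :class:`AddressError` naming the address.
    """
    out: set[str] = set()
    own: set[str] = set()
    for tn in tree_numbers:
        if tn not in index.address_to_class:
            raise AddressError(f"unresolvable address {tn!r} in source {index.source!r}")
        own.add(index.address_to_class[tn])
        for pre in address_ancestors(tn):
            if pre in index.address_to_class:
                out.add(index.address_to_class[pre])
    return out - own
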