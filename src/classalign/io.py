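"""Plain-text interchange formats and input validation.

All tables are UTF-8, tab-separated, with a header row:

* ``classes.tsv`` — source, class_id, label, kind, addresses
  (addresses semicolon-separated)
* ``drugs.tsv`` — source, drug_id, label, is_precise, is_clinical
* ``membership.tsv`` — source, drug_id, class_id, relation
  (relation one of pa, hm, parent, level5)
* ``normmap.tsv`` — from_id, to_ingredient_id
* ``synonyms.tsv`` — concept_id, term
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .eligibility import NormalizationMap
from .lexalign import SynonymTable
from .membership import MembershipLink
from .model import Drug, DrugClass, is_atc_code

__all__ = [
    "SchemaError",
    "ValidationIssue",
    "ValidationReport",
    "SCHEMAS",
    "read_table",
    "load_classes",
    "load_drugs",
    "load_links",
    "load_normmap",
    "load_synonyms",
    "validate_inputs",
]

SCHEMAS: dict[str, list[str]] = {
    "classes": ["source", "class_id", "label", "kind", "addresses"],
    "drugs": ["source", "drug_id", "label", "is_precise", "is_clinical"],
    "membership": ["source", "drug_id", "class_id", "relation"],
    "normmap": ["from_id", "to_ingredient_id"],
    "synonyms": ["concept_id", "term"],
}

_RELATIONS = {"pa", "hm", "parent", "level5"}


class SchemaError(ValueError):
    """A malformed input table; the message names the file and line."""


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    line: int | None
    severity: str  # error | warning
    message: str

    def __str__(self) -> str:
        loc = f"{self.file}" + (f":{self.line}" if self.line is not None else "")
        return f"[{self.severity}] {loc}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, file: str, line: int | None, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(str(file), line, severity, message))


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one interchange table, enforcing its column schema.

    Raises :class:`SchemaError` naming the file and first offending line
    for a wrong header or a row with the wrong number of fields.
    """
    path = Path(path)
    expected = SCHEMAS[kind]
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise SchemaError(
                f"{path}:1: expected columns {expected}, found {header}"
            )
        rows = []
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(expected):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(expected)} fields, found {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=expected, dtype=str)
    return df


def _as_bool(value: str, path: str, lineno: int | None, column: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no", ""):
        return False
    raise SchemaError(f"{path}: non-boolean value {value!r} in column {column}")


def load_classes(path: str | Path, coded_split: bool = True) -> list[DrugClass]:
    """Parse class records.

    A coded-source record listing several codes in ``addresses`` is split
    into one class per code (sharing the label), with the code as the
    class id; tree-numbered records keep all their addresses on one class.
    """
    df = read_table(path, "classes")
    # addressing style is a property of the whole source: any dotted
    # address marks it tree-numbered (dotless roots like "D03" would
    # otherwise be mistaken for codes)
    styles: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        if any("." in a for a in rec.addresses.split(";")):
            styles[rec.source] = "tree"
    out: list[DrugClass] = []
    for rec in df.itertuples(index=False):
        style = styles.get(rec.source, "coded")
        addresses = tuple(a.strip() for a in rec.addresses.split(";") if a.strip())
        kind = rec.kind.strip() or "unspecified"
        if (
            coded_split and style == "coded" and len(addresses) > 1
            and all(is_atc_code(a) for a in addresses)
        ):
            for a in addresses:
                out.append(
                    DrugClass(class_id=a.upper(), label=rec.label, source=rec.source,
                              kind=kind, addresses=(a.upper(),), style=style)
                )
        else:
            if style == "coded":
                addresses = tuple(a.upper() if is_atc_code(a) else a for a in addresses)
            out.append(
                DrugClass(class_id=rec.class_id, label=rec.label, source=rec.source,
                          kind=kind, addresses=addresses, style=style)
            )
    return out


def load_drugs(path: str | Path) -> list[Drug]:
    df = read_table(path, "drugs")
    return [
        Drug(
            drug_id=r.drug_id,
            label=r.label,
            source=r.source,
            is_precise_form=_as_bool(r.is_precise, str(path), None, "is_precise"),
            is_clinical=_as_bool(r.is_clinical, str(path), None, "is_clinical"),
        )
        for r in df.itertuples(index=False)
    ]


def load_links(path: str | Path) -> dict[str, list[MembershipLink]]:
    """Membership edges grouped by source; duplicate rows are dropped."""
    df = read_table(path, "membership")
    out: dict[str, list[MembershipLink]] = {}
    seen: set[tuple] = set()
    for r in df.itertuples(index=False):
        key = (r.source, r.drug_id, r.class_id, r.relation)
        if key in seen:
            continue
        seen.add(key)
        out.setdefault(r.source, []).append(MembershipLink(r.drug_id, r.class_id, r.relation))
    return out


def load_normmap(path: str | Path) -> NormalizationMap:
    df = read_table(path, "normmap")
    nmap = NormalizationMap()
    for r in df.itertuples(index=False):
        prev = nmap.precise_to_ingredient.get(r.from_id)
        if prev is not None and prev != r.to_ingredient_id:
            raise SchemaError(
                f"{path}: drug id {r.from_id!r} maps to both {prev!r} and {r.to_ingredient_id!r}"
            )
        nmap.precise_to_ingredient[r.from_id] = r.to_ingredient_id
    return nmap


def load_synonyms(path: str | Path) -> SynonymTable:
    df = read_table(path, "synonyms")
    return SynonymTable.from_pairs((r.concept_id, r.term) for r in df.itertuples(index=False))


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Per-file schema checks plus cross-file referential checks.

    ``paths`` maps table kind (classes, drugs, membership, normmap,
    synonyms) to a file path; missing optional tables (synonyms) are
    skipped.  The report lists errors and warnings; it never raises.
    """
    rep = ValidationReport()
    frames: dict[str, pd.DataFrame] = {}
    for kind in SCHEMAS:
        p = paths.get(kind)
        if p is None:
            if kind in ("classes", "drugs"):
                rep.add(kind, None, "error", "required table missing")
            continue
        p = Path(p)
        if not p.exists():
            rep.add(str(p), None, "error", "file not found")
            continue
        try:
            frames[kind] = read_table(p, kind)
        except SchemaError as e:
            rep.add(str(p), None, "error", str(e))

    classes = frames.get("classes")
    drugs = frames.get("drugs")
    memb = frames.get("membership")
    nmap = frames.get("normmap")

    if memb is not None:
        mpath = str(paths["membership"])
        bad_rel = memb[~memb.relation.isin(_RELATIONS)]
        for i in bad_rel.index[:5]:
            rep.add(mpath, int(i) + 2, "error", f"unknown relation {memb.relation[i]!r}")
        dups = memb.duplicated(subset=["source", "drug_id", "class_id", "relation"]).sum()
        if dups:
            rep.add(mpath, None, "warning", f"{dups} duplicated membership rows (deduplicated)")
        if classes is not None and drugs is not None:
            known = set(classes.class_id) | set(drugs.drug_id)
            missing = memb[~memb.class_id.isin(known)]
            for i in missing.index[:5]:
                rep.add(
                    mpath, int(i) + 2, "error",
                    f"membership target {memb.class_id[i]!r} is neither a class nor a drug",
                )
            unknown_drug = memb[~memb.drug_id.isin(set(drugs.drug_id))]
            for i in unknown_drug.index[:5]:
                rep.add(mpath, int(i) + 2, "error", f"unknown drug id {memb.drug_id[i]!r}")
        if len(memb) == 0:
            rep.add(mpath, None, "warning", "membership table is empty")

    if nmap is not None and drugs is not None:
        conflicting = nmap.groupby("from_id")["to_ingredient_id"].nunique()
        for from_id in conflicting[conflicting > 1].index[:5]:
            rep.add(str(paths["normmap"]), None, "error", f"drug id {from_id!r} maps to multiple ingredients")

    if classes is not None:
        dup = classes.duplicated(subset=["source", "class_id"]).sum()
        if dup:
            rep.add(str(paths["classes"]), None, "error", f"{dup} duplicated (source, class_id) records")
    return rep
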