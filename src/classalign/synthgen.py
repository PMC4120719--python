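"""Synthetic paired classifications with planted alignment structure.

The generator emulates the statistical situation the alignment framework
assumes: two overlapping drug classifications over a shared ingredient
universe, one coded (ATC-style level-4 classes populated by level-5 drug
codes) and one tree-numbered (MeSH-style descriptors populated through
parent / pharmacologic-action edges), with planted cross-source
equivalence and inclusion relations, plus the distracting structure the
eligibility filters must remove (combination classes, top-level classes,
classes holding only non-clinical drugs).

Planted pairs draw their member ingredients from disjoint slices of the
pool, so with zero noise the scored pair list is exactly the planted list
and recovery can be checked against the emitted ground truth.  It does
not attempt realistic drug nomenclature: labels and identifiers are
synthetic.

Ground truth (``truth.json``) records, per planted pair, the member-count
triple and the downstream flags expected at the default 0.5 thresholds.
The expected flags are derived inside this module by direct arithmetic on
the planted counts, independently of the scoring implementation, so they
can serve as an oracle for it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PlantedPair", "SynthSpec", "SynthBundle", "generate", "table8_fixture"]

_A_SOURCE = "A"
_B_SOURCE = "B"


@dataclass(frozen=True)
class PlantedPair:
    """One cross-source relation to plant.

    For ``relation="equivalence"``, ``overlap`` is the shared fraction of
    the member union; for ``relation="inclusion"`` it is the coverage of
    the smaller (contained) class by the larger.
    """

    relation: str  # equivalence | inclusion
    size_a: int
    size_b: int
    overlap: float

    def counts(self) -> tuple[int, int, int]:
        """(am, a_only, m_only) realizing the planted sizes and overlap."""
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError(f"overlap must be in [0, 1], got {self.overlap}")
        if min(self.size_a, self.size_b) < 1:
            raise ValueError("class sizes must be >= 1")
        if self.relation == "equivalence":
            union = self.size_a + self.size_b
            am = round(self.overlap * union / (1.0 + self.overlap))
        elif self.relation == "inclusion":
            am = round(self.overlap * min(self.size_a, self.size_b))
        else:
            raise ValueError(f"unknown planted relation {self.relation!r}")
        if am < 1 or am > min(self.size_a, self.size_b):
            raise ValueError(
                f"infeasible planted pair: overlap {self.overlap} with sizes "
                f"({self.size_a}, {self.size_b}) yields shared count {am}"
            )
        return am, self.size_a - am, self.size_b - am


def _default_planted() -> tuple[PlantedPair, ...]:
    return (
        PlantedPair("equivalence", 10, 10, 0.80),
        PlantedPair("equivalence", 12, 12, 0.85),
        PlantedPair("equivalence", 8, 9, 0.80),
        PlantedPair("inclusion", 6, 25, 1.00),
        PlantedPair("inclusion", 30, 8, 0.90),
        PlantedPair("inclusion", 5, 18, 0.80),
    )


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic bundle.

    Defaults plant three equivalences (overlap 0.80-0.85, sizes 8-12) and
    three inclusions (coverage 0.80-1.0, container 3-5x the contained
    class), over a pool of 300 ingredients of which 10% are non-clinical;
    10% of the coded source's filler classes are combination classes.
    ``noise`` is the fraction of extra random membership rows relative to
    the planted rows.  Generation is deterministic given ``seed``.
    """

    seed: int = 0
    n_ingredients: int = 300
    planted: tuple[PlantedPair, ...] = field(default_factory=_default_planted)
    noise: float = 0.0
    combination_fraction: float = 0.10
    nonclinical_fraction: float = 0.10
    n_filler_classes: int = 10

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        need = sum(p.size_a + p.size_b for p in self.planted)
        if need > self.n_ingredients:
            raise ValueError(
                f"infeasible spec: planted pairs need up to {need} ingredients, "
                f"pool has {self.n_ingredients}"
            )


@dataclass
class SynthBundle:
    """In-memory TSV bundle plus ground truth."""

    classes: pd.DataFrame
    drugs: pd.DataFrame
    membership: pd.DataFrame
    normmap: pd.DataFrame
    synonyms: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name in ("classes", "drugs", "membership", "normmap", "synonyms"):
            p = out / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = p
        tp = out / "truth.json"
        tp.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        paths["truth"] = tp
        return paths

    def paths(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        return {n: out / f"{n}.tsv" for n in ("classes", "drugs", "membership", "normmap", "synonyms")}


def _expected_flags(am: int, a_only: int, m_only: int, thr: float = 0.5) -> dict:
    """Ground-truth flags by direct arithmetic on the planted counts."""
    es = math.sqrt(am * max(am - 0.8, 0.0)) / (am + a_only + m_only)
    if a_only == 0 and m_only == 0:
        isc = 0.0
    else:
        isc = ((a_only - m_only) / (a_only + m_only)) * (am / min(am + a_only, am + m_only))
    return {
        "eq": es >= thr,
        "in": abs(isc) >= thr,
        "direction": "none" if abs(isc) < thr else ("A_in_B" if isc < 0 else "B_in_A"),
    }


_ATC_LETTERS = "ABCDGHJLMNPRSV"


def _atc_level4(i: int) -> str:
    """i-th synthetic level-4 code, e.g. A01AA, A01AB, ..."""
    letter = _ATC_LETTERS[i // 26 % len(_ATC_LETTERS)]
    group = i // (26 * len(_ATC_LETTERS)) + 1
    sub = chr(ord("A") + i % 26)
    return f"{letter}{group:02d}A{sub}"


def generate(spec: SynthSpec, out_dir: str | Path | None = None) -> SynthBundle:
    """Build a full synthetic bundle; optionally write it to ``out_dir``.

    Shared planted drugs are members on both sides; side-specific drugs
    exist in both sources (so they survive the shared-universe filter) but
    are members only on their own side.  Sub-generators draw their seeds
    from a single root sequence, so the bundle is reproducible byte for
    byte given the spec.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_noise, rng_fill = (np.random.default_rng(s) for s in root.spawn(2))

    ingredients = [f"ING{i:04d}" for i in range(spec.n_ingredients)]
    n_nonclin = round(spec.nonclinical_fraction * spec.n_ingredients)
    nonclinical = set(ingredients[len(ingredients) - n_nonclin :])

    classes_rows: list[dict] = []
    drugs_rows: list[dict] = []
    memb_rows: list[dict] = []
    norm_rows: list[dict] = []
    syn_rows: list[dict] = []
    truth_pairs: list[dict] = []

    pool = iter(ingredients)
    a_drug_id: dict[str, str] = {}
    b_drug_id: dict[str, str] = {}

    def _ensure_drug(ing: str, side: str, code: str | None = None) -> str:
        """Register a drug record for `ing` on `side`; return its drug id."""
        reg = a_drug_id if side == _A_SOURCE else b_drug_id
        if ing in reg:
            return reg[ing]
        did = code if code is not None else (f"XA-{ing}" if side == _A_SOURCE else f"Q{ing}")
        reg[ing] = did
        drugs_rows.append(
            {
                "source": side,
                "drug_id": did,
                "label": f"substance {ing.lower()}",
                "is_precise": 0,
                "is_clinical": 0 if ing in nonclinical else 1,
            }
        )
        norm_rows.append({"from_id": did, "to_ingredient_id": ing})
        return did

    # --- planted pairs ---------------------------------------------------
    for i, pp in enumerate(spec.planted):
        am, a_only, m_only = pp.counts()
        a_cid = _atc_level4(i)
        b_cid = f"B{i:05d}"
        a_label, b_label, syn = _pair_labels(i, pp.relation)
        if syn is not None:
            concept = f"CONC{i:04d}"
            syn_rows.append({"concept_id": concept, "term": a_label})
            syn_rows.append({"concept_id": concept, "term": b_label})
        kind = "functional" if i % 2 else "structural"
        classes_rows.append(
            {"source": _A_SOURCE, "class_id": a_cid, "label": a_label, "kind": "unspecified", "addresses": a_cid}
        )
        classes_rows.append(
            {"source": _B_SOURCE, "class_id": b_cid, "label": b_label, "kind": kind, "addresses": f"D03.{i + 100:03d}"}
        )
        shared = [next(pool) for _ in range(am)]
        a_extra = [next(pool) for _ in range(a_only)]
        b_extra = [next(pool) for _ in range(m_only)]
        for k, ing in enumerate(shared + a_extra):
            _ensure_drug(ing, _A_SOURCE, code=f"{a_cid}{k + 1:02d}")
        for ing in b_extra:
            _ensure_drug(ing, _A_SOURCE)  # in source A but member of no A class
        b_rel = "pa" if kind == "functional" else "parent"
        for ing in shared + b_extra:
            did = _ensure_drug(ing, _B_SOURCE)
            memb_rows.append({"source": _B_SOURCE, "drug_id": did, "class_id": b_cid, "relation": b_rel})
        for ing in a_extra:
            _ensure_drug(ing, _B_SOURCE)  # in source B but member of no B class
        flags = _expected_flags(am, a_only, m_only)
        # member pools are disjoint across pairs, so each planted class has
        # exactly one scored pair: best-pair selections follow from the flags
        best_eq_for = [a_cid, b_cid] if flags["eq"] else []
        if flags["direction"] == "A_in_B":
            best_in_for = [a_cid]
        elif flags["direction"] == "B_in_A":
            best_in_for = [b_cid]
        else:
            best_in_for = []
        truth_pairs.append(
            {
                "a_class_id": a_cid,
                "b_class_id": b_cid,
                "relation": pp.relation,
                "am": am,
                "a_only": a_only,
                "m_only": m_only,
                **{f"expected_{k}": v for k, v in flags.items()},
                "expected_best_equivalence_for": best_eq_for,
                "expected_best_inclusion_for": best_in_for,
            }
        )

    n_planted = len(spec.planted)

    # --- distracting structure the filters must remove --------------------
    # a top-level class on each side
    classes_rows.append(
        {"source": _A_SOURCE, "class_id": "A", "label": "Top level group A", "kind": "unspecified", "addresses": "A"}
    )
    classes_rows.append(
        {"source": _B_SOURCE, "class_id": "BTOP", "label": "Top level group B", "kind": "unspecified", "addresses": "D03"}
    )
    # a class pair whose drugs are all non-clinical -> excluded as empty
    nc_a = _atc_level4(n_planted)
    nc_ings = sorted(nonclinical)[: min(3, len(nonclinical))]
    if nc_ings:
        classes_rows.append(
            {"source": _A_SOURCE, "class_id": nc_a, "label": "Non clinical residue", "kind": "unspecified", "addresses": nc_a}
        )
        for k, ing in enumerate(nc_ings):
            _ensure_drug(ing, _A_SOURCE, code=f"{nc_a}{k + 1:02d}")
    # combination classes among the coded fillers
    n_comb = round(spec.combination_fraction * spec.n_filler_classes)
    for j in range(spec.n_filler_classes):
        cid = _atc_level4(n_planted + 1 + j)
        label = (
            f"Filler group {j} combinations" if j < n_comb else f"Filler group {j}"
        )
        classes_rows.append(
            {"source": _A_SOURCE, "class_id": cid, "label": label, "kind": "unspecified", "addresses": cid}
        )

    # --- noise ------------------------------------------------------------
    n_noise = round(spec.noise * len(memb_rows)) if spec.noise else 0
    planted_b = [r for r in classes_rows if r["source"] == _B_SOURCE and r["class_id"].startswith("B0")]
    all_known = sorted(set(a_drug_id) | set(b_drug_id))
    for _ in range(n_noise):
        ing = all_known[int(rng_noise.integers(len(all_known)))]
        row = planted_b[int(rng_noise.integers(len(planted_b)))]
        did = _ensure_drug(ing, _B_SOURCE)
        memb_rows.append({"source": _B_SOURCE, "drug_id": did, "class_id": row["class_id"], "relation": "parent"})

    membership = pd.DataFrame(memb_rows, columns=["source", "drug_id", "class_id", "relation"]).drop_duplicates()
    bundle = SynthBundle(
        classes=pd.DataFrame(classes_rows, columns=["source", "class_id", "label", "kind", "addresses"]),
        drugs=pd.DataFrame(drugs_rows, columns=["source", "drug_id", "label", "is_precise", "is_clinical"]),
        membership=membership,
        normmap=pd.DataFrame(norm_rows, columns=["from_id", "to_ingredient_id"]),
        synonyms=pd.DataFrame(syn_rows, columns=["concept_id", "term"]),
        truth={
            "seed": spec.seed,
            "noise": spec.noise,
            "pairs": truth_pairs,
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _pair_labels(i: int, relation: str) -> tuple[str, str, str | None]:
    """Labels for planted pair i: the first three planted pairs exercise the
    three lexical techniques (identical, plural variant, cosynonym)."""
    base = f"planted {relation} {i}"
    if i == 0:
        return f"Shared label {base} agents", f"Shared label {base} agents", None
    if i == 1:
        return f"{base} blocking agents", f"{base.title()} Blocking Agent", None
    if i == 2:
        return f"{base} inhibitors", f"Enzyme suppressors {i}", "cosyn"
    return f"{base} class A{i}", f"{base} class B{i}", None


# ---------------------------------------------------------------------------
# Worked-example fixture: ten fully specified best-pair rows
# ---------------------------------------------------------------------------

#: (ddi_class, a_id, a_label, b_id, b_label, b_kind, am, a_only, m_only, rel)
TABLE8_ROWS: tuple[tuple, ...] = (
    ("Triptans", "N02CC", "Selective serotonin (5HT1) agonists",
     "D014363", "Tryptamines", "structural", 7, 0, 1, "Eq"),
    ("Proton pump inhibitors", "A02BC", "Proton pump inhibitors",
     "D053799", "2-Pyridinylmethylsulfinyl-benzimidazoles", "structural", 5, 1, 0, "Eq"),
    ("HMG CoA reductase inhibitors", "C10AA", "HMG CoA reductase inhibitors",
     "D019161", "Hydroxymethylglutaryl-CoA Reductase Inhibitors", "functional", 8, 0, 2, "Eq"),
    ("Tricyclic antidepressants", "N06AA", "Non-selective monoamine reuptake inhibitors",
     "D000929", "Antidepressive Agents, Tricyclic", "structural", 10, 2, 2, "Eq"),
    ("Protease inhibitors", "J05AE", "Protease inhibitors",
     "D017320", "HIV Protease Inhibitors", "functional", 8, 3, 1, "Eq"),
    ("Narcotic analgesics", "N02A", "OPIOIDS",
     "D009294", "Narcotics", "functional", 15, 3, 11, "Eq"),
    ("Selective serotonin reuptake inhibitors (SSRIs)", "N06AB", "Selective serotonin reuptake inhibitors",
     "D017367", "Serotonin Uptake Inhibitors", "functional", 6, 0, 8, "In"),
    ("MAO inhibitors", "N06AF", "Monoamine oxidase inhibitors, non-selective",
     "D008996", "Monoamine Oxidase Inhibitors", "functional", 3, 0, 5, "In"),
    ("Macrolides", "J01FA", "Macrolides",
     "D018942", "Macrolides", "structural", 8, 0, 21, "In"),
    ("Azoles", "D01AC", "Imidazole and triazole derivatives",
     "D001393", "Azoles", "structural", 11, 1, 147, "In"),
)


def table8_fixture(out_dir: str | Path | None = None) -> SynthBundle:
    """Bundle realizing the ten fully specified worked-example class pairs.

    Each pair's eligible member counts equal its published member-count
    triple; drug identifiers are synthetic.  Member pools are disjoint
    across pairs, classes pass every eligibility filter, and side-specific
    drugs exist in both sources, so the scored pair list downstream is
    exactly these ten pairs with exactly these counts.
    """
    classes_rows: list[dict] = []
    drugs_rows: list[dict] = []
    memb_rows: list[dict] = []
    norm_rows: list[dict] = []
    syn_rows: list[dict] = [
        {"concept_id": "C0162554", "term": "Selective serotonin reuptake inhibitors"},
        {"concept_id": "C0162554", "term": "Serotonin Uptake Inhibitors"},
    ]
    truth_pairs: list[dict] = []

    for r_i, (ddi, a_id, a_label, b_id, b_label, b_kind, am, a_only, m_only, rel) in enumerate(TABLE8_ROWS):
        classes_rows.append(
            {"source": _A_SOURCE, "class_id": a_id, "label": a_label, "kind": "unspecified", "addresses": a_id}
        )
        classes_rows.append(
            {"source": _B_SOURCE, "class_id": b_id, "label": b_label, "kind": b_kind,
             "addresses": f"D03.{r_i + 1:03d}"}
        )
        ings = [f"ING-{a_id}-{k:03d}" for k in range(am + a_only + m_only)]
        shared, a_extra, b_extra = ings[:am], ings[am : am + a_only], ings[am + a_only :]

        # coded-source drugs: members carry level-5 codes under the class
        # (or, for a level-3 class, under an absent level-4 child so that
        # membership arrives by inference); side-only drugs carry opaque ids
        code_root = a_id if len(a_id) == 5 else a_id + "X"
        for k, ing in enumerate(shared + a_extra):
            code = f"{code_root}{k + 1:02d}"
            drugs_rows.append(
                {"source": _A_SOURCE, "drug_id": code, "label": ing.lower(), "is_precise": 0, "is_clinical": 1}
            )
            norm_rows.append({"from_id": code, "to_ingredient_id": ing})
        for ing in b_extra:
            did = f"XA-{ing}"
            drugs_rows.append(
                {"source": _A_SOURCE, "drug_id": did, "label": ing.lower(), "is_precise": 0, "is_clinical": 1}
            )
            norm_rows.append({"from_id": did, "to_ingredient_id": ing})

        b_rel = "pa" if b_kind == "functional" else "parent"
        for ing in ings:
            did = f"Q{ing}"
            drugs_rows.append(
                {"source": _B_SOURCE, "drug_id": did, "label": ing.lower(), "is_precise": 0, "is_clinical": 1}
            )
            norm_rows.append({"from_id": did, "to_ingredient_id": ing})
            if ing in shared or ing in b_extra:
                memb_rows.append({"source": _B_SOURCE, "drug_id": did, "class_id": b_id, "relation": b_rel})

        truth_pairs.append(
            {
                "ddi_class": ddi,
                "a_class_id": a_id,
                "b_class_id": b_id,
                "relation": rel,
                "am": am,
                "a_only": a_only,
                "m_only": m_only,
            }
        )

    bundle = SynthBundle(
        classes=pd.DataFrame(classes_rows, columns=["source", "class_id", "label", "kind", "addresses"]),
        drugs=pd.DataFrame(drugs_rows, columns=["source", "drug_id", "label", "is_precise", "is_clinical"]),
        membership=pd.DataFrame(memb_rows, columns=["source", "drug_id", "class_id", "relation"]),
        normmap=pd.DataFrame(norm_rows, columns=["from_id", "to_ingredient_id"]),
        synonyms=pd.DataFrame(syn_rows, columns=["concept_id", "term"]),
        truth={"pairs": truth_pairs},
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
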