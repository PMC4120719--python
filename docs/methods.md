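# Methods

## Problem and model

`classalign` compares two drug classifications through the drugs they
classify. Classes are treated as sets of instances (individual drugs),
not as subclasses of one another, which is what makes instance-based
(extensional) alignment applicable: two classes are candidates for
equivalence when their member sets largely coincide, and for inclusion
when one member set sits almost entirely inside the other.

The pipeline has five stages: establishing a common drug reference,
building per-class member sets, lexical alignment of class names,
instance-based scoring and classification of class pairs, and
consistency assessment / hierarchy integration.

### Common reference

Drugs from each source are normalized to base-form ingredients through a
drug-id → ingredient map (salts and esters collapse onto their base
ingredient; records collapsing onto one ingredient are merged; a precise
form with no mapping is dropped with a logged count). The eligible drug
universe is the intersection of the two sources' clinically relevant
ingredient sets — an ingredient qualifies when at least one clinical
drug record maps to it. Classes are filtered by three rules:

1. **top-level** classes are excluded — any class with a depth-1
   address, plus classes at root addresses listed in the configuration
   (e.g. the roots of a pharmacologic-action branch);
2. **combination** classes are excluded — a literal, case-insensitive
   substring test for "combination" on the class label and on every
   ancestor's label. The test is deliberately blunt (a label containing
   "non-combination" is flagged too); tokenizing would trade documented
   fidelity for marginal precision;
3. classes with **no eligible member drug**, directly or through a
   descendant, are excluded.

Rules 1–2 alone define the *lexical-eligible* set; all three define the
smaller *instance-eligible* set. Name matching does not need member
data, so the lexical aligner runs on the larger set.

### Membership

Coded sources: a level-5 drug code asserts membership in its level-4
prefix class and infers membership in the level-3 and level-2 prefix
classes; level-1 classes are ignored. The inference walk proceeds from
specific to general and stops at a combination class: a drug whose
asserted class is a combination class is a combination drug and
contributes no membership at all.

Tree-numbered sources: membership is asserted by pharmacologic-action
edges (functional channel), heading-mapped-to edges from supplementary
records (structural), and direct-parent edges from descriptor-level
drugs (structural). A supplementary record mapped to another *drug*
rather than to a class inherits that drug descriptor's structural
parents (one indirection step). Inference adds every ancestor of each
asserted class across all its tree numbers, preserving the channel;
top-level classes receive nothing. Each (ingredient, class) pair is kept
once, asserted provenance winning over inferred.

Addressing-style ambiguity: a dotless tree root such as `D03` is also a
well-formed level-2 code. The style is therefore a property of the
source, not of the address — any dotted address marks the whole source
tree-numbered — and classes carry the resolved style so depth and
top-level status are computed consistently.

### Lexical alignment

Per first-source class, exact matching (case-folded label identity,
against second-source labels and against synonym terms) is tried first;
normalized matching only when exact yields nothing. Matches established
through a shared concept rather than string identity are tagged
cosynonyms and keep the concept id; a label reaching a partner through
more than one concept is flagged ambiguous rather than disambiguated.
One-to-many matches are all kept.

The normalizer handles case, punctuation and hyphen variation,
possessives, inflectional plural suffixes (with a short exception list),
and word order (tokens are sorted). It performs no derivational
morphology and no abbreviation expansion — "HMG CoA" will never match
"Hydroxymethylglutaryl-CoA" — on the expectation that the synonym table
carries such equivalences. The normalizer is idempotent by construction.

### Scoring and classification

With am shared eligible members and a, m side-specific members:

* ES(A,M) = sqrt(am · (am − 0.8)) / (a + m + am). The square-root factor
  damps small intersections relative to the plain Jaccard coefficient:
  ES < JC always, 0 ≤ ES < 1, and ES is strictly increasing in am. The
  0.8 constant is part of the score's definition.
* IS(A,M) = ((a − m)/(a + m)) · (am / min(am + a, am + m)), with IS = 0
  for identical member sets (a = m = 0) and undefined for disjoint
  classes. Negative IS means the first-source class is contained;
  a = 0 forces IS = −1 exactly.

Only pairs with am ≥ 1 are materialized; an inverted drug → classes
index keeps the cost proportional to actual co-membership rather than
the full cross-product. Both scores are computed in full precision;
reported values are rounded half-up to 2 decimals.

Thresholds default to 0.5 for both ES and |IS| and compare with ≥.
Best equivalence per class is the maximum-ES pair at or above threshold
(ties: larger am, then lexicographically smaller partner id). Best
inclusion is the first pair in descending-ES order whose |IS| reaches
threshold *and* whose sign makes the class the contained side; ranking
by |IS| instead would systematically select the broadest container,
whereas a high ES among qualifying pairs identifies the *smallest*
class that still covers the contained one. The same pair may serve as
both best equivalence and best inclusion. Where the second source
distinguishes structural from functional classes, the summary tables
additionally select best inclusions per target kind, so a class can
have one best structural container and one best functional container.

### Consistency and integration

The consistency matrix crosses LEX± with EQ± over the cross-product of
the two instance-eligible sets. Lexical matches involving a class with
no eligible drug cannot be assessed extensionally and are tallied as
"no data" outside the four cells. The LEX−/EQ− cell is the arithmetic
remainder of the universe and is never enumerated.

Integration induces the subgraph over a scope of classes, their
bridged partners and all ancestors, then adds typed bridge edges:
equivalence (undirected, stored once with sorted endpoints) for EQ+
pairs and inclusion (directed contained → container) for IN+ pairs.
The JSON form is canonical; the DOT rendering is generated from it and
carries the same node and edge multiset.

## Synthetic data

The generator emulates the structural features the method depends on:
a shared ingredient pool with a configurable non-clinical fraction, a
coded source populated through level-5 codes and a tree-numbered source
populated through parent/pharmacologic-action edges, planted
cross-source relations, combination-labelled and top-level distractor
classes, and optional random extra memberships (noise). Planted pairs
draw disjoint ingredient slices, so at zero noise the scored pair list
equals the planted list exactly and recovery is checkable against the
emitted ground truth; side-specific drugs exist in both sources (as
class-less records) so they survive the shared-universe filter without
perturbing other pairs.

Defaults plant three equivalences (overlap 0.80–0.85 of the union,
sizes 8–12 — comfortably above threshold without being degenerate) and
three inclusions (coverage 0.80–1.0, containers 3–5× the contained
class, on both directions), over 300 ingredients with 10% non-clinical
and one combination filler class in ten. For an equivalence, the shared
count is overlap · union (am = round(o·(sa+sb)/(1+o))); for an
inclusion it is overlap · contained-class size. Expected downstream
flags in `truth.json` are derived inside the generator by direct
arithmetic on the planted counts, independent of the scoring module, so
they can serve as an oracle for it.

What the generator does *not* emulate: realistic drug nomenclature
(labels are synthetic), multi-parentage tree numbers, qualifier
semantics, or the size and sparsity of full production terminologies.
Passing the recovery tests therefore demonstrates correctness of the
mechanics on controlled structure, not performance on licensed
real-world releases — corpus-level counts from such releases are
explicitly out of scope.

A second fixture (`table8_fixture`) realizes ten fully specified
best-pair rows for clinically relevant drug–drug-interaction classes,
with member counts equal to their published triples; it exercises both
membership styles (one class receives members only by inference from
level-5 codes under an absent level-4 child) and is the basis of the
worked-example reproduction in `scripts/acceptance.py`.

## Numerical and design notes

* The published rendering of the equivalence-score formula is
  typographically garbled; the implementation uses the reconstruction
  sqrt(am·(am−0.8))/(a+m+am), which reproduces all twelve independently
  printed values at two decimals. The clamp max(am−0.8, 0) only matters
  at am = 0, which stored pairs never reach.
* The inclusion score's sign convention follows the published score
  tables (negative = first-source class contained); the accompanying
  prose states one worked magnitude with the opposite sign, and the
  tables were taken as normative. Thresholding uses |IS|.
* The degenerate-case guard for IS is read as "both side-specific
  counts zero", i.e. identical member sets, consistent with the printed
  0 for a (10, 2, 2)-style symmetric pair.
* Rounding for reports is decimal half-up (away from zero), not
  banker's rounding, to match the printed two-decimal values.
* Top-level classes are retained in the hierarchy index (ancestor
  computation may pass through them) but flagged and excluded from
  membership and scoring.
* A coded-source record listing several codes is split into one class
  per code at ingest, sharing the label; tree-numbered records keep all
  tree numbers on one class and take their level as the minimum depth,
  so a class is top-level as soon as any of its addresses is.
* Determinism: the generator draws all randomness from seeds spawned
  off a single root seed; the pipeline itself is deterministic, and two
  runs over the same inputs produce byte-identical outputs apart from
  the manifest timestamp.

## Limitations

* The local normalizer approximates dictionary-grade lexical-variant
  generation; recall on real class names depends on the supplied
  synonym table.
* The combination filter's substring rule can over-exclude
  (documented and tested as such).
* Only pairwise, two-source alignment is supported; aligning three or
  more classifications requires repeated pairwise runs.
* Thresholds (0.5/0.5) are the published heuristics; their sensitivity
  is not explored here, though both are configurable.
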