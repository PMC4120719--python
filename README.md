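# classalign

Tools for assessing the consistency of drug classes across two
classification sources — for example an ATC-style coded classification
(five levels, codes like `C10AA`) and a MeSH-style tree-numbered
descriptor system (tree numbers like `D03.438.810.835`).

Drug classifications built for different purposes rarely agree: classes
with similar names can hold different drugs, and classes with similar
drugs can carry unrelated names. `classalign` is aimed at terminologists
and pharmacovigilance engineers who need to curate a crosswalk between
two such systems. It aligns the classes two independent ways and
contrasts the results:

* **lexically**, by class names — exact match, normalized match
  (case/punctuation/inflection/word order), and cosynonymy through a
  concept-keyed synonym table;
* **extensionally**, by the drug members the classes share, after
  normalizing drugs to base-form ingredients and restricting to
  clinically relevant ingredients present in both sources.

## Scores

For a class *A* from the first source and *M* from the second, with *am*
shared member drugs and *a*, *m* drugs specific to each side:

* **Equivalence score** (a modified Jaccard coefficient that damps pairs
  sharing few drugs):

  ```
  ES(A,M) = sqrt(am · (am − 0.8)) / (a + m + am)
  ```

* **Inclusion score** (one-sidedness of the non-shared drugs times
  coverage of the smaller class):

  ```
  IS(A,M) = ((a − m) / (a + m)) · (am / min(am + a, am + m))
  ```

  with IS = 0 when a = m = 0. IS ∈ [−1, 1]; −1 means A is strictly
  contained in M, +1 the reverse.

Pairs with ES ≥ 0.5 are flagged equivalent (EQ+); pairs with |IS| ≥ 0.5
are flagged inclusions (IN+). Per class, the best equivalence partner is
the highest-ES pair; the best inclusion partner is the first pair in
descending-ES order whose inclusion points the right way (the highest-|IS|
pair would name the broadest possible container, not the tightest one).
Lexical and instance-based alignments are then crossed into a
LEX± × EQ± consistency matrix, and the strong relations can be emitted
as bridge edges that merge the two hierarchies into one graph (DOT/JSON).

## Worked example

The ten fully specified best-pair rows for clinically relevant drug–drug
interaction classes ship as a generated fixture. Running the pipeline on
them:

```
classalign synth --table8 --out bundle/
classalign classify --classes bundle/classes.tsv --drugs bundle/drugs.tsv \
    --membership bundle/membership.tsv --normmap bundle/normmap.tsv \
    --synonyms bundle/synonyms.tsv --out out/
# -> 10 pairs: 6 EQ+, 7 IN+ -> out/relations.tsv
```

`out/relations.tsv` then contains, per pair, the member counts and both
scores, e.g.:

```
a_class  b_class   am  a_only  m_only  jc    es    is     eq_flag  in_flag  direction
N02CC    D014363   7   0       1       0.88  0.82  -1.0   1        1        A_in_B
N02A     D009294   15  3       11      0.52  0.50  -0.48  1        0        none
N06AB    D017367   6   0       8       0.43  0.40  -1.0   0        1        A_in_B
D01AC    D001393   11  1       147     0.07  0.07  -0.9   0        1        A_in_B
```

Read: the serotonin-agonist class is equivalent to (and strictly
contained in) the tryptamines class; the opioid classes sit exactly at
the equivalence threshold; the SSRI pair misses equivalence but is a
clear inclusion; the azole pair shows how a narrow therapeutic class
nests inside a broad structural one. Six rows are equivalences and the
remaining four come out as pure inclusions, matching their curated
relation labels.

The `synth` subcommand (without `--table8`) generates paired synthetic
classifications with planted equivalence/inclusion structure, noise,
combination classes and non-clinical drugs, plus a `truth.json` for
checking recovery; `validate`, `score`, `report`, `integrate` and `run`
cover the rest of the pipeline (see `classalign --help`).

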