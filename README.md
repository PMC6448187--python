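# phenotext

Portable phenotyping of unstructured clinical notes, built around the OMOP
Common Data Model.

## The problem

Discharge summaries carry most of what a chart says about a patient's
diseases, but it is locked in free text. Phenotyping — deciding per document
whether a condition is **Present**, **Absent**, **Questionable** or
**Unmentioned** — is usually solved either with site-specific regular-expression
rules (accurate, not portable) or with statistical classifiers over standard
concept annotations (portable, weaker on rare classes). `phenotext`
implements the middle ground: every annotation, whether a UMLS concept
mention or a rule match, is persisted as a *stand-off* record in the OMOP CDM
`NOTE_NLP` table, and classification hybridizes a rule cascade with
bag-of-CUIs machine learning.

Two labeling tasks are supported per (document, disease) pair: the
**textual** judgment (what the note explicitly states: Present / Absent /
Questionable / Unmentioned) and the **intuitive** judgment (what a clinician
would conclude: Present / Absent / Questionable).

## The core mechanism: blank-fill offset recording

A cascade of three stages runs per disease: uncertainty contexts first
("possible X", "X?"), then negation contexts ("no evidence of X", "X was
ruled out"), then bare mentions, with strict precedence
Questionable > Absent > Present. Classic cascades *delete* each matched
phrase before the next stage, which destroys character positions. Here each
matched span is instead replaced by **spaces of the same length**, so the
working text never changes length and every recorded span is simultaneously
valid in the original document:

for every recorded match, `original[dis_pos] == dis_alias` and
`original[sen_pos] == sentence`, after any number of cascade stages.

That invariant is what lets rule matches be stored as stand-off `NOTE_NLP`
rows (offset, lexical_variant, snippet) next to concept annotations, and be
reused across systems.

## Pipeline

1. **prep** — split a master file on the `[record_end]` tag into records;
   expand abbreviations (whole-token, table-driven); detect sections by
   matching a heading dictionary at line starts. Section spans partition the
   document exactly (half-open, 0-based).
2. **concepts** — tag CUIs with a gazetteer (longest-match, word-boundary)
   or read MetaMap MMI fielded output.
3. **store** — persist notes and all annotations as OMOP CDM `NOTE_NLP`
   rows in SQLite; each row is assigned a section by offset.
4. **rules** — the blank-fill cascade above, per disease.
5. **features/classification** — per-note CUI-frequency matrix, optionally
   dropping family-history-section concepts and/or restricting to 15
   clinically relevant semantic types; LR / SVM / decision-tree /
   random-forest classifiers tuned by 3-fold cross-validated grid search;
   hybrid prediction: models decide the major classes (intuitive:
   Present/Absent; textual: Present/Unmentioned), the rule cascade decides
   the minor ones.
6. **evaluation** — micro- and macro-averaged precision/recall/F over all
   (document, disease) decisions per task.

A synthetic-corpus generator (`phenotext.synth`) emits sectioned notes,
gazetteer, rule set, abbreviation table and dual gold labels with the
statistical structure the pipeline assumes, so everything is testable
without access-restricted clinical data.

## Worked example

```python
from phenotext import DiseaseRules, classify_disease

rules = DiseaseRules("coronary artery disease",
                     aliases=["coronary artery disease"])
text = ("possible coronary artery disease "
        "but no evidence of coronary artery disease")
judgment, tables = classify_disease(text, rules)
print(judgment)
for m in tables.questionable + tables.absent:
    print(m.category, m.dis_pos, repr(m.sentence), m.sen_pos)
```

prints

```
Questionable
Questionable (9, 32) 'possible coronary artery disease' (0, 32)
Absent (52, 75) 'no evidence of coronary artery disease' (37, 75)
```

The uncertainty stage matched first and blanked its phrase, the negation
stage then matched the second clause, and the final judgment is
Questionable by precedence. Both recorded spans slice the *original* string
to exactly the recorded alias and sentence — e.g. `text[9:32]` is
`"coronary artery disease"` — which is the offset-fidelity guarantee.

End to end, on a seeded synthetic corpus:

```bash
phenotext simulate --n-notes 200 --seed 1 --out-dir scratch/corpus
phenotext run-all --corpus scratch/corpus/master.txt \
  --gazetteer scratch/corpus/gazetteer.tsv --rules scratch/corpus/ruleset.yaml \
  --sections scratch/corpus/sections.yaml \
  --abbreviations scratch/corpus/abbreviations.tsv \
  --gold scratch/corpus/gold.tsv --out-dir scratch/run --seed 1
```

prints one metric row per task, e.g.

```
task          P-Micro  P-Macro  R-Micro  R-Macro  F-Micro  F-Macro
textual        1.0000   1.0000   1.0000   1.0000   1.0000   1.0000
```

(perfect recovery is expected here: synthetic notes are built from the same
templates the rules and features can express — see `docs/methods.md` for
what that does and does not establish).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main result from scratch: it generates a seeded
200-note synthetic corpus over 16 diseases, runs the entire pipeline
(preparation → sections → tagging → NOTE_NLP persistence → rule cascade →
hybrid decision-tree classification on a held-out 40% split), prints the
micro/macro metric tables for both tasks, and writes the results JSON to
`--out`.
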