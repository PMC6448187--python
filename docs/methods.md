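# Methods

This note documents the models, conventions and design choices behind
`phenotext`, and what its synthetic-data tests do and do not establish.

## Offsets and stand-off annotation

All spans are 0-based, half-open `[start, end)` character offsets into the
*prepared* (deabbreviated) record text. Section boundary detection uses an
inclusive-end convention in some descriptions of this kind of system
("section 1 ends one character before section 2 starts"); here that is
represented as `end == next.start`, a pure notation change. Deabbreviation
runs per record *before* any offset-bearing annotation, so its length
changes are harmless; the raw record text is kept immutable alongside.

Section detection matches dictionary headings case-insensitively at line
starts only; ties at one offset go to the longest heading. Detected spans
always partition `[0, len(text))`: text before the first heading is a
preamble pseudo-section with id 0, and a heading-free document is a single
preamble. Every stored `NOTE_NLP` row is assigned the unique section
containing its start offset.

## The rule cascade and blank-fill

For one disease the cascade is: Questionable stage (uncertainty trigger and
alias co-occurring within one clause, in either order, up to 60 interleaving
non-boundary characters), Absent stage (negation triggers, same geometry),
Present stage (remaining bare aliases). Each match is recorded, then its
full context span is overwritten with same-length whitespace before matching
continues. Consequences, all property-tested:

- **length invariance** — the working text never changes length;
- **offset fidelity** — every recorded `dis_pos`/`sen_pos` slices the
  original document to exactly the recorded alias/sentence;
- **precedence** — final judgment is Questionable > Absent > Present; no
  match at all is Unmentioned (textual task) or a no-decision marker
  (intuitive task, where Unmentioned is not a legal class).

The "sentence" of a Questionable/Absent match is the maximal span the
context pattern itself matched, not an independently segmented sentence;
clause boundaries are `. ; : ?` and newline. Within a stage, patterns are
applied in trigger order (trigger-before-alias, then alias-before-trigger),
repeatedly until exhausted; blank-filling makes later overlapping matches
impossible, so the procedure is deterministic. The shipped trigger
inventories (uncertainty: possible, probable, question of, rule out, r/o,
`\?`; negation: no evidence of, denies, negative for, ruled out, without)
are editable YAML configuration, not fixed truth — real deployments tune
them per corpus.

## NOTE_NLP persistence

`NOTE_NLP` carries exactly the standard columns (note_nlp_id, note_id,
section_concept_id, snippet, offset, lexical_variant, note_nlp_concept_id,
nlp_system, nlp_date_time). The `offset` column serializes `"start:end"`;
concept rows put the CUI in `note_nlp_concept_id`, rule rows a
`disease:category` code with `nlp_system = "rule_engine"`. Snippets are the
context sentence for Questionable/Absent rule rows and a ±50-character
clipped window otherwise. Semantic types live in a `CONCEPT_SEMANTIC_TYPE`
side table keyed by concept id so the standard table is not extended;
`nlp_date_time` is caller-injected for reproducibility (wall clock only in
the CLI). The backend is a single SQLite file; the portable artifact is the
schema, and MySQL-flavoured DDL can be emitted for server deployments.

## Features, classifiers, hybrid

Features are per-note CUI occurrence counts. Two filters:

- **family history** — drop rows whose section is the flagged
  family-history section (a relative's disease is not the patient's);
- **semantic types** — keep only concepts among 15 clinically relevant
  types (anatomy T017/T022/T023; disorders T047/T048/T049/T184; findings
  T033; lab results T034; procedures T059/T060/T061; drugs/chemicals
  T121/T122/T123).

The row set is always *all* notes — a fully filtered note keeps an all-zero
row — so train/test splits stay aligned across filter configurations, and
any filtered matrix is elementwise ≤ the unfiltered one.

Four classifiers (logistic regression, SVM, decision tree, random forest)
are tuned by exhaustive grid search over fixed grids (LR: C ∈ {0.01, 0.1,
1, 10, 100}; SVM: same C × {linear, rbf}; DT: criterion ∈ {gini, entropy};
RF: n_estimators ∈ {5, 10, 30, 50, 80, 100} × criterion — 5/10/2/12
configurations) with stratified, seeded 3-fold cross-validation. The CV
scoring criterion is micro-averaged F, matching the headline evaluation
metric; this is a package choice, exposed in config. One independent model
is trained per disease and task.

**Hybrid combination.** Minor classes (intuitive: Questionable; textual:
Questionable and Absent) have too few examples to train on, so models are
fit on major-class records only (intuitive: Present/Absent; textual:
Present/Unmentioned) and minor-class labels come from the rule cascade. At
prediction time a minor-class rule judgment always wins; otherwise the model
decides. When rules and model disagree on a *major* class the model wins by
default (`rule_overrides_majors` flips this) — the conflict policy is
genuinely open and therefore configurable. The six-iteration tuning
protocol is the cross product {all-classes ML, majors-hybrid} × {all CUIs,
−family history, −family history + 15 types}.

## Evaluation

Decisions are pooled over all (note, disease) pairs of a task into one
contingency table. Micro metrics pool TP/FP/FN over classes first; macro
metrics average per-class P/R/F, by default over classes with nonzero gold
support only (a class that never occurs in gold would contribute an
undefined recall; including it as zero is available via flag). F is
2PR/(P+R), defined as 0 at P+R=0. In single-label multiclass data micro-P =
micro-R = micro-F, a useful self-check that holds by construction. Whether
macro should average over classes, diseases, or both is a genuinely open
convention; pooled-over-diseases-then-per-class is implemented and isolated
in one function.

## The synthetic corpus: what it states and what it can't show

The generator's defaults describe a comorbidity-rich discharge-summary
population over obesity and fifteen comorbidities: per disease, Present
0.35, Absent 0.25, Questionable 0.10, Unmentioned 0.30; abbreviation rate
0.30; family-history confounder rate 0.10. Category realizations are the
template sentences above, which makes the textual gold label *derivable*:
running the emitted rule set over the emitted notes reproduces the textual
gold exactly, and the tests verify this exhaustively.

Two non-obvious generator choices:

- **Confounders avoid Unmentioned diseases.** The cascade is
  section-agnostic by design (family-history handling belongs to the
  feature filter), so a family-history mention of an otherwise-unmentioned
  disease would flip the cascade's judgment to Present and break gold
  derivability. Confounders are therefore only attached to diseases already
  mentioned in the note body; a dedicated constructed corpus (tests) covers
  the family-history-only case for the filter-direction check.
- **Intuitive labels are realized, not just sampled.** For a
  textual-Unmentioned disease the intuitive label is Present with prior 0.5,
  and when Present the note receives the disease's two *marker* concepts
  (e.g. metformin + elevated hemoglobin A1c for diabetes) without naming the
  disease — mimicking how clinicians infer unstated conditions, and giving
  the bag-of-CUIs model a learnable signal where rules are silent.

Because mentions, markers and labels are generated from the same templates
the rules and features can express, the end-to-end hybrid run recovers gold
nearly perfectly (micro-F ≥ 0.95 at n=400; typically 1.0). A green
end-to-end test therefore establishes *mechanical correctness of the whole
chain* — offsets, persistence, filtering, training, combination, scoring —
not clinical accuracy. Real discharge summaries have misspellings, unlisted
aliases, cross-sentence negation scope, hedging the trigger inventory
misses, and label noise; none of that is modeled, and published-corpus
scores cannot be reproduced without the restricted data.

## Numerical and degenerate-input choices

- Gazetteer tagging is longest-match-first, case-insensitive, word-boundary
  anchored; overlapping shorter matches are suppressed.
- MMI positional info is read as 0-based start/length; a one-based flag
  shifts by −1 (dialects differ). Malformed lines are skipped with a
  warning by default, or raise in strict mode.
- Empty master file → zero notes; missing end tag → one record with a
  warning; empty text → zero sections; empty gazetteer → zero annotations.
- A training class with fewer than 3 members cannot be stratified into 3 CV
  folds: `train_eval` raises, and the pipeline falls back to predicting the
  most frequent training label for that disease (ties broken
  lexicographically), logged.
- Train/test split is a seeded 60/40 shuffle (the challenge's official
  split is unavailable); all randomness flows from explicit integer seeds
  and fixed iteration orders, so identical configurations are byte-identical
  in reports and manifests.

## Known limitations

- Negation/uncertainty detection is trigger-window based; no syntactic
  scope, no cross-sentence resolution, no machine-learned context
  classifier.
- The gazetteer tagger is a desk-scale stand-in for a full UMLS
  concept extractor; it does no word-sense disambiguation.
- Only the NOTE/NOTE_NLP slice of the CDM is modeled (no person, visit or
  vocabulary tables).
- The per-disease one-vs-rest architecture and the macro-averaging
  convention are documented choices; alternative conventions would change
  macro numbers on unbalanced data.
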