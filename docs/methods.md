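# Methods

## Identification model

The in vivo pharmacology subset of an assay table is defined by the
conjunction of five clauses evaluated independently per record:

| clause | predicate | rejection code |
|---|---|---|
| format | `bao_format == "BAO_0000218"` (organism-based) | `NOT_ORGANISM_FORMAT` |
| organism | `assay_organism_l2 == "Mammalia"` **or** `target_organism_l2 == "Mammalia"` | `NOT_MAMMAL` |
| description | no case-insensitive match of `in[ -]?vitro\|ex[ -]?vivo` | `DESCRIPTION_EXCLUSION` |
| type | `assay_type != 'A'` (excludes ADME(T)/pharmacokinetics) | `ADMET_TYPE` |
| source | `src_id ∈ {1}` (scientific literature) | `NOT_LITERATURE` |

The organism OR-clause is essential for xenograft studies, where the assay
organism is the host animal and the target organism the implanted species.
Records with an empty description are accepted but flagged
`MISSING_DESCRIPTION`: an exclusion regex is vacuously false on absent
text, and such assays simply cannot be annotated. Organism comparison is a
case-sensitive exact match by default because the upstream database stores
the literal class label; `ignore_organism_case=True` relaxes it. Duplicate
assay identifiers collapse to their first row (DISTINCT semantics) with a
logged warning. The BAO identifier, mammal label and admitted source codes
are all configurable; the defaults above are the curation conditions the
package models.

## Annotation model

The classification dictionary is an ordered list of level-3 assay classes,
each carrying level-2/level-1 parents, a source (`Hock_2016`, `Vogel_2008`,
`Vogel_2013` for reference animal models; `phenotype` for disease/endpoint
terms), one or more regex patterns, MeSH descriptor labels, and optional
inducer / positive-control compounds. Matching rules:

- patterns are applied exactly as written (case variation is usually
  encoded in the pattern, e.g. `[Tt]ail\W?[Ff]lick`); an optional per-entry
  `i` flag enables ignore-case for simple phenotype terms;
- in the flat file, `|` separates *alternative patterns* of one entry, so a
  single pattern may not use top-level alternation — semantically
  equivalent, and it keeps the file format trivially splittable;
- an entry contributes at most one hit per assay: patterns are tried in
  order and the first that matches anywhere records the hit (leftmost
  match, lowest pattern index), because the mapping table links assays to
  classes, not to patterns;
- all matching entries are kept (multi-label; no precedence or
  suppression), each hit recording the exact matched substring;
- hits are sorted by (assay_id, assay_class_id) so output files are
  reproducible.

Per assay, `has_model_annotation` is true when any hit comes from a
Hock/Vogel source, `has_phenotype_annotation` when any hit has source
`phenotype`, and `annotated` is their disjunction.

The shipped seed dictionary covers 27 classes — every class used by the
worked examples plus the classes exercised by the synthetic generator.
Only the tail-flick pattern is an externally given pattern
(`provenance=external`); the remaining patterns, some level-1/2 parents and
some MeSH lists were written for this package from the class names
(`provenance=repo`). The dictionary format deliberately matches what a
full, externally curated dictionary (hundreds of models) would use.

## MeSH mapping

MeSH descriptor labels attach to assays only through classes: an assay's
term set is the deduplicated union over its hit classes' term lists, kept
byte-for-byte as stored (uppercase labels; semicolon-joined in files, so
labels may contain commas). Tree-letter categories for reporting (C04,
C23, ...) come from a separate term→codes crosswalk; the shipped table
covers the seed vocabulary only and is repo-curated — one term may carry
several codes because MeSH places many descriptors in multiple branches.
Direct assay-level MeSH assignment without an intermediate class is
intentionally unsupported.

## Reporting

Coverage percentages use the total number of identified assays as base —
the only base under which the headline rates (fraction annotated, by
model, by phenotype, by both) are mutually consistent, since
`annotated = model + phenotype − both` under inclusion–exclusion. The API
returns full precision; display rounding (`CoverageStats.formatted`)
rounds overall coverage to one decimal and the source-specific rates to
whole percent. Breakdowns count distinct (assay, label) pairs — an assay
with two level-1 parents counts once per parent, so totals differ between
axes by design. Labels below the threshold (defaults: 2% for level-1, 3%
for MeSH tree; both configurable in [0, 100]) merge into an "Other" row
whose member labels are retained. Row order is (count desc, label asc);
the breakdown is invariant to input order.

## Evaluation

The gold standard is a list of curator-labelled assays; an assay is
curator-positive when any experiment **or** phenotype phrase was assigned
(the phrase columns are kept for manual inspection only — per-class
agreement is out of scope, the binary annotated/not decision is scored).
Rows flagged `excluded` (judged not in vivo after the fact) are skipped
before counting. Gold assays without a prediction row count as
predicted-negative with a warning; `strict_missing` turns this into an
error. Statistics follow the standard definitions — sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), F1
2TP/(2TP+FP+FN) — computed at full precision; a statistic whose
denominator is zero is reported as absent (`None`, listed in
`undefined`), never as 0.

## Synthetic data generator

The generator emulates the *structure* of a literature-extracted in vivo
corpus, not its language: descriptions come from ~20 hand-written templates
with varying species, dose, route and timing. Annotatable templates embed a
trigger phrase for known seed-dictionary classes; decoy templates reuse
pharmacology vocabulary with no trigger (true negatives); each contaminant
template fails exactly one identification clause. About one in eight in
vivo records is a xenograft-style record (mammalian target organism only).

Category counts are apportioned **exactly** (largest-remainder method) from
the `CorpusSpec` fractions rather than drawn per record, so corpus composition is
exact and small validation sets can be sized precisely; the seeded RNG
(NumPy `default_rng`, PCG64 — fixed so fixtures are stable) only shuffles
the category assignment and fills template parameters. Defaults mirror the
coverage structure of the curated corpus the package models: 66.5% of in
vivo assays annotated, 38% by a reference model, 51% by a phenotype, 23% by
both (`fraction_annotatable` defaults to the inclusion–exclusion identity
`model + phenotype − both`); `n_assays=500` and 70% in vivo keep the
default corpus small and mixed. `generate_gold` derives a curator gold
standard from the planted truth with controlled disagreement: `flip_fp`
truth-annotated assays become curator-negative (yielding false positives of
the pipeline), `flip_fn` truth-unannotated assays become curator-positive
(false negatives), and `n_excluded` rejected records (in vitro phrases
preferred) are appended as excluded rows.

Because planted labels are recovered exactly by construction, passing tests
demonstrate the *mechanics* of the pipeline — clause logic, pattern
matching, counting, scoring — not annotation accuracy on real descriptions,
whose vocabulary, misspellings, negations and sparsity the templates do not
model. Real-corpus accuracy is what the evaluation module is for.

## Numerical and degenerate-input choices

- Percentages with a zero base are errors, not 0 (`coverage_summary`
  rejects `n_total == 0`).
- Breakdown threshold 0 disables "Other" grouping; an empty pair set yields
  an empty breakdown.
- Confusion-matrix cells must be non-negative; duplicate gold ids are
  errors.
- File I/O: UTF-8 TSV without quoting; values may not contain tab or
  newline (writers reject them); `;` joins multi-valued cells and may not
  occur inside values; empty string means absent. TSV over CSV because
  descriptions routinely contain commas.
- Output files are byte-identical across reruns with identical inputs and
  configuration; the run manifest holds the configuration hash and row
  counts and contains no timestamps.

## Problem sizes

The test suite and the acceptance script run synthetic corpora of 100–1000
records and a 500-assay gold standard (488 scored after 12 exclusions, 351
annotated, 36/63 planted disagreements — the validation design the package
models); these sizes exercise every code path exactly while keeping the
default runs fast.

## Known limitations

- Pattern-based annotation has no negation handling ("no analgesic
  activity" still annotates analgesia) and no fuzzy matching; a model not
  named by a characteristic phrase cannot be annotated.
- The seed dictionary is a small, representative slice; corpus-scale
  coverage numbers require a full curated dictionary supplied externally.
- MeSH labels are not validated against an NLM vocabulary release, and no
  cross-ontology resolution (EFO/DOID/UMLS) is attempted.
- Organism classes are consumed as pre-joined level-2 labels; taxonomy
  resolution from raw taxon identifiers is out of scope.
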