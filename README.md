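# invivoannot

Curation of **in vivo pharmacology assays** from flat tabular assay records.

Large bioactivity databases such as ChEMBL hold hundreds of thousands of
assays whose only description is compact free text written by data
extractors ("Analgesic activity in tail flick test, oral administration").
Among them sit the in vivo experiments — compounds tested in whole-animal
disease, phenotype and toxicity models — which are hard to use because no
ontology organises animal models and the descriptions follow no controlled
vocabulary. `invivoannot` implements a rule-based curation pipeline for
this problem, aimed at cheminformaticians and drug-discovery data
scientists:

1. **Identification** — select in vivo pharmacology assays with five
   auditable filter clauses over assay metadata: BioAssay Ontology format
   is *organism-based* (`BAO_0000218`); assay **or** target organism class
   is `Mammalia` (the OR admits xenografts); the description does not match
   the case-insensitive regex `in[ -]?vitro|ex[ -]?vivo`; the assay type is
   not ADME(T) (`assay_type != 'A'`); the source is scientific literature
   (`src_id == 1`). Every rejection carries its reason codes.
2. **Annotation** — match a curated dictionary of regular-expression text
   patterns against each description to assign a three-level assay
   classification (level 1: broad disease/phenotype category; level 2:
   related group; level 3: specific model or endpoint). Two annotation
   stages are distinguished by the entry source: *reference animal models*
   from the Hock/Vogel pharmacological-assay reference works (e.g.
   `[Tt]ail\W?[Ff]lick` → "Radiant Heat Method") and *phenotype endpoints*
   from common disease terms (e.g. "antimalarial"). Annotation is
   multi-label: all matching classes are kept, with the matched substring
   recorded for provenance.
3. **MeSH mapping** — project class hits onto Medical Subject Headings
   descriptor labels (the per-assay term set is the union over its classes)
   for interoperability with other disease-indexed resources.
4. **Reporting** — corpus coverage (fraction annotated, by model, by
   phenotype, by both) and frequency breakdowns by level-1 heading or MeSH
   tree category, with low-frequency labels grouped into "Other".
5. **Evaluation** — confusion matrix and sensitivity / specificity /
   precision / F1 of the binary annotated-vs-not decision against a curator
   gold standard, skipping gold rows flagged as not-in-vivo.

A deterministic **synthetic corpus generator** produces assay records,
planted ground truth and gold standards so the whole pipeline is testable
without any database access. A seed classification dictionary (27 classes
with patterns, MeSH terms, inducer and positive-control compounds) ships as
package data; externally curated dictionaries in the same TSV schema load
through the same path.

## Worked example

The ten example assay descriptions shipped with the package (from the
publicly documented ChEMBL in vivo dataset) run through the first three
stages:

```python
from importlib import resources
from invivoannot import (identify_corpus, annotate_corpus, mesh_corpus,
                         seed_dictionary, coverage_summary)
from invivoannot.io import read_assays

dictionary = seed_dictionary()
with resources.as_file(resources.files("invivoannot.data")
                       / "worked_example_assays.tsv") as p:
    records = read_assays(p)

accepted, decisions = identify_corpus(records)
table = annotate_corpus(accepted, dictionary)
coverage = coverage_summary(table, n_total=len(accepted))
print(f"accepted {len(accepted)} of {len(records)} assays")
print(f"annotated: {coverage.n_annotated} "
      f"({coverage.formatted()['pct_annotated']}%)")
```

prints

```
accepted 10 of 10 assays
annotated: 8 (80.0%)
```

and the per-assay summaries show the expected mix — two assays annotated
only by a reference animal model (adjuvant arthritis; renal hypertension),
two only by a phenotype endpoint (airway obstruction; antimalarial
activity), four by both (two tail-flick analgesia assays, a CCl4
liver-injury assay, an L1210 leukemia assay), and two whose descriptions
are too unspecific to annotate:

```
  CHEMBL772714  model           AC_ADJUVANT_ARTHRITIS
  CHEMBL777832  model           AC_RENAL_HTN
  CHEMBL683996  phenotype       AC_AIRWAY
  CHEMBL716118  phenotype       AC_ANTIMALARIAL
  CHEMBL732290  model+phenotype AC_ANALGESIC_PHEN;AC_RADIANT_HEAT
  CHEMBL723844  model+phenotype AC_ANALGESIC_PHEN;AC_RADIANT_HEAT
 CHEMBL2328414  model+phenotype AC_CCL4_LIVER;AC_DILI_PHEN
  CHEMBL703119  model+phenotype AC_L1210;AC_LEUKEMIA_PHEN;AC_NEOPLASM_PHEN
  CHEMBL785102  -               -
  CHEMBL732935  -               -
```

MeSH mapping then attaches descriptor terms through the hit classes, e.g.
`CHEMBL703119 → {LEUKEMIA, LEUKEMIA L1210, NEOPLASMS}`.

## Command line

Each stage is a subcommand of the `invivoannot` console script
(`identify`, `annotate`, `mesh`, `report`, `evaluate`, `simulate`, and
`run` for the whole pipeline with a YAML config). For example:

```sh
invivoannot simulate --n 500 --seed 7 --out-assays assays.tsv --out-truth truth.tsv
invivoannot run --assays assays.tsv --out-dir out/
```

All inputs and outputs are UTF-8 tab-delimited files (schemas documented in
`invivoannot/io.py`); outputs are byte-identical across reruns with the
same inputs and configuration.

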