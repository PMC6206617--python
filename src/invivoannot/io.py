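"""Readers and writers for the pipeline's tab-delimited flat files.

All files are UTF-8, tab-delimited, header-first, unquoted. An empty cell
means "absent". Multi-valued cells join with ";" (MeSH terms, compounds,
class ids, reasons) except regex pattern lists, which join with "|"; values
therefore may not contain their delimiter, and no value may contain a tab
or newline — writers reject such values rather than quote them.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

from .annotation import AnnotationHit, AnnotationTable, AssaySummary
from .dictionary import CompiledDictionary, load_dictionary
from .evaluation import ClassificationStats, ConfusionMatrix, GoldLabel
from .mesh import MeshAssignment
from .records import AssayRecord, FilterDecision

ASSAY_COLUMNS = [
    "assay_id", "description", "assay_type", "bao_format",
    "assay_organism_l2", "target_organism_l2", "src_id",
]
DECISION_COLUMNS = ["assay_id", "accepted", "reasons"]
DICTIONARY_COLUMNS = [
    "assay_class_id", "level1", "level2", "level3", "source", "patterns",
    "pattern_flags", "mesh_terms", "inducer_compounds", "control_compounds",
    "provenance",
]
MAPPING_COLUMNS = ["assay_id", "assay_class_id", "matched_text"]
SUMMARY_COLUMNS = [
    "assay_id", "annotated", "has_model_annotation",
    "has_phenotype_annotation", "class_ids",
]
MESH_COLUMNS = ["assay_id", "mesh_terms", "contributing_class_ids"]
GOLD_COLUMNS = ["assay_id", "curator_positive", "excluded"]
TREE_CODE_COLUMNS = ["mesh_term", "tree_codes"]
TRUTH_COLUMNS = [
    "assay_id", "accepted", "reasons", "class_ids",
    "has_model_annotation", "has_phenotype_annotation",
]


class SchemaError(ValueError):
    """A flat file does not match its declared schema."""


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a TSV as strings, verifying the required header columns.

    Unknown columns are preserved; missing cells become empty strings. A
    ragged row (e.g. caused by a stray tab inside a value) raises
    :class:`SchemaError` with its line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False,
            quoting=3, encoding="utf-8",  # QUOTE_NONE: cells are raw text
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed row: {exc}") from exc
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def write_table(
    frame: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write a TSV (unquoted), refusing values that embed tab or newline."""
    if columns is not None:
        ordered = list(columns) + [c for c in frame.columns if c not in columns]
        frame = frame[ordered]
    for column in frame.columns:
        bad = frame[column].astype(str).str.contains(r"[\t\n\r]", regex=True)
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: value in column {column!r} (row {row}) contains an "
                "embedded tab or newline"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, quoting=3, encoding="utf-8")


# ---------------------------------------------------------------- assays

def _record_from_row(row: Mapping[str, str], line: int, path) -> AssayRecord:
    src = row.get("src_id", "")
    try:
        src_id = int(src) if src != "" else None
    except ValueError:
        raise SchemaError(f"{path}: line {line}: src_id {src!r} is not an integer")
    try:
        return AssayRecord(
            assay_id=row["assay_id"],
            description=row.get("description", ""),
            assay_type=row.get("assay_type", ""),
            bao_format=row.get("bao_format", ""),
            assay_organism_l2=row.get("assay_organism_l2", ""),
            target_organism_l2=row.get("target_organism_l2", ""),
            src_id=src_id,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: line {line}: {exc}") from exc


def read_assays(path: str | Path) -> list[AssayRecord]:
    frame = read_table(path, ASSAY_COLUMNS)
    return [
        _record_from_row(row, line, path)
        for line, row in enumerate(frame.to_dict("records"), start=2)
    ]


def assays_frame(records: Iterable[AssayRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_id": r.assay_id,
                "description": r.description,
                "assay_type": r.assay_type,
                "bao_format": r.bao_format,
                "assay_organism_l2": r.assay_organism_l2,
                "target_organism_l2": r.target_organism_l2,
                "src_id": "" if r.src_id is None else str(r.src_id),
            }
            for r in records
        ],
        columns=ASSAY_COLUMNS,
    )


def write_assays(records: Iterable[AssayRecord], path: str | Path) -> None:
    write_table(assays_frame(records), path, ASSAY_COLUMNS)


# -------------------------------------------------------------- decisions

def write_decisions(decisions: Iterable[FilterDecision], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "assay_id": d.assay_id,
                "accepted": str(int(d.accepted)),
                "reasons": ";".join(d.reasons),
            }
            for d in decisions
        ],
        columns=DECISION_COLUMNS,
    )
    write_table(frame, path, DECISION_COLUMNS)


def read_decisions(path: str | Path) -> list[FilterDecision]:
    frame = read_table(path, DECISION_COLUMNS)
    return [
        FilterDecision(
            assay_id=row["assay_id"],
            accepted=row["accepted"] == "1",
            reasons=tuple(r for r in row["reasons"].split(";") if r),
        )
        for row in frame.to_dict("records")
    ]


# ------------------------------------------------------------- dictionary

def read_dictionary_file(path: str | Path) -> CompiledDictionary:
    frame = read_table(path, DICTIONARY_COLUMNS)
    return load_dictionary(frame.to_dict("records"))


def dictionary_frame(dictionary: CompiledDictionary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_class_id": e.assay_class_id,
                "level1": e.level1,
                "level2": e.level2,
                "level3": e.level3,
                "source": e.source,
                "patterns": "|".join(e.patterns),
                "pattern_flags": e.pattern_flags,
                "mesh_terms": ";".join(e.mesh_terms),
                "inducer_compounds": ";".join(e.inducer_compounds),
                "control_compounds": ";".join(e.control_compounds),
                "provenance": e.provenance,
            }
            for e in dictionary
        ],
        columns=DICTIONARY_COLUMNS,
    )


def write_dictionary(dictionary: CompiledDictionary, path: str | Path) -> None:
    write_table(dictionary_frame(dictionary), path, DICTIONARY_COLUMNS)


# ------------------------------------------------------------- annotation

def write_annotation(table: AnnotationTable, mapping_path, summary_path) -> None:
    mapping = pd.DataFrame(
        [
            {
                "assay_id": h.assay_id,
                "assay_class_id": h.assay_class_id,
                "matched_text": h.matched_text,
            }
            for h in table.hits
        ],
        columns=MAPPING_COLUMNS,
    )
    write_table(mapping, mapping_path, MAPPING_COLUMNS)
    summary = pd.DataFrame(
        [
            {
                "assay_id": s.assay_id,
                "annotated": str(int(s.annotated)),
                "has_model_annotation": str(int(s.has_model_annotation)),
                "has_phenotype_annotation": str(int(s.has_phenotype_annotation)),
                "class_ids": ";".join(s.class_ids),
            }
            for s in table.summaries
        ],
        columns=SUMMARY_COLUMNS,
    )
    write_table(summary, summary_path, SUMMARY_COLUMNS)


def read_annotation(mapping_path, summary_path) -> AnnotationTable:
    mapping = read_table(mapping_path, MAPPING_COLUMNS)
    summary = read_table(summary_path, SUMMARY_COLUMNS)
    hits = [
        AnnotationHit(
            assay_id=row["assay_id"],
            assay_class_id=row["assay_class_id"],
            matched_text=row["matched_text"],
        )
        for row in mapping.to_dict("records")
    ]
    summaries = [
        AssaySummary(
            assay_id=row["assay_id"],
            annotated=row["annotated"] == "1",
            has_model_annotation=row["has_model_annotation"] == "1",
            has_phenotype_annotation=row["has_phenotype_annotation"] == "1",
            class_ids=tuple(c for c in row["class_ids"].split(";") if c),
        )
        for row in summary.to_dict("records")
    ]
    return AnnotationTable(hits=hits, summaries=summaries)


# ------------------------------------------------------------------- mesh

def write_mesh(assignments: Iterable[MeshAssignment], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "assay_id": a.assay_id,
                "mesh_terms": ";".join(sorted(a.mesh_terms)),
                "contributing_class_ids": ";".join(sorted(a.contributing_class_ids)),
            }
            for a in assignments
        ],
        columns=MESH_COLUMNS,
    )
    write_table(frame, path, MESH_COLUMNS)


def read_mesh(path: str | Path) -> list[MeshAssignment]:
    frame = read_table(path, MESH_COLUMNS)
    return [
        MeshAssignment(
            assay_id=row["assay_id"],
            mesh_terms=frozenset(t for t in row["mesh_terms"].split(";") if t),
            contributing_class_ids=frozenset(
                c for c in row["contributing_class_ids"].split(";") if c
            ),
        )
        for row in frame.to_dict("records")
    ]


# ------------------------------------------------------------------- gold

def read_gold(path: str | Path) -> list[GoldLabel]:
    frame = read_table(path, GOLD_COLUMNS)
    return [
        GoldLabel(
            assay_id=row["assay_id"],
            curator_positive=row["curator_positive"] == "1",
            excluded=row["excluded"] == "1",
            experiment_phrase=row.get("experiment_phrase", ""),
            phenotype_phrase=row.get("phenotype_phrase", ""),
        )
        for row in frame.to_dict("records")
    ]


def write_gold(gold: Iterable[GoldLabel], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "assay_id": g.assay_id,
                "curator_positive": str(int(g.curator_positive)),
                "excluded": str(int(g.excluded)),
                "experiment_phrase": g.experiment_phrase,
                "phenotype_phrase": g.phenotype_phrase,
            }
            for g in gold
        ],
        columns=GOLD_COLUMNS + ["experiment_phrase", "phenotype_phrase"],
    )
    write_table(frame, path)


# -------------------------------------------------------------- crosswalk

def read_tree_codes_file(path: str | Path) -> dict[str, tuple[str, ...]]:
    frame = read_table(path, TREE_CODE_COLUMNS)
    return {
        row["mesh_term"]: tuple(c for c in row["tree_codes"].split(";") if c)
        for row in frame.to_dict("records")
    }


# ------------------------------------------------------------- evaluation

def evaluation_payload(
    cm: ConfusionMatrix, stats: ClassificationStats
) -> dict[str, object]:
    """JSON-ready bundle of the matrix and its statistics."""
    return {
        "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "n_scored": cm.n_scored,
        "statistics": {
            "sensitivity": stats.sensitivity,
            "specificity": stats.specificity,
            "precision": stats.precision,
            "f1": stats.f1,
        },
        "statistics_2dp": stats.rounded(2),
        "undefined": list(stats.undefined),
    }
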