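"""Corpus-level coverage statistics and frequency breakdowns.

Coverage counts how many identified in vivo assays received any annotation,
a reference-animal-model annotation, a phenotype annotation, or both. All
percentages use the total number of identified assays as their base — the
only base under which the published headline figures are mutually
consistent. Frequency breakdowns tally distinct (assay, label) pairs on a
chosen axis (level-1 assay-classification headings, or MeSH tree-letter
categories) and merge low-frequency labels into an "Other" row.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .annotation import AnnotationTable
from .dictionary import CompiledDictionary
from .mesh import MeshAssignment

LEVEL1 = "LEVEL1"
MESH_TREE = "MESH_TREE"
AXES = (LEVEL1, MESH_TREE)

#: Default "Other" grouping cutoffs (percent) per axis.
DEFAULT_THRESHOLDS = {LEVEL1: 2.0, MESH_TREE: 3.0}


@dataclass(frozen=True)
class CoverageStats:
    """Annotation coverage of an identified in vivo assay corpus."""

    n_total: int
    n_annotated: int
    n_model: int
    n_phenotype: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive (percentages undefined)")
        if self.n_annotated > self.n_total:
            raise ValueError("n_annotated exceeds n_total")
        if self.n_both > min(self.n_model, self.n_phenotype):
            raise ValueError("n_both exceeds a marginal count")

    @property
    def n_unannotated(self) -> int:
        return self.n_total - self.n_annotated

    @property
    def pct_annotated(self) -> float:
        return 100.0 * self.n_annotated / self.n_total

    @property
    def pct_unannotated(self) -> float:
        return 100.0 * self.n_unannotated / self.n_total

    @property
    def pct_model(self) -> float:
        return 100.0 * self.n_model / self.n_total

    @property
    def pct_phenotype(self) -> float:
        return 100.0 * self.n_phenotype / self.n_total

    @property
    def pct_both(self) -> float:
        return 100.0 * self.n_both / self.n_total

    def formatted(self) -> dict[str, float | int]:
        """Display rounding: overall coverage to 1 dp, the source-specific
        rates to whole percent. Internal values stay full precision."""
        return {
            "n_total": self.n_total,
            "n_annotated": self.n_annotated,
            "n_unannotated": self.n_unannotated,
            "n_model": self.n_model,
            "n_phenotype": self.n_phenotype,
            "n_both": self.n_both,
            "pct_annotated": round(self.pct_annotated, 1),
            "pct_unannotated": round(self.pct_unannotated, 1),
            "pct_model": round(self.pct_model),
            "pct_phenotype": round(self.pct_phenotype),
            "pct_both": round(self.pct_both),
        }


def coverage_summary(annotation_table: AnnotationTable, n_total: int) -> CoverageStats:
    """Tally annotation flags over a corpus, with percentage base *n_total*.

    *n_total* may exceed the table's row count (assays missing from the
    table count as unannotated) but not undercut it.
    """
    if n_total < annotation_table.n_assays:
        raise ValueError(
            f"n_total={n_total} smaller than the annotation table "
            f"({annotation_table.n_assays} assays)"
        )
    summaries = annotation_table.summaries
    return CoverageStats(
        n_total=n_total,
        n_annotated=sum(s.annotated for s in summaries),
        n_model=sum(s.has_model_annotation for s in summaries),
        n_phenotype=sum(s.has_phenotype_annotation for s in summaries),
        n_both=sum(
            s.has_model_annotation and s.has_phenotype_annotation for s in summaries
        ),
    )


@dataclass(frozen=True)
class BreakdownRow:
    label: str
    count: int
    percentage: float


@dataclass(frozen=True)
class FrequencyBreakdown:
    axis: str
    rows: tuple[BreakdownRow, ...]
    other_threshold_pct: float
    other_row: BreakdownRow | None = None
    other_labels: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(r.count for r in self.rows) + (
            self.other_row.count if self.other_row else 0
        )


def breakdown(
    pairs: Iterable[tuple[str, str]],
    axis: str,
    threshold_pct: float | None = None,
) -> FrequencyBreakdown:
    """Frequency table of distinct (assay_id, label) pairs on *axis*.

    An assay contributes one count per distinct label it maps to, so counts
    across axes need not agree. Labels whose share falls below
    *threshold_pct* (default per axis: 2% for LEVEL1, 3% for MESH_TREE) merge
    into an "Other" row; rows sort by descending count then label.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r} (expected one of {AXES})")
    if threshold_pct is None:
        threshold_pct = DEFAULT_THRESHOLDS[axis]
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold_pct must lie in [0, 100]")

    counts = Counter(label for _, label in set(pairs))
    total = sum(counts.values())
    rows, other_labels, other_count = [], [], 0
    for label, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        pct = 100.0 * count / total if total else 0.0
        if pct < threshold_pct:
            other_labels.append(label)
            other_count += count
        else:
            rows.append(BreakdownRow(label, count, pct))
    other_row = None
    if other_labels:
        other_row = BreakdownRow(
            "Other", other_count, 100.0 * other_count / total if total else 0.0
        )
    return FrequencyBreakdown(
        axis=axis,
        rows=tuple(rows),
        other_threshold_pct=threshold_pct,
        other_row=other_row,
        other_labels=tuple(sorted(other_labels)),
    )


def level1_pairs(
    annotation_table: AnnotationTable, dictionary: CompiledDictionary
) -> set[tuple[str, str]]:
    """(assay_id, level-1 heading) pairs for the LEVEL1 breakdown axis."""
    return {
        (hit.assay_id, dictionary[hit.assay_class_id].level1)
        for hit in annotation_table.hits
    }


def mesh_tree_pairs(
    assignments: Iterable[MeshAssignment],
    tree_codes: Mapping[str, tuple[str, ...]],
) -> set[tuple[str, str]]:
    """(assay_id, tree code) pairs for the MESH_TREE breakdown axis.

    A term absent from the crosswalk contributes nothing; a term with
    several codes contributes one pair per code.
    """
    pairs = set()
    for assignment in assignments:
        for term in assignment.mesh_terms:
            for code in tree_codes.get(term, ()):
                pairs.add((assignment.assay_id, code))
    return pairs
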