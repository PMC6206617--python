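"""Multi-label annotation of assay descriptions with the pattern dictionary.

Every dictionary entry is searched against every description. An entry
contributes at most one hit per assay: its patterns are tried in order and
the first pattern that matches anywhere records the hit (leftmost match,
lowest pattern index). All matching entries are kept — descriptions are
legitimately multi-label, e.g. a tail-flick assay carries both the
Hock/Vogel reference-model class and a general analgesia phenotype class.

Patterns are applied exactly as written; case tolerance is usually encoded
inside the pattern (``[Tt]ail\\W?[Ff]lick``), with a per-entry ``i`` flag
available for simple phenotype terms.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

from .dictionary import CompiledDictionary
from .records import AssayRecord


@dataclass(frozen=True)
class AnnotationHit:
    """A single assay-to-class link with the matched text for provenance."""

    assay_id: str
    assay_class_id: str
    matched_text: str
    pattern_index: int = 0


@dataclass(frozen=True)
class AssaySummary:
    """Per-assay annotation flags derived from its hits."""

    assay_id: str
    annotated: bool
    has_model_annotation: bool
    has_phenotype_annotation: bool
    class_ids: tuple[str, ...] = ()


@dataclass
class AnnotationTable:
    """All hits for a corpus plus one summary row per assay (corpus order)."""

    hits: list[AnnotationHit]
    summaries: list[AssaySummary]

    def summary_for(self, assay_id: str) -> AssaySummary:
        if not hasattr(self, "_index"):
            self._index = {s.assay_id: s for s in self.summaries}
        return self._index[assay_id]

    def annotated_flags(self) -> dict[str, bool]:
        """assay_id -> annotated, e.g. as predictions for evaluation."""
        return {s.assay_id: s.annotated for s in self.summaries}

    @property
    def n_assays(self) -> int:
        return len(self.summaries)


def annotate_description(
    description: str,
    dictionary: CompiledDictionary,
    assay_id: str = "",
) -> list[AnnotationHit]:
    """Return one hit per dictionary entry matching *description*.

    Hits appear in dictionary order; an empty description yields no hits.
    """
    hits = []
    for entry in dictionary:
        for index, pattern in enumerate(entry.compiled):
            match = pattern.search(description)
            if match:
                hits.append(
                    AnnotationHit(
                        assay_id=assay_id,
                        assay_class_id=entry.assay_class_id,
                        matched_text=match.group(0),
                        pattern_index=index,
                    )
                )
                break
    return hits


def annotate_corpus(
    assays: Iterable[AssayRecord],
    dictionary: CompiledDictionary,
) -> AnnotationTable:
    """Annotate every assay of an (already identified) corpus.

    Hits are ordered by (assay_id, assay_class_id) for reproducible output
    files; summaries keep corpus order. Assays already screened by
    identification are not re-checked here.
    """
    all_hits: list[AnnotationHit] = []
    summaries: list[AssaySummary] = []
    for record in assays:
        hits = annotate_description(record.description, dictionary, record.assay_id)
        has_model = any(dictionary[h.assay_class_id].is_model for h in hits)
        has_phenotype = any(
            dictionary[h.assay_class_id].is_phenotype for h in hits
        )
        summaries.append(
            AssaySummary(
                assay_id=record.assay_id,
                annotated=bool(hits),
                has_model_annotation=has_model,
                has_phenotype_annotation=has_phenotype,
                class_ids=tuple(sorted(h.assay_class_id for h in hits)),
            )
        )
        all_hits.extend(hits)
    all_hits.sort(key=lambda h: (h.assay_id, h.assay_class_id))
    return AnnotationTable(hits=all_hits, summaries=summaries)
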