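"""Project class-level annotations onto MeSH descriptor terms.

MeSH terms attach to assays only through classification entries: an assay's
term set is the deduplicated union of the MeSH lists of every class it was
annotated with. Labels are preserved byte-for-byte as stored in the
dictionary (uppercase descriptor labels, e.g. ``COLITIS, ULCERATIVE``).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

from .annotation import AnnotationHit, AnnotationTable
from .dictionary import CompiledDictionary


@dataclass(frozen=True)
class MeshAssignment:
    assay_id: str
    mesh_terms: frozenset[str]
    contributing_class_ids: frozenset[str]


def mesh_for_assay(
    hits: Iterable[AnnotationHit],
    dictionary: CompiledDictionary,
    assay_id: str = "",
) -> MeshAssignment:
    """Union the MeSH terms of every class hit for one assay.

    Raises ``KeyError`` naming any hit class absent from the dictionary.
    Classes without MeSH terms contribute nothing; no hits (or no mapped
    terms) yields an empty term set.
    """
    terms: set[str] = set()
    class_ids: set[str] = set()
    for hit in hits:
        entry = dictionary[hit.assay_class_id]
        class_ids.add(entry.assay_class_id)
        terms.update(entry.mesh_terms)
        if not assay_id:
            assay_id = hit.assay_id
    return MeshAssignment(
        assay_id=assay_id,
        mesh_terms=frozenset(terms),
        contributing_class_ids=frozenset(class_ids),
    )


def mesh_corpus(
    annotation_table: AnnotationTable,
    dictionary: CompiledDictionary,
) -> list[MeshAssignment]:
    """One MeshAssignment per annotated assay, ordered by assay_id."""
    by_assay: dict[str, list[AnnotationHit]] = {}
    for hit in annotation_table.hits:
        by_assay.setdefault(hit.assay_id, []).append(hit)
    return [
        mesh_for_assay(by_assay[assay_id], dictionary, assay_id)
        for assay_id in sorted(by_assay)
    ]
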