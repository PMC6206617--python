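"""Core record types shared across the pipeline stages.

An :class:`AssayRecord` is one row of the flat assay table. The columns are a
denormalised view of the assay metadata a relational bioactivity database such
as ChEMBL would hold across several joined tables:

==================  ==========================================================
column              relational origin
==================  ==========================================================
assay_id            assays.chembl_id
description         assays.description (free text written by data extractors)
assay_type          assays.assay_type (B binding, F functional, A ADME(T), ...)
bao_format          assays.bao_format (BioAssay Ontology format identifier)
assay_organism_l2   organism_class.l2 for the assay taxon (e.g. "Mammalia")
target_organism_l2  organism_class.l2 for the target taxon
src_id              assays.src_id (1 = scientific literature)
==================  ==========================================================

Empty strings denote absent values throughout (the flat-file contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AssayRecord:
    """One assay row flowing through identification and annotation."""

    assay_id: str
    description: str = ""
    assay_type: str = ""
    bao_format: str = ""
    assay_organism_l2: str = ""
    target_organism_l2: str = ""
    src_id: int | None = None

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ValueError("assay_id must be non-empty")
        if len(self.assay_type) > 1:
            raise ValueError(
                f"assay_type must be a single character, got {self.assay_type!r}"
            )


# Rejection-reason codes, in the order the filter clauses are evaluated.
NOT_ORGANISM_FORMAT = "NOT_ORGANISM_FORMAT"
NOT_MAMMAL = "NOT_MAMMAL"
DESCRIPTION_EXCLUSION = "DESCRIPTION_EXCLUSION"
ADMET_TYPE = "ADMET_TYPE"
NOT_LITERATURE = "NOT_LITERATURE"
# Warning only: an empty description cannot be annotated downstream but does
# not by itself exclude an assay from the in vivo set.
MISSING_DESCRIPTION = "MISSING_DESCRIPTION"

REJECTION_REASONS = (
    NOT_ORGANISM_FORMAT,
    NOT_MAMMAL,
    DESCRIPTION_EXCLUSION,
    ADMET_TYPE,
    NOT_LITERATURE,
    MISSING_DESCRIPTION,
)

#: Reasons that block acceptance (MISSING_DESCRIPTION is a warning, not a veto).
BLOCKING_REASONS = frozenset(REJECTION_REASONS) - {MISSING_DESCRIPTION}


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the in vivo identification filter for one assay."""

    assay_id: str
    accepted: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        unknown = set(self.reasons) - set(REJECTION_REASONS)
        if unknown:
            raise ValueError(f"unknown rejection reasons: {sorted(unknown)}")
        blocking = set(self.reasons) & BLOCKING_REASONS
        if self.accepted == bool(blocking):
            raise ValueError(
                "accepted flag inconsistent with blocking reasons "
                f"({self.assay_id}: accepted={self.accepted}, reasons={self.reasons})"
            )
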