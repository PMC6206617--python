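"""Select disease-/phenotype-relevant in vivo assays from a flat assay table.

An assay is kept when all of the following hold:

1. its BioAssay Ontology format is "organism-based format" (``BAO_0000218``),
   i.e. the experiment was performed in a whole organism;
2. the assay organism *or* the target organism is classified as ``Mammalia``
   (the OR admits xenograft studies, where e.g. a human cell line — the target
   organism — is implanted into a mouse — the assay organism);
3. the free-text description does not refer to an in vitro or ex vivo
   experiment (case-insensitive ``in[ -]?vitro|ex[ -]?vivo``);
4. the assay is not an ADME(T)/pharmacokinetic assay (``assay_type != 'A'``);
5. the record was extracted from the scientific literature (``src_id == 1``),
   which excludes deposited datasets such as TG-GATES.

Records with an empty description are kept but flagged with a
``MISSING_DESCRIPTION`` warning: the exclusion regex is vacuously false on an
absent description, and such assays simply cannot be annotated downstream.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable

from .records import (
    ADMET_TYPE,
    DESCRIPTION_EXCLUSION,
    MISSING_DESCRIPTION,
    NOT_LITERATURE,
    NOT_MAMMAL,
    NOT_ORGANISM_FORMAT,
    AssayRecord,
    FilterDecision,
)

logger = logging.getLogger(__name__)

#: BAO identifier for "organism-based format".
ORGANISM_BASED_BAO = "BAO_0000218"
#: Level-2 organism-class label selecting mammalian assay/target organisms.
MAMMAL_LABEL = "Mammalia"
#: Source codes admitted by default (1 = scientific literature).
LITERATURE_SRC_IDS = frozenset({1})

#: Descriptions matching this pattern describe in vitro / ex vivo work.
EXCLUSION_PATTERN = r"in[ -]?vitro|ex[ -]?vivo"
_EXCLUSION_RE = re.compile(EXCLUSION_PATTERN, re.IGNORECASE)


def description_exclusion_matches(text: str) -> bool:
    """True iff *text* refers to an in vitro or ex vivo experiment.

    The match is case-insensitive and unanchored; an empty string never
    matches.
    """
    return bool(_EXCLUSION_RE.search(text))


def is_in_vivo_candidate(
    record: AssayRecord,
    *,
    bao_id: str = ORGANISM_BASED_BAO,
    mammal_label: str = MAMMAL_LABEL,
    src_ids: frozenset[int] | set[int] = LITERATURE_SRC_IDS,
    ignore_organism_case: bool = False,
) -> FilterDecision:
    """Evaluate the five filter clauses for one assay record.

    Returns a :class:`FilterDecision` whose ``reasons`` lists every failed
    clause in evaluation order. Organism-class comparison is case-sensitive
    exact match by default (the database stores the literal label);
    ``ignore_organism_case`` relaxes it.
    """
    if not src_ids:
        raise ValueError("src_ids must be non-empty")
    reasons: list[str] = []

    if record.bao_format != bao_id:
        reasons.append(NOT_ORGANISM_FORMAT)

    if ignore_organism_case:
        mammal = mammal_label.casefold()
        organisms = (
            record.assay_organism_l2.casefold(),
            record.target_organism_l2.casefold(),
        )
    else:
        mammal = mammal_label
        organisms = (record.assay_organism_l2, record.target_organism_l2)
    if mammal not in organisms:
        reasons.append(NOT_MAMMAL)

    if description_exclusion_matches(record.description):
        reasons.append(DESCRIPTION_EXCLUSION)

    if record.assay_type == "A":
        reasons.append(ADMET_TYPE)

    if record.src_id not in src_ids:
        reasons.append(NOT_LITERATURE)

    accepted = not reasons
    if not record.description.strip():
        reasons.append(MISSING_DESCRIPTION)

    return FilterDecision(record.assay_id, accepted, tuple(reasons))


def identify_corpus(
    records: Iterable[AssayRecord],
    **clause_options,
) -> tuple[list[AssayRecord], list[FilterDecision]]:
    """Apply :func:`is_in_vivo_candidate` to a corpus.

    Duplicate ``assay_id`` rows collapse to their first occurrence (DISTINCT
    semantics; a warning is logged). Input order is preserved; ``decisions``
    holds one entry per distinct input assay_id, accepted or not.
    """
    accepted: list[AssayRecord] = []
    decisions: list[FilterDecision] = []
    seen: set[str] = set()
    for record in records:
        if record.assay_id in seen:
            logger.warning("duplicate assay_id %s: keeping first row", record.assay_id)
            continue
        seen.add(record.assay_id)
        decision = is_in_vivo_candidate(record, **clause_options)
        decisions.append(decision)
        if decision.accepted:
            accepted.append(record)
    return accepted, decisions
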