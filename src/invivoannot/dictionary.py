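"""The three-level assay classification dictionary.

Each entry is one level-3 assay class — a specific reference animal model
(from the Hock/Vogel pharmacological-assay reference works) or a disease /
phenotype endpoint — together with its level-2 group and broad level-1
heading, one or more regular-expression text patterns that recognise the
class in free-text assay descriptions, the MeSH descriptor labels mapped to
the class, and any inducer / positive-control compounds.

Sources distinguish the two annotation stages: ``Hock_2016``, ``Vogel_2008``
and ``Vogel_2013`` mark reference animal models; ``phenotype`` marks a common
disease/phenotype term identified directly in descriptions.

A seed dictionary covering all classes used by the worked examples and the
synthetic corpus generator ships with the package (:func:`seed_dictionary`);
full externally curated dictionaries load through the same
:func:`load_dictionary` path.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources

#: Sources denoting a reference animal model (stage-one annotation).
MODEL_SOURCES = frozenset({"Hock_2016", "Vogel_2008", "Vogel_2013"})
#: Source denoting a disease/phenotype endpoint (stage-two annotation).
PHENOTYPE_SOURCE = "phenotype"
VALID_SOURCES = MODEL_SOURCES | {PHENOTYPE_SOURCE}


@dataclass(frozen=True)
class ClassificationEntry:
    """One level-3 assay class with its parents, patterns and mappings."""

    assay_class_id: str
    level1: str
    level2: str
    level3: str
    source: str
    patterns: tuple[str, ...]
    pattern_flags: str = ""
    mesh_terms: tuple[str, ...] = ()
    inducer_compounds: tuple[str, ...] = ()
    control_compounds: tuple[str, ...] = ()
    provenance: str = "repo"
    compiled: tuple[re.Pattern, ...] = field(repr=False, compare=False, default=())

    @property
    def is_model(self) -> bool:
        return self.source in MODEL_SOURCES

    @property
    def is_phenotype(self) -> bool:
        return self.source == PHENOTYPE_SOURCE


class DictionaryError(ValueError):
    """Raised when a classification dictionary fails validation."""


class CompiledDictionary:
    """An ordered, validated collection of :class:`ClassificationEntry`."""

    def __init__(self, entries: Iterable[ClassificationEntry]):
        self.entries: list[ClassificationEntry] = list(entries)
        self.by_id: dict[str, ClassificationEntry] = {}
        for entry in self.entries:
            if entry.assay_class_id in self.by_id:
                raise DictionaryError(
                    f"duplicate assay_class_id {entry.assay_class_id!r}"
                )
            self.by_id[entry.assay_class_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, assay_class_id: str) -> ClassificationEntry:
        try:
            return self.by_id[assay_class_id]
        except KeyError:
            raise KeyError(f"unknown assay_class_id {assay_class_id!r}") from None

    def __contains__(self, assay_class_id: str) -> bool:
        return assay_class_id in self.by_id


def _compile_flags(flag_string: str, class_id: str) -> int:
    flags = 0
    for ch in flag_string:
        if ch == "i":
            flags |= re.IGNORECASE
        else:
            raise DictionaryError(
                f"entry {class_id}: unsupported pattern flag {ch!r} (only 'i')"
            )
    return flags


def load_dictionary(rows: Iterable[Mapping[str, object]]) -> CompiledDictionary:
    """Build a :class:`CompiledDictionary` from classification-table rows.

    Each row mapping supplies ``assay_class_id``, the three level headings,
    ``source`` and ``patterns`` (a list of regex strings, or a single
    pipe-separated string); ``pattern_flags``, ``mesh_terms``,
    ``inducer_compounds``, ``control_compounds`` and ``provenance`` are
    optional. Raises :class:`DictionaryError` naming the offending class for
    invalid regexes, duplicate ids, unknown sources or empty headings.
    """
    entries = []
    for row in rows:
        class_id = str(row.get("assay_class_id", "") or "")
        if not class_id:
            raise DictionaryError("row with empty assay_class_id")
        levels = {lvl: str(row.get(lvl, "") or "").strip() for lvl in
                  ("level1", "level2", "level3")}
        for lvl, value in levels.items():
            if not value:
                raise DictionaryError(f"entry {class_id}: empty {lvl} heading")
        source = str(row.get("source", "") or "").strip()
        if source.lower() == PHENOTYPE_SOURCE:
            source = PHENOTYPE_SOURCE  # tolerate capitalised "Phenotype"
        if source not in VALID_SOURCES:
            raise DictionaryError(
                f"entry {class_id}: unknown source {source!r} "
                f"(expected one of {sorted(VALID_SOURCES)})"
            )
        # In the flat file "|" separates alternative patterns, so a single
        # pattern cell may not use top-level regex alternation; express
        # alternatives as separate patterns instead.
        raw_patterns = row.get("patterns", "")
        if isinstance(raw_patterns, str):
            patterns = tuple(p for p in raw_patterns.split("|") if p)
        else:
            patterns = tuple(str(p) for p in raw_patterns)
        if not patterns:
            raise DictionaryError(f"entry {class_id}: no patterns")
        flag_string = str(row.get("pattern_flags", "") or "")
        flags = _compile_flags(flag_string, class_id)
        compiled = []
        for pattern in patterns:
            try:
                compiled.append(re.compile(pattern, flags))
            except re.error as exc:
                raise DictionaryError(
                    f"entry {class_id}: invalid pattern {pattern!r}: {exc}"
                ) from exc

        def _multi(name: str) -> tuple[str, ...]:
            value = row.get(name, "")
            if isinstance(value, str):
                return tuple(v.strip() for v in value.split(";") if v.strip())
            return tuple(str(v) for v in value)

        entries.append(
            ClassificationEntry(
                assay_class_id=class_id,
                level1=levels["level1"],
                level2=levels["level2"],
                level3=levels["level3"],
                source=source,
                patterns=patterns,
                pattern_flags=flag_string,
                mesh_terms=_multi("mesh_terms"),
                inducer_compounds=_multi("inducer_compounds"),
                control_compounds=_multi("control_compounds"),
                provenance=str(row.get("provenance", "repo") or "repo"),
                compiled=tuple(compiled),
            )
        )
    return CompiledDictionary(entries)


def _data_path(name: str):
    return resources.files("invivoannot.data").joinpath(name)


def seed_dictionary() -> CompiledDictionary:
    """Load the classification dictionary shipped with the package."""
    from .io import read_dictionary_file

    with resources.as_file(_data_path("seed_dictionary.tsv")) as path:
        return read_dictionary_file(path)


def seed_tree_codes() -> dict[str, tuple[str, ...]]:
    """MeSH descriptor label -> tree-letter category codes (e.g. C04).

    Repo-curated crosswalk covering the seed dictionary's vocabulary only; a
    term may carry several codes because MeSH places many descriptors in more
    than one branch of its tree.
    """
    from .io import read_tree_codes_file

    with resources.as_file(_data_path("mesh_tree_codes.tsv")) as path:
        return read_tree_codes_file(path)
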