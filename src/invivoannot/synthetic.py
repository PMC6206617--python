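"""Deterministic synthetic assay corpora with planted ground truth.

The generator emulates the structure of a literature-extracted in vivo
assay corpus: free-text descriptions built from parameterised templates
(species, dose, route, timing vary) that either embed a trigger phrase for
known seed-dictionary classes ("tail flick", "carrageenan-induced paw
edema", "CCl4-induced ... hepatic injury", "forced swimming test", "L1210
leukemia", ...) or reuse pharmacology vocabulary without any trigger
(decoys, exercising true-negative behaviour). Contaminant records each fail
exactly one identification clause (in vitro phrase, ADMET type, non-mammal
organism, non-literature source, non-organism BAO format).

Category counts are apportioned exactly (largest-remainder method) rather
than drawn per record, so a given :class:`CorpusSpec` always yields the same
composition; the seeded generator (NumPy ``default_rng``, PCG64) only
shuffles assignments and fills template parameters. Default fractions
mirror the coverage structure of the curated corpus this emulates: 66.5% of
in vivo assays annotated, 38% by a reference animal model, 51% by a
phenotype endpoint, 23% by both.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .evaluation import GoldLabel
from .records import (
    ADMET_TYPE,
    DESCRIPTION_EXCLUSION,
    NOT_LITERATURE,
    NOT_MAMMAL,
    NOT_ORGANISM_FORMAT,
    AssayRecord,
)

#: Contaminant kinds and the single identification clause each one fails.
CONTAMINANT_REASONS = {
    "in_vitro_phrase": DESCRIPTION_EXCLUSION,
    "admet_type": ADMET_TYPE,
    "non_mammal": NOT_MAMMAL,
    "non_literature": NOT_LITERATURE,
    "non_organism_format": NOT_ORGANISM_FORMAT,
}

_DEFAULT_CONTAMINANT_RATES = {
    "in_vitro_phrase": 0.3,
    "admet_type": 0.25,
    "non_mammal": 0.2,
    "non_literature": 0.15,
    "non_organism_format": 0.1,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Composition of a synthetic corpus.

    Fractions are of the whole corpus (``fraction_in_vivo``) or of the in
    vivo subset (the annotation fractions). ``fraction_annotatable`` defaults
    to ``fraction_model + fraction_phenotype - fraction_both`` (the
    inclusion–exclusion identity of the emulated corpus); when given
    explicitly, the model/phenotype/both mix is rescaled to it.
    """

    n_assays: int = 500
    fraction_in_vivo: float = 0.7
    fraction_annotatable: float | None = None
    fraction_model: float = 0.38
    fraction_phenotype: float = 0.51
    fraction_both: float = 0.23
    contaminant_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTAMINANT_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assays < 0:
            raise ValueError("n_assays must be non-negative")
        for name in ("fraction_in_vivo", "fraction_model",
                     "fraction_phenotype", "fraction_both"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.fraction_annotatable is not None and not (
            0.0 <= self.fraction_annotatable <= 1.0
        ):
            raise ValueError("fraction_annotatable outside [0, 1]")
        if self.fraction_both > min(self.fraction_model, self.fraction_phenotype):
            raise ValueError(
                "fraction_both exceeds min(fraction_model, fraction_phenotype)"
            )
        if any(rate < 0 for rate in self.contaminant_rates.values()):
            raise ValueError("contaminant rates must be non-negative")
        unknown = set(self.contaminant_rates) - set(CONTAMINANT_REASONS)
        if unknown:
            raise ValueError(f"unknown contaminant kinds: {sorted(unknown)}")

    @property
    def derived_fraction_annotatable(self) -> float:
        if self.fraction_annotatable is not None:
            return self.fraction_annotatable
        return self.fraction_model + self.fraction_phenotype - self.fraction_both


@dataclass(frozen=True)
class TruthRow:
    """Expected pipeline outcome for one generated record."""

    assay_id: str
    accepted: bool
    reasons: tuple[str, ...]
    class_ids: tuple[str, ...]
    has_model_annotation: bool
    has_phenotype_annotation: bool

    @property
    def annotated(self) -> bool:
        return bool(self.class_ids)


_SPECIES = ("rat", "mouse", "guinea pig", "rabbit", "dog")
_ROUTES = ("oral", "intraperitoneal", "subcutaneous", "intravenous")
_DOSES = ("0.3", "1", "3", "10", "30", "100")
_HOURS = ("1", "2", "4", "6", "24")

# Each template: (description format, planted class ids). Class ids refer to
# the seed dictionary; the planted-truth soundness test verifies every
# template truly triggers exactly its listed classes.
_MODEL_ONLY_TEMPLATES = [
    ("Adjuvant arthritic {species} activity determined at a dose of"
     " {dose} mg/kg", ("AC_ADJUVANT_ARTHRITIS",)),
    ("Antihypertensive activity in renal hypertensive {species} after"
     " {route} administration at {dose} mg/kg", ("AC_RENAL_HTN",)),
    ("Acoustic startle response in {species} measured {hours} h after"
     " {route} administration of {dose} mg/kg", ("AC_STARTLE",)),
    ("Spatial discrimination learning in the radial arm maze in {species}"
     " at {dose} mg/kg", ("AC_RADIAL_MAZE",)),
    ("Effect on mean arterial blood pressure in anesthetized {species} at"
     " {dose} mg/kg after {route} administration", ("AC_MEAN_BP",)),
]
_PHENOTYPE_ONLY_TEMPLATES = [
    ("In vivo antimalarial activity against Plasmodium berghei in {species}"
     " after {route} administration at {dose} mg/kg", ("AC_ANTIMALARIAL",)),
    ("Compound was evaluated in vivo for airway obstruction in {species} at"
     " {hours} h after {route} administration", ("AC_AIRWAY",)),
    ("Antidepressant-like activity in {species} assessed as reduction in"
     " immobility time at {dose} mg/kg {route} by tail suspension test",
     ("AC_ANTIDEPRESSANT",)),
    ("Anti-inflammatory activity in {species} assessed as inhibition of"
     " granuloma formation at {dose} mg/kg", ("AC_ANTIINFLAM",)),
    ("Antitumor activity against solid tumor xenograft in {species} at"
     " {dose} mg/kg after {route} administration", ("AC_NEOPLASM_PHEN",)),
]
_BOTH_TEMPLATES = [
    ("Analgesic activity in tail flick test in {species}, {route}"
     " administration", ("AC_RADIANT_HEAT", "AC_ANALGESIC_PHEN")),
    ("Compound was evaluated for opioid agonist activity by antinociceptive"
     " tail-flick assay in {species} at {dose} mg/kg",
     ("AC_RADIANT_HEAT", "AC_ANALGESIC_PHEN")),
    ("Antioxidant activity against CCl4-induced oxidative hepatic injury in"
     " {species} model at {dose} mg/kg, {route}",
     ("AC_CCL4_LIVER", "AC_DILI_PHEN")),
    ("Antidepressant-like activity in {species} assessed as reduction in"
     " immobility time at {dose} mg/kg, {route} by forced swimming test",
     ("AC_DESPAIR_SWIM", "AC_ANTIDEPRESSANT")),
    ("Antitumor activity against L1210 leukemia in {species} measured as"
     " T/C value",
     ("AC_L1210", "AC_LEUKEMIA_PHEN", "AC_NEOPLASM_PHEN")),
    ("Anti-inflammatory activity in {species} assessed as reduction of"
     " carrageenan-induced paw edema at {dose} mg/kg, {route}",
     ("AC_PAW_EDEMA", "AC_ANTIINFLAM")),
]
# Decoys: in vivo vocabulary, no trigger phrase.
_DECOY_TEMPLATES = [
    "Compound was evaluated for the time from injection to peak inhibition"
    " of the twitch response at {dose} mg/kg dose",
    "Binding specificity of the compound in {species} striatum at {hours} h"
    " after {route} injection",
    "Percent reduction was determined using the ratio of mean of treated"
    " animal to that of control animal at a dose of {dose} mg/kg",
    "Change in rectal temperature in {species} at a dose of {dose} umol/kg"
    " by {route} administration",
    "Number of {species} with greater than 100% GH increase over the"
    " control group at {dose} mg/kg",
]
_CONTAMINANT_TEMPLATES = {
    "in_vitro_phrase": (
        "Compound was evaluated in vitro for binding affinity to the"
        " {species} receptor at {dose} uM",
        "Inhibitory activity in ex vivo tissue preparation from {species}"
        " at {dose} uM",
    ),
    "admet_type": (
        "Pharmacokinetics in {species}: Cmax after {route} administration"
        " at {dose} mg/kg",
        "Bioavailability in {species} after {route} administration at"
        " {dose} mg/kg",
    ),
    "non_mammal": (
        "In vivo insecticidal activity against Drosophila melanogaster at"
        " {dose} ppm",
        "In vivo activity in zebrafish larvae at {dose} uM",
    ),
    "non_literature": (
        "Deposited screening result: effect in {species} at {dose} mg/kg"
        " after {route} administration",
    ),
    "non_organism_format": (
        "Inhibition of enzyme activity in a cell based assay at {dose} uM",
    ),
}


def _apportion(total: int, weights: list[float]) -> list[int]:
    """Integer counts summing to *total*, proportional to *weights*
    (largest-remainder method; ties resolved by lower index)."""
    weight_sum = sum(weights)
    if total == 0:
        return [0] * len(weights)
    if weight_sum <= 0:
        raise ValueError("weights must sum to a positive value")
    quotas = [total * w / weight_sum for w in weights]
    counts = [int(q) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(
        range(len(weights)), key=lambda i: (counts[i] - quotas[i], i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _fill(template: str, rng: np.random.Generator) -> str:
    return template.format(
        species=_SPECIES[rng.integers(len(_SPECIES))],
        route=_ROUTES[rng.integers(len(_ROUTES))],
        dose=_DOSES[rng.integers(len(_DOSES))],
        hours=_HOURS[rng.integers(len(_HOURS))],
    )


def _in_vivo_metadata(rng: np.random.Generator) -> dict[str, object]:
    # ~1 in 8 records emulate xenografts: mammalian target organism only.
    if rng.integers(8) == 0:
        organisms = {"assay_organism_l2": "", "target_organism_l2": "Mammalia"}
    else:
        organisms = {"assay_organism_l2": "Mammalia", "target_organism_l2": ""}
    return {
        "assay_type": "F" if rng.integers(4) else "B",
        "bao_format": "BAO_0000218",
        "src_id": 1,
        **organisms,
    }


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[AssayRecord], list[TruthRow]]:
    """Generate records and their expected pipeline outcomes.

    Deterministic for a fixed spec (including its seed); records and truth
    rows align one-to-one in corpus order.
    """
    rng = np.random.default_rng(spec.seed)
    n_in_vivo = round(spec.n_assays * spec.fraction_in_vivo)
    n_out = spec.n_assays - n_in_vivo

    n_annotatable = round(n_in_vivo * spec.derived_fraction_annotatable)
    mix_weights = [
        spec.fraction_model - spec.fraction_both,      # model only
        spec.fraction_phenotype - spec.fraction_both,  # phenotype only
        spec.fraction_both,                            # both
    ]
    if n_annotatable and sum(mix_weights) <= 0:
        raise ValueError(
            "annotatable assays requested but the model/phenotype/both mix "
            "has zero weight"
        )
    n_model_only, n_phen_only, n_both = (
        _apportion(n_annotatable, mix_weights) if n_annotatable else (0, 0, 0)
    )
    n_decoy = n_in_vivo - n_annotatable

    kinds = sorted(spec.contaminant_rates)
    if n_out:
        rates = [spec.contaminant_rates[k] for k in kinds]
        contaminant_counts = _apportion(n_out, rates)
    else:
        contaminant_counts = [0] * len(kinds)

    categories: list[tuple[str, object]] = (
        [("model_only", None)] * n_model_only
        + [("phenotype_only", None)] * n_phen_only
        + [("both", None)] * n_both
        + [("decoy", None)] * n_decoy
        + [
            ("contaminant", kind)
            for kind, count in zip(kinds, contaminant_counts)
            for _ in range(count)
        ]
    )
    rng.shuffle(categories)

    template_pools = {
        "model_only": _MODEL_ONLY_TEMPLATES,
        "phenotype_only": _PHENOTYPE_ONLY_TEMPLATES,
        "both": _BOTH_TEMPLATES,
    }

    records: list[AssayRecord] = []
    truth: list[TruthRow] = []
    for index, (category, kind) in enumerate(categories):
        assay_id = f"SYN{index:06d}"
        if category == "contaminant":
            pool = _CONTAMINANT_TEMPLATES[kind]
            description = _fill(pool[rng.integers(len(pool))], rng)
            metadata = _in_vivo_metadata(rng)
            if kind == "admet_type":
                metadata["assay_type"] = "A"
            elif kind == "non_mammal":
                metadata["assay_organism_l2"] = "Insecta"
                metadata["target_organism_l2"] = ""
            elif kind == "non_literature":
                metadata["src_id"] = 7
            elif kind == "non_organism_format":
                metadata["bao_format"] = "BAO_0000219"
            records.append(AssayRecord(assay_id, description, **metadata))
            truth.append(
                TruthRow(
                    assay_id=assay_id,
                    accepted=False,
                    reasons=(CONTAMINANT_REASONS[kind],),
                    class_ids=(),
                    has_model_annotation=False,
                    has_phenotype_annotation=False,
                )
            )
            continue

        if category == "decoy":
            template = _DECOY_TEMPLATES[rng.integers(len(_DECOY_TEMPLATES))]
            class_ids: tuple[str, ...] = ()
        else:
            pool = template_pools[category]
            template, class_ids = pool[rng.integers(len(pool))]
        description = _fill(template, rng)
        records.append(
            AssayRecord(assay_id, description, **_in_vivo_metadata(rng))
        )
        truth.append(
            TruthRow(
                assay_id=assay_id,
                accepted=True,
                reasons=(),
                class_ids=tuple(sorted(class_ids)),
                has_model_annotation=category in ("model_only", "both"),
                has_phenotype_annotation=category in ("phenotype_only", "both"),
            )
        )
    return records, truth


def generate_gold(
    truth: list[TruthRow],
    flip_fp: int,
    flip_fn: int,
    seed: int,
    n_excluded: int = 0,
) -> list[GoldLabel]:
    """Derive a curator gold standard from planted truth, with controlled
    disagreement.

    ``flip_fp`` truth-annotated assays receive a curator-negative label
    (becoming false positives of the pipeline) and ``flip_fn``
    truth-unannotated assays a curator-positive label (false negatives);
    both subsets are chosen deterministically by *seed*. ``n_excluded``
    rejected records (in vitro / ex vivo contaminants preferred) are
    appended with ``excluded=True``, emulating gold entries that turn out
    not to be in vivo and are dropped before scoring.
    """
    positives = [t for t in truth if t.accepted and t.annotated]
    negatives = [t for t in truth if t.accepted and not t.annotated]
    rejected = sorted(
        (t for t in truth if not t.accepted),
        key=lambda t: (DESCRIPTION_EXCLUSION not in t.reasons, t.assay_id),
    )
    if flip_fp > len(positives):
        raise ValueError(
            f"flip_fp={flip_fp} exceeds {len(positives)} annotated assays"
        )
    if flip_fn > len(negatives):
        raise ValueError(
            f"flip_fn={flip_fn} exceeds {len(negatives)} unannotated assays"
        )
    if n_excluded > len(rejected):
        raise ValueError(
            f"n_excluded={n_excluded} exceeds {len(rejected)} rejected records"
        )
    rng = np.random.default_rng(seed)
    fp_ids = {
        positives[i].assay_id
        for i in rng.choice(len(positives), size=flip_fp, replace=False)
    } if flip_fp else set()
    fn_ids = {
        negatives[i].assay_id
        for i in rng.choice(len(negatives), size=flip_fn, replace=False)
    } if flip_fn else set()

    gold = [
        GoldLabel(
            assay_id=t.assay_id,
            curator_positive=(
                t.annotated != (t.assay_id in fp_ids or t.assay_id in fn_ids)
            ),
        )
        for t in truth
        if t.accepted
    ]
    gold.extend(
        GoldLabel(assay_id=t.assay_id, curator_positive=True, excluded=True)
        for t in rejected[:n_excluded]
    )
    return gold


def truth_frame(truth: list[TruthRow]):
    """Truth rows as a DataFrame matching the truth-table file schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "assay_id": t.assay_id,
                "accepted": str(int(t.accepted)),
                "reasons": ";".join(t.reasons),
                "class_ids": ";".join(t.class_ids),
                "has_model_annotation": str(int(t.has_model_annotation)),
                "has_phenotype_annotation": str(int(t.has_phenotype_annotation)),
            }
            for t in truth
        ]
    )
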