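"""Evaluation of the binary annotated/not-annotated decision against a gold
standard of curator-labelled assays.

The gold standard emulates a set of assays whose descriptions were manually
read by database curators; an assay is curator-positive when any experiment
or phenotype phrase was assigned. Assays the curators considered in vivo
but that are in fact in vitro / ex vivo carry ``excluded=True`` and never
enter the confusion matrix.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldLabel:
    assay_id: str
    curator_positive: bool
    excluded: bool = False
    experiment_phrase: str = ""
    phenotype_phrase: str = ""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of the four agreement cells over the scored (non-excluded) set."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n_scored(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassificationStats:
    """Derived statistics; a statistic with a zero denominator is None and
    its name is listed in ``undefined``."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            name: (None if value is None else round(value, ndigits))
            for name, value in [
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("precision", self.precision),
                ("f1", self.f1),
            ]
        }


def confusion_matrix(
    predictions: Mapping[str, bool],
    gold: Iterable[GoldLabel],
    *,
    strict_missing: bool = False,
) -> ConfusionMatrix:
    """Cross-tabulate pipeline predictions against gold labels.

    *predictions* maps assay_id -> annotated flag (see
    ``AnnotationTable.annotated_flags``). Excluded gold rows are skipped
    before scoring. A scored gold assay missing from *predictions* counts as
    predicted-negative with a warning, or raises under ``strict_missing``.
    Duplicate gold assay_ids raise ``ValueError``.
    """
    seen: set[str] = set()
    tp = fn = fp = tn = 0
    for label in gold:
        if label.assay_id in seen:
            raise ValueError(f"duplicate gold assay_id {label.assay_id!r}")
        seen.add(label.assay_id)
        if label.excluded:
            continue
        if label.assay_id in predictions:
            predicted = predictions[label.assay_id]
        elif strict_missing:
            raise ValueError(
                f"gold assay_id {label.assay_id!r} has no prediction"
            )
        else:
            logger.warning(
                "no prediction for gold assay %s: counting as negative",
                label.assay_id,
            )
            predicted = False
        if predicted and label.curator_positive:
            tp += 1
        elif predicted:
            fp += 1
        elif label.curator_positive:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def classification_stats(cm: ConfusionMatrix) -> ClassificationStats:
    """Sensitivity, specificity, precision and F1 from a confusion matrix.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); F1 = 2·TP/(2·TP+FP+FN). Full precision is
    returned; display rounding is the caller's concern (``rounded``).
    """
    undefined = []

    def _ratio(name: str, num: int, denom: int) -> float | None:
        if denom == 0:
            undefined.append(name)
            return None
        return num / denom

    return ClassificationStats(
        sensitivity=_ratio("sensitivity", cm.tp, cm.tp + cm.fn),
        specificity=_ratio("specificity", cm.tn, cm.tn + cm.fp),
        precision=_ratio("precision", cm.tp, cm.tp + cm.fp),
        f1=_ratio("f1", 2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        undefined=tuple(undefined),
    )
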