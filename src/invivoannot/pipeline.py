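"""End-to-end pipeline: identify -> annotate -> mesh -> report (-> evaluate).

All stage outputs are plain TSV/JSON files that are byte-identical across
repeated runs on the same inputs and configuration; the JSON run manifest
carries versions, a configuration hash and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .annotation import annotate_corpus
from .dictionary import seed_dictionary, seed_tree_codes
from .evaluation import classification_stats, confusion_matrix
from .identification import (
    LITERATURE_SRC_IDS,
    MAMMAL_LABEL,
    ORGANISM_BASED_BAO,
    identify_corpus,
)
from .io import (
    evaluation_payload,
    read_assays,
    read_dictionary_file,
    read_gold,
    read_tree_codes_file,
    write_annotation,
    write_assays,
    write_decisions,
    write_mesh,
)
from .mesh import mesh_corpus
from .reporting import (
    LEVEL1,
    MESH_TREE,
    breakdown,
    coverage_summary,
    level1_pairs,
    mesh_tree_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    assays_path: str
    out_dir: str
    dictionary_path: str | None = None  # None -> packaged seed dictionary
    gold_path: str | None = None
    tree_codes_path: str | None = None
    bao_id: str = ORGANISM_BASED_BAO
    mammal_label: str = MAMMAL_LABEL
    src_ids: tuple[int, ...] = tuple(sorted(LITERATURE_SRC_IDS))
    level1_threshold_pct: float = 2.0
    mesh_threshold_pct: float = 3.0
    strict_missing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.src_ids:
            raise ValueError("src_ids must be non-empty")
        for name in ("level1_threshold_pct", "mesh_threshold_pct"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name}={value} outside [0, 100]")


def _breakdown_payload(bd) -> dict:
    payload = {
        "axis": bd.axis,
        "other_threshold_pct": bd.other_threshold_pct,
        "rows": [
            {"label": r.label, "count": r.count, "percentage": r.percentage}
            for r in bd.rows
        ],
    }
    if bd.other_row:
        payload["other"] = {
            "label": bd.other_row.label,
            "count": bd.other_row.count,
            "percentage": bd.other_row.percentage,
            "grouped_labels": list(bd.other_labels),
        }
    return payload


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages, writing outputs under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``). Any stage
    error propagates as :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    stage = "identify"
    try:
        records = read_assays(config.assays_path)
        accepted, decisions = identify_corpus(
            records,
            bao_id=config.bao_id,
            mammal_label=config.mammal_label,
            src_ids=frozenset(config.src_ids),
        )
        write_assays(accepted, out_dir / "accepted_assays.tsv")
        write_decisions(decisions, out_dir / "decisions.tsv")
        counts["input_assays"] = len(records)
        counts["accepted_assays"] = len(accepted)
        logger.info(
            "identify: %d of %d assays accepted", len(accepted), len(decisions)
        )

        stage = "annotate"
        dictionary = (
            read_dictionary_file(config.dictionary_path)
            if config.dictionary_path
            else seed_dictionary()
        )
        table = annotate_corpus(accepted, dictionary)
        write_annotation(
            table, out_dir / "mapping.tsv", out_dir / "summary.tsv"
        )
        counts["annotation_hits"] = len(table.hits)
        counts["annotated_assays"] = sum(s.annotated for s in table.summaries)
        logger.info(
            "annotate: %d hits over %d of %d assays",
            len(table.hits), counts["annotated_assays"], len(accepted),
        )

        stage = "mesh"
        assignments = mesh_corpus(table, dictionary)
        write_mesh(assignments, out_dir / "mesh.tsv")
        counts["mesh_assignments"] = len(assignments)
        logger.info("mesh: %d assays carry MeSH terms", len(assignments))

        stage = "report"
        report: dict = {}
        if accepted:
            coverage = coverage_summary(table, n_total=len(accepted))
            report["coverage"] = coverage.formatted()
            report["level1_breakdown"] = _breakdown_payload(
                breakdown(
                    level1_pairs(table, dictionary),
                    LEVEL1,
                    config.level1_threshold_pct,
                )
            )
            tree_codes = (
                read_tree_codes_file(config.tree_codes_path)
                if config.tree_codes_path
                else seed_tree_codes()
            )
            report["mesh_breakdown"] = _breakdown_payload(
                breakdown(
                    mesh_tree_pairs(assignments, tree_codes),
                    MESH_TREE,
                    config.mesh_threshold_pct,
                )
            )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        logger.info("report: written")

        if config.gold_path:
            stage = "evaluate"
            gold = read_gold(config.gold_path)
            cm = confusion_matrix(
                table.annotated_flags(), gold,
                strict_missing=config.strict_missing,
            )
            stats = classification_stats(cm)
            (out_dir / "evaluation.json").write_text(
                json.dumps(evaluation_payload(cm, stats), indent=2,
                           sort_keys=True) + "\n"
            )
            counts["gold_rows"] = len(gold)
            counts["scored_assays"] = cm.n_scored
            logger.info(
                "evaluate: %d scored (tp=%d fn=%d fp=%d tn=%d)",
                cm.n_scored, cm.tp, cm.fn, cm.fp, cm.tn,
            )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    config_dict = asdict(config)
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package": "invivoannot",
        "version": __version__,
        "config": config_dict,
        "config_sha256": config_hash,
        "row_counts": counts,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
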