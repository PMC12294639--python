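"""End-to-end pipeline: generate -> detect -> classify -> partition ->
sample -> evaluate.

Chart review is modeled as a labeling oracle that reads the synthetic
ground truth (``truth_pwud``) of the sampled encounters; an external
review-label CSV (columns ``encounter_id,confirmed``) can replace the
oracle so real annotations plug into the same arithmetic.

Every stage is deterministic under the configured seeds, and every
intermediate artifact is written to the output directory:

* ``cohort.jsonl`` — the generated encounters;
* ``structured.csv`` — flat structured fields;
* ``flags.csv`` / ``spans.csv`` — per-encounter criteria and NLP evidence;
* ``partition.json`` — Venn cell counts and id lists;
* ``review_*.csv`` — the sampled ids with oracle labels;
* ``report.md`` / ``summary.json`` — evaluation output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as pio
from .cohort import build_partition, cell_label, comparison_groups, select_review_sample
from .criteria import CodeTable, classify_encounter
from .stats_eval import disparity_report, ppv
from .synthetic_emr import GenerationConfig, generate_cohort, structured_frame
from .text_matching import KeywordLexicon, MatcherConfig
from .types import Encounter

logger = logging.getLogger(__name__)


@dataclass
class ReviewPlan:
    """Which cells get chart review and how many charts."""

    d_only_fraction: Optional[float] = 0.10
    n_only_fraction: Optional[float] = 0.35
    d_only_n: Optional[int] = None
    n_only_n: Optional[int] = None
    seed: int = 0


@dataclass
class PipelineConfig:
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    matcher: MatcherConfig = field(default_factory=MatcherConfig)
    lexicon_path: Optional[str] = None
    code_table_path: Optional[str] = None
    review: ReviewPlan = field(default_factory=ReviewPlan)
    review_labels_path: Optional[str] = None  # external chart-review labels
    output_dir: str = "pipeline_out"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _review_ppv(
    sample_ids: list[str],
    truth: dict[str, Optional[bool]],
    external: Optional[pd.DataFrame],
):
    if external is not None:
        pio.require_columns(external, ["encounter_id", "confirmed"])
        labels = dict(zip(external["encounter_id"].astype(str), external["confirmed"]))
        confirmed = sum(bool(labels[eid]) for eid in sample_ids if eid in labels)
        reviewed = sum(eid in labels for eid in sample_ids)
    else:
        confirmed = sum(bool(truth[eid]) for eid in sample_ids)
        reviewed = len(sample_ids)
    return ppv(confirmed, reviewed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run summary (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        lexicon = (
            KeywordLexicon.from_file(config.lexicon_path)
            if config.lexicon_path else KeywordLexicon.default()
        )
        code_table = (
            CodeTable.from_csv(config.code_table_path)
            if config.code_table_path else CodeTable.default()
        )
        encounters = generate_cohort(config.generation, lexicon=lexicon)
        pio.write_cohort_jsonl(encounters, out / "cohort.jsonl")
        structured_frame(encounters).to_csv(out / "structured.csv", index=False)

        stage = "classify"
        flags = []
        spans = []
        for e in encounters:
            f = classify_encounter(e, code_table, lexicon, config.matcher)
            flags.append((e.encounter_id, f))
        pio.flags_to_frame(flags).to_csv(out / "flags.csv", index=False)

        stage = "partition"
        partition = build_partition(flags)
        bdmn_ids, n_only_ids = comparison_groups(partition)
        partition_payload = {
            "counts": partition.counts(),
            "total_included": partition.total_included,
            "n_excluded": len(partition.excluded_ids),
            "cells": {cell_label(k): v for k, v in sorted(partition.cells.items(),
                                                          key=lambda kv: cell_label(kv[0]))},
        }
        (out / "partition.json").write_text(
            json.dumps(partition_payload, indent=2, sort_keys=True), encoding="utf-8"
        )

        stage = "sample"
        truth = {e.encounter_id: e.truth_pwud for e in encounters}
        external = (
            pd.read_csv(config.review_labels_path)
            if config.review_labels_path else None
        )
        reviews = {}
        for cell, frac, n_abs in (
            ("D", config.review.d_only_fraction, config.review.d_only_n),
            ("N", config.review.n_only_fraction, config.review.n_only_n),
        ):
            if not partition.cell(cell):
                logger.warning("cell %s empty; skipping review sample", cell)
                continue
            sample = select_review_sample(
                partition, cell,
                fraction=None if n_abs is not None else frac,
                n=n_abs, seed=config.review.seed,
            )
            result = _review_ppv(sample.sampled_ids, truth, external)
            reviews[cell] = {"sample": sample, "ppv": result}
            pd.DataFrame(
                {
                    "encounter_id": sample.sampled_ids,
                    "confirmed": [int(bool(truth[eid])) for eid in sample.sampled_ids],
                }
            ).to_csv(out / f"review_{cell}.csv", index=False)

        stage = "evaluate"
        report = disparity_report(partition, encounters)
        (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    summary = {
        "seeds": {
            "generation": config.generation.seed,
            "review": config.review.seed,
        },
        "lexicon_version": lexicon.version,
        "code_table_version": code_table.version,
        "n_encounters": len(encounters),
        "total_included": partition.total_included,
        "n_excluded": len(partition.excluded_ids),
        "cell_counts": partition.counts(),
        "group_sizes": {"bdmn": len(bdmn_ids), "n_only": len(n_only_ids)},
        "review_source": "external" if config.review_labels_path else "synthetic_truth_oracle",
        "ppv": {
            cell: {
                "reviewed": r["ppv"].reviewed,
                "confirmed": r["ppv"].confirmed,
                "ppv": r["ppv"].ppv,
                "ppv_pct_rounded": r["ppv"].ppv_pct_rounded,
                "ci95": list(r["ppv"].ci95),
            }
            for cell, r in reviews.items()
        },
        "odds_ratios": {
            term: {
                "or": orr.or_point,
                "ci95": list(orr.ci95),
                "method": orr.method,
            }
            for term, orr in report.unadjusted.items()
        },
        "adjusted_or": {
            term: {
                "or": fit.or_estimates[{"race": "white", "svi": "svi_34"}[term]],
                "ci95": list(fit.wald_ci95[{"race": "white", "svi": "svi_34"}[term]]),
                "n_used": fit.n_used,
                "converged": fit.converged,
            }
            for term, fit in report.adjusted.items()
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    logger.info(
        "pipeline complete: lexicon=%s codes=%s seeds=%s",
        lexicon.version, code_table.version, summary["seeds"],
    )
    return summary
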