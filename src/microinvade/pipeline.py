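"""End-to-end analysis pipeline.

Stages run in a fixed order mirroring the study's workflow: control-based
curation → prevalence contaminant removal → relative abundance → alpha
diversity / ordination / permutation tests → colonisation classification.
Contaminant removal always precedes colonisation filtering, since the
cleanup was applied to the full table before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import colonisation, preprocess, stats
from .model import (
    AsvCountTable,
    SampleRecord,
    check_join,
    metadata_frame,
)
from .stats import QpcrQuantity


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    params: dict
    contaminant_reports: list = field(default_factory=list)
    curation_discarded: list[str] = field(default_factory=list)
    contaminants_removed: list[str] = field(default_factory=list)
    clean_table: AsvCountTable | None = None
    alpha: pd.DataFrame | None = None
    distance: stats.DistanceMatrix | None = None
    pcoa: stats.PcoaResult | None = None
    permanova: list = field(default_factory=list)
    dispersion: stats.PermutationTestResult | None = None
    alpha_anova: dict = field(default_factory=dict)
    qpcr_table: pd.DataFrame | None = None
    pool: set[str] = field(default_factory=set)
    calls_by_unit: dict = field(default_factory=dict)
    counts: pd.DataFrame | None = None
    global_summary: dict = field(default_factory=dict)
    replicate_count_table: pd.DataFrame | None = None
    replicate_count_anova: dict = field(default_factory=dict)
    heatmap_table: pd.DataFrame | None = None

    def summary(self) -> dict:
        per_unit = (
            self.counts.to_dict(orient="records") if self.counts is not None else []
        )
        return {
            "params": self.params,
            "n_asvs_after_cleanup": (
                len(self.clean_table.asv_ids) if self.clean_table else None
            ),
            "curation_discarded": len(self.curation_discarded),
            "contaminants_removed": len(self.contaminants_removed),
            "pool_size": len(self.pool),
            "per_unit_counts": per_unit,
            **self.global_summary,
            "snow_unique_non_invaders": (
                colonisation.non_invading_pool_count(
                    len(self.pool), self.global_summary.get("global_invaders", 0)
                )
                if self.pool
                else 0
            ),
        }


def run_pipeline(
    table: AsvCountTable,
    records: Sequence[SampleRecord],
    qpcr: Sequence[QpcrQuantity] | None = None,
    detection_threshold: int = 1,
    min_days: int = 2,
    n_permutations: int = 999,
    seed: int | None = None,
    contaminant_score_threshold: float = 0.1,
    include_control_flow_through: bool = True,
) -> PipelineResult:
    """Run every stage on a validated dataset and collect all outputs."""
    result = PipelineResult(
        params={
            "detection_threshold": detection_threshold,
            "min_days": min_days,
            "n_permutations": n_permutations,
            "seed": seed,
            "contaminant_score_threshold": contaminant_score_threshold,
            "include_control_flow_through": include_control_flow_through,
            "negative_controls": "kit and run controls pooled as one batch",
        }
    )

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(name, exc) from exc

        return wrap

    stage("validate")(check_join, table, records)
    lab_ids = [r.sample_id for r in records if r.compartment == "lab_control"]
    lab_ids = [s for s in lab_ids if s in table.sample_ids]

    work = table
    if lab_ids:
        work, discarded = stage("curation")(
            preprocess.control_abundance_curation, work, lab_ids
        )
        result.curation_discarded = discarded
        reports = stage("contaminants")(
            preprocess.prevalence_contaminant_filter,
            work,
            lab_ids,
            contaminant_score_threshold,
            detection_threshold,
        )
        result.contaminant_reports = reports
        flagged = [r.asv_id for r in reports if r.is_contaminant]
        result.contaminants_removed = flagged
        work = work.drop_asvs(flagged)

    # lab controls leave the analysis once cleanup is done
    real_records = [r for r in records if r.compartment != "lab_control"]
    real_ids = [r.sample_id for r in real_records if r.sample_id in set(work.sample_ids)]
    work = stage("subset")(work.subset_samples, real_ids)
    result.clean_table = work

    meta = metadata_frame(real_records).set_index("sample_id").loc[real_ids]

    alpha_rows = []
    for j, sid in enumerate(work.sample_ids):
        col = work.counts[:, j]
        alpha_rows.append(
            {
                "sample_id": sid,
                "richness": stats.richness(col),
                "shannon": stats.shannon(col),
            }
        )
    result.alpha = pd.DataFrame(alpha_rows).merge(
        meta.reset_index(), on="sample_id"
    )

    dm = stage("bray_curtis")(stats.bray_curtis, work)
    result.distance = dm
    result.pcoa = stage("pcoa")(stats.pcoa, dm)

    compartment = meta["compartment"].to_numpy()
    factors = pd.DataFrame({"compartment": compartment})
    result.permanova = stage("permanova")(
        stats.permanova, dm, factors, n_permutations, seed
    )
    result.dispersion = stage("dispersion")(
        stats.dispersion_homogeneity, dm, compartment, n_permutations, seed
    )
    for metric in ("richness", "shannon"):
        anova = stage("alpha_anova")(
            stats.anova_factorial,
            result.alpha[metric].to_numpy(),
            factors,
        )
        result.alpha_anova[metric] = anova

    if qpcr:
        rows = [
            {
                "sample_id": q.sample_id,
                "copies_per_reaction": q.copies_per_reaction,
                "copies_per_unit": stats.qpcr_normalize(q),
            }
            for q in qpcr
            if q.sample_id in set(work.sample_ids)
        ]
        result.qpcr_table = pd.DataFrame(rows)

    tensor = stage("detection")(
        colonisation.DetectionTensor.from_table, work, real_records, detection_threshold
    )
    result.pool = stage("candidate_pool")(
        colonisation.candidate_pool, tensor, include_control_flow_through
    )
    result.calls_by_unit = stage("classification")(
        colonisation.classify_dataset,
        tensor,
        pool=result.pool,
        min_days=min_days,
        include_control_flow_through=include_control_flow_through,
    )
    result.counts, result.global_summary = stage("counts")(
        colonisation.summarize_counts, result.calls_by_unit
    )
    units = list(result.calls_by_unit)
    replicated = [
        u
        for u in units
        if len(
            {
                r.replicate
                for r in real_records
                if r.compartment == "soil"
                and r.arm == "treatment"
                and (r.experiment, r.condition) == u
                and r.replicate is not None
            }
        )
        >= 2
    ]
    if len(replicated) >= 2:
        result.replicate_count_table, result.replicate_count_anova = stage(
            "replicate_anova"
        )(colonisation.replicate_counts_anova, tensor, result.pool, replicated,
          "D29", min_days)
    result.heatmap_table = stage("heatmap")(
        colonisation.export_heatmap_table, result.calls_by_unit, work, real_records
    )
    return result


def calls_frame(calls_by_unit) -> pd.DataFrame:
    """Flatten per-unit colonisation calls into a tidy table."""
    from .model import day_sort_key

    rows = [
        {
            "asv_id": c.asv_id,
            "experiment": c.experiment,
            "condition": c.condition,
            "status": c.status,
            "detection_days": ",".join(sorted(c.detection_days, key=day_sort_key)),
            "detected_on_final_day": c.detected_on_final_day,
        }
        for calls in calls_by_unit.values()
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "asv_id",
            "experiment",
            "condition",
            "status",
            "detection_days",
            "detected_on_final_day",
        ],
    )


def permanova_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "df": r.df,
                "statistic": r.statistic,
                "r_squared": r.r_squared,
                "n_permutations": r.n_permutations,
                "p_value": r.p_value,
            }
            for r in (results if isinstance(results, list) else [results])
        ]
    )


def contaminant_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "asv_id": r.asv_id,
                "prevalence_in_negatives": r.prevalence_in_negatives,
                "prevalence_in_samples": r.prevalence_in_samples,
                "score": r.score,
                "is_contaminant": r.is_contaminant,
            }
            for r in reports
        ],
        columns=[
            "asv_id",
            "prevalence_in_negatives",
            "prevalence_in_samples",
            "score",
            "is_contaminant",
        ],
    )
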