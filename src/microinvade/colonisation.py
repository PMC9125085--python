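"""Classification of snow-derived ASVs as invaders and colonists.

The chain applied to each experiment's treated soils:

1. *Candidate pool* — ASVs detected in at least one snow sample, minus any
   ASV detected in a control microcosm (any compartment, any day) or in a
   pre-treatment soil (field sampling DS, set-up D-10, first day D0, both
   arms).  These are the taxa that can only have arrived with the snow.
2. *Invader* — a pool member detected in a treated soil on at least one
   post-start day (D5–D29).
3. *Potential colonist* — an invader detected on at least ``min_days``
   distinct post-start days, replicates pooled.  Days need not be
   consecutive: a taxon can dip below the detection threshold and
   reappear, so gaps do not disqualify.
4. *Potentially successful colonist* — a potential colonist still detected
   on the final sampling day (D29) in any replicate.

Abundance trends play no role: only presence/absence across days counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AsvCountTable,
    ConfigurationError,
    EXPERIMENTS,
    FINAL_DAY,
    POST_START_DAYS,
    PRE_TREATMENT_DAYS,
    SampleRecord,
    ValidationError,
    check_join,
    day_sort_key,
)
from .preprocess import presence_matrix, relative_abundance

STATUS_ORDER = (
    "excluded",
    "candidate",
    "invader",
    "potential_colonist",
    "successful_colonist",
)

_STATUS_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}


def status_rank(status: str) -> int:
    return _STATUS_RANK[status]


class DetectionTensor:
    """Boolean detection profiles indexed by ASV and sample metadata."""

    def __init__(
        self,
        asv_ids: Sequence[str],
        records: Sequence[SampleRecord],
        presence: np.ndarray,
        threshold: int,
    ) -> None:
        self.asv_ids = list(asv_ids)
        self.records = list(records)
        if presence.shape != (len(self.asv_ids), len(self.records)):
            raise ValidationError("presence shape does not match ASVs × samples")
        self.presence = presence.astype(bool)
        self.threshold = int(threshold)
        self._asv_index = {a: i for i, a in enumerate(self.asv_ids)}

    @classmethod
    def from_table(
        cls,
        table: AsvCountTable,
        records: Sequence[SampleRecord],
        threshold: int = 1,
    ) -> "DetectionTensor":
        check_join(table, records)
        by_id = {r.sample_id: r for r in records}
        ordered = [by_id[s] for s in table.sample_ids]
        return cls(
            table.asv_ids, ordered, presence_matrix(table, threshold), threshold
        )

    # -- metadata queries --------------------------------------------------
    def sample_mask(
        self,
        compartment: str | Iterable[str] | None = None,
        experiment: str | None = None,
        arm: str | None = None,
        condition: str | None = None,
        days: Iterable[str] | None = None,
        replicate: int | None = None,
    ) -> np.ndarray:
        if isinstance(compartment, str):
            compartment = {compartment}
        days = set(days) if days is not None else None
        mask = np.ones(len(self.records), dtype=bool)
        for i, r in enumerate(self.records):
            if (
                (compartment is not None and r.compartment not in compartment)
                or (experiment is not None and r.experiment != experiment)
                or (arm is not None and r.arm != arm)
                or (condition is not None and r.condition != condition)
                or (days is not None and r.day not in days)
                or (replicate is not None and r.replicate != replicate)
            ):
                mask[i] = False
        return mask

    def detected_in(self, mask: np.ndarray) -> set[str]:
        """ASVs detected in at least one sample selected by ``mask``."""
        if not mask.any():
            return set()
        hits = self.presence[:, mask].any(axis=1)
        return {self.asv_ids[i] for i in np.flatnonzero(hits)}

    def detection_days(
        self, asv_id: str, mask: np.ndarray
    ) -> set[str]:
        """Days (pooled over replicates) on which ``asv_id`` is detected."""
        i = self._asv_index[asv_id]
        cols = np.flatnonzero(mask & self.presence[i])
        return {self.records[j].day for j in cols}


@dataclass(frozen=True)
class ColonisationCall:
    """Per-(ASV, experimental unit) colonisation status."""

    asv_id: str
    experiment: str
    condition: str | None
    status: str
    detection_days: frozenset[str]
    detected_on_final_day: bool

    @property
    def label(self) -> str:
        return self.condition if self.condition is not None else self.experiment


def candidate_pool(
    tensor: DetectionTensor,
    include_control_flow_through: bool = True,
) -> set[str]:
    """Snow-detected ASVs absent from controls and pre-treatment soils.

    ``include_control_flow_through`` extends the control exclusion set to
    the control microcosms' flow-through samples (all samples from those
    microcosms), not just their soils.
    """
    snow_mask = tensor.sample_mask(compartment="snow")
    if not snow_mask.any():
        raise ConfigurationError("dataset contains no snow samples")
    snow_detected = tensor.detected_in(snow_mask)

    control_compartments = (
        {"soil", "flow_through"} if include_control_flow_through else {"soil"}
    )
    control_mask = tensor.sample_mask(compartment=control_compartments, arm="control")
    pre_mask = tensor.sample_mask(compartment="soil", days=PRE_TREATMENT_DAYS)
    excluded = tensor.detected_in(control_mask) | tensor.detected_in(pre_mask)
    return snow_detected - excluded


def _treated_soil_mask(
    tensor: DetectionTensor,
    experiment: str,
    condition: str | None,
    days: Iterable[str],
    replicate: int | None = None,
) -> np.ndarray:
    return tensor.sample_mask(
        compartment="soil",
        experiment=experiment,
        arm="treatment",
        condition=condition,
        days=days,
        replicate=replicate,
    )


def classify_experiment(
    pool: Iterable[str],
    tensor: DetectionTensor,
    experiment: str,
    condition: str | None = None,
    final_day: str = FINAL_DAY,
    min_days: int = 2,
    replicate: int | None = None,
) -> list[ColonisationCall]:
    """Classify every pool member for one experimental unit.

    ``replicate`` restricts the detection profile to a single replicate
    microcosm (used for per-replicate count ANOVA); by default detections
    are pooled over replicates.
    """
    if experiment not in EXPERIMENTS:
        raise ValidationError(
            f"unknown experiment {experiment!r}; allowed: {EXPERIMENTS}"
        )
    pool = set(pool)
    unknown = pool - set(tensor.asv_ids)
    if unknown:
        raise ValidationError(
            f"pool ASVs missing from table: {', '.join(sorted(unknown))}"
        )
    post_days = [d for d in POST_START_DAYS if day_sort_key(d) <= day_sort_key(final_day)]
    mask = _treated_soil_mask(tensor, experiment, condition, post_days, replicate)
    observed_days = {tensor.records[j].day for j in np.flatnonzero(mask)}
    if len(observed_days) < 2:
        raise ConfigurationError(
            f"unit ({experiment}, {condition}) has treated-soil samples on "
            f"{len(observed_days)} post-start day(s); need >= 2"
        )
    calls = []
    for asv in sorted(pool):
        days = frozenset(tensor.detection_days(asv, mask))
        on_final = final_day in days
        if not days:
            status = "candidate"
        elif len(days) >= min_days and on_final:
            status = "successful_colonist"
        elif len(days) >= min_days:
            status = "potential_colonist"
        else:
            status = "invader"
        calls.append(
            ColonisationCall(asv, experiment, condition, status, days, on_final)
        )
    _assert_nested_chain(calls)
    return calls


def _assert_nested_chain(calls: Sequence[ColonisationCall]) -> None:
    """Invariant: successful ⊆ colonists ⊆ invaders, per unit."""
    for c in calls:
        if c.status == "successful_colonist":
            assert c.detected_on_final_day and len(c.detection_days) >= 2
        if c.status in ("potential_colonist", "successful_colonist"):
            assert len(c.detection_days) >= 2
        if status_rank(c.status) >= status_rank("invader"):
            assert len(c.detection_days) >= 1


def experimental_units(
    records: Sequence[SampleRecord],
) -> list[tuple[str, str | None]]:
    """Distinct (experiment, condition) units with treated-soil samples."""
    units = []
    for r in records:
        if r.compartment == "soil" and r.arm == "treatment" and r.day in POST_START_DAYS:
            key = (r.experiment, r.condition)
            if key not in units:
                units.append(key)
    return units


def classify_dataset(
    tensor: DetectionTensor,
    pool: Iterable[str] | None = None,
    units: Sequence[tuple[str, str | None]] | None = None,
    final_day: str = FINAL_DAY,
    min_days: int = 2,
    include_control_flow_through: bool = True,
) -> dict[tuple[str, str | None], list[ColonisationCall]]:
    """Pool (dataset-wide) then classify each experimental unit."""
    if pool is None:
        pool = candidate_pool(tensor, include_control_flow_through)
    if units is None:
        units = experimental_units(tensor.records)
    return {
        unit: classify_experiment(
            pool, tensor, unit[0], unit[1], final_day=final_day, min_days=min_days
        )
        for unit in units
    }


def summarize_counts(
    calls_by_unit: Mapping[tuple[str, str | None], Sequence[ColonisationCall]],
) -> tuple[pd.DataFrame, dict]:
    """Per-unit invader/colonist/successful counts plus global union sizes.

    Per-experiment sets may overlap (the same ASV can invade several
    units), so global counts are union sizes, not column sums.
    """
    rows = []
    global_invaders: set[str] = set()
    global_colonists: set[str] = set()
    global_successful: set[str] = set()
    for (experiment, condition), calls in calls_by_unit.items():
        inv = {c.asv_id for c in calls if status_rank(c.status) >= status_rank("invader")}
        col = {
            c.asv_id
            for c in calls
            if status_rank(c.status) >= status_rank("potential_colonist")
        }
        suc = {c.asv_id for c in calls if c.status == "successful_colonist"}
        assert suc <= col <= inv
        global_invaders |= inv
        global_colonists |= col
        global_successful |= suc
        rows.append(
            {
                "experiment": experiment,
                "condition": condition,
                "invaders": len(inv),
                "colonists": len(col),
                "successful": len(suc),
            }
        )
    summary = {
        "global_invaders": len(global_invaders),
        "global_colonists": len(global_colonists),
        "global_successful": len(global_successful),
    }
    return pd.DataFrame(rows), summary


def non_invading_pool_count(pool_size: int, invader_count: int) -> int:
    """Snow-unique ASVs never detected in treated soil: pool − invaders."""
    if pool_size < 0 or invader_count < 0:
        raise ValidationError("counts must be non-negative")
    if invader_count > pool_size:
        raise ValidationError("invader count cannot exceed pool size")
    return pool_size - invader_count


def replicate_counts(
    tensor: DetectionTensor,
    pool: Iterable[str],
    units: Sequence[tuple[str, str | None]] | None = None,
    final_day: str = FINAL_DAY,
    min_days: int = 2,
) -> pd.DataFrame:
    """Invader/colonist/successful counts per (unit, replicate).

    The status definitions are re-applied within each replicate microcosm
    alone, so a taxon detected on one day in each of two replicates is an
    invader, not a colonist, at the replicate level.
    """
    pool = set(pool)
    if units is None:
        units = experimental_units(tensor.records)
    rows = []
    for experiment, condition in units:
        reps = sorted(
            {
                r.replicate
                for r in tensor.records
                if r.compartment == "soil"
                and r.arm == "treatment"
                and r.experiment == experiment
                and r.condition == condition
                and r.replicate is not None
            }
        )
        if len(reps) < 2:
            raise ConfigurationError(
                f"unit ({experiment}, {condition}) has fewer than 2 replicates"
            )
        for rep in reps:
            calls = classify_experiment(
                pool,
                tensor,
                experiment,
                condition,
                final_day=final_day,
                min_days=min_days,
                replicate=rep,
            )
            inv = sum(status_rank(c.status) >= status_rank("invader") for c in calls)
            col = sum(
                status_rank(c.status) >= status_rank("potential_colonist")
                for c in calls
            )
            suc = sum(c.status == "successful_colonist" for c in calls)
            rows.append(
                {
                    "experiment": experiment,
                    "condition": condition,
                    "replicate": rep,
                    "invaders": inv,
                    "colonists": col,
                    "successful": suc,
                }
            )
    return pd.DataFrame(rows)


def replicate_counts_anova(
    tensor: DetectionTensor,
    pool: Iterable[str],
    units: Sequence[tuple[str, str | None]] | None = None,
    final_day: str = FINAL_DAY,
    min_days: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """One-way ANOVA of per-replicate counts across experimental units."""
    from .stats import oneway_anova

    counts = replicate_counts(tensor, pool, units, final_day, min_days)
    if counts[["experiment", "condition"]].drop_duplicates().shape[0] < 2:
        raise ConfigurationError("count ANOVA needs >= 2 experimental units")
    results = {}
    label = counts["experiment"].astype(str) + ":" + counts["condition"].astype(str)
    for category in ("invaders", "colonists", "successful"):
        groups = {
            lvl: counts.loc[label == lvl, category].to_numpy()
            for lvl in label.unique()
        }
        f, df1, df2, p = oneway_anova(groups)
        results[category] = {"F": f, "df1": df1, "df2": df2, "p": p}
    return counts, results


def export_heatmap_table(
    calls_by_unit: Mapping[tuple[str, str | None], Sequence[ColonisationCall]],
    table: AsvCountTable,
    records: Sequence[SampleRecord],
    days: Sequence[str] = POST_START_DAYS,
) -> pd.DataFrame:
    """Long-format invader abundances for heatmap rendering.

    One row per invader × replicate × post-start day, zero-filled where the
    ASV was not observed; suitable for a tile plot grouped by unit.
    """
    check_join(table, records)
    rel = relative_abundance(table)
    col_index = {s: j for j, s in enumerate(table.sample_ids)}
    sample_lookup: dict[tuple, str] = {}
    replicates: dict[tuple[str, str | None], set[int]] = {}
    for r in records:
        if r.compartment == "soil" and r.arm == "treatment" and r.day in days:
            key = (r.experiment, r.condition)
            sample_lookup[(r.experiment, r.condition, r.replicate, r.day)] = r.sample_id
            replicates.setdefault(key, set()).add(r.replicate)
    rows = []
    for (experiment, condition), calls in calls_by_unit.items():
        invaders = [
            c for c in calls if status_rank(c.status) >= status_rank("invader")
        ]
        for call in invaders:
            i = table.asv_index(call.asv_id)
            for rep in sorted(replicates.get((experiment, condition), ())):
                for day in days:
                    sid = sample_lookup.get((experiment, condition, rep, day))
                    abundance = (
                        float(rel[i, col_index[sid]]) if sid is not None else 0.0
                    )
                    rows.append(
                        {
                            "asv_id": call.asv_id,
                            "experiment": experiment,
                            "condition": condition,
                            "replicate": rep,
                            "day": day,
                            "relative_abundance": abundance,
                            "status": call.status,
                        }
                    )
    columns = [
        "asv_id",
        "experiment",
        "condition",
        "replicate",
        "day",
        "relative_abundance",
        "status",
    ]
    return pd.DataFrame(rows, columns=columns)
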