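"""Dataset model for snow→soil microcosm sequencing experiments.

The experimental design monitored three compartments — melted snow (the
inoculum), soil microcosm columns, and the flow-through (FT) percolating out
of each column — over an ordered schedule of sampling days.  ``DS`` is the
day of field sampling, ``D-10`` the microcosm set-up day, ``D0`` the first
experimental day, and ``D5``–``D29`` the post-start sampling days.  Kit and
sequencing negative controls are a fourth, design-free compartment
(``lab_control``).

Two experiments were run, each with four arms in triplicate (12 microcosms
per experiment): a snowmelt-rate experiment (average vs fast flow, each with
a melted-snow treatment and a sterile-water control) and a soil-pH
experiment (acidic vs alkaline, same arm structure; the acidoneutral arm is
the melt-rate/average arm reused).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when data violates the schema or a model invariant."""


class SchemaError(ValidationError):
    """Raised when a required column or field is missing."""


class ConfigurationError(ValueError):
    """Raised when an analysis is configured inconsistently with the data."""


#: Total ordering of sampling-day labels (field sampling → end of experiment).
DAY_LABELS: tuple[str, ...] = ("DS", "D-10", "D0", "D5", "D9", "D14", "D20", "D29")

DAY_INDEX: Mapping[str, int] = {d: i for i, d in enumerate(DAY_LABELS)}

#: Numeric offsets (days relative to experiment start) for plotting only.
#: The soil was stored for 100 days between field sampling and set-up.
DAY_OFFSETS: Mapping[str, int] = {
    "DS": -110,
    "D-10": -10,
    "D0": 0,
    "D5": 5,
    "D9": 9,
    "D14": 14,
    "D20": 20,
    "D29": 29,
}

#: Days whose soil samples count as pre-treatment community members.
PRE_TREATMENT_DAYS: frozenset[str] = frozenset({"DS", "D-10", "D0"})

#: Days on which a treated-soil detection counts toward invasion/colonisation.
POST_START_DAYS: tuple[str, ...] = ("D5", "D9", "D14", "D20", "D29")

FINAL_DAY = "D29"

COMPARTMENTS = ("snow", "soil", "flow_through", "lab_control")
EXPERIMENTS = ("melt_rate", "soil_ph")
ARMS = ("treatment", "control")

#: Allowed condition labels per experiment.
CONDITIONS: Mapping[str, tuple[str, ...]] = {
    "melt_rate": ("average", "fast"),
    "soil_ph": ("acidic", "acidoneutral", "alkaline"),
}


def day_sort_key(day: str) -> int:
    """Position of ``day`` in the experimental schedule (DS first)."""
    try:
        return DAY_INDEX[day]
    except KeyError:
        raise ValidationError(
            f"unknown day label {day!r}; allowed: {', '.join(DAY_LABELS)}"
        ) from None


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequenced sample.

    ``denom`` is the qPCR normalisation denominator: grams of soil extracted
    or millilitres of snow/flow-through filtered.  ``lab_control`` samples
    (kit and sequencing controls) carry no design fields.
    """

    sample_id: str
    compartment: str
    experiment: str | None = None
    arm: str | None = None
    condition: str | None = None
    replicate: int | None = None
    day: str | None = None
    denom: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if self.compartment == "lab_control":
            return  # design fields are optional for kit/sequencing controls
        if self.experiment not in EXPERIMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: experiment {self.experiment!r} "
                f"not in {EXPERIMENTS}"
            )
        if self.compartment == "snow":
            # snow is the shared inoculum; by convention it belongs to the
            # treatment arm and carries no replicate requirement
            object.__setattr__(self, "arm", "treatment")
        elif self.arm not in ARMS:
            raise ValidationError(
                f"sample {self.sample_id!r}: arm {self.arm!r} not in {ARMS}"
            )
        if self.condition is not None:
            allowed = CONDITIONS[self.experiment]
            if self.condition not in allowed:
                raise ValidationError(
                    f"sample {self.sample_id!r}: condition {self.condition!r} "
                    f"invalid for {self.experiment} (allowed: {allowed})"
                )
        if self.replicate is not None and (
            not isinstance(self.replicate, (int, np.integer)) or self.replicate < 1
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )
        if self.day is not None:
            day_sort_key(self.day)
        if self.denom is not None and not self.denom > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: denom must be positive"
            )

    @property
    def is_pre_treatment_soil(self) -> bool:
        return self.compartment == "soil" and self.day in PRE_TREATMENT_DAYS


class AsvCountTable:
    """Integer ASV × sample count matrix with optional taxonomy annotation."""

    def __init__(
        self,
        asv_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts,
        taxonomy: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.asv_ids = list(asv_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs × {len(self.sample_ids)} samples"
            )
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate asv_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValidationError("counts must be finite")
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                bad = np.argwhere(rounded != counts)[0]
                raise ValidationError(
                    f"non-integer count at ASV {self.asv_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at ASV {self.asv_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.taxonomy = dict(taxonomy) if taxonomy else None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, taxonomy=None) -> "AsvCountTable":
        """Build from a DataFrame with ASV rows and sample columns."""
        return cls(
            frame.index.astype(str).tolist(),
            frame.columns.astype(str).tolist(),
            frame.to_numpy(),
            taxonomy=taxonomy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.asv_ids, name="asv_id"),
            columns=self.sample_ids,
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def asv_index(self, asv_id: str) -> int:
        return self.asv_ids.index(asv_id)

    # -- subsetting ---------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvCountTable":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return AsvCountTable(self.asv_ids, keep, self.counts[:, idx], self.taxonomy)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvCountTable":
        keep = list(asv_ids)
        idx = [self.asv_ids.index(a) for a in keep]
        tax = (
            {a: self.taxonomy[a] for a in keep if a in self.taxonomy}
            if self.taxonomy
            else None
        )
        return AsvCountTable(keep, self.sample_ids, self.counts[idx, :], tax)

    def drop_asvs(self, asv_ids: Iterable[str]) -> "AsvCountTable":
        drop = set(asv_ids)
        return self.subset_asvs([a for a in self.asv_ids if a not in drop])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvCountTable):
            return NotImplemented
        return (
            self.asv_ids == other.asv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )

    def __repr__(self) -> str:
        return f"AsvCountTable({len(self.asv_ids)} ASVs × {len(self.sample_ids)} samples)"


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tidy one-row-per-sample view of a list of :class:`SampleRecord`."""
    rows = [
        {
            "sample_id": r.sample_id,
            "compartment": r.compartment,
            "experiment": r.experiment,
            "arm": r.arm,
            "condition": r.condition,
            "replicate": r.replicate,
            "day": r.day,
            "denom": r.denom,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def check_join(table: AsvCountTable, records: Sequence[SampleRecord]) -> None:
    """Verify every table sample resolves to exactly one metadata record."""
    meta_ids = [r.sample_id for r in records]
    if len(set(meta_ids)) != len(meta_ids):
        raise ValidationError("duplicate sample_id in metadata")
    missing = set(table.sample_ids) - set(meta_ids)
    if missing:
        raise ValidationError(
            f"samples without metadata: {', '.join(sorted(missing))}"
        )
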