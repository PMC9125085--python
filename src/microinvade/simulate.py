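"""Ground-truthed microcosm dataset simulator.

Emulates the post-denoising state of a snow→soil microcosm experiment: an
ASV count table over snow, soil, flow-through and lab-control samples for
two experiments (melt rate: average/fast; soil pH: acidic/alkaline, with
acidoneutral represented by the average-flow arm), four arms each, in
triplicate, on the DS…D29 schedule.

The generative model, in brief:

* baseline communities are log-normal rank-abundance profiles per
  compartment; a block of *shared* taxa occurs in both snow and soil,
  *soil-only* and *snow-only* blocks occur in one compartment each;
* a configurable number of snow-only taxa are *planted* as potential
  invaders: per experimental unit they arrive in treated soils on
  ``arrival_day`` and persist through each subsequent sampling day with a
  per-interval survival probability (reduced by a washout multiplier in
  fast-flow units), independently per replicate — and never occur in
  control microcosms or pre-treatment soils;
* flow-through is a snow/soil mixture with a relic-DNA washout boost on D5;
* contaminant taxa are abundant in lab controls, with half also leaking
  into real samples at trace level;
* counts are multinomial draws at a fixed sequencing depth, so sampling can
  remove but never add presences relative to the latent state.

Ground truth records each taxon's origin and, per unit, the colonisation
status implied by its realized latent detection-day trajectory — the
reference for precision/recall testing of the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AsvCountTable,
    ConfigurationError,
    FINAL_DAY,
    POST_START_DAYS,
    SampleRecord,
    ValidationError,
    day_sort_key,
)
from .stats import QpcrQuantity

DEFAULT_UNITS: tuple[tuple[str, str], ...] = (
    ("melt_rate", "average"),
    ("melt_rate", "fast"),
    ("soil_ph", "acidic"),
    ("soil_ph", "alkaline"),
)

_SNOW_DAYS = ("DS", "D-10", "D0", "D5", "D9", "D14")
_SOIL_DAYS = ("D0", "D5", "D9", "D14", "D20", "D29")
_FT_DAYS = ("D5", "D9", "D14")
_PRE_DAYS = ("DS", "D-10")

_PHYLA = (
    "Acidobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Chloroflexi",
    "Gemmatimonadetes",
    "Planctomycetes",
    "Proteobacteria",
    "Verrucomicrobia",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic microcosm experiment.

    Defaults encode the study design: two experiments with four arms each
    in triplicate, fixed sequencing depth of 30,114 reads/sample, snow at
    ~40.2 16S copies per ml with soil and flow-through orders of magnitude
    higher.
    """

    seed: int = 0
    units: tuple[tuple[str, str], ...] = DEFAULT_UNITS
    replicates: int = 3
    reads_per_sample: int = 30114
    # taxon budgets
    n_soil_taxa: int = 120
    n_snow_taxa: int = 60
    n_shared_taxa: int = 20
    contaminant_taxa: int = 6
    planted_invaders: int = 12
    # abundance model (log-normal rank-abundance shape)
    abundance_sdlog: float = 1.5
    min_shared_relabund: float = 5e-4
    sample_jitter_sdlog: float = 0.3
    snow_drift_sdlog: float = 0.0
    # planted-invader dynamics
    invasion_probability: float = 0.6
    #: per-condition override of the arrival probability (e.g. to plant a
    #: between-experiment difference in the expected invader count)
    invasion_probability_overrides: Mapping[str, float] = field(default_factory=dict)
    arrival_day: str = "D5"
    survival_probability: float = 0.7
    washout: Mapping[str, float] = field(default_factory=lambda: {"fast": 0.6})
    planted_relative_abundance: float = 5e-3
    planted_abundance_multiplier: float = 1.0
    detection_probability: float = 1.0
    # flow-through mixing
    ft_snow_fraction: float = 0.4
    ft_relic_boost: float = 2.0
    # contamination
    lab_controls: int = 3
    contaminant_relabund_controls: float = 0.15
    contaminant_leak_relabund: float = 2e-4
    # qPCR model (arithmetic-mean copies per unit denom, log-normal noise)
    qpcr_mean_copies: Mapping[str, float] = field(
        default_factory=lambda: {"snow": 40.2, "soil": 5e8, "flow_through": 2e5}
    )
    qpcr_sdlog: float = 0.5
    soil_denom_g: float = 0.25
    filtered_volume_ml: float = 250.0
    eluate_volume_ul: float = 100.0
    template_volume_ul: float = 2.0

    def __post_init__(self) -> None:
        for name in ("invasion_probability", "survival_probability", "detection_probability"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        for cond, v in self.invasion_probability_overrides.items():
            if not (0 < v <= 1):
                raise ConfigurationError(
                    f"invasion_probability_overrides[{cond!r}] must be in (0, 1]"
                )
        if self.reads_per_sample < 1:
            raise ConfigurationError("reads_per_sample must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        for name in ("n_soil_taxa", "n_snow_taxa", "n_shared_taxa", "contaminant_taxa"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.planted_invaders > self.n_snow_taxa:
            raise ConfigurationError(
                "planted_invaders exceeds n_snow_taxa; planted taxa are "
                "snow-only and disjoint from the shared background"
            )
        if self.arrival_day not in POST_START_DAYS:
            raise ConfigurationError(
                f"arrival_day must be a post-start day, got {self.arrival_day!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = [list(u) for u in self.units]
        d["washout"] = dict(self.washout)
        d["qpcr_mean_copies"] = dict(self.qpcr_mean_copies)
        d["invasion_probability_overrides"] = dict(self.invasion_probability_overrides)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"unknown simulation config field(s): {', '.join(sorted(unknown))}"
            )
        if "units" in data:
            data["units"] = tuple(tuple(u) for u in data["units"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted labels and dynamics behind a simulated dataset."""

    origin: dict[str, str]  # asv_id -> soil | snow | shared | contaminant
    planted_status: dict[tuple[str, tuple[str, str]], str]
    planted_days: dict[tuple[str, tuple[str, str]], frozenset[str]]
    dynamics: dict

    def status_frame(self) -> pd.DataFrame:
        rows = [
            {
                "asv_id": asv,
                "experiment": unit[0],
                "condition": unit[1],
                "status": status,
                "latent_days": ",".join(
                    sorted(self.planted_days.get((asv, unit), ()), key=day_sort_key)
                ),
            }
            for (asv, unit), status in sorted(self.planted_status.items())
        ]
        return pd.DataFrame(
            rows, columns=["asv_id", "experiment", "condition", "status", "latent_days"]
        )

    def origin_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"asv_id": a, "origin": o} for a, o in sorted(self.origin.items())]
        )


def _lognormal_profile(rng: np.random.Generator, n: int, sdlog: float) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sdlog, size=n)
    return w / w.sum()


def _status_from_days(days: frozenset[str], min_days: int = 2) -> str:
    if not days:
        return "none"
    if len(days) >= min_days and FINAL_DAY in days:
        return "successful_colonist"
    if len(days) >= min_days:
        return "potential_colonist"
    return "invader"


def qpcr_copies(
    rng: np.random.Generator, mean_copies: float, sdlog: float, n: int = 1
) -> np.ndarray:
    """Log-normal copy numbers with the configured *arithmetic* mean."""
    meanlog = np.log(mean_copies) - sdlog**2 / 2.0
    return rng.lognormal(mean=meanlog, sigma=sdlog, size=n)


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[AsvCountTable, list[SampleRecord], GroundTruth, list[QpcrQuantity]]:
    """Generate one complete microcosm dataset.

    Returns the count table, sample metadata, ground truth, and qPCR
    quantities.  ``seed`` overrides ``config.seed``; identical seeds give
    bit-identical outputs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    soil_taxa = [f"ASV_SOIL_{i:04d}" for i in range(config.n_soil_taxa)]
    snow_taxa = [f"ASV_SNOW_{i:04d}" for i in range(config.n_snow_taxa)]
    shared_taxa = [f"ASV_SHARED_{i:04d}" for i in range(config.n_shared_taxa)]
    cont_taxa = [f"ASV_CONT_{i:04d}" for i in range(config.contaminant_taxa)]
    all_taxa = soil_taxa + snow_taxa + shared_taxa + cont_taxa
    index = {a: i for i, a in enumerate(all_taxa)}
    n_taxa = len(all_taxa)

    planted = list(
        rng.choice(snow_taxa, size=config.planted_invaders, replace=False)
    ) if config.planted_invaders else []
    planted_set = set(planted)
    # diffuse contaminants leak into real samples; the rest stay exclusive
    n_diffuse = len(cont_taxa) // 2
    diffuse_cont = cont_taxa[:n_diffuse]

    origin = {a: "soil" for a in soil_taxa}
    origin.update({a: "snow" for a in snow_taxa})
    origin.update({a: "shared" for a in shared_taxa})
    origin.update({a: "contaminant" for a in cont_taxa})

    taxonomy = _make_taxonomy(rng, soil_taxa, snow_taxa, shared_taxa, cont_taxa, planted_set)

    # -- baseline compositional profiles ----------------------------------
    soil_block = soil_taxa + shared_taxa
    base_soil = _lognormal_profile(rng, len(soil_block), config.abundance_sdlog)
    # floor shared taxa so pre-treatment soils reliably witness them
    shared_slice = slice(len(soil_taxa), len(soil_block))
    base_soil[shared_slice] = np.maximum(base_soil[shared_slice].copy(),
                                         config.min_shared_relabund * base_soil.sum())
    base_soil /= base_soil.sum()

    unit_soil: dict[tuple[str, str], np.ndarray] = {}
    for unit in config.units:
        shift = rng.lognormal(mean=0.0, sigma=0.5, size=len(soil_block))
        w = base_soil * shift
        w[shared_slice] = np.maximum(w[shared_slice], config.min_shared_relabund)
        unit_soil[unit] = w / w.sum()

    snow_block = snow_taxa + shared_taxa
    w_snow = _lognormal_profile(rng, len(snow_block), config.abundance_sdlog)
    # pin planted taxa at their configured snow relative abundance
    for t in planted:
        w_snow[snow_block.index(t)] = 0.0
    w_snow = w_snow / w_snow.sum() * (1.0 - config.planted_relative_abundance * len(planted))
    for t in planted:
        w_snow[snow_block.index(t)] = config.planted_relative_abundance
    base_snow = w_snow / w_snow.sum()

    # -- latent planted trajectories ---------------------------------------
    post_days = list(POST_START_DAYS)
    arrival_idx = post_days.index(config.arrival_day)
    latent: dict[tuple[str, tuple[str, str], int], set[str]] = {}
    planted_days: dict[tuple[str, tuple[str, str]], frozenset[str]] = {}
    planted_status: dict[tuple[str, tuple[str, str]], str] = {}
    for unit in config.units:
        survival = config.survival_probability * config.washout.get(unit[1], 1.0)
        survival = min(survival, 1.0)
        p_arrival = config.invasion_probability_overrides.get(
            unit[1], config.invasion_probability
        )
        for t in planted:
            arrives = rng.random() < p_arrival
            pooled: set[str] = set()
            for rep in range(1, config.replicates + 1):
                days: set[str] = set()
                if arrives:
                    alive = True
                    for d in post_days[arrival_idx:]:
                        if d != config.arrival_day:
                            alive = alive and (rng.random() < survival)
                        if alive:
                            days.add(d)
                        else:
                            break
                latent[(t, unit, rep)] = days
                pooled |= days
            planted_days[(t, unit)] = frozenset(pooled)
            planted_status[(t, unit)] = _status_from_days(frozenset(pooled))

    # -- assemble samples ---------------------------------------------------
    sample_profiles: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []

    def add_sample(record: SampleRecord, profile: np.ndarray) -> None:
        records.append(record)
        sample_profiles[record.sample_id] = profile

    def full_vector(block: Sequence[str], weights: np.ndarray) -> np.ndarray:
        v = np.zeros(n_taxa)
        for name, w in zip(block, weights):
            v[index[name]] = w
        return v

    def jitter(v: np.ndarray, sdlog: float) -> np.ndarray:
        if sdlog <= 0:
            return v / v.sum()
        w = v * rng.lognormal(0.0, sdlog, size=v.shape)
        return w / w.sum()

    def leak_contaminants(v: np.ndarray) -> np.ndarray:
        if not diffuse_cont or config.contaminant_leak_relabund <= 0:
            return v / v.sum()
        v = v / v.sum() * (1.0 - config.contaminant_leak_relabund * len(diffuse_cont))
        for t in diffuse_cont:
            v[index[t]] += config.contaminant_leak_relabund
        return v / v.sum()

    snow_full = full_vector(snow_block, base_snow)
    for day in _SNOW_DAYS:
        profile = leak_contaminants(jitter(snow_full, config.snow_drift_sdlog))
        add_sample(
            SampleRecord(
                sample_id=f"SNOW_{day}",
                compartment="snow",
                experiment="melt_rate",
                arm="treatment",
                day=day,
                denom=config.filtered_volume_ml,
            ),
            profile,
        )

    base_soil_full = full_vector(soil_block, base_soil)
    for experiment in dict.fromkeys(e for e, _ in config.units):
        for day in _PRE_DAYS:
            profile = leak_contaminants(jitter(base_soil_full, config.sample_jitter_sdlog))
            add_sample(
                SampleRecord(
                    sample_id=f"SOIL_PRE_{experiment}_{day}",
                    compartment="soil",
                    experiment=experiment,
                    arm="control",
                    day=day,
                    denom=config.soil_denom_g,
                ),
                profile,
            )

    growth = config.planted_abundance_multiplier
    for unit in config.units:
        experiment, condition = unit
        soil_full = full_vector(soil_block, unit_soil[unit])
        for arm in ("treatment", "control"):
            for rep in range(1, config.replicates + 1):
                for day in _SOIL_DAYS:
                    v = jitter(soil_full, config.sample_jitter_sdlog)
                    if arm == "treatment" and day in POST_START_DAYS:
                        for t in planted:
                            if day not in latent[(t, unit, rep)]:
                                continue
                            if rng.random() >= config.detection_probability:
                                continue
                            age = post_days.index(day) - arrival_idx
                            v[index[t]] = (
                                config.planted_relative_abundance * growth**age
                            )
                        v = v / v.sum()
                    profile = leak_contaminants(v)
                    add_sample(
                        SampleRecord(
                            sample_id=f"SOIL_{condition}_{arm}_{rep}_{day}",
                            compartment="soil",
                            experiment=experiment,
                            arm=arm,
                            condition=condition,
                            replicate=rep,
                            day=day,
                            denom=config.soil_denom_g,
                        ),
                        profile,
                    )
                for day in _FT_DAYS:
                    relic = config.ft_relic_boost if day == "D5" else 1.0
                    if arm == "treatment":
                        w = config.ft_snow_fraction
                        v = w * snow_full + (1.0 - w) * relic * soil_full
                    else:
                        v = relic * soil_full
                    profile = leak_contaminants(
                        jitter(v, config.sample_jitter_sdlog)
                    )
                    add_sample(
                        SampleRecord(
                            sample_id=f"FT_{condition}_{arm}_{rep}_{day}",
                            compartment="flow_through",
                            experiment=experiment,
                            arm=arm,
                            condition=condition,
                            replicate=rep,
                            day=day,
                            denom=config.filtered_volume_ml,
                        ),
                        profile,
                    )

    # lab controls: contaminants dominate, plus faint cross-talk
    if config.lab_controls and cont_taxa:
        # planted taxa are excluded so curation can never discard them
        carryover_pool = [
            t for t in soil_taxa + snow_taxa + shared_taxa if t not in planted_set
        ]
        carryover = rng.choice(
            carryover_pool, size=min(10, len(carryover_pool)), replace=False
        )
        for i in range(1, config.lab_controls + 1):
            v = np.zeros(n_taxa)
            for t in cont_taxa:
                v[index[t]] = config.contaminant_relabund_controls
            rest = 1.0 - v.sum()
            w = rng.lognormal(0.0, 1.0, size=len(carryover))
            for t, wt in zip(carryover, w / w.sum() * rest):
                v[index[t]] += wt
            add_sample(
                SampleRecord(sample_id=f"KITCTL_{i}", compartment="lab_control"),
                v / v.sum(),
            )

    # -- draw counts --------------------------------------------------------
    counts = np.zeros((n_taxa, len(records)), dtype=np.int64)
    for j, r in enumerate(records):
        counts[:, j] = rng.multinomial(
            config.reads_per_sample, sample_profiles[r.sample_id]
        )
    table = AsvCountTable(all_taxa, [r.sample_id for r in records], counts, taxonomy)

    # -- qPCR ----------------------------------------------------------------
    qpcr: list[QpcrQuantity] = []
    ratio = config.eluate_volume_ul / config.template_volume_ul
    for r in records:
        if r.compartment == "lab_control":
            continue
        mean = config.qpcr_mean_copies[r.compartment]
        cpu = float(qpcr_copies(rng, mean, config.qpcr_sdlog, 1)[0])
        qpcr.append(
            QpcrQuantity(
                sample_id=r.sample_id,
                copies_per_reaction=cpu * r.denom / ratio,
                eluate_volume_ul=config.eluate_volume_ul,
                template_volume_ul=config.template_volume_ul,
                denom=r.denom,
            )
        )

    truth = GroundTruth(
        origin=origin,
        planted_status=planted_status,
        planted_days=planted_days,
        dynamics={
            "arrival_day": config.arrival_day,
            "survival_probability": config.survival_probability,
            "washout": dict(config.washout),
            "invasion_probability": config.invasion_probability,
            "detection_probability": config.detection_probability,
            "planted": sorted(planted_set),
        },
    )
    return table, records, truth, qpcr


def _make_taxonomy(rng, soil_taxa, snow_taxa, shared_taxa, cont_taxa, planted_set):
    taxonomy = {}
    for t in soil_taxa + shared_taxa:
        phylum = _PHYLA[rng.integers(len(_PHYLA))]
        taxonomy[t] = ["Bacteria", phylum, "", "", "", ""]
    for t in snow_taxa:
        if t in planted_set:
            phylum = "Proteobacteria" if rng.random() < 0.6 else "Bacteroidetes"
            cls = {
                "Proteobacteria": "Alphaproteobacteria",
                "Bacteroidetes": "Flavobacteriia",
            }[phylum]
            taxonomy[t] = ["Bacteria", phylum, cls, "", "", ""]
        else:
            taxonomy[t] = ["Bacteria", "Proteobacteria", "", "", "", ""]
    for t in cont_taxa:
        taxonomy[t] = ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "", "", ""]
    return taxonomy


def truth_confusion(calls_by_unit, truth: GroundTruth) -> pd.DataFrame:
    """Cumulative precision/recall per planted status.

    Statuses are nested, so each level is scored cumulatively: an ASV
    counts as a predicted/true *invader* if its status is invader or
    stronger, and so on.  Precision with no predicted positives is
    undefined and reported as NaN.
    """
    call_ids = {c.asv_id for calls in calls_by_unit.values() for c in calls}
    unknown = call_ids - set(truth.origin)
    if unknown:
        raise ValidationError(
            f"calls reference ASVs absent from truth: {', '.join(sorted(unknown))}"
        )
    from .colonisation import status_rank

    levels = ("invader", "potential_colonist", "successful_colonist")
    predicted = {lvl: set() for lvl in levels}
    for unit, calls in calls_by_unit.items():
        for c in calls:
            for lvl in levels:
                if status_rank(c.status) >= status_rank(lvl):
                    predicted[lvl].add((c.asv_id, unit))
    actual = {lvl: set() for lvl in levels}
    truth_rank = {"none": 0, "invader": 1, "potential_colonist": 2, "successful_colonist": 3}
    level_rank = {"invader": 1, "potential_colonist": 2, "successful_colonist": 3}
    for (asv, unit), status in truth.planted_status.items():
        if unit not in calls_by_unit:
            continue
        for lvl in levels:
            if truth_rank[status] >= level_rank[lvl]:
                actual[lvl].add((asv, unit))
    rows = []
    for lvl in levels:
        tp = len(predicted[lvl] & actual[lvl])
        fp = len(predicted[lvl] - actual[lvl])
        fn = len(actual[lvl] - predicted[lvl])
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
        recall = tp / (tp + fn) if (tp + fn) else float("nan")
        rows.append(
            {
                "status": lvl,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)
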