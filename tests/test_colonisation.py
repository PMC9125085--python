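import numpy as np
import pandas as pd
import pytest

from microinvade.colonisation import (
    DetectionTensor,
    candidate_pool,
    classify_dataset,
    classify_experiment,
    export_heatmap_table,
    non_invading_pool_count,
    replicate_counts,
    replicate_counts_anova,
    status_rank,
    summarize_counts,
)
from microinvade.model import ConfigurationError, ValidationError
from microinvade.preprocess import relative_abundance
from microinvade.simulate import SimulationConfig, simulate_dataset, truth_confusion

from conftest import make_toy_dataset

UNIT = ("melt_rate", "average")


def build_tensor(detections, threshold=1):
    table, records = make_toy_dataset(detections)
    return table, records, DetectionTensor.from_table(table, records, threshold)


class TestCandidatePool:
    def test_snow_only_in_pool_and_control_detected_excluded(self):
        detections = {
            "snow_only": {"snow": True},
            "snow_and_control": {"snow": True, "control": True},
            "snow_and_pre": {"snow": True, "pre": True},
            "soil_only": {"treated": [(1, "D5")]},
        }
        _, _, tensor = build_tensor(detections)
        pool = candidate_pool(tensor)
        assert pool == {"snow_only"}

    def test_pool_matches_brute_force_set_algebra(self):
        detections = {
            "a1": {"snow": True},
            "a2": {"snow": True, "treated": [(1, "D5")]},
            "a3": {"snow": True, "treated": [(2, "D9"), (1, "D29")]},
            "a4": {"snow": True, "control": True, "treated": [(1, "D5")]},
            "a5": {"pre": True, "treated": [(1, "D14")]},
            "a6": {"snow": True, "pre": True},
        }
        table, records, tensor = build_tensor(detections)
        pool = candidate_pool(tensor)
        assert pool == {"a1", "a2", "a3"}
        # independent oracle: loop over every sample and cell
        by_id = {r.sample_id: r for r in records}
        snow, excluded = set(), set()
        for i, asv in enumerate(table.asv_ids):
            for j, sid in enumerate(table.sample_ids):
                if table.counts[i, j] < 1:
                    continue
                r = by_id[sid]
                if r.compartment == "snow":
                    snow.add(asv)
                if r.arm == "control" and r.compartment in ("soil", "flow_through"):
                    excluded.add(asv)
                if r.compartment == "soil" and r.day in ("DS", "D-10", "D0"):
                    excluded.add(asv)
        assert pool == snow - excluded

    def test_no_snow_samples_is_configuration_error(self):
        detections = {"a1": {"treated": [(1, "D5")]}}
        table, records, tensor = build_tensor(detections)
        keep = [r for r in records if r.compartment != "snow"]
        sub = table.subset_samples([r.sample_id for r in keep])
        tensor = DetectionTensor.from_table(sub, keep)
        with pytest.raises(ConfigurationError, match="snow"):
            candidate_pool(tensor)


class TestClassification:
    def classify(self, detections, pool=None, **kwargs):
        _, _, tensor = build_tensor(detections)
        pool = pool if pool is not None else set(detections)
        calls = classify_experiment(pool, tensor, "melt_rate", "average", **kwargs)
        return {c.asv_id: c for c in calls}

    def test_definition_examples(self):
        calls = self.classify(
            {
                "full_run": {"snow": True, "treated": [(1, "D5"), (1, "D9"), (2, "D29")]},
                "one_day": {"snow": True, "treated": [(3, "D5")]},
                "gap": {"snow": True, "treated": [(1, "D5"), (1, "D29")]},
                "absent": {"snow": True},
            }
        )
        assert calls["full_run"].status == "successful_colonist"
        assert calls["one_day"].status == "invader"
        # a D9–D20 detection gap does not disqualify persistence to D29
        assert calls["gap"].status == "successful_colonist"
        assert calls["absent"].status == "candidate"
        assert calls["gap"].detected_on_final_day
        assert calls["one_day"].detection_days == frozenset({"D5"})

    def test_multiple_days_without_final_day_is_potential_colonist(self):
        calls = self.classify(
            {"mid": {"snow": True, "treated": [(1, "D5"), (2, "D14")]}}
        )
        assert calls["mid"].status == "potential_colonist"

    def test_detection_pooled_across_replicates(self):
        # same day in two replicates is still one distinct day
        calls = self.classify(
            {"two_reps": {"snow": True, "treated": [(1, "D9"), (2, "D9")]}}
        )
        assert calls["two_reps"].status == "invader"

    def test_nested_chain_invariant(self, default_sim):
        table, records, _, _ = default_sim
        tensor = DetectionTensor.from_table(table, records)
        calls_by_unit = classify_dataset(tensor)
        for calls in calls_by_unit.values():
            inv = {c.asv_id for c in calls if status_rank(c.status) >= 2}
            col = {c.asv_id for c in calls if status_rank(c.status) >= 3}
            suc = {c.asv_id for c in calls if status_rank(c.status) >= 4}
            assert suc <= col <= inv
            pool = {c.asv_id for c in calls}
            assert inv <= pool

    def test_threshold_monotonicity_of_invader_count(self, default_sim):
        table, records, _, _ = default_sim
        last = None
        for threshold in (1, 2, 5, 20, 100):
            tensor = DetectionTensor.from_table(table, records, threshold)
            calls_by_unit = classify_dataset(tensor)
            _, summary = summarize_counts(calls_by_unit)
            n = summary["global_invaders"]
            if last is not None:
                assert n <= last
            last = n

    def test_unknown_experiment_rejected(self):
        _, _, tensor = build_tensor({"a": {"snow": True}})
        with pytest.raises(ValidationError, match="unknown experiment"):
            classify_experiment({"a"}, tensor, "nope")


class TestSummaries:
    def test_empty_calls_give_zero_counts(self):
        counts, summary = summarize_counts({UNIT: []})
        row = counts.iloc[0]
        assert (row[["invaders", "colonists", "successful"]] == 0).all()
        assert summary["global_invaders"] == 0

    def test_engineered_counts(self):
        detections = {
            "gap": {"snow": True, "treated": [(1, "D5"), (1, "D29")]},
            "one_day": {"snow": True, "treated": [(3, "D5")]},
        }
        _, _, tensor = build_tensor(detections)
        calls = classify_experiment(set(detections), tensor, *UNIT)
        counts, summary = summarize_counts({UNIT: calls})
        row = counts.iloc[0]
        assert (row["invaders"], row["colonists"], row["successful"]) == (2, 1, 1)
        assert summary["global_invaders"] == 2

    def test_pool_minus_invaders_identity(self):
        assert non_invading_pool_count(541, 16) == 525
        with pytest.raises(ValidationError):
            non_invading_pool_count(5, 6)

    def test_global_counts_deduplicate_across_units(self, default_sim):
        table, records, _, _ = default_sim
        tensor = DetectionTensor.from_table(table, records)
        calls_by_unit = classify_dataset(tensor)
        counts, summary = summarize_counts(calls_by_unit)
        union = set()
        for calls in calls_by_unit.values():
            union |= {c.asv_id for c in calls if status_rank(c.status) >= 2}
        assert summary["global_invaders"] == len(union)
        assert summary["global_invaders"] <= counts["invaders"].sum()


class TestGroundTruthRecovery:
    def test_noiseless_simulation_recovers_planted_labels(self, noiseless_sim):
        table, records, truth, _ = noiseless_sim
        tensor = DetectionTensor.from_table(table, records)
        calls_by_unit = classify_dataset(tensor)
        confusion = truth_confusion(calls_by_unit, truth)
        assert (confusion["precision"].dropna() == 1.0).all()
        assert (confusion["recall"].dropna() == 1.0).all()
        assert confusion["fp"].sum() == 0 and confusion["fn"].sum() == 0

    def test_default_simulation_calls_equal_planted_labels(self, default_sim):
        """detection probability 1 and high depth: observed = latent."""
        table, records, truth, _ = default_sim
        tensor = DetectionTensor.from_table(table, records)
        calls_by_unit = classify_dataset(tensor)
        lookup = {
            (c.asv_id, unit): c.status
            for unit, calls in calls_by_unit.items()
            for c in calls
        }
        for (asv, unit), status in truth.planted_status.items():
            expected = "candidate" if status == "none" else status
            assert lookup[(asv, unit)] == expected

    def test_reduced_detection_probability_degrades_successful_recall(self):
        recalls = {}
        for p in (1.0, 0.3):
            cfg = SimulationConfig(detection_probability=p, planted_invaders=20)
            table, records, truth, _ = simulate_dataset(cfg, seed=21)
            tensor = DetectionTensor.from_table(table, records)
            confusion = truth_confusion(classify_dataset(tensor), truth)
            row = confusion.set_index("status").loc["successful_colonist"]
            recalls[p] = row["recall"]
        assert recalls[0.3] <= recalls[1.0]


class TestReplicateCounts:
    def test_counts_equal_brute_force_recount(self, default_sim):
        table, records, _, _ = default_sim
        tensor = DetectionTensor.from_table(table, records)
        pool = candidate_pool(tensor)
        counts = replicate_counts(tensor, pool)
        by_id = {r.sample_id: r for r in records}
        presence = table.counts >= 1
        for _, row in counts.iterrows():
            day_sets = {}
            for i, asv in enumerate(table.asv_ids):
                if asv not in pool:
                    continue
                days = set()
                for j, sid in enumerate(table.sample_ids):
                    r = by_id[sid]
                    if (
                        presence[i, j]
                        and r.compartment == "soil"
                        and r.arm == "treatment"
                        and r.experiment == row["experiment"]
                        and r.condition == row["condition"]
                        and r.replicate == row["replicate"]
                        and r.day in ("D5", "D9", "D14", "D20", "D29")
                    ):
                        days.add(r.day)
                if days:
                    day_sets[asv] = days
            inv = len(day_sets)
            col = sum(len(d) >= 2 for d in day_sets.values())
            suc = sum(len(d) >= 2 and "D29" in d for d in day_sets.values())
            assert (row["invaders"], row["colonists"], row["successful"]) == (
                inv,
                col,
                suc,
            )

    def test_identical_replicates_give_flat_anova(self):
        detections = {
            "a": {
                "snow": True,
                "treated": [(r, d) for r in (1, 2, 3) for d in ("D5", "D29")],
            }
        }
        _, _, tensor = build_tensor(detections)
        # duplicate the single unit by relabelling conditions is not possible
        # in the toy; instead check the per-replicate counts are constant
        counts = replicate_counts(tensor, {"a"}, [UNIT])
        assert counts["invaders"].nunique() == 1

    def test_planted_rate_difference_detected_in_most_runs(self):
        """10 vs 2 expected invaders, 3 replicates: the one-way ANOVA on
        per-replicate invader counts is significant in >= 80% of runs."""
        cfg = SimulationConfig(
            units=(("melt_rate", "average"), ("melt_rate", "fast")),
            n_soil_taxa=40,
            n_snow_taxa=30,
            n_shared_taxa=10,
            contaminant_taxa=0,
            lab_controls=0,
            reads_per_sample=3000,
            planted_invaders=12,
            invasion_probability_overrides={"average": 10 / 12, "fast": 2 / 12},
        )
        significant = 0
        for s in range(100):
            table, records, _, _ = simulate_dataset(cfg, seed=5000 + s)
            tensor = DetectionTensor.from_table(table, records)
            pool = candidate_pool(tensor)
            _, results = replicate_counts_anova(tensor, pool)
            significant += results["invaders"]["p"] < 0.05
        assert significant >= 80

    def test_single_replicate_rejected(self):
        detections = {"a": {"snow": True, "treated": [(1, "D5")]}}
        table, records = make_toy_dataset(detections)
        keep = [
            r
            for r in records
            if not (r.compartment == "soil" and (r.replicate or 1) > 1)
        ]
        sub = table.subset_samples([r.sample_id for r in keep])
        tensor = DetectionTensor.from_table(sub, keep)
        with pytest.raises(ConfigurationError, match="replicates"):
            replicate_counts(tensor, {"a"}, [UNIT])


class TestHeatmapExport:
    def test_no_invaders_gives_empty_table_with_header(self):
        _, _, tensor = build_tensor({"a": {"snow": True}})
        calls = classify_experiment({"a"}, tensor, *UNIT)
        table, records = make_toy_dataset({"a": {"snow": True}})
        out = export_heatmap_table({UNIT: calls}, table, records)
        assert len(out) == 0
        assert list(out.columns)[:4] == ["asv_id", "experiment", "condition", "replicate"]

    def test_cardinality_and_values_match_relabund(self):
        detections = {
            "x": {"snow": True, "treated": [(1, "D5"), (1, "D29")]},
            "y": {"snow": True, "treated": [(2, "D9")]},
        }
        table, records, tensor = build_tensor(detections)
        calls = classify_experiment(set(detections), tensor, *UNIT)
        out = export_heatmap_table({UNIT: calls}, table, records)
        # 2 invaders × 3 replicates × 5 post-start days
        assert len(out) == 30
        rel = relative_abundance(table)
        by_id = {r.sample_id: r for r in records}
        sample_of = {
            (r.replicate, r.day): r.sample_id
            for r in records
            if r.compartment == "soil" and r.arm == "treatment"
        }
        for _, row in out.iterrows():
            sid = sample_of[(row["replicate"], row["day"])]
            i = table.asv_ids.index(row["asv_id"])
            j = table.sample_ids.index(sid)
            assert row["relative_abundance"] == pytest.approx(rel[i, j])
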