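import numpy as np
import pytest

from microinvade.model import AsvCountTable, SampleRecord
from microinvade.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset, shared across tests."""
    return simulate_dataset(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noiseless conditions: certain detection, certain survival."""
    cfg = SimulationConfig(
        detection_probability=1.0,
        survival_probability=1.0,
        washout={},
        planted_invaders=20,
    )
    return simulate_dataset(cfg, seed=7)


@pytest.fixture()
def small_table():
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 4],
            [1, 1, 1, 1],
        ]
    )
    return AsvCountTable(
        ["ASV_A", "ASV_B", "ASV_C"], ["S1", "S2", "S3", "S4"], counts
    )


def make_toy_dataset(detections):
    """Hand-built one-unit dataset for colonisation tests.

    ``detections`` maps asv_id -> dict of sample kinds it appears in:
    'snow', 'control' (control soil D14), 'pre' (treated-arm soil DS),
    and treated-soil post-start entries as (replicate, day) tuples.
    """
    asv_ids = sorted(detections)
    records = [
        SampleRecord("SNOW_1", "snow", "melt_rate", "treatment", day="D5"),
        SampleRecord(
            "CTRL_SOIL", "soil", "melt_rate", "control", "average", 1, "D14"
        ),
        SampleRecord("PRE_SOIL", "soil", "melt_rate", "control", day="DS"),
    ]
    treated = []
    for rep in (1, 2, 3):
        for day in ("D5", "D9", "D14", "D20", "D29"):
            sid = f"T{rep}_{day}"
            treated.append((sid, rep, day))
            records.append(
                SampleRecord(
                    sid, "soil", "melt_rate", "treatment", "average", rep, day
                )
            )
    sample_ids = [r.sample_id for r in records]
    counts = np.zeros((len(asv_ids), len(sample_ids)), dtype=np.int64)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, asv in enumerate(asv_ids):
        spots = detections[asv]
        if "snow" in spots:
            counts[i, col["SNOW_1"]] = 10
        if "control" in spots:
            counts[i, col["CTRL_SOIL"]] = 10
        if "pre" in spots:
            counts[i, col["PRE_SOIL"]] = 10
        for rep, day in spots.get("treated", ()):
            counts[i, col[f"T{rep}_{day}"]] = 10
    # keep every sample non-empty so relative abundance is defined
    filler = np.full((1, len(sample_ids)), 100, dtype=np.int64)
    table = AsvCountTable(asv_ids + ["ASV_FILLER"], sample_ids,
                          np.vstack([counts, filler]))
    return table, records
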