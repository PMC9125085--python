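"""Readers and writers for the package's on-disk formats.

Count tables are tab-delimited matrices with a leading ``asv_id`` column
(ASVs as rows, samples as columns — the canonical orientation).  Tables with
a leading ``sample_id`` column are auto-transposed with a logged warning.
A minimal BIOM v1 (JSON, dense or sparse) reader/writer is provided for
interoperability with QIIME-era tooling.

Metadata, taxonomy, and all result tables are plain TSV; run summaries are
JSON key-value files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AsvCountTable,
    SampleRecord,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("microinvade")

_METADATA_COLUMNS = (
    "sample_id",
    "compartment",
    "experiment",
    "arm",
    "condition",
    "replicate",
    "day",
)

_TAXONOMY_RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


def _parse_matrix_frame(frame: pd.DataFrame, path) -> AsvCountTable:
    for j, col in enumerate(frame.columns):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            row = frame.index[int(values.isna().to_numpy().argmax())]
            raise ValidationError(
                f"{path}: cell at row {row!r}, column {col!r} is not a number"
            )
        frame[col] = values
    arr = frame.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    if not np.array_equal(np.rint(arr), arr):
        i, j = np.argwhere(np.rint(arr) != arr)[0]
        raise ValidationError(
            f"{path}: non-integer count at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    return AsvCountTable.from_frame(frame.astype(np.int64))


def read_count_table(path, format: str = "tsv_matrix") -> AsvCountTable:
    """Read an ASV count table.

    ``tsv_matrix``: tab-delimited with a leading ``asv_id`` (canonical) or
    ``sample_id`` (transposed; auto-corrected) identifier column.
    ``biom``: BIOM v1 JSON.
    """
    path = Path(path)
    if format == "biom":
        return _read_biom(path)
    if format != "tsv_matrix":
        raise ValueError(f"unknown count-table format {format!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    orientation = str(frame.index.name or "").strip().lower()
    table = _parse_matrix_frame(frame, path)
    if orientation == "sample_id":
        logger.warning(
            "%s: samples found on rows; transposing to ASV-rows orientation", path
        )
        table = AsvCountTable(
            table.sample_ids, table.asv_ids, table.counts.T
        )
    elif orientation != "asv_id":
        logger.warning(
            "%s: leading column named %r (expected 'asv_id'); assuming ASV rows",
            path,
            frame.index.name,
        )
    return table


def write_count_table(table: AsvCountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


# -- BIOM v1 JSON ---------------------------------------------------------


def _read_biom(path: Path) -> AsvCountTable:
    with open(path) as fh:
        doc = json.load(fh)
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    counts = np.zeros((len(asv_ids), len(sample_ids)), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        counts[:] = np.asarray(doc["data"])
    else:  # sparse [row, col, value] triples
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    taxonomy = None
    if any("metadata" in r and r["metadata"] for r in doc["rows"]):
        taxonomy = {
            r["id"]: list(r["metadata"].get("taxonomy", []))
            for r in doc["rows"]
            if r.get("metadata")
        }
    return AsvCountTable(asv_ids, sample_ids, counts, taxonomy=taxonomy)


def write_biom(table: AsvCountTable, path) -> None:
    rows = []
    for a in table.asv_ids:
        meta = None
        if table.taxonomy and a in table.taxonomy:
            meta = {"taxonomy": list(table.taxonomy[a])}
        rows.append({"id": a, "metadata": meta})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microinvade",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": list(table.shape),
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# -- metadata -------------------------------------------------------------


def read_metadata(path) -> list[SampleRecord]:
    """Read sample metadata (TSV, one row per sample) into SampleRecords."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing metadata columns: {', '.join(missing)}")
    records = []
    for _, row in frame.iterrows():
        def get(col):
            v = row.get(col)
            return None if (v is None or pd.isna(v) or v == "") else v

        replicate = get("replicate")
        denom = get("denom")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                compartment=str(row["compartment"]),
                experiment=get("experiment"),
                arm=get("arm"),
                condition=get("condition"),
                replicate=int(float(replicate)) if replicate is not None else None,
                day=get("day"),
                denom=float(denom) if denom is not None else None,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate sample_id(s): {', '.join(dupes)}")
    return records


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    from .model import metadata_frame

    metadata_frame(records).to_csv(path, sep="\t", index=False)


# -- taxonomy -------------------------------------------------------------


def read_taxonomy(path) -> dict[str, list[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in frame.columns:
        raise SchemaError(f"{path}: taxonomy table needs an 'asv_id' column")
    ranks = [c for c in frame.columns if c != "asv_id"]
    return {
        str(row["asv_id"]): [row[r] if pd.notna(row[r]) else "" for r in ranks]
        for _, row in frame.iterrows()
    }


def write_taxonomy(taxonomy: Mapping[str, Sequence[str]], path) -> None:
    n_ranks = max((len(v) for v in taxonomy.values()), default=len(_TAXONOMY_RANKS))
    ranks = [
        _TAXONOMY_RANKS[i] if i < len(_TAXONOMY_RANKS) else f"Rank{i + 1}"
        for i in range(n_ranks)
    ]
    rows = []
    for a, lineage in taxonomy.items():
        lineage = list(lineage)
        rows.append(
            {
                "asv_id": a,
                **{
                    r: (lineage[i] if i < len(lineage) else "")
                    for i, r in enumerate(ranks)
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- qPCR tables ----------------------------------------------------------


def read_qpcr(path) -> list:
    from .stats import QpcrQuantity

    frame = pd.read_csv(path, sep="\t")
    required = [
        "sample_id",
        "copies_per_reaction",
        "eluate_volume_ul",
        "template_volume_ul",
        "denom",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing qPCR columns: {', '.join(missing)}")
    return [
        QpcrQuantity(
            sample_id=str(row["sample_id"]),
            copies_per_reaction=float(row["copies_per_reaction"]),
            eluate_volume_ul=float(row["eluate_volume_ul"]),
            template_volume_ul=float(row["template_volume_ul"]),
            denom=float(row["denom"]) if pd.notna(row["denom"]) else None,
        )
        for _, row in frame.iterrows()
    ]


def write_qpcr(quantities, path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "copies_per_reaction": q.copies_per_reaction,
                "eluate_volume_ul": q.eluate_volume_ul,
                "template_volume_ul": q.template_volume_ul,
                "denom": q.denom,
            }
            for q in quantities
        ]
    ).to_csv(path, sep="\t", index=False)


# -- run summaries --------------------------------------------------------


def write_run_summary(summary: Mapping, path) -> None:
    """Write a machine-readable key-value run summary (JSON)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_run_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")
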