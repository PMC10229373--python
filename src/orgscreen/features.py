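"""Assemble per-sequence feature vectors and (de)serialize the feature table.

Each assembly sequence yields one numeric row combining intrinsic features
(length, GC, GC deviation from the assembly average) with evidence densities
per 1 Mb (repeats, rRNA, tRNA, CpG islands, mitochondrial and plastid gene
hits), plus raw hit counts and best bitscores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .evidence import EvidenceSet
from .seq_features import AssemblyGCStats, SequenceRecord, gc_content, gc_deviation

__all__ = [
    "SCHEMA_VERSION",
    "COLUMNS",
    "CLASSES",
    "LabeledTable",
    "density_per_mb",
    "build_features",
    "write_table",
    "read_table",
    "read_labels",
    "write_labels",
    "attach_labels",
]

SCHEMA_VERSION = "orgscreen-features-v1"

CLASSES = ("nuclear", "mitochondrion", "plastid")

_INT_COLUMNS = ("length_bp", "gc_outlier_flag", "mito_hit_count", "plastid_hit_count")

COLUMNS = [
    "seq_id",
    "length_bp",
    "gc",
    "gc_delta",
    "gc_zscore",
    "gc_outlier_flag",
    "repeat_density",
    "repeat_frac",
    "rrna_density",
    "trna_density",
    "cpg_density",
    "mito_hit_density",
    "plastid_hit_density",
    "mito_hit_count",
    "plastid_hit_count",
    "best_mito_bitscore",
    "best_plastid_bitscore",
]


@dataclass
class LabeledTable:
    """A feature table (one row per sequence) with optional class labels."""

    frame: pd.DataFrame
    labels: dict[str, str] | None = None
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"feature table is missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)
        if self.labels is not None:
            unlabeled = [s for s in self.frame["seq_id"] if s not in self.labels]
            if unlabeled:
                raise InputError(f"{len(unlabeled)} row(s) have no label, e.g. {unlabeled[:3]}")
            bad = sorted({c for c in self.labels.values() if c not in CLASSES})
            if bad:
                raise InputError(f"unknown class label(s): {bad}; expected one of {CLASSES}")

    @property
    def seq_ids(self) -> list[str]:
        return list(self.frame["seq_id"])

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise InputError("table has no labels attached")
        return np.array([self.labels[s] for s in self.frame["seq_id"]])

    def __len__(self) -> int:
        return len(self.frame)


def density_per_mb(count: float, length_bp: int) -> float:
    """Feature count scaled to occurrences per 1,000,000 bp."""
    if length_bp < 1:
        raise InputError(f"length_bp must be >= 1, got {length_bp}")
    return count * 1e6 / length_bp


def build_features(
    records: Sequence[SequenceRecord],
    stats: AssemblyGCStats,
    evidence: Mapping[str, EvidenceSet],
) -> LabeledTable:
    """One FeatureVector row per record, in record order. Pure and deterministic.

    ``evidence`` may omit sequences (treated as all-zero) but must not name
    ids outside the assembly — reconciliation belongs upstream.
    """
    ids = {r.id for r in records}
    stray = sorted(set(evidence) - ids)
    if stray:
        raise InputError(f"evidence names unknown sequence id(s): {stray[:5]}")

    rows = []
    for rec in records:
        ev = evidence.get(rec.id, EvidenceSet(seq_id=rec.id))
        n = rec.length
        dev = gc_deviation(rec, stats)
        rows.append(
            {
                "seq_id": rec.id,
                "length_bp": n,
                "gc": gc_content(rec),
                "gc_delta": dev.delta,
                "gc_zscore": dev.zscore,
                "gc_outlier_flag": int(dev.flag),
                "repeat_density": density_per_mb(ev.repeat_count, n),
                "repeat_frac": ev.repeat_bp / n,
                "rrna_density": density_per_mb(ev.rrna_count, n),
                "trna_density": density_per_mb(ev.trna_count, n),
                "cpg_density": density_per_mb(ev.cpg_island_count, n),
                "mito_hit_density": density_per_mb(ev.mito_hit_count, n),
                "plastid_hit_density": density_per_mb(ev.plastid_hit_count, n),
                "mito_hit_count": ev.mito_hit_count,
                "plastid_hit_count": ev.plastid_hit_count,
                "best_mito_bitscore": ev.best_mito_bitscore,
                "best_plastid_bitscore": ev.best_plastid_bitscore,
            }
        )
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return LabeledTable(frame=frame)


def write_table(table: LabeledTable, path) -> None:
    """Write the table as TSV; floats use 17 significant digits for bit-exact round-trips."""
    with open(path, "w") as fh:
        fh.write(f"#schema={table.schema_version}\n")
        table.frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> LabeledTable:
    """Read a feature table written by :func:`write_table`.

    Columns may appear in any order (header-driven); the schema line must match.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#schema="):
            raise SchemaError(f"{path}: missing '#schema=' header line")
        version = first.split("=", 1)[1]
        if version != SCHEMA_VERSION:
            raise SchemaError(f"{path}: schema {version!r} is incompatible with {SCHEMA_VERSION!r}")
        frame = pd.read_csv(fh, sep="\t", dtype={"seq_id": str}, float_precision="round_trip")
    if frame.empty and "seq_id" not in frame.columns:
        frame = pd.DataFrame(columns=COLUMNS)
    for col in _INT_COLUMNS:
        if col in frame.columns and len(frame):
            frame[col] = frame[col].astype(np.int64)
    return LabeledTable(frame=frame, schema_version=version)


def write_labels(labels: Mapping[str, str], path) -> None:
    """Write per-sequence class labels as a two-column TSV (seq_id, class)."""
    with open(path, "w") as fh:
        for sid in labels:
            fh.write(f"{sid}\t{labels[sid]}\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column labels TSV; an optional header line is tolerated."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, cls = parts
            if lineno == 1 and cls not in CLASSES:
                continue  # header line
            if cls not in CLASSES:
                raise InputError(f"{path}:{lineno}: unknown class {cls!r}; expected one of {CLASSES}")
            labels[sid] = cls
    return labels


def attach_labels(table: LabeledTable, labels: Mapping[str, str]) -> LabeledTable:
    """Return a copy of the table with labels attached (every row must be labeled)."""
    return LabeledTable(frame=table.frame.copy(), labels=dict(labels), schema_version=table.schema_version)
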