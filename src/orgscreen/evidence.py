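"""Ingest annotator output files and reduce them to per-sequence evidence counts.

The pipeline never runs the external annotators (repeat finder, rRNA/tRNA
scanners, protein homology search); it consumes their standard output
formats: GFF3 for intervals, the tRNA scanner's tabular output, and
12-column blast-style tabular hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ParseError
from .seq_features import CpGIsland

__all__ = [
    "EvidenceSet",
    "HomologyHit",
    "read_gff_intervals",
    "read_trna_tabular",
    "read_homology_tabular",
    "collapse_evidence",
    "merge_intervals",
]

DEFAULT_EVALUE_CEILING = 1e-5

BLAST_TABULAR_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


@dataclass
class EvidenceSet:
    """Per-sequence annotation-evidence counts; all-zero when no evidence exists."""

    seq_id: str
    repeat_count: int = 0
    repeat_bp: int = 0
    rrna_count: int = 0
    trna_count: int = 0
    cpg_island_count: int = 0
    mito_hit_count: int = 0
    plastid_hit_count: int = 0
    best_mito_bitscore: float = 0.0
    best_plastid_bitscore: float = 0.0


@dataclass(frozen=True)
class HomologyHit:
    seq_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float
    target_db: str  # "mito" or "plastid"


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged (adjacent intervals join)."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_gff_intervals(path, feature_types: set[str]) -> dict[str, list[tuple[int, int]]]:
    """Extract intervals of the given feature types from a GFF3 file.

    GFF 1-based inclusive coordinates are converted to 0-based half-open.
    Comment/directive lines are skipped; an embedded ##FASTA section ends
    parsing. Unknown feature types are ignored.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if line == "##FASTA":
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, lineno, f"expected 9 tab-separated GFF columns, got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}..{end_s!r}") from None
            if start < 1 or end < start:
                raise ParseError(path, lineno, f"invalid GFF interval {start}..{end}")
            out.setdefault(seq_id, []).append((start - 1, end))
    return out


def read_trna_tabular(path, count_pseudo: bool = True) -> dict[str, int]:
    """Count tRNA predictions per sequence from tRNA-scanner tabular output.

    Format: 3 header lines, then whitespace-delimited rows whose first column
    is the sequence name. Rows whose note column marks a pseudogene are
    skipped when ``count_pseudo`` is False.
    """
    counts: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        warnings.warn(f"{path}: fewer than 3 header lines and no data rows; treating as empty")
        return counts
    for line in lines[3:]:
        if not line.strip():
            continue
        fields = line.split()
        if not count_pseudo and "pseudo" in line.lower():
            continue
        counts[fields[0]] = counts.get(fields[0], 0) + 1
    return counts


def read_homology_tabular(path, target_db: str, evalue_ceiling: float = DEFAULT_EVALUE_CEILING) -> list[HomologyHit]:
    """Parse 12-column blast-style tabular hits; rows above the e-value ceiling are dropped."""
    if target_db not in ("mito", "plastid"):
        raise ValueError(f"target_db must be 'mito' or 'plastid', got {target_db!r}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != BLAST_TABULAR_COLUMNS:
                raise ParseError(path, lineno, f"expected {BLAST_TABULAR_COLUMNS} columns, got {len(cols)}")
            try:
                pident = float(cols[2])
                align_len = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric pident/length/evalue/bitscore") from None
            if evalue > evalue_ceiling:
                continue
            hits.append(
                HomologyHit(
                    seq_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=pident,
                    align_len=align_len,
                    evalue=evalue,
                    bitscore=bitscore,
                    target_db=target_db,
                )
            )
    return hits


def collapse_evidence(
    seq_ids: Sequence[str],
    interval_maps: Mapping[str, Mapping[str, list[tuple[int, int]]]] | None = None,
    trna_counts: Mapping[str, int] | None = None,
    hits: Iterable[HomologyHit] = (),
    islands: Iterable[CpGIsland] = (),
) -> dict[str, EvidenceSet]:
    """Reduce all evidence to one EvidenceSet per assembly sequence.

    ``interval_maps`` has keys "repeat" and/or "rrna", each mapping
    seq_id -> interval list. Evidence for ids not in ``seq_ids`` triggers a
    reconciliation warning and is dropped. repeat_bp is the length of the
    union of repeat intervals.
    """
    known = set(seq_ids)
    if len(known) != len(seq_ids):
        raise ValueError("seq_ids contains duplicates")
    out = {sid: EvidenceSet(seq_id=sid) for sid in seq_ids}
    interval_maps = interval_maps or {}
    trna_counts = trna_counts or {}

    unknown: set[str] = set()

    for sid, intervals in interval_maps.get("repeat", {}).items():
        if sid not in known:
            unknown.add(sid)
            continue
        out[sid].repeat_count = len(intervals)
        out[sid].repeat_bp = sum(e - s for s, e in merge_intervals(intervals))
    for sid, intervals in interval_maps.get("rrna", {}).items():
        if sid not in known:
            unknown.add(sid)
            continue
        out[sid].rrna_count = len(intervals)
    for sid, count in trna_counts.items():
        if sid not in known:
            unknown.add(sid)
            continue
        out[sid].trna_count = count
    for hit in hits:
        if hit.seq_id not in known:
            unknown.add(hit.seq_id)
            continue
        es = out[hit.seq_id]
        if hit.target_db == "mito":
            es.mito_hit_count += 1
            es.best_mito_bitscore = max(es.best_mito_bitscore, hit.bitscore)
        else:
            es.plastid_hit_count += 1
            es.best_plastid_bitscore = max(es.best_plastid_bitscore, hit.bitscore)
    for isl in islands:
        if isl.seq_id not in known:
            unknown.add(isl.seq_id)
            continue
        out[isl.seq_id].cpg_island_count += 1

    if unknown:
        warnings.warn(
            f"evidence for {len(unknown)} sequence id(s) not present in the assembly was dropped: "
            + ", ".join(sorted(unknown)[:5])
        )
    return out
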