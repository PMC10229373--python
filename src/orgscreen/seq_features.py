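"""Intrinsic per-sequence features computed directly from residues.

GC content, assembly-wide GC statistics, per-sequence GC deviation, and
CpG-island detection by the classic sliding-window criteria (100 bp window
advanced 1 bp at a time; a window qualifies when G+C >= 50% and the
observed/expected CpG dinucleotide ratio >= 0.6; qualifying windows are
merged and merged regions shorter than 200 bp discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

from .errors import InputError

__all__ = [
    "SequenceRecord",
    "AssemblyGCStats",
    "CpGIsland",
    "GCDeviation",
    "read_fasta",
    "gc_content",
    "assembly_gc_stats",
    "gc_deviation",
    "find_cpg_islands",
    "islands_to_gff",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier plus residues (A/C/G/T/N, case-insensitive)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise InputError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise InputError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AssemblyGCStats:
    """Length-weighted mean and standard deviation of per-sequence GC."""

    mean_gc: float
    sd_gc: float


@dataclass(frozen=True)
class CpGIsland:
    """A merged CpG-island interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float


class GCDeviation(NamedTuple):
    delta: float
    zscore: float
    flag: bool


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA; ids are the first whitespace-delimited header token."""
    records = [SequenceRecord(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate sequence ids in {path}")
    return records


def gc_content(record: SequenceRecord) -> float:
    """(#G + #C) / (#A + #C + #G + #T); ambiguity codes excluded from both sides.

    Returns 0.0 for a sequence of only ambiguity codes.
    """
    s = record.residues.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    return gc / denom if denom else 0.0


def assembly_gc_stats(records: Iterable[SequenceRecord]) -> AssemblyGCStats:
    """Length-weighted mean/sd of per-sequence GC over a whole assembly."""
    records = list(records)
    if not records:
        raise InputError("assembly_gc_stats requires at least one sequence")
    lengths = [float(r.length) for r in records]
    gcs = [gc_content(r) for r in records]
    # fsum keeps the result exactly permutation-invariant
    total = math.fsum(lengths)
    mean = math.fsum(l * g for l, g in zip(lengths, gcs)) / total
    var = math.fsum(l * (g - mean) ** 2 for l, g in zip(lengths, gcs)) / total
    return AssemblyGCStats(mean_gc=mean, sd_gc=math.sqrt(max(var, 0.0)))


def gc_deviation(record: SequenceRecord, stats: AssemblyGCStats, z_threshold: float = 2.0) -> GCDeviation:
    """Deviation of a sequence's GC from the assembly mean.

    delta is the signed difference, zscore is delta/sd (0 when sd is 0), and
    flag marks |z| > z_threshold as a substantial outlier.
    """
    delta = gc_content(record) - stats.mean_gc
    z = delta / stats.sd_gc if stats.sd_gc > 0 else 0.0
    return GCDeviation(delta=delta, zscore=z, flag=abs(z) > z_threshold)


def _region_stats(is_c: np.ndarray, is_g: np.ndarray, is_cg: np.ndarray, start: int, end: int) -> tuple[float, float]:
    length = end - start
    c = int(is_c[start:end].sum())
    g = int(is_g[start:end].sum())
    cg = int(is_cg[start : max(end - 1, start)].sum())
    gc_frac = (c + g) / length
    oe = cg * length / (c * g) if c * g > 0 else 0.0
    return gc_frac, oe


def find_cpg_islands(
    record: SequenceRecord,
    window: int = 100,
    shift: int = 1,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Detect CpG islands by sliding-window scan and merge.

    A window of ``window`` bp advanced by ``shift`` qualifies when its GC
    fraction (over the full window) is >= ``min_gc`` and its observed/expected
    CpG ratio (#CG * window / (#C * #G), 0 if #C*#G = 0) is >= ``min_oe``.
    Overlapping or adjacent qualifying windows are merged; merged regions
    shorter than ``min_len`` are discarded. Coordinates are 0-based half-open.
    """
    if window < 1 or shift < 1:
        raise InputError("window and shift must be positive")
    seq = record.residues.upper()
    n = len(seq)
    if window > n:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = is_c[:-1] * is_g[1:] if n > 1 else np.zeros(0, dtype=np.int64)

    c_cum = np.concatenate(([0], np.cumsum(is_c)))
    g_cum = np.concatenate(([0], np.cumsum(is_g)))
    cg_cum = np.concatenate(([0], np.cumsum(is_cg)))

    starts = np.arange(0, n - window + 1, shift)
    c_w = c_cum[starts + window] - c_cum[starts]
    g_w = g_cum[starts + window] - g_cum[starts]
    # CG dinucleotides fully inside the window start at [s, s+window-1)
    cg_w = cg_cum[starts + window - 1] - cg_cum[starts]
    gc_frac = (c_w + g_w) / window
    prod = c_w * g_w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(prod > 0, cg_w * window / np.maximum(prod, 1), 0.0)
    ok = (gc_frac >= min_gc) & (oe >= min_oe)
    ok_starts = starts[ok]
    if ok_starts.size == 0:
        return []

    # Merge qualifying windows: a window [s, s+window) joins the current run
    # when it overlaps or abuts it, i.e. s <= previous start + window.
    breaks = np.flatnonzero(np.diff(ok_starts) > window)
    group_firsts = np.concatenate(([0], breaks + 1))
    group_lasts = np.concatenate((breaks, [ok_starts.size - 1]))

    islands = []
    for fi, la in zip(group_firsts, group_lasts):
        start = int(ok_starts[fi])
        end = int(ok_starts[la]) + window
        if end - start < min_len:
            continue
        gf, oev = _region_stats(is_c, is_g, is_cg, start, end)
        islands.append(CpGIsland(seq_id=record.id, start=start, end=end, gc_fraction=gf, obs_exp_cpg=oev))
    return islands


def islands_to_gff(islands: Iterable[CpGIsland], path) -> None:
    """Write islands as GFF3 (1-based inclusive coordinates, type CpG_island)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for isl in islands:
            attrs = f"gc_fraction={isl.gc_fraction:.4f};obs_exp_cpg={isl.obs_exp_cpg:.4f}"
            fh.write(
                f"{isl.seq_id}\torgscreen\tCpG_island\t{isl.start + 1}\t{isl.end}\t.\t.\t.\t{attrs}\n"
            )
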