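"""Seeded synthetic assemblies with matching evidence files and ground truth.

The generator emulates the labeled corpus the classifier is trained on: a
genome assembly FASTA in which a small minority of contigs are organellar,
with class-dependent GC content, length distributions, and annotation
evidence written in the exact file dialects the ingest readers consume
(GFF3 intervals, tRNA-scanner tabular output, 12-column blast-style hits,
two-column labels TSV). Every bundle carries the feature table expected
from its own ground truth so readers and the feature builder can be checked
for exact round-trips.

Residues are drawn per-base Bernoulli at the class GC level; optional CpG
enrichment plants CG-repeat segments in organellar contigs. Evidence counts
are Poisson at class-specific rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .errors import InputError
from .evidence import EvidenceSet, merge_intervals
from .features import LabeledTable, attach_labels, build_features, write_labels, write_table
from .seq_features import SequenceRecord, assembly_gc_stats, find_cpg_islands

__all__ = ["SimulationConfig", "FixtureBundle", "simulate_assembly", "imbalanced_corpus"]

_CLASSES = ("nuclear", "mitochondrion", "plastid")

DEFAULT_EVIDENCE_RATES = {
    # expected counts per sequence, Poisson-drawn
    "nuclear": {"repeat": 20.0, "rrna": 0.1, "trna": 0.5, "mito_hit": 0.0, "plastid_hit": 0.0},
    "mitochondrion": {"repeat": 2.0, "rrna": 2.0, "trna": 15.0, "mito_hit": 5.0, "plastid_hit": 0.0},
    "plastid": {"repeat": 2.0, "rrna": 4.0, "trna": 25.0, "mito_hit": 0.0, "plastid_hit": 5.0},
}

_MITO_GENES = ["COX1", "COX2", "COX3", "CYTB", "ND1", "ND2", "ND4", "ND5", "ATP6", "ATP8"]
_PLASTID_GENES = ["psbA", "rbcL", "matK", "atpB", "ndhF", "rpoC1", "psaA", "petB", "rps4", "ycf1"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic assembly.

    Defaults model a small eukaryotic assembly in which 5% of 2,000 contigs
    are organellar, organellar GC is shifted 0.2 below nuclear (organellar
    genomes are AT-rich), and organellar contigs carry homology hits against
    their own gene set at a mean rate of 5 per contig.
    """

    n_sequences: int = 2000
    organellar_fraction: float = 0.05
    mito_plastid_ratio: float = 0.5
    nuclear_gc: tuple[float, float] = (0.41, 0.02)
    organellar_gc_shift: float = -0.2
    nuclear_length: tuple[float, float] = (9.2, 1.0)  # lognormal (mu, sigma) of bp
    organellar_length: tuple[int, int] | None = (12_000, 160_000)  # uniform bp; None -> nuclear dist
    evidence_rates: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EVIDENCE_RATES.items()})
    cpg_enrichment: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.organellar_fraction <= 1.0:
            raise InputError("organellar_fraction must be in [0,1]")
        if not 0.0 <= self.mito_plastid_ratio <= 1.0:
            raise InputError("mito_plastid_ratio must be in [0,1]")
        if self.n_sequences < 1:
            raise InputError("n_sequences must be >= 1")


@dataclass
class FixtureBundle:
    """Paths of one generated assembly plus its ground-truth expectations."""

    root: Path
    fasta_path: Path
    repeat_gff_path: Path
    rrna_gff_path: Path
    trna_path: Path
    mito_hits_path: Path
    plastid_hits_path: Path
    labels_path: Path
    expected_table_path: Path
    labels: dict[str, str]
    expected_table: LabeledTable


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_residues(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    second = rng.integers(0, 2, length)  # A/T or C/G coin
    codes = np.where(is_gc, np.where(second == 0, ord("C"), ord("G")), np.where(second == 0, ord("A"), ord("T")))
    return codes.astype(np.uint8).tobytes().decode("ascii")


def _plant_cpg_segments(rng: np.random.Generator, residues: str) -> str:
    n = len(residues)
    seq = list(residues)
    for _ in range(int(rng.integers(1, 4))):
        seg_len = int(rng.integers(300, 601))
        if seg_len >= n:
            continue
        start = int(rng.integers(0, n - seg_len))
        seq[start : start + seg_len] = ("CG" * ((seg_len + 1) // 2))[:seg_len]
    return "".join(seq)


def _write_fasta(records: list[SequenceRecord], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


def _random_intervals(rng: np.random.Generator, count: int, seq_len: int, lo: int, hi: int) -> list[tuple[int, int]]:
    intervals = []
    for _ in range(count):
        length = min(int(rng.integers(lo, hi + 1)), seq_len)
        start = int(rng.integers(0, max(seq_len - length, 0) + 1))
        intervals.append((start, start + length))
    return intervals


def simulate_assembly(config: SimulationConfig, out_dir) -> FixtureBundle:
    """Generate one assembly with evidence files; deterministic given config.seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_sequences
    n_org = round(n * config.organellar_fraction)
    if config.organellar_fraction > 0 and n_org < 1:
        warnings.warn("organellar_fraction * n_sequences < 1; emitting zero organellar sequences")
        n_org = 0
    n_mito = round(n_org * config.mito_plastid_ratio)
    classes = (
        ["nuclear"] * (n - n_org) + ["mitochondrion"] * n_mito + ["plastid"] * (n_org - n_mito)
    )
    rng.shuffle(classes)

    mu, sigma = config.nuclear_length
    nuc_mean, nuc_sd = config.nuclear_gc
    shift = config.organellar_gc_shift

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    evidence: dict[str, EvidenceSet] = {}
    repeat_rows: list[tuple[str, int, int]] = []
    rrna_rows: list[tuple[str, int, int]] = []
    trna_rows: list[tuple[str, int, int, int]] = []
    hit_rows: dict[str, list[str]] = {"mito": [], "plastid": []}

    for i, cls in enumerate(classes):
        sid = f"seq{i + 1:05d}"
        labels[sid] = cls
        if cls == "nuclear" or config.organellar_length is None:
            length = int(np.clip(rng.lognormal(mu, sigma), 500, 5_000_000))
        else:
            lo, hi = config.organellar_length
            length = int(rng.integers(lo, hi + 1))
        gc_target = rng.normal(nuc_mean + (shift if cls != "nuclear" else 0.0), nuc_sd)
        gc_target = float(np.clip(gc_target, 0.05, 0.95))
        residues = _draw_residues(rng, length, gc_target)
        if config.cpg_enrichment and cls != "nuclear":
            residues = _plant_cpg_segments(rng, residues)
        records.append(SequenceRecord(id=sid, residues=residues))

        rates = config.evidence_rates[cls]
        es = EvidenceSet(seq_id=sid)

        rep_intervals = _random_intervals(rng, int(rng.poisson(rates["repeat"])), length, 100, 1000)
        es.repeat_count = len(rep_intervals)
        es.repeat_bp = sum(e - s for s, e in merge_intervals(rep_intervals))
        repeat_rows.extend((sid, s, e) for s, e in rep_intervals)

        rrna_intervals = _random_intervals(rng, int(rng.poisson(rates["rrna"])), length, 1200, 1800)
        es.rrna_count = len(rrna_intervals)
        rrna_rows.extend((sid, s, e) for s, e in rrna_intervals)

        n_trna = int(rng.poisson(rates["trna"]))
        es.trna_count = n_trna
        for t in range(n_trna):
            start = int(rng.integers(0, max(length - 80, 1)))
            trna_rows.append((sid, t + 1, start + 1, start + 73))

        for db, genes, count_attr, best_attr in (
            ("mito", _MITO_GENES, "mito_hit_count", "best_mito_bitscore"),
            ("plastid", _PLASTID_GENES, "plastid_hit_count", "best_plastid_bitscore"),
        ):
            n_hits = int(rng.poisson(rates[f"{db}_hit"]))
            for _ in range(n_hits):
                gene = genes[int(rng.integers(0, len(genes)))]
                pident = round(float(rng.uniform(70, 100)), 1)
                alen = int(rng.integers(100, 501))
                evalue = 10.0 ** float(rng.uniform(-30, -6))
                bits = round(float(rng.uniform(60, 400)), 1)
                qstart = int(rng.integers(1, max(length - alen, 2)))
                hit_rows[db].append(
                    f"{sid}\t{gene}\t{pident}\t{alen}\t{int(rng.integers(0, 20))}\t{int(rng.integers(0, 3))}"
                    f"\t{qstart}\t{qstart + alen - 1}\t1\t{alen}\t{evalue:.3e}\t{bits}"
                )
                setattr(es, count_attr, getattr(es, count_attr) + 1)
                setattr(es, best_attr, max(getattr(es, best_attr), bits))
            # decoy rows above the default e-value ceiling; readers must drop them
            for _ in range(int(rng.poisson(0.2))):
                gene = genes[int(rng.integers(0, len(genes)))]
                hit_rows[db].append(
                    f"{sid}\t{gene}\t{round(float(rng.uniform(40, 70)), 1)}\t{int(rng.integers(50, 150))}"
                    f"\t{int(rng.integers(10, 40))}\t{int(rng.integers(0, 3))}\t1\t100\t1\t100"
                    f"\t{10.0 ** float(rng.uniform(-4, -1)):.3e}\t{round(float(rng.uniform(20, 40)), 1)}"
                )
        evidence[sid] = es

    # islands belong to ground truth too: the expected table is built from
    # in-memory records + planted evidence, not from re-reading the files
    for rec in records:
        evidence[rec.id].cpg_island_count = len(find_cpg_islands(rec))

    fasta = out / "assembly.fasta"
    _write_fasta(records, fasta)

    repeat_gff = out / "repeats.gff3"
    with open(repeat_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, s, e in repeat_rows:
            fh.write(f"{sid}\tRed\tdispersed_repeat\t{s + 1}\t{e}\t.\t+\t.\tID=rep\n")

    rrna_gff = out / "rrna.gff3"
    with open(rrna_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, s, e in rrna_rows:
            fh.write(f"{sid}\tbarrnap\trRNA\t{s + 1}\t{e}\t.\t+\t.\tName=rRNA\n")

    trna_path = out / "trna.tsv"
    with open(trna_path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\tBounds\ttRNA\tAnti\tIntron\tIntron\tInf\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n")
        fh.write("--------\t------\t-----\t------\t----\t-----\t-----\t----\t------\t------\n")
        for sid, num, begin, end in trna_rows:
            fh.write(f"{sid}\t{num}\t{begin}\t{end}\tLeu\tCAA\t0\t0\t65.0\t\n")

    mito_hits = out / "mito_hits.tsv"
    plastid_hits = out / "plastid_hits.tsv"
    mito_hits.write_text("\n".join(hit_rows["mito"]) + ("\n" if hit_rows["mito"] else ""))
    plastid_hits.write_text("\n".join(hit_rows["plastid"]) + ("\n" if hit_rows["plastid"] else ""))

    labels_path = out / "labels.tsv"
    write_labels(labels, labels_path)

    stats = assembly_gc_stats(records)
    table = attach_labels(build_features(records, stats, evidence), labels)
    expected_path = out / "expected_features.tsv"
    write_table(table, expected_path)

    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
        fh.write("\n")

    return FixtureBundle(
        root=out,
        fasta_path=fasta,
        repeat_gff_path=repeat_gff,
        rrna_gff_path=rrna_gff,
        trna_path=trna_path,
        mito_hits_path=mito_hits,
        plastid_hits_path=plastid_hits,
        labels_path=labels_path,
        expected_table_path=expected_path,
        labels=labels,
        expected_table=table,
    )


def imbalanced_corpus(
    config: SimulationConfig, n_assemblies: int, out_dir, sparse: bool = False
) -> list[FixtureBundle]:
    """Generate several assemblies with deterministically derived per-assembly seeds.

    With ``sparse`` each assembly carries 0-2 organellar contigs (mean 1),
    mimicking corpora where organellar sequences are a ~5e-4 minority.
    """
    if n_assemblies < 1:
        raise InputError("n_assemblies must be >= 1")
    out = Path(out_dir)
    child_seeds = [int(s) % 2**31 for s in np.random.SeedSequence(config.seed).generate_state(n_assemblies)]
    sparse_rng = np.random.default_rng(config.seed)
    bundles = []
    for i, child in enumerate(child_seeds):
        cfg = replace(config, seed=child)
        if sparse:
            k = int(sparse_rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25]))
            cfg = replace(cfg, organellar_fraction=k / config.n_sequences)
        bundles.append(simulate_assembly(cfg, out / f"assembly_{i:03d}"))
    return bundles
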