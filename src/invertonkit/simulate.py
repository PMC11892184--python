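"""Synthetic community generator with planted invertons and an exact mapper.

This module manufactures desk-scale versions of the inputs the detection
workflow consumes: random genomes with invertons planted at known
coordinates (IR · payload · reverse-complemented IR), closely related
strains derived by independent per-site substitution (optionally keeping an
inverton neighborhood bitwise identical across strains — the hard case for
multi-mapping), and paired-end reads drawn from a specified
forward/reverse orientation mixture per inverton.  Every fragment's
origin, coordinates and orientation are logged to a truth table so each
downstream stage can be scored against ground truth.

:func:`reference_map_exact` is a deliberately transparent, test-scoped
stand-in for a short-read aligner: it places each mate at every exact-match
position in the augmented reference, enumerates concordant pair placements,
and assigns MAPQ 42 to uniquely placed pairs and MAPQ 0 to multi-placed
ones (one placement reported, chosen at random from the seeded generator —
mirroring how aligners break ties).  Production workflows align with a real
aligner and feed SAM into :mod:`invertonkit.orient_count`; the exact mapper
exists so the MAPQ semantics in tests are fully inspectable.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import InvertonLocus, revcomp
from .ir_locate import AugmentedReference
from .orient_count import AlignmentRecord

__all__ = [
    "make_genome",
    "PlantSpec",
    "plant_inverton",
    "derive_related_strain",
    "ReadSimParams",
    "ReadPair",
    "simulate_paired_reads",
    "write_fastq",
    "reference_map_exact",
    "write_sam",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_genome(length: int, gc_fraction: float = 0.5, seed=0) -> str:
    """Random genome with the given GC content; reproducible given seed."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    return "".join(rng.choice(_BASES, size=length, p=[at, gc, gc, at]))


@dataclass(frozen=True)
class PlantSpec:
    """Where and what to plant: an IR, an invertible payload, and the true
    reverse-orientation probability rho used when simulating reads."""

    contig_key: str
    position: int
    ir: str
    payload: str
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if len(self.payload) < 1:
            raise ValueError("payload must be at least 1 nt (zero-length loop)")
        if len(self.ir) < 1:
            raise ValueError("IR must be non-empty")


def plant_inverton(
    genome: str,
    spec: PlantSpec,
    existing: Sequence[InvertonLocus] = (),
) -> tuple[str, InvertonLocus]:
    """Overwrite ``IR · payload · revcomp(IR)`` into the genome at the spec
    position and return the modified genome with the ground-truth locus.

    The bases immediately flanking the construct (outside the IRs and at
    the payload edges) are adjusted so the IR pair is not extendable by
    chance, making the planted coordinates exactly recoverable by the IR
    search under exact-match scoring.  Overlap with an existing plant is an
    error.
    """
    ir, payload = spec.ir.upper(), spec.payload.upper()
    construct = ir + payload + revcomp(ir)
    pos = spec.position
    if pos < 1 or pos + len(construct) + 1 > len(genome):
        raise ValueError("plant does not fit inside the genome (1 nt margin needed)")
    a, b = pos, pos + len(ir)
    c, d = pos + len(ir) + len(payload), pos + len(construct)
    for l in existing:
        if l.contig_key == spec.contig_key and min(l.span[1], d) > max(l.span[0], a):
            raise ValueError(f"plant collides with existing inverton {l.inverton_id}")

    g = list(genome.upper())
    g[a:d] = construct

    def _break_pair(i: int, j: int) -> None:
        # ensure g[i] is not the complement of g[j]
        if _COMP.get(g[i]) == g[j]:
            g[i] = "A" if _COMP.get(g[j]) != "A" else "C"

    _break_pair(a - 1, d)  # outward extension
    if c - b >= 2:
        _break_pair(b, c - 1)  # inward extension
    locus = InvertonLocus(spec.contig_key, a, b, c, d)
    return "".join(g), locus


def derive_related_strain(
    genome: str,
    divergence: float,
    seed=0,
    preserve: Sequence[tuple[int, int]] = (),
) -> str:
    """Mutate a genome by independent per-site substitutions at the given
    rate.  Intervals in ``preserve`` (e.g. a shared inverton neighborhood)
    are kept bitwise identical — the regime in which multi-mapping between
    closely related strains defeats naive read assignment."""
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must lie in [0, 0.2]")
    rng = _as_rng(seed)
    arr = np.array(list(genome.upper()))
    hit = rng.random(len(arr)) < divergence
    for lo, hi in preserve:
        hit[lo:hi] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end read simulation parameters."""

    read_len: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    n_pairs: int = 1000
    error_rate: float = 0.0

    def validate(self) -> None:
        if self.read_len >= self.insert_mean:
            raise ValueError("read_len must be smaller than insert_mean")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str
    contig_key: str
    frag_start: int
    frag_end: int
    orientation: str  # F or R relative to the reference genome
    inverton_id: str = ""


def simulate_paired_reads(
    genome_db: Mapping[str, str],
    planted: Sequence[tuple[InvertonLocus, float]] = (),
    params: ReadSimParams | None = None,
    seed=0,
    region: tuple[str, int, int] | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw paired-end fragments; fragments overlapping a planted
    invertible region come from the flipped haplotype with probability rho.

    ``region`` optionally restricts fragment starts to one window (useful
    for focusing depth on a locus).  Returns the reads and a truth table
    logging every fragment's origin and orientation.  Reproducible given
    seed.
    """
    params = params or ReadSimParams()
    params.validate()
    rng = _as_rng(seed)

    flipped: dict[str, dict[str, str]] = {}
    by_contig: dict[str, list[tuple[InvertonLocus, float]]] = {}
    for locus, rho in planted:
        seq = genome_db[locus.contig_key]
        b, c = locus.invertible_region
        flipped.setdefault(locus.contig_key, {})[locus.inverton_id] = (
            seq[:b] + revcomp(seq[b:c]) + seq[c:]
        )
        by_contig.setdefault(locus.contig_key, []).append((locus, rho))

    contigs = sorted(genome_db)
    lengths = np.array([len(genome_db[c]) for c in contigs], dtype=float)
    if region is not None and region[0] not in genome_db:
        raise KeyError(f"region contig {region[0]!r} not in genome db")

    pairs: list[ReadPair] = []
    truth_rows = []
    rl = params.read_len
    for k in range(params.n_pairs):
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(insert, rl + 2)
        if region is None:
            ci = rng.choice(len(contigs), p=lengths / lengths.sum())
            contig = contigs[int(ci)]
            clen = len(genome_db[contig])
            if insert > clen:
                raise ValueError("insert size exceeds contig length")
            start = int(rng.integers(0, clen - insert + 1))
        else:
            contig, lo, hi = region
            clen = len(genome_db[contig])
            if insert > clen:
                raise ValueError("insert size exceeds contig length")
            start = int(rng.integers(lo, max(lo + 1, hi - insert)))
        end = start + insert

        orientation, iid, src = "F", "", genome_db[contig]
        for locus, rho in by_contig.get(contig, ()):
            b, c = locus.invertible_region
            if min(end, c) > max(start, b):  # overlaps invertible region
                iid = locus.inverton_id
                if rng.random() < rho:
                    orientation = "R"
                    src = flipped[contig][iid]
                break
        frag = src[start:end]
        seq1, seq2 = frag[:rl], revcomp(frag[-rl:])
        if params.error_rate > 0:
            seq1 = _apply_errors(seq1, params.error_rate, rng)
            seq2 = _apply_errors(seq2, params.error_rate, rng)
        name = f"frag{k:07d}"
        pairs.append(ReadPair(name, seq1, seq2, contig, start, end, orientation, iid))
        truth_rows.append(
            {
                "read_name": name,
                "contig_key": contig,
                "frag_start": start,
                "frag_end": end,
                "orientation": orientation,
                "inverton_id": iid,
            }
        )
    return pairs, pd.DataFrame(truth_rows)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def write_fastq(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write mates to a FASTQ file pair (gzipped when the name ends .gz)."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with _open(path1) as f1, _open(path2) as f2:
        for p in pairs:
            q1, q2 = "I" * len(p.seq1), "I" * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# Exact mapper (test-scoped)
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def reference_map_exact(
    pairs: Sequence[ReadPair],
    augref: AugmentedReference,
    seed=0,
    insert_min: int = 0,
    insert_max: int = 2000,
) -> list[AlignmentRecord]:
    """Map read pairs by exact matching against the augmented reference.

    A *concordant placement* puts both mates on one record, inward-facing,
    within the insert bounds.  A pair with exactly one concordant placement
    gets MAPQ 42; with several, MAPQ 0 (one reported, drawn from the seeded
    generator); with none, both mates are reported unmapped.  Output is
    name-grouped and directly consumable by
    :func:`invertonkit.orient_count.count_sample`.
    """
    rng = _as_rng(seed)
    refs = [(r.name, r.seq) for r in augref]
    out: list[AlignmentRecord] = []
    for pair in pairs:
        placements = []
        for name, seq in refs:
            p1f = _find_all(seq, pair.seq1)
            p2r = _find_all(seq, revcomp(pair.seq2))
            for i in p1f:
                for j in p2r:
                    ins = j + len(pair.seq2) - i
                    if j >= i and insert_min <= ins <= insert_max:
                        placements.append((name, i, j, False))
            p1r = _find_all(seq, revcomp(pair.seq1))
            p2f = _find_all(seq, pair.seq2)
            for j in p1r:
                for i in p2f:
                    ins = j + len(pair.seq1) - i
                    if j >= i and insert_min <= ins <= insert_max:
                        placements.append((name, j, i, True))
        if not placements:
            for is_r1 in (True, False):
                out.append(
                    AlignmentRecord(
                        qname=pair.name,
                        ref_name=None,
                        pos=0,
                        length=len(pair.seq1 if is_r1 else pair.seq2),
                        mapq=0,
                        is_reverse=False,
                        is_read1=is_r1,
                        seq=pair.seq1 if is_r1 else pair.seq2,
                    )
                )
            continue
        mapq = 42 if len(placements) == 1 else 0
        placements.sort()
        chosen = placements[int(rng.integers(0, len(placements)))]
        name, pos1, pos2, r1_rev = chosen
        out.append(
            AlignmentRecord(
                qname=pair.name,
                ref_name=name,
                pos=pos1,
                length=len(pair.seq1),
                mapq=mapq,
                is_reverse=r1_rev,
                is_read1=True,
                seq=pair.seq1,
            )
        )
        out.append(
            AlignmentRecord(
                qname=pair.name,
                ref_name=name,
                pos=pos2,
                length=len(pair.seq2),
                mapq=mapq,
                is_reverse=not r1_rev,
                is_read1=False,
                seq=pair.seq2,
            )
        )
    return out


def write_sam(
    records: Sequence[AlignmentRecord],
    augref: AugmentedReference,
    path: str | Path,
) -> None:
    """Write mapper output as SAM against the augmented reference."""
    import pysam

    names = [r.name for r in augref]
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": r.name, "LN": len(r.seq)} for r in augref],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.qname
            a.query_sequence = rec.seq or ("N" * rec.length)
            a.flag = (
                (0x1 | 0x40 if rec.is_read1 else 0x1 | 0x80)
                | (0x10 if rec.is_reverse else 0)
                | (0x4 if rec.is_unmapped else 0)
            )
            if not rec.is_unmapped:
                a.reference_id = tid[rec.ref_name]
                a.reference_start = rec.pos
                a.cigarstring = f"{rec.length}M"
            a.mapping_quality = rec.mapq
            fh.write(a)
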