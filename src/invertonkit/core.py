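"""Domain types and file I/O for inverton analysis.

An *inverton* is a genomic segment flanked by a pair of inverted repeats
(IRs) that can be flipped by site-specific recombination.  Every analysis in
this package is anchored on two records defined here:

* :class:`InvertonLocus` — the four IR coordinates on a contig, printed and
  parsed in the ``<contig_key>:<a>-<b>-<c>-<d>`` identifier form, where
  ``[a, b)`` is the left IR, ``[c, d)`` the right IR and ``[b, c)`` the
  invertible region.  All internal coordinates are 0-based half-open.
* :class:`OrientationCounts` — per-sample read support for the forward and
  reverse orientations (``Pe_*`` from paired-end geometry, ``Span_*`` from
  junction-spanning reads).

The module also loads the defined-community genome database (FASTA plus a
strain manifest mapping contigs to strains and GTDB-style taxonomy), GFF3
gene annotations, sample metadata, and the orientation-count TSV tables.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "revcomp",
    "InvertonIdError",
    "InvertonLocus",
    "parse_inverton_id",
    "format_inverton_id",
    "Strain",
    "StrainManifest",
    "OrientationCounts",
    "SampleMeta",
    "GeneRecord",
    "load_genome_db",
    "read_gff3",
    "write_gff3",
    "read_sample_metadata",
    "read_counts_table",
    "write_counts_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvertonIdError(ValueError):
    """Raised for malformed or non-monotone inverton identifiers."""


@dataclass(frozen=True, order=True)
class InvertonLocus:
    """Four IR coordinates on a contig, 0-based half-open.

    ``[left_ir_start, left_ir_end)`` is the left IR, ``[right_ir_start,
    right_ir_end)`` the right IR and ``[left_ir_end, right_ir_start)`` the
    invertible region that flips between orientations.
    """

    contig_key: str
    left_ir_start: int
    left_ir_end: int
    right_ir_start: int
    right_ir_end: int

    def __post_init__(self) -> None:
        a, b, c, d = (
            self.left_ir_start,
            self.left_ir_end,
            self.right_ir_start,
            self.right_ir_end,
        )
        if not a < b:
            raise InvertonIdError(
                f"left IR empty or inverted: left_ir_start={a} >= left_ir_end={b}"
            )
        if not b <= c:
            raise InvertonIdError(
                f"IRs overlap: left_ir_end={b} > right_ir_start={c}"
            )
        if not c < d:
            raise InvertonIdError(
                f"right IR empty or inverted: right_ir_start={c} >= right_ir_end={d}"
            )
        if a < 0:
            raise InvertonIdError(f"negative coordinate: left_ir_start={a}")

    @property
    def strain_abbrev(self) -> str:
        """Strain abbreviation, the part of the contig key before ``__``."""
        return self.contig_key.rsplit("__", 1)[0]

    @property
    def invertible_region(self) -> tuple[int, int]:
        return (self.left_ir_end, self.right_ir_start)

    @property
    def span(self) -> tuple[int, int]:
        """Outer extent ``[left_ir_start, right_ir_end)``."""
        return (self.left_ir_start, self.right_ir_end)

    @property
    def ir_length(self) -> int:
        return self.left_ir_end - self.left_ir_start

    @property
    def inverton_id(self) -> str:
        return format_inverton_id(self)


_ID_RE = re.compile(r"^(?P<key>.+):(?P<a>\d+)-(?P<b>\d+)-(?P<c>\d+)-(?P<d>\d+)$")


def parse_inverton_id(id_string: str) -> InvertonLocus:
    """Parse ``<contig_key>:<a>-<b>-<c>-<d>`` into an :class:`InvertonLocus`.

    The printed numbers are preserved verbatim as the internal 0-based
    half-open coordinates, so ``format_inverton_id(parse_inverton_id(s)) == s``.
    """
    m = _ID_RE.match(id_string)
    if m is None:
        raise InvertonIdError(
            f"malformed inverton id {id_string!r}: expected "
            "'<contig_key>:<a>-<b>-<c>-<d>' with integer coordinates"
        )
    return InvertonLocus(
        contig_key=m.group("key"),
        left_ir_start=int(m.group("a")),
        left_ir_end=int(m.group("b")),
        right_ir_start=int(m.group("c")),
        right_ir_end=int(m.group("d")),
    )


def format_inverton_id(locus: InvertonLocus) -> str:
    return (
        f"{locus.contig_key}:{locus.left_ir_start}-{locus.left_ir_end}"
        f"-{locus.right_ir_start}-{locus.right_ir_end}"
    )


# ---------------------------------------------------------------------------
# Strain manifest
# ---------------------------------------------------------------------------

_TAXON_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Strain:
    """One community member: name, abbreviation, its contigs, taxonomy."""

    name: str
    abbrev: str
    contig_ids: tuple[str, ...]
    taxonomy: Mapping[str, str] = field(default_factory=dict)

    @property
    def phylum(self) -> str:
        return self.taxonomy.get("phylum", "")


class StrainManifest:
    """Maps contigs to strains; the sole source of taxonomy in the package.

    Invariants enforced on construction: abbreviations are unique and every
    contig id belongs to exactly one strain.
    """

    def __init__(self, strains: Sequence[Strain]):
        self.strains = tuple(strains)
        abbrevs = [s.abbrev for s in self.strains]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValueError(f"duplicate strain abbreviations: {dupes}")
        self._by_contig: dict[str, Strain] = {}
        for s in self.strains:
            for cid in s.contig_ids:
                if cid in self._by_contig:
                    raise ValueError(
                        f"contig {cid!r} assigned to both "
                        f"{self._by_contig[cid].abbrev!r} and {s.abbrev!r}"
                    )
                self._by_contig[cid] = s
        self._by_abbrev = {s.abbrev: s for s in self.strains}

    def strain_for_contig(self, contig_id: str) -> Strain | None:
        return self._by_contig.get(contig_id)

    def strain(self, abbrev: str) -> Strain:
        return self._by_abbrev[abbrev]

    def __iter__(self):
        return iter(self.strains)

    def __len__(self) -> int:
        return len(self.strains)

    def contig_key(self, contig_id: str) -> str:
        """``<abbrev>__<zero-based contig index>`` for a raw FASTA record id."""
        strain = self._by_contig.get(contig_id)
        if strain is None:
            raise KeyError(f"contig {contig_id!r} not present in manifest")
        return f"{strain.abbrev}__{strain.contig_ids.index(contig_id)}"

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainManifest":
        """Read a manifest TSV: strain_name, abbrev, contig_ids (comma-sep),
        optional taxonomy columns (phylum .. species)."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        strains = []
        for _, row in df.iterrows():
            taxonomy = {r: row[r] for r in _TAXON_RANKS if r in df.columns}
            strains.append(
                Strain(
                    name=row["strain_name"],
                    abbrev=row["abbrev"],
                    contig_ids=tuple(
                        c for c in str(row["contig_ids"]).split(",") if c
                    ),
                    taxonomy=taxonomy,
                )
            )
        return cls(strains)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s in self.strains:
            row = {
                "strain_name": s.name,
                "abbrev": s.abbrev,
                "contig_ids": ",".join(s.contig_ids),
            }
            row.update({r: s.taxonomy.get(r, "") for r in _TAXON_RANKS})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_genome_db(
    fasta_paths: Sequence[str | Path] | str | Path,
    manifest: StrainManifest,
) -> dict[str, str]:
    """Load FASTA genomes into a ``contig_key -> sequence`` database.

    Contig keys follow ``<abbrev>__<index>`` with the index taken from the
    order of ``contig_ids`` in the manifest.  Records absent from the
    manifest, duplicated records and manifest contigs missing from the FASTA
    input are all hard errors.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    db: dict[str, str] = {}
    seen_raw: set[str] = set()
    unknown: list[str] = []
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen_raw:
                raise ValueError(f"duplicate FASTA record id {rec.id!r}")
            seen_raw.add(rec.id)
            if manifest.strain_for_contig(rec.id) is None:
                unknown.append(rec.id)
                continue
            db[manifest.contig_key(rec.id)] = str(rec.seq).upper()
    if unknown:
        raise ValueError(
            f"FASTA records absent from manifest: {sorted(unknown)}"
        )
    missing = [
        cid
        for s in manifest
        for cid in s.contig_ids
        if manifest.contig_key(cid) not in db
    ]
    if missing:
        raise ValueError(f"manifest contigs missing from FASTA input: {missing}")
    return db


# ---------------------------------------------------------------------------
# Orientation counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationCounts:
    """Per-sample forward/reverse read support for one inverton.

    ``pe_*`` counts come from paired-end orientation, ``span_*`` from reads
    directly spanning an IR junction.  Ratios are reverse over total; they
    are NaN (not 0) when the denominator is zero, distinguishing "no data"
    from "all forward".
    """

    inverton_id: str
    sample_id: str
    pe_f: int = 0
    pe_r: int = 0
    span_f: int = 0
    span_r: int = 0

    def __post_init__(self) -> None:
        for name in ("pe_f", "pe_r", "span_f", "span_r"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def pe_ratio(self) -> float:
        tot = self.pe_f + self.pe_r
        return self.pe_r / tot if tot else math.nan

    @property
    def span_ratio(self) -> float:
        tot = self.span_f + self.span_r
        return self.span_r / tot if tot else math.nan

    def __add__(self, other: "OrientationCounts") -> "OrientationCounts":
        if other.inverton_id != self.inverton_id:
            raise ValueError("cannot add counts for different invertons")
        return replace(
            self,
            sample_id="pooled",
            pe_f=self.pe_f + other.pe_f,
            pe_r=self.pe_r + other.pe_r,
            span_f=self.span_f + other.span_f,
            span_r=self.span_r + other.span_r,
        )


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata: type, source strain (for isolates), timepoint."""

    sample_id: str
    sample_type: str  # isolate | mouse_stool | mixed_carrier | mixed_supernatant
    strain: str = ""
    timepoint: str = ""
    timepoint_order: int = 0


SAMPLE_TYPES = ("isolate", "mouse_stool", "mixed_carrier", "mixed_supernatant")


def read_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read sample metadata TSV (sample_id, sample_type, strain, timepoint,
    timepoint_order) into a dict keyed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        if row["sample_type"] not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {row['sample_type']!r} for sample "
                f"{row['sample_id']!r}"
            )
        out[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            sample_type=row["sample_type"],
            strain=row.get("strain", ""),
            timepoint=row.get("timepoint", ""),
            timepoint_order=int(row["timepoint_order"] or 0),
        )
    return out


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A coding sequence: 0-based half-open coordinates, strand, annotation."""

    contig_key: str
    start: int
    end: int
    strand: str
    gene_id: str
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end (start for +, end for -)."""
        return self.start if self.strand == "+" else self.end


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return ""


def read_gff3(path: str | Path, feature_types: Iterable[str] = ("CDS",)) -> list[GeneRecord]:
    """Read gene records from GFF3 (1-based inclusive on disk, converted to
    0-based half-open).  Annotation text is taken from ``product=`` falling
    back to ``Name=``."""
    wanted = set(feature_types)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS, dtype=str
    )
    genes = []
    for _, row in df.iterrows():
        if row["type"] not in wanted:
            continue
        attrs = row["attributes"]
        gene_id = _gff_attr(attrs, "ID") or f"{row['seqid']}:{row['start']}"
        annotation = _gff_attr(attrs, "product") or _gff_attr(attrs, "Name")
        genes.append(
            GeneRecord(
                contig_key=row["seqid"],
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                strand=row["strand"],
                gene_id=gene_id,
                annotation=annotation,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};product={g.annotation}"
            fh.write(
                f"{g.contig_key}\tinvertonkit\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Counts table IO (Pe_F/Pe_R/Span_F/Span_R schema)
# ---------------------------------------------------------------------------

_COUNT_COLS = [
    "inverton_id", "sample_id", "Pe_F", "Pe_R", "Pe_ratio", "Span_F", "Span_R", "Span_ratio",
]


def write_counts_table(counts: Sequence[OrientationCounts], path: str | Path) -> None:
    rows = [
        {
            "inverton_id": c.inverton_id,
            "sample_id": c.sample_id,
            "Pe_F": c.pe_f,
            "Pe_R": c.pe_r,
            "Pe_ratio": c.pe_ratio,
            "Span_F": c.span_f,
            "Span_R": c.span_r,
            "Span_ratio": c.span_ratio,
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=_COUNT_COLS).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_counts_table(path: str | Path) -> list[OrientationCounts]:
    """Read the orientation-count TSV.  Integer counts are validated
    (negative values are errors); ratios are re-derived from the counts, the
    on-disk ratio columns are never trusted."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLS[:2] + ["Pe_F", "Pe_R", "Span_F", "Span_R"] if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            OrientationCounts(
                inverton_id=row["inverton_id"],
                sample_id=str(row["sample_id"]),
                pe_f=int(row["Pe_F"]),
                pe_r=int(row["Pe_R"]),
                span_f=int(row["Span_F"]),
                span_r=int(row["Span_R"]),
            )
        )
    return out
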