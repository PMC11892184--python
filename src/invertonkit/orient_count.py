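"""Classify paired-end alignments into orientation support and call invertons.

Reads are aligned (by an external aligner, or the test-scoped exact mapper
in :mod:`invertonkit.simulate`) against the augmented orientation
reference.  Each properly-oriented pair whose placement is consistent with
only one orientation record contributes a paired-end vote (``Pe_F`` /
``Pe_R``); each single mate crossing an IR/invertible-region junction by at
least ``junction_overhang`` nucleotides on both sides contributes a
spanning vote (``Span_F`` / ``Span_R``).  Alignments below the MAPQ
threshold (default 30) are discarded outright, which is what suppresses
cross-strain mismapping between near-identical genomes.

Counts are produced per sample, pooled across samples under a declarative
policy (a strain's own isolates plus all community samples by default), and
invertons are called when all four pooled counts meet the threshold
(default 5 each).  No minor-orientation-frequency floor is applied, so
rarely flipped invertons remain callable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .core import OrientationCounts, SampleMeta
from .ir_locate import AugmentedReference, RefRecord, ROLE_FORWARD, ROLE_REVERSE

__all__ = [
    "ClassifierParams",
    "CallThresholds",
    "Classification",
    "AlignmentRecord",
    "classify_alignment_pair",
    "pair_events",
    "count_sample",
    "read_sam",
    "pool_counts",
    "default_pooling_policy",
    "call_invertons",
    "inversion_ratio",
    "minor_orientation_frequency",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Alignment-filtering and classification geometry."""

    mapq_min: int = 30
    junction_overhang: int = 10
    insert_min: int = 0
    insert_max: int = 2000

    def validate(self) -> None:
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if self.junction_overhang < 1:
            raise ValueError("junction_overhang must be >= 1")
        if self.insert_min < 0 or self.insert_max < self.insert_min:
            raise ValueError("invalid insert bounds")


@dataclass(frozen=True)
class CallThresholds:
    """Minimum pooled read support per channel for calling an inverton."""

    min_pe_f: int = 5
    min_pe_r: int = 5
    min_span_f: int = 5
    min_span_r: int = 5

    def validate(self) -> None:
        if min(self.min_pe_f, self.min_pe_r, self.min_span_f, self.min_span_r) < 0:
            raise ValueError("thresholds must be >= 0")


class Classification(str, Enum):
    PE_F = "PE_F"
    PE_R = "PE_R"
    SPAN_F = "SPAN_F"
    SPAN_R = "SPAN_R"
    UNINFORMATIVE = "UNINFORMATIVE"
    DISCARDED_MAPQ = "DISCARDED_MAPQ"


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal ungapped alignment record against the augmented reference."""

    qname: str
    ref_name: str | None
    pos: int
    length: int
    mapq: int
    is_reverse: bool
    is_read1: bool
    seq: str = ""

    @property
    def is_unmapped(self) -> bool:
        return self.ref_name is None

    @property
    def end(self) -> int:
        return self.pos + self.length


@dataclass(frozen=True)
class PairEvents:
    """Orientation events contributed by one mate pair: at most one PE event
    for the pair and at most one SPAN event per mate."""

    inverton_id: str | None = None
    pe: Classification | None = None
    spans: tuple[Classification, ...] = ()
    discarded: bool = False

    @property
    def primary(self) -> Classification:
        if self.discarded:
            return Classification.DISCARDED_MAPQ
        if self.pe is not None:
            return self.pe
        if self.spans:
            return self.spans[0]
        return Classification.UNINFORMATIVE


def _mate_spans_junction(rec: AlignmentRecord, junction: int, overhang: int) -> bool:
    return rec.pos <= junction - overhang and rec.end >= junction + overhang


def pair_events(
    r1: AlignmentRecord | None,
    r2: AlignmentRecord | None,
    augref: AugmentedReference,
    params: ClassifierParams | None = None,
) -> PairEvents:
    """Full event accounting for a mate pair (or a singleton mate)."""
    params = params or ClassifierParams()
    params.validate()
    mates = [r for r in (r1, r2) if r is not None]
    if not mates:
        return PairEvents()
    if len(mates) == 2 and mates[0].qname != mates[1].qname:
        raise ValueError(
            f"mate names differ: {mates[0].qname!r} vs {mates[1].qname!r}"
        )
    if any(m.is_unmapped for m in mates):
        return PairEvents()
    if any(m.mapq < params.mapq_min for m in mates):
        return PairEvents(discarded=True)

    ref_names = {m.ref_name for m in mates}
    if len(ref_names) != 1:
        return PairEvents()
    rec = augref[mates[0].ref_name]
    if rec.role not in (ROLE_FORWARD, ROLE_REVERSE) or rec.locus is None:
        return PairEvents()
    jb, jc = rec.inner_junctions
    forward = rec.role == ROLE_FORWARD
    iid = rec.locus.inverton_id

    spans = []
    span_cls = Classification.SPAN_F if forward else Classification.SPAN_R
    for m in mates:
        if _mate_spans_junction(m, jb, params.junction_overhang) or _mate_spans_junction(
            m, jc, params.junction_overhang
        ):
            spans.append(span_cls)

    pe = None
    if len(mates) == 2:
        m1, m2 = mates
        proper = m1.is_reverse != m2.is_reverse
        left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
        proper = proper and not left.is_reverse and right.is_reverse
        insert = right.end - left.pos
        proper = proper and params.insert_min <= insert <= params.insert_max
        if proper:
            overlaps_interior = any(
                min(m.end, jc) > max(m.pos, jb) for m in mates
            )
            straddles = (left.pos < jb < right.end) or (left.pos < jc < right.end)
            if overlaps_interior and straddles:
                pe = Classification.PE_F if forward else Classification.PE_R

    # cap total events at the number of retained mates so that counts are
    # conserved (a pair never outvotes its own read records)
    if pe is not None and len(spans) + 1 > len(mates):
        spans = spans[: len(mates) - 1]
    if pe is None and not spans:
        return PairEvents(inverton_id=iid)
    return PairEvents(inverton_id=iid, pe=pe, spans=tuple(spans))


def classify_alignment_pair(
    r1: AlignmentRecord | None,
    r2: AlignmentRecord | None,
    augref: AugmentedReference,
    params: ClassifierParams | None = None,
) -> Classification:
    """Primary classification of a mate pair (PE events take precedence over
    SPAN events when both are present; see :func:`pair_events` for the full
    accounting used by counting)."""
    return pair_events(r1, r2, augref, params).primary


def count_sample(
    records: Iterable[AlignmentRecord],
    augref: AugmentedReference,
    params: ClassifierParams | None = None,
    sample_id: str = "sample",
) -> list[OrientationCounts]:
    """Accumulate orientation counts for one sample.

    The stream must be name-grouped (mates adjacent).  Every candidate in
    the reference gets a row, so an empty stream yields all-zero counts.
    Classified events never exceed the number of retained records.
    """
    params = params or ClassifierParams()
    tallies: dict[str, dict[str, int]] = {
        iid: {"pe_f": 0, "pe_r": 0, "span_f": 0, "span_r": 0}
        for iid in augref.inverton_ids
    }

    def _apply(ev: PairEvents) -> None:
        if ev.inverton_id is None:
            return
        t = tallies[ev.inverton_id]
        if ev.pe is Classification.PE_F:
            t["pe_f"] += 1
        elif ev.pe is Classification.PE_R:
            t["pe_r"] += 1
        for s in ev.spans:
            if s is Classification.SPAN_F:
                t["span_f"] += 1
            else:
                t["span_r"] += 1

    pending: AlignmentRecord | None = None
    for rec in records:
        if pending is None:
            pending = rec
            continue
        if rec.qname == pending.qname:
            _apply(pair_events(pending, rec, augref, params))
            pending = None
        else:
            _apply(pair_events(pending, None, augref, params))
            pending = rec
    if pending is not None:
        _apply(pair_events(pending, None, augref, params))

    return [
        OrientationCounts(inverton_id=iid, sample_id=sample_id, **t)
        for iid, t in sorted(tallies.items())
    ]


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream a (name-grouped) SAM/BAM file as :class:`AlignmentRecord`."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            length = aln.query_alignment_length or (
                len(aln.query_sequence) if aln.query_sequence else 0
            )
            yield AlignmentRecord(
                qname=aln.query_name,
                ref_name=None if aln.is_unmapped else aln.reference_name,
                pos=aln.reference_start if not aln.is_unmapped else 0,
                length=length,
                mapq=aln.mapping_quality,
                is_reverse=aln.is_reverse,
                is_read1=not aln.is_read2,
                seq=aln.query_sequence or "",
            )


# ---------------------------------------------------------------------------
# Pooling and calling
# ---------------------------------------------------------------------------


def default_pooling_policy(strain_abbrev: str, meta: SampleMeta) -> bool:
    """Pool a strain's own isolate cultures plus every community sample
    (mouse stool and mixed in vitro cultures)."""
    if meta.sample_type == "isolate":
        return meta.strain == strain_abbrev
    return True


def pool_counts(
    counts: Sequence[OrientationCounts],
    meta: Mapping[str, SampleMeta] | None = None,
    policy=default_pooling_policy,
) -> dict[str, OrientationCounts]:
    """Element-wise sums per inverton over the samples admitted by the
    pooling policy.  Order-independent.  With ``meta=None`` all samples
    pool unconditionally."""
    from .core import parse_inverton_id

    pooled: dict[str, OrientationCounts] = {}
    for c in counts:
        if meta is not None:
            if c.sample_id not in meta:
                raise KeyError(f"unknown sample_id {c.sample_id!r}")
            strain = parse_inverton_id(c.inverton_id).strain_abbrev
            if not policy(strain, meta[c.sample_id]):
                continue
        if c.inverton_id in pooled:
            pooled[c.inverton_id] = pooled[c.inverton_id] + c
        else:
            pooled[c.inverton_id] = OrientationCounts(
                inverton_id=c.inverton_id,
                sample_id="pooled",
                pe_f=c.pe_f,
                pe_r=c.pe_r,
                span_f=c.span_f,
                span_r=c.span_r,
            )
    return pooled


def call_invertons(
    pooled: Mapping[str, OrientationCounts],
    thresholds: CallThresholds | None = None,
) -> set[str]:
    """Call an inverton when all four pooled counts meet their thresholds.

    Deliberately, no minor-orientation-frequency floor is applied: an
    inverton with e.g. counts (1000, 9, 1000, 9) is called even though its
    minor orientation frequency is below 1%.
    """
    t = thresholds or CallThresholds()
    t.validate()
    return {
        iid
        for iid, c in pooled.items()
        if c.pe_f >= t.min_pe_f
        and c.pe_r >= t.min_pe_r
        and c.span_f >= t.min_span_f
        and c.span_r >= t.min_span_r
    }


def inversion_ratio(counts: OrientationCounts) -> float:
    """Reverse over total paired-end counts, R/(R+F); NaN when undefined."""
    return counts.pe_ratio


def minor_orientation_frequency(counts: OrientationCounts) -> float:
    """min(R, F)/(R+F) on paired-end counts; NaN when undefined, <= 0.5."""
    tot = counts.pe_f + counts.pe_r
    return min(counts.pe_f, counts.pe_r) / tot if tot else math.nan
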