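"""Inverted-repeat search and the augmented orientation reference.

Candidate invertons are pairs of inverted repeats: a left IR ``[a, b)``
whose sequence matches the reverse complement of a right IR ``[c, d)`` on
the same contig.  The search is seed-and-extend: exact ``min_ir_len``-mer
seeds between the forward strand and the reverse complement are extended
outward and inward, ungapped, to the maximum-scoring endpoints under
+match/-mismatch scoring.  Default scoring mirrors the conventions of
classical IR finders (match +3, mismatch -4, score threshold 50, maximum
extent 750 nt); all knobs live in :class:`IRSearchParams`.

The augmented reference emitted by :func:`build_orientation_index` contains,
for every candidate, a forward-orientation record and a reverse-orientation
record (the invertible region reverse-complemented in place), each with a
flanking buffer, plus *intervening* records tiling all genome between
candidates.  Aligning reads against this index makes multi-mapping between
near-identical strains visible to MAPQ filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import InvertonLocus, revcomp

__all__ = [
    "IRSearchParams",
    "find_inverted_repeats",
    "locate_candidates",
    "ir_pair_score",
    "RefRecord",
    "AugmentedReference",
    "build_orientation_index",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_candidates_bed",
]

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class IRSearchParams:
    """Scoring and geometry bounds for the IR search.

    ``gap_penalty`` is kept for interface parity with gapped IR finders but
    the built-in extension is ungapped and does not consume it.
    """

    match_score: int = 3
    mismatch_penalty: int = -4
    gap_penalty: int = -12
    min_score: int = 50
    min_ir_len: int = 10
    max_ir_len: int = 100
    max_span: int = 750
    min_loop: int = 0
    flank_len: int = 500

    def validate(self) -> None:
        if self.min_ir_len < 1:
            raise ValueError("min_ir_len must be >= 1")
        if self.min_ir_len > self.max_ir_len:
            raise ValueError("min_ir_len must be <= max_ir_len")
        if self.max_span <= 2 * self.min_ir_len:
            raise ValueError("max_span must exceed twice min_ir_len")
        if self.match_score <= 0 or self.mismatch_penalty >= 0:
            raise ValueError("match_score must be > 0 and mismatch_penalty < 0")
        if self.min_loop < 0 or self.flank_len < 0:
            raise ValueError("min_loop and flank_len must be >= 0")


def ir_pair_score(seq: str, locus: InvertonLocus, params: IRSearchParams) -> int:
    """Ungapped score of the left IR against the reverse complement of the
    right IR (positions with N never match)."""
    left = seq[locus.left_ir_start : locus.left_ir_end]
    right_rc = revcomp(seq[locus.right_ir_start : locus.right_ir_end])
    if len(left) != len(right_rc):
        raise ValueError("IR lengths differ")
    score = 0
    for x, y in zip(left, right_rc):
        if x == y and x in _COMP:
            score += params.match_score
        else:
            score += params.mismatch_penalty
    return score


def _extend(
    seq: str,
    a: int,
    b: int,
    c: int,
    d: int,
    params: IRSearchParams,
) -> tuple[int, int, int, int, int]:
    """Extend a seeded IR pair to maximum-scoring endpoints.

    The pair aligns position ``a+t`` against the complement of ``d-1-t``.
    Outward extension grows ``a`` down / ``d`` up; inward extension grows
    ``b`` up / ``c`` down, subject to loop >= min_loop and IR length <=
    max_ir_len.  Each direction independently takes the longest prefix of
    steps achieving the maximal cumulative score, so the result is not
    extendable without score loss.
    """
    n = len(seq)
    match, mismatch = params.match_score, params.mismatch_penalty

    def step_score(i: int, j: int) -> int:
        x, y = seq[i], seq[j]
        return match if (x in _COMP and _COMP[x] == y) else mismatch

    # outward: pairs (a-1, d), (a-2, d+1), ...
    best_gain, gain, take = 0, 0, 0
    k = 0
    while True:
        i, j = a - 1 - k, d + k
        L = (b - a) + k + 1
        if i < 0 or j >= n or L > params.max_ir_len or (j + 1) - i > params.max_span:
            break
        gain += step_score(i, j)
        if gain >= best_gain:
            best_gain, take = gain, k + 1
        k += 1
    a, d = a - take, d + take
    score_out = best_gain

    # inward: pairs (b, c-1), (b+1, c-2), ...
    best_gain, gain, take = 0, 0, 0
    k = 0
    while True:
        i, j = b + k, c - 1 - k
        L = (b - a) + k + 1
        # loop remaining after taking pair (i, j) is j - (i + 1)
        if j - i - 1 < params.min_loop or L > params.max_ir_len:
            break
        gain += step_score(i, j)
        if gain >= best_gain:
            best_gain, take = gain, k + 1
        k += 1
    b, c = b + take, c - take
    return a, b, c, d, score_out + best_gain


def find_inverted_repeats(
    seq: str,
    params: IRSearchParams | None = None,
    contig_key: str = "contig",
) -> list[InvertonLocus]:
    """Locate candidate invertons (IR pairs) on one contig.

    Seeds are exact ``min_ir_len``-mer matches between the sequence and its
    reverse complement; every exact IR pair of length >= ``min_ir_len``
    therefore contains at least one seed and cannot be missed.  Reported
    pairs satisfy the score, length, span and loop bounds and are sorted by
    ``(left_ir_start, right_ir_end)``; output is deterministic.
    """
    params = params or IRSearchParams()
    params.validate()
    seq = seq.upper()
    n = len(seq)
    k = params.min_ir_len
    if n < 2 * k + params.min_loop:
        return []

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)

    found: dict[tuple[int, int, int, int], int] = {}
    for j in range(n - k + 1):
        w = seq[j : j + k]
        if "N" in w:
            continue
        w_rc = revcomp(w)
        for i in index.get(w_rc, ()):
            # left IR seed [i, i+k), right IR seed [j, j+k)
            if j - (i + k) < params.min_loop:
                continue
            if (j + k) - i > params.max_span:
                continue
            a, b, c, d, score = _extend(
                seq, i, i + k, j, j + k, params
            )
            score += k * params.match_score  # seed itself is all matches
            if score < params.min_score:
                continue
            L = b - a
            if not (params.min_ir_len <= L <= params.max_ir_len):
                continue
            if d - a > params.max_span:
                continue
            key = (a, b, c, d)
            if key not in found or score > found[key]:
                found[key] = score

    # drop candidates strictly contained in a same-score-or-better candidate
    # that extends them on the same alignment diagonal (seed fragments of a
    # longer maximal pair)
    keys = sorted(found)
    kept = []
    for key in keys:
        a, b, c, d = key
        contained = any(
            k2 != key
            and a + d == k2[0] + k2[3]  # same alignment anti-diagonal
            and k2[0] <= a
            and b <= k2[1]
            and k2[2] <= c
            and d <= k2[3]
            for k2 in keys
        )
        if not contained:
            kept.append(key)

    loci = [
        InvertonLocus(contig_key, a, b, c, d) for (a, b, c, d) in kept
    ]
    loci.sort(key=lambda l: (l.left_ir_start, l.right_ir_end, l.left_ir_end))
    return loci


def locate_candidates(
    genome_db: Mapping[str, str], params: IRSearchParams | None = None
) -> list[InvertonLocus]:
    """Run the IR search on every contig of a genome database."""
    params = params or IRSearchParams()
    out: list[InvertonLocus] = []
    for contig_key in sorted(genome_db):
        out.extend(find_inverted_repeats(genome_db[contig_key], params, contig_key))
    return out


# ---------------------------------------------------------------------------
# Augmented orientation reference
# ---------------------------------------------------------------------------

ROLE_FORWARD = "F"
ROLE_REVERSE = "R"
ROLE_INTERVENING = "IV"


@dataclass(frozen=True)
class RefRecord:
    """One record of the augmented reference with its genome back-map.

    ``start``/``end`` are contig coordinates of the whole record (flank
    included for orientation records); ``core_start``/``core_end`` are the
    candidate's outer IR bounds for orientation records.
    """

    name: str
    seq: str
    role: str
    contig_key: str
    start: int
    end: int
    locus: InvertonLocus | None = None

    @property
    def inner_junctions(self) -> tuple[int, int] | None:
        """Record-local coordinates of the IR/invertible-region junctions."""
        if self.locus is None:
            return None
        return (
            self.locus.left_ir_end - self.start,
            self.locus.right_ir_start - self.start,
        )

    @property
    def invertible_local(self) -> tuple[int, int] | None:
        return self.inner_junctions


class AugmentedReference:
    """Forward/reverse orientation records plus intervening genome records.

    Concatenating intervening and forward records (flanks removed) tiles
    every contig exactly; :meth:`reconstruct` asserts this property.
    """

    def __init__(self, records: Sequence[RefRecord]):
        self.records = tuple(records)
        self._by_name = {r.name: r for r in self.records}
        if len(self._by_name) != len(self.records):
            raise ValueError("duplicate record names in augmented reference")

    def __getitem__(self, name: str) -> RefRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def inverton_ids(self) -> list[str]:
        return sorted(
            {r.locus.inverton_id for r in self.records if r.locus is not None}
        )

    def orientation_records(self) -> list[RefRecord]:
        return [r for r in self.records if r.role in (ROLE_FORWARD, ROLE_REVERSE)]

    def reconstruct(self, contig_key: str) -> str:
        """Rebuild a contig from intervening records plus forward records
        with flanks stripped."""
        pieces = []
        for r in self.records:
            if r.contig_key != contig_key:
                continue
            if r.role == ROLE_INTERVENING:
                pieces.append((r.start, r.seq))
            elif r.role == ROLE_FORWARD:
                assert r.locus is not None
                lo = r.locus.left_ir_start - r.start
                hi = r.locus.right_ir_end - r.start
                pieces.append((r.locus.left_ir_start, r.seq[lo:hi]))
        pieces.sort()
        return "".join(s for _, s in pieces)

    def write_fasta(self, path: str | Path) -> None:
        """Write the index as FASTA; back-map metadata is encoded in the
        record description so the index round-trips through disk."""
        with open(path, "w") as fh:
            for r in self.records:
                locus_txt = r.locus.inverton_id if r.locus else "."
                fh.write(
                    f">{r.name} role={r.role} contig={r.contig_key} "
                    f"start={r.start} end={r.end} locus={locus_txt}\n"
                )
                for i in range(0, len(r.seq), 80):
                    fh.write(r.seq[i : i + 80] + "\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "AugmentedReference":
        from Bio import SeqIO
        from .core import parse_inverton_id

        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            meta = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            locus = None
            if meta.get("locus", ".") != ".":
                locus = parse_inverton_id(meta["locus"])
            records.append(
                RefRecord(
                    name=rec.id,
                    seq=str(rec.seq).upper(),
                    role=meta["role"],
                    contig_key=meta["contig"],
                    start=int(meta["start"]),
                    end=int(meta["end"]),
                    locus=locus,
                )
            )
        return cls(records)


def _resolve_overlaps(
    seq: str, loci: list[InvertonLocus], params: IRSearchParams
) -> list[InvertonLocus]:
    """Keep at most one candidate per overlapping set: higher score wins,
    ties broken leftmost then shortest."""
    scored = sorted(
        loci,
        key=lambda l: (
            -ir_pair_score(seq, l, params),
            l.left_ir_start,
            l.right_ir_end - l.left_ir_start,
        ),
    )
    kept: list[InvertonLocus] = []
    for cand in scored:
        s, e = cand.span
        clash = any(not (e <= k.span[0] or k.span[1] <= s) for k in kept)
        if clash:
            logger.info("dropping overlapping candidate %s", cand.inverton_id)
            continue
        kept.append(cand)
    kept.sort()
    return kept


def build_orientation_index(
    genome_db: Mapping[str, str],
    candidates: Sequence[InvertonLocus],
    params: IRSearchParams | None = None,
) -> AugmentedReference:
    """Build the augmented orientation reference for a candidate set.

    Per candidate: a forward record over ``[a - flank, d + flank)`` clipped
    at contig edges, and a reverse record identical except the invertible
    region ``[b, c)`` reverse-complemented in place.  Intervening records
    cover all genome outside candidate cores ``[a, d)``.
    """
    params = params or IRSearchParams()
    by_contig: dict[str, list[InvertonLocus]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_key, []).append(c)

    records: list[RefRecord] = []
    for contig_key in sorted(set(genome_db) | set(by_contig)):
        if contig_key not in genome_db:
            raise KeyError(f"candidate contig {contig_key!r} not in genome db")
        seq = genome_db[contig_key]
        n = len(seq)
        loci = _resolve_overlaps(seq, by_contig.get(contig_key, []), params)
        for locus in loci:
            a, d = locus.span
            if d > n:
                raise ValueError(
                    f"candidate {locus.inverton_id} exceeds contig length {n}"
                )
            lo = max(0, a - params.flank_len)
            hi = min(n, d + params.flank_len)
            fwd = seq[lo:hi]
            b_loc, c_loc = locus.left_ir_end - lo, locus.right_ir_start - lo
            rev = fwd[:b_loc] + revcomp(fwd[b_loc:c_loc]) + fwd[c_loc:]
            iid = locus.inverton_id
            records.append(
                RefRecord(f"{iid}|F", fwd, ROLE_FORWARD, contig_key, lo, hi, locus)
            )
            records.append(
                RefRecord(f"{iid}|R", rev, ROLE_REVERSE, contig_key, lo, hi, locus)
            )
        # intervening records tile the complement of candidate cores
        pos = 0
        for locus in loci:
            a, d = locus.span
            if a > pos:
                records.append(
                    RefRecord(
                        f"{contig_key}|IV|{pos}-{a}",
                        seq[pos:a],
                        ROLE_INTERVENING,
                        contig_key,
                        pos,
                        a,
                    )
                )
            pos = d
        if pos < n:
            records.append(
                RefRecord(
                    f"{contig_key}|IV|{pos}-{n}",
                    seq[pos:n],
                    ROLE_INTERVENING,
                    contig_key,
                    pos,
                    n,
                )
            )
    return AugmentedReference(records)


# ---------------------------------------------------------------------------
# Candidate table IO
# ---------------------------------------------------------------------------


def write_candidates_tsv(loci: Sequence[InvertonLocus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "inverton_id": l.inverton_id,
                "contig_key": l.contig_key,
                "left_ir_start": l.left_ir_start,
                "left_ir_end": l.left_ir_end,
                "right_ir_start": l.right_ir_start,
                "right_ir_end": l.right_ir_end,
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path, one_based: bool = False) -> list[InvertonLocus]:
    """Read a 4-coordinate candidate table.  ``one_based=True`` converts
    from 1-based inclusive coordinates (the convention of external IR
    finders) to the internal 0-based half-open convention."""
    df = pd.read_csv(path, sep="\t")
    off = 1 if one_based else 0
    return [
        InvertonLocus(
            contig_key=row["contig_key"],
            left_ir_start=int(row["left_ir_start"]) - off,
            left_ir_end=int(row["left_ir_end"]),
            right_ir_start=int(row["right_ir_start"]) - off,
            right_ir_end=int(row["right_ir_end"]),
        )
        for _, row in df.iterrows()
    ]


def write_candidates_bed(loci: Sequence[InvertonLocus], path: str | Path) -> None:
    """BED6 over the outer IR span; score column is the IR length."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.contig_key}\t{l.left_ir_start}\t{l.right_ir_end}\t"
                f"{l.inverton_id}\t{l.ir_length}\t+\n"
            )
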