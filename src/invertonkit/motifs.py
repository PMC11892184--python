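"""PWM scanning with exact p-values and the promoter-orientation test.

A motif is a position weight matrix (PWM).  Scanning scores every window of
every contig on both strands with the log-odds score against a background
base composition; the p-value of a score is the exact probability, under
the background model, that a random word scores at least as high.  That
tail probability is computed by dynamic programming over a discretized
score distribution (the classic exact-p approach of FIMO-style scanners),
with the discretization step set to 1/1000 of the total score range.

Each reported instance is then related to its nearest gene.  An instance is
*promoter-consistent* when it lies upstream of and on the same strand as
its nearest gene.  Whether a motif shows more promoter-consistent instances
than chance is judged against three permutation nulls (n = 10,000 each by
default): shuffling instance loci along their contig, flipping instance
strands with fair coins, and flipping gene strands with fair coins.  A
motif is called a putative promoter only when the observed count exceeds
the 99.9th percentile of all three nulls.  Because either the motif or its
reverse complement may be the promoter element, both orientations are
tested and the one aligned with the nearest genes is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GeneRecord, InvertonLocus, revcomp

__all__ = [
    "PWM",
    "read_meme_motifs",
    "MotifInstance",
    "scan_genome",
    "NearestGeneRelation",
    "nearest_gene",
    "annotate_nearest_genes",
    "promoter_consistency_count",
    "permutation_null",
    "PromoterCall",
    "call_putative_promoter",
    "promoter_orientation_test",
    "assign_instances_to_invertons",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with background frequencies.

    ``matrix`` is L x 4 (columns A, C, G, T), each row a probability
    distribution; a pseudocount applied at construction keeps all entries
    positive so log-odds are finite.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if (m <= 0).any():
            raise ValueError("PWM entries must be > 0 (apply a pseudocount)")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must be a positive length-4 distribution")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background.copy(),
        )

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(
            motif_id,
            c / c.sum(axis=1, keepdims=True),
            UNIFORM_BG.copy() if background is None else background,
        )

    @classmethod
    def from_sites(
        cls,
        motif_id: str,
        sites: Sequence[str],
        background: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "PWM":
        """Build a PWM from equal-length aligned site sequences."""
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("sites must be equal length")
        counts = np.zeros((L, 4))
        for s in sites:
            for i, ch in enumerate(s.upper()):
                if ch in _BASE_INDEX:
                    counts[i, _BASE_INDEX[ch]] += 1
        return cls.from_counts(motif_id, counts, background, pseudocount)


def read_meme_motifs(path: str | Path, pseudocount: float = 1e-4) -> list[PWM]:
    """Read PWMs from a MEME minimal-format motif file."""
    motifs: list[PWM] = []
    bg = UNIFORM_BG.copy()
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            bg = np.array([float(vals[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                j += 1
            rows = []
            j += 1
            while j < len(lines) and lines[j].strip() and not lines[j].startswith("MOTIF"):
                parts = lines[j].split()
                if len(parts) >= 4:
                    rows.append([float(x) for x in parts[:4]])
                    j += 1
                else:
                    break
            m = np.asarray(rows)
            m = (m + pseudocount) / (m + pseudocount).sum(axis=1, keepdims=True)
            motifs.append(PWM(motif_id, m, bg.copy()))
            i = j
            continue
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# Exact p-values and scanning
# ---------------------------------------------------------------------------


def _discretized_scores(pwm: PWM, bins: int = 1000) -> tuple[np.ndarray, float]:
    """Integerize per-position log-odds at a step of (range / bins)."""
    lo = pwm.log_odds
    rng = float(lo.max(axis=1).sum() - lo.min(axis=1).sum())
    step = rng / bins if rng > 0 else 1.0
    return np.round(lo / step).astype(int), step


def score_distribution(pwm: PWM, bins: int = 1000) -> tuple[np.ndarray, int, float]:
    """Exact pmf of the discretized score of a background-random word.

    Returns ``(pmf, offset, step)`` where ``pmf[k]`` is the probability of
    integer score ``k + offset``.
    """
    q, step = _discretized_scores(pwm, bins)
    lo_min = int(q.min(axis=1).sum())
    lo_max = int(q.max(axis=1).sum())
    pmf = np.zeros(lo_max - lo_min + 1)
    offset = lo_min
    pmf[0] = 1.0
    cur_min = 0
    for i in range(len(pwm)):
        row_min, row_max = int(q[i].min()), int(q[i].max())
        new = np.zeros(len(pmf))
        for b in range(4):
            shift = int(q[i, b]) - row_min
            new[shift : shift + len(pmf) - (row_max - row_min)] += (
                pwm.background[b] * pmf[: len(pmf) - (row_max - row_min)]
            )
        pmf = new
        cur_min += row_min
    # cur_min equals lo_min by construction
    return pmf, offset, step


def _tail_pvalues(pmf: np.ndarray) -> np.ndarray:
    """P(score >= k) for every integer score bin."""
    return np.cumsum(pmf[::-1])[::-1]


@dataclass(frozen=True)
class NearestGeneRelation:
    gene_id: str
    distance: int
    placement: str  # upstream | downstream | overlapping
    same_strand: bool


@dataclass(frozen=True)
class MotifInstance:
    """A PWM hit with location, strand, exact p-value, and (once annotated)
    its relation to the nearest gene and owning inverton."""

    contig_key: str
    start: int
    end: int
    strand: str
    motif_id: str
    p_value: float
    score: float = 0.0
    nearest: NearestGeneRelation | None = None
    inverton_id: str | None = None

    @property
    def is_promoter_consistent(self) -> bool:
        return (
            self.nearest is not None
            and self.nearest.placement == "upstream"
            and self.nearest.same_strand
        )


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def scan_genome(
    pwm: PWM,
    genome_db: Mapping[str, str],
    p_cutoff: float = 1e-8,
    bins: int = 1000,
) -> list[MotifInstance]:
    """Scan both strands of every contig, reporting hits with exact
    p <= cutoff.  Windows containing N never match.  Contigs shorter than
    the motif are skipped.  Deterministic."""
    L = len(pwm)
    q, step = _discretized_scores(pwm, bins)
    pmf, offset, _ = score_distribution(pwm, bins)
    tails = _tail_pvalues(pmf)

    def pvalue_of(int_score: int) -> float:
        idx = int_score - offset
        if idx < 0:
            return 1.0
        if idx >= len(tails):
            return float(tails[-1])
        return float(tails[idx])

    # minimal integer score achieving the cutoff
    qual = np.nonzero(tails <= p_cutoff)[0]
    if len(qual) == 0:
        return []
    min_int = int(qual[0]) + offset

    qr = q[::-1, ::-1]  # reverse-complement motif scores
    out: list[MotifInstance] = []
    for contig_key in sorted(genome_db):
        seq = genome_db[contig_key]
        if len(seq) < L:
            continue
        codes = _encode(seq)
        n_win = len(seq) - L + 1
        for strand, qmat in (("+", q), ("-", qr)):
            scores = np.zeros(n_win, dtype=np.int64)
            valid = np.ones(n_win, dtype=bool)
            qn = np.column_stack([qmat, np.zeros(L, dtype=int)])  # N column
            for t in range(L):
                col = codes[t : t + n_win]
                scores += qn[t, col]
                valid &= col != 4
            hits = np.nonzero(valid & (scores >= min_int))[0]
            for i in hits:
                s = int(scores[i])
                out.append(
                    MotifInstance(
                        contig_key=contig_key,
                        start=int(i),
                        end=int(i) + L,
                        strand=strand,
                        motif_id=pwm.motif_id,
                        p_value=pvalue_of(s),
                        score=s * step,
                    )
                )
    out.sort(key=lambda m: (m.contig_key, m.start, m.strand))
    return out


# ---------------------------------------------------------------------------
# Nearest-gene relations
# ---------------------------------------------------------------------------


def nearest_gene(
    instance: MotifInstance, genes: Sequence[GeneRecord]
) -> NearestGeneRelation | None:
    """Nearest gene on the instance's contig by genomic gap distance
    (0 when overlapping); ties broken by smaller gene start.  Placement is
    relative to the gene's 5'->3' direction.  Returns None when the contig
    has no genes."""
    cands = [g for g in genes if g.contig_key == instance.contig_key]
    if not cands:
        return None

    def dist(g: GeneRecord) -> int:
        if min(instance.end, g.end) > max(instance.start, g.start):
            return 0
        if instance.end <= g.start:
            return g.start - instance.end
        return instance.start - g.end

    best = min(cands, key=lambda g: (dist(g), g.start))
    d = dist(best)
    if d == 0:
        placement = "overlapping"
    elif instance.end <= best.start:
        placement = "upstream" if best.strand == "+" else "downstream"
    else:
        placement = "downstream" if best.strand == "+" else "upstream"
    return NearestGeneRelation(
        gene_id=best.gene_id,
        distance=d,
        placement=placement,
        same_strand=instance.strand == best.strand,
    )


def annotate_nearest_genes(
    instances: Sequence[MotifInstance], genes: Sequence[GeneRecord]
) -> list[MotifInstance]:
    return [replace(m, nearest=nearest_gene(m, genes)) for m in instances]


def promoter_consistency_count(
    instances: Sequence[MotifInstance],
    genes: Sequence[GeneRecord] | None = None,
    mode: str = "upstream",
) -> int:
    """Count instances upstream of (or, in the terminator-like 'downstream'
    mode, downstream of) and on the same strand as their nearest gene."""
    if mode not in ("upstream", "downstream"):
        raise ValueError(f"unknown mode {mode!r}")
    if genes is not None:
        instances = annotate_nearest_genes(instances, genes)
    return sum(
        1
        for m in instances
        if m.nearest is not None
        and m.nearest.placement == mode
        and m.nearest.same_strand
    )


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

NULL_KINDS = ("shuffle_loci", "permute_motif_strand", "permute_gene_strand")


def _gene_arrays(genes: Sequence[GeneRecord]):
    """Per-contig sorted gene arrays for vectorized nearest-gene lookup.

    Assumes genes within a contig do not overlap one another (the scalar
    :func:`nearest_gene` has no such restriction)."""
    by_contig: dict[str, dict[str, np.ndarray]] = {}
    for contig in {g.contig_key for g in genes}:
        gs = sorted(
            (g for g in genes if g.contig_key == contig), key=lambda g: g.start
        )
        by_contig[contig] = {
            "start": np.array([g.start for g in gs]),
            "end": np.array([g.end for g in gs]),
            "plus": np.array([g.strand == "+" for g in gs]),
        }
    return by_contig


def _vector_relations(
    starts: np.ndarray,
    ends: np.ndarray,
    garr: Mapping[str, np.ndarray],
):
    """Vectorized nearest-gene relation for query intervals on one contig.

    Returns (gene_idx, upstream_if_plus, overlapping) arrays where
    ``upstream_if_plus`` says the instance sits before the gene start in
    contig coordinates."""
    gs, ge = garr["start"], garr["end"]
    r = np.searchsorted(gs, ends, side="left")
    n = len(gs)
    dist_r = np.where(r < n, gs[np.minimum(r, n - 1)] - ends, np.iinfo(np.int64).max)
    li = r - 1
    has_l = li >= 0
    le = np.where(has_l, ge[np.maximum(li, 0)], np.iinfo(np.int64).min)
    overlap_l = has_l & (le > starts)
    dist_l = np.where(has_l, starts - le, np.iinfo(np.int64).max)
    dist_l = np.where(overlap_l, 0, dist_l)
    # tie -> smaller gene start, i.e. the left gene
    choose_left = (dist_l <= dist_r) & has_l
    gene_idx = np.where(choose_left, np.maximum(li, 0), np.minimum(r, n - 1))
    before_gene = ~choose_left  # instance lies before the chosen (right) gene
    overlapping = choose_left & overlap_l
    return gene_idx, before_gene, overlapping


def permutation_null(
    instances: Sequence[MotifInstance],
    genes: Sequence[GeneRecord],
    genome_db: Mapping[str, str],
    kind: str,
    n_samples: int = 10000,
    seed: int | np.random.Generator = 0,
    mode: str = "upstream",
) -> np.ndarray:
    """Null distribution of the promoter-consistency count.

    * ``shuffle_loci`` — each instance placed uniformly on its own contig,
      length and strand preserved;
    * ``permute_motif_strand`` — each instance's strand flipped with
      probability 1/2;
    * ``permute_gene_strand`` — each gene's strand flipped with
      probability 1/2.

    Reproducible given the seed.
    """
    if kind not in NULL_KINDS:
        raise ValueError(f"unknown null kind {kind!r}; expected one of {NULL_KINDS}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("upstream", "downstream"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    instances = annotate_nearest_genes(instances, genes)
    n_inst = len(instances)
    if n_inst == 0:
        return np.zeros(n_samples, dtype=int)

    want_up = mode == "upstream"

    if kind == "permute_motif_strand":
        placed = np.array(
            [
                m.nearest is not None and m.nearest.placement == mode
                for m in instances
            ]
        )
        same = np.array(
            [m.nearest is not None and m.nearest.same_strand for m in instances]
        )
        flips = rng.random((n_samples, n_inst)) < 0.5
        consistent = placed[None, :] & (same[None, :] ^ flips)
        return consistent.sum(axis=1)

    if kind == "permute_gene_strand":
        gene_ids = [g.gene_id for g in genes]
        gidx = {g: i for i, g in enumerate(gene_ids)}
        c_keep = np.zeros(n_inst, dtype=bool)  # consistent if gene unflipped
        c_flip = np.zeros(n_inst, dtype=bool)  # consistent if gene flipped
        inst_gene = np.full(n_inst, -1)
        other = "downstream" if want_up else "upstream"
        for i, m in enumerate(instances):
            if m.nearest is None:
                continue
            inst_gene[i] = gidx[m.nearest.gene_id]
            c_keep[i] = m.nearest.placement == mode and m.nearest.same_strand
            c_flip[i] = m.nearest.placement == other and not m.nearest.same_strand
        flips = rng.random((n_samples, len(genes))) < 0.5
        has_gene = inst_gene >= 0
        gi = np.maximum(inst_gene, 0)
        inst_flipped = flips[:, gi]
        consistent = has_gene[None, :] & np.where(
            inst_flipped, c_flip[None, :], c_keep[None, :]
        )
        return consistent.sum(axis=1)

    # shuffle_loci
    garrs = _gene_arrays(genes)
    counts = np.zeros(n_samples, dtype=int)
    by_contig: dict[str, list[int]] = {}
    for i, m in enumerate(instances):
        by_contig.setdefault(m.contig_key, []).append(i)
    for contig, idxs in sorted(by_contig.items()):
        clen = len(genome_db[contig])
        lens = np.array([instances[i].end - instances[i].start for i in idxs])
        if (clen - lens < 0).any():
            raise ValueError(
                f"contig {contig!r} shorter than a motif instance; cannot shuffle"
            )
        inst_plus = np.array([instances[i].strand == "+" for i in idxs])
        garr = garrs.get(contig)
        if garr is None:
            continue  # no genes -> never consistent
        gplus = garr["plus"]
        for s in range(n_samples):
            starts = rng.integers(0, clen - lens + 1)
            ends = starts + lens
            gene_i, before, overl = _vector_relations(starts, ends, garr)
            g_is_plus = gplus[gene_i]
            upstream = ~overl & (before == g_is_plus)
            placement_ok = upstream if want_up else (~overl & ~upstream)
            same = inst_plus == g_is_plus
            counts[s] += int(np.sum(placement_ok & same))
    return counts


@dataclass(frozen=True)
class PromoterCall:
    called: bool
    observed: int
    exceedance: dict  # kind -> number of null samples strictly below observed
    n_samples: int
    orientation: str = "original"  # or "revcomp"
    mode: str = "upstream"


def call_putative_promoter(
    observed: int,
    nulls: Mapping[str, np.ndarray],
    exceed_quantile: float = 0.999,
) -> PromoterCall:
    """Putative-promoter decision: observed must strictly exceed at least
    ``exceed_quantile`` of the samples in *every* null (9990/10,000 at the
    defaults)."""
    lengths = {len(v) for v in nulls.values()}
    if len(lengths) != 1:
        raise ValueError("null vectors must have equal lengths")
    n = lengths.pop()
    need = math.ceil(exceed_quantile * n - 1e-9)
    exceed = {k: int(np.sum(np.asarray(v) < observed)) for k, v in nulls.items()}
    return PromoterCall(
        called=all(e >= need for e in exceed.values()),
        observed=observed,
        exceedance=exceed,
        n_samples=n,
    )


def _flip_strands(instances: Sequence[MotifInstance]) -> list[MotifInstance]:
    return [
        replace(m, strand="-" if m.strand == "+" else "+", nearest=None)
        for m in instances
    ]


def promoter_orientation_test(
    instances: Sequence[MotifInstance],
    genes: Sequence[GeneRecord],
    genome_db: Mapping[str, str],
    n_samples: int = 10000,
    seed: int = 0,
    exceed_quantile: float = 0.999,
    mode: str = "upstream",
) -> PromoterCall:
    """Run the full three-null promoter test on a motif's instances.

    Both the given orientation and the reverse complement (all instance
    strands flipped) are evaluated; the orientation with more consistent
    instances — i.e. the one aligned with the nearest genes — is reported.
    """
    variants = {
        "original": list(instances),
        "revcomp": _flip_strands(instances),
    }
    obs = {
        k: promoter_consistency_count(v, genes, mode=mode)
        for k, v in variants.items()
    }
    orientation = max(obs, key=lambda k: (obs[k], k == "original"))
    chosen = variants[orientation]
    nulls = {
        kind: permutation_null(
            chosen, genes, genome_db, kind, n_samples, seed=seed + i, mode=mode
        )
        for i, kind in enumerate(NULL_KINDS)
    }
    call = call_putative_promoter(obs[orientation], nulls, exceed_quantile)
    return replace(call, orientation=orientation, mode=mode)


def assign_instances_to_invertons(
    instances: Sequence[MotifInstance],
    loci: Sequence[InvertonLocus],
    interior_only: bool = False,
) -> list[MotifInstance]:
    """Attach the owning inverton id to instances inside an inverton span
    (or strictly inside the invertible region when ``interior_only``)."""
    out = []
    for m in instances:
        owner = None
        for l in loci:
            if l.contig_key != m.contig_key:
                continue
            lo, hi = (l.invertible_region if interior_only else l.span)
            if lo <= m.start and m.end <= hi:
                owner = l.inverton_id
                break
        out.append(replace(m, inverton_id=owner))
    return out
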