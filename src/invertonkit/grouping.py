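"""Group invertons by inverted-repeat homology.

The pipeline is distance matrix -> guide tree -> branch-length-threshold
clustering.  Pairwise distances are ``1 - fractional identity`` of a global
pairwise alignment, strand-aware for DNA (the better of sequence vs its
reverse complement).  The guide tree is neighbor joining with midpoint
rooting.  Clustering cuts the tree into the minimal number of clades whose
maximum (or average) within-clade leaf-to-leaf path length does not exceed
the threshold T.

The threshold is chosen by a scan over T = 0.01..0.99 in steps of 0.01,
maximizing the number of groups in which a motif can be discovered (ties
broken toward larger T, i.e. coarser grouping).  The built-in
discoverability callback asks whether some 6-12mer (or its reverse
complement) occurs in at least 80% of a group's members; an external motif
discovery tool can be substituted through the same callback signature.

The identical distance->tree->threshold pipeline, on protein identity
distances without strand awareness, groups invertase (site-specific
recombinase) genes at a default cutoff of T = 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align

from .core import revcomp

__all__ = [
    "ir_distance_matrix",
    "protein_distance_matrix",
    "build_guide_tree",
    "cluster_tree",
    "cluster_sequences",
    "IRGroup",
    "group_invertons",
    "ThresholdScanResult",
    "scan_thresholds",
    "default_motif_finder",
    "cluster_invertase_proteins",
    "THRESHOLD_GRID",
]

logger = logging.getLogger(__name__)

THRESHOLD_GRID = tuple(round(0.01 * i, 2) for i in range(1, 100))


def _aligner(protein: bool = False) -> Align.PairwiseAligner:
    # gaps are penalized heavily so the identity fraction of unrelated
    # sequences stays near the ungapped expectation; otherwise gap-padded
    # alignments inflate identity and compress the distance scale
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _identity_distance(aligner: Align.PairwiseAligner, s1: str, s2: str) -> float:
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 1.0 - counts.identities / total if total else 1.0


def ir_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric DNA distance matrix: 1 - fractional identity of the better
    of (s_i vs s_j) and (s_i vs revcomp(s_j)) global alignments."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    sequences = [s.upper() for s in sequences]
    aligner = _aligner()
    n = len(sequences)
    d = np.zeros((n, n))
    rcs = [revcomp(s) for s in sequences]
    for i in range(n):
        for j in range(i + 1, n):
            fwd = _identity_distance(aligner, sequences[i], sequences[j])
            rev = _identity_distance(aligner, sequences[i], rcs[j])
            d[i, j] = d[j, i] = min(fwd, rev)
    return d


def protein_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric protein distance matrix (identity-based, no strand)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    aligner = _aligner(protein=True)
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _identity_distance(aligner, sequences[i], sequences[j])
    return d


def build_guide_tree(distances: np.ndarray, ids: Sequence[str]):
    """Neighbor-joining guide tree with midpoint rooting (skbio TreeNode).

    On an exactly additive matrix, tree path lengths reproduce the input
    distances.  Negative NJ branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix, TreeNode
    from skbio.tree import nj

    distances = np.asarray(distances, dtype=float)
    if np.isnan(distances).any():
        raise ValueError("distance matrix contains NaN")
    n = len(ids)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        h = distances[0, 1] / 2.0
        return TreeNode.read([f"({ids[0]}:{h},{ids[1]}:{h});"])
    tree = nj(DistanceMatrix(distances, list(ids)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # zero-diameter trees have no midpoint
        pass
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


@dataclass
class _Component:
    """A still-connected cluster hanging below the current tree node."""

    leaves: list[str]
    depth: float  # max leaf distance to current node
    sum_depth: float  # sum of leaf distances to current node
    sum_pairs: float  # sum of pairwise leaf distances within

    @property
    def n(self) -> int:
        return len(self.leaves)


def cluster_tree(tree, threshold: float, mode: str = "max") -> list[set[str]]:
    """Cut a rooted tree into the minimal number of clades whose within-clade
    leaf-to-leaf path length statistic (max or average) is <= threshold.

    Greedy bottom-up: at each node, child components are merged; while the
    constraint is violated the deepest component is cut off and emitted as
    a finished cluster.  Deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if mode not in ("max", "avg"):
        raise ValueError(f"unknown mode {mode!r}")

    clusters: list[set[str]] = []
    comp_at: dict[int, _Component] = {}

    def merged_stat(comps: list[_Component]) -> float:
        if mode == "max":
            depths = sorted((c.depth for c in comps), reverse=True)
            return depths[0] + depths[1] if len(depths) > 1 else 0.0
        # average over all cross+within pairs
        n = sum(c.n for c in comps)
        if n < 2:
            return 0.0
        total = sum(c.sum_pairs for c in comps)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                total += comps[i].n * comps[j].sum_depth + comps[j].n * comps[i].sum_depth
        return total / (n * (n - 1) / 2)

    for node in tree.postorder(include_self=True):
        if node.is_tip():
            comp_at[id(node)] = _Component([node.name], 0.0, 0.0, 0.0)
            continue
        comps = []
        for child in node.children:
            c = comp_at.pop(id(child))
            edge = child.length or 0.0
            comps.append(
                _Component(
                    c.leaves,
                    c.depth + edge,
                    c.sum_depth + c.n * edge,
                    c.sum_pairs,
                )
            )
        comps.sort(key=lambda c: (-c.depth, sorted(c.leaves)[0]))
        while len(comps) > 1 and merged_stat(comps) > threshold:
            cut = comps.pop(0)  # deepest
            clusters.append(set(cut.leaves))
        # merge the remainder into one component
        leaves = [l for c in comps for l in c.leaves]
        depth = max(c.depth for c in comps)
        sum_depth = sum(c.sum_depth for c in comps)
        sum_pairs = sum(c.sum_pairs for c in comps)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                sum_pairs += (
                    comps[i].n * comps[j].sum_depth + comps[j].n * comps[i].sum_depth
                )
        comp_at[id(node)] = _Component(leaves, depth, sum_depth, sum_pairs)

    root_comp = comp_at[id(tree)]
    clusters.append(set(root_comp.leaves))
    return clusters


def cluster_sequences(
    sequences: Sequence[str],
    ids: Sequence[str],
    threshold: float,
    protein: bool = False,
    mode: str = "max",
) -> dict[str, int]:
    """Distance -> tree -> threshold pipeline; returns id -> group number.

    Group numbers are assigned 1..k in order of each group's smallest input
    index, so permuting input order relabels but never re-partitions.
    """
    if len(sequences) != len(set(ids)):
        raise ValueError("ids must be unique and match sequences")
    if len(sequences) == 1:
        return {ids[0]: 1}
    dm = (
        protein_distance_matrix(sequences)
        if protein
        else ir_distance_matrix(sequences)
    )
    tree = build_guide_tree(dm, ids)
    parts = cluster_tree(tree, threshold, mode=mode)
    order = {x: i for i, x in enumerate(ids)}
    parts.sort(key=lambda grp: min(order[x] for x in grp))
    return {leaf: gi + 1 for gi, grp in enumerate(parts) for leaf in grp}


@dataclass(frozen=True)
class IRGroup:
    """An inverton group: members sharing homologous IR sequences."""

    group_id: int
    members: tuple[str, ...]
    dominant_phylum: str = ""
    dominant_count: int = 0
    motif: str | None = None


def group_invertons(
    ir_sequences: Mapping[str, str],
    threshold: float = 0.60,
    phylum_of: Mapping[str, str] | None = None,
    mode: str = "max",
) -> list[IRGroup]:
    """Group invertons by IR homology at a tree-distance threshold
    (default 0.60).  ``phylum_of`` optionally maps inverton id -> phylum to
    annotate each group's dominant phylum."""
    ids = list(ir_sequences)
    assignment = cluster_sequences([ir_sequences[i] for i in ids], ids, threshold, mode=mode)
    groups: dict[int, list[str]] = {}
    for iid, g in assignment.items():
        groups.setdefault(g, []).append(iid)
    out = []
    for g in sorted(groups):
        members = tuple(sorted(groups[g]))
        phylum, count = "", 0
        if phylum_of:
            tally: dict[str, int] = {}
            for m in members:
                p = phylum_of.get(m, "")
                tally[p] = tally.get(p, 0) + 1
            phylum, count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(IRGroup(g, members, phylum, count))
    return out


# ---------------------------------------------------------------------------
# Threshold scan
# ---------------------------------------------------------------------------


def default_motif_finder(
    sequences: Sequence[str],
    min_k: int = 6,
    max_k: int = 12,
    min_fraction: float = 0.8,
) -> bool:
    """Shared-kmer motif discoverability: True iff some k-mer (6-12 nt, or
    its reverse complement) occurs in >= 80% of the group's sequences.  A
    lightweight stand-in for zero-or-one-occurrence motif discovery; any
    callable with the same signature can replace it."""
    if len(sequences) < 2:
        return False
    seqs = [s.upper() for s in sequences]
    need = max(2, int(np.ceil(min_fraction * len(seqs))))
    for k in range(max_k, min_k - 1, -1):
        counts: dict[str, int] = {}
        for s in seqs:
            kmers = {s[i : i + k] for i in range(len(s) - k + 1)}
            canon = {min(w, revcomp(w)) for w in kmers if "N" not in w}
            for w in canon:
                counts[w] = counts.get(w, 0) + 1
        if counts and max(counts.values()) >= need:
            return True
    return False


@dataclass(frozen=True)
class ThresholdScanResult:
    """Per-threshold group counts plus the chosen threshold."""

    thresholds: tuple[float, ...]
    group_counts: tuple[int, ...]
    motif_counts: tuple[int, ...]
    chosen: float

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "T": self.thresholds,
                "n_groups": self.group_counts,
                "n_groups_with_motif": self.motif_counts,
            }
        )


def scan_thresholds(
    ir_sequences: Mapping[str, str],
    motif_finder: Callable[[Sequence[str]], bool] = default_motif_finder,
    grid: Sequence[float] = THRESHOLD_GRID,
    mode: str = "max",
) -> ThresholdScanResult:
    """Scan clustering thresholds, choosing the one that maximizes the
    number of multi-member groups in which a motif is discoverable (ties
    broken toward larger T).  A callback failure marks that group
    motif-negative and is logged."""
    ids = list(ir_sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences to scan thresholds")
    dm = ir_distance_matrix([ir_sequences[i] for i in ids])
    tree = build_guide_tree(dm, ids)
    group_counts, motif_counts = [], []
    for t in grid:
        parts = cluster_tree(tree, t, mode=mode)
        group_counts.append(len(parts))
        found = 0
        for grp in parts:
            if len(grp) < 2:
                continue
            try:
                if motif_finder([ir_sequences[i] for i in sorted(grp)]):
                    found += 1
            except Exception:  # callback failure counts as motif-negative
                logger.warning("motif callback failed on a group at T=%.2f", t)
        motif_counts.append(found)
    best = max(range(len(grid)), key=lambda i: (motif_counts[i], grid[i]))
    return ThresholdScanResult(
        tuple(grid), tuple(group_counts), tuple(motif_counts), grid[best]
    )


def cluster_invertase_proteins(
    protein_sequences: Mapping[str, str], threshold: float = 0.8
) -> dict[str, int]:
    """Group invertase proteins (identity distance -> NJ -> max-clade) at a
    default tree-distance cutoff of 0.8.  Empty input yields an empty
    grouping."""
    ids = list(protein_sequences)
    if not ids:
        return {}
    return cluster_sequences(
        [protein_sequences[i] for i in ids], ids, threshold, protein=True
    )
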