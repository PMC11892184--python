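"""Gene-neighborhood classification and enrichment around invertons.

Genes near an inverton (within a ±5 kb window of its outer IR bounds) fall
into exactly one of three proximity types:

* ``intersecting`` — the gene overlaps the inverton span itself;
* ``regulatable`` — the gene's 5' end faces the inverton and every gene
  between it and the inverton also faces it (an unbroken read-through
  chain), so a promoter embedded in the inverton could drive the gene
  after flipping;
* ``non_regulatable`` — within the window but failing the chain rule.

Enrichment of gene families (unique annotation strings) near invertons is
tested with one 2x2 Fisher exact table per (annotation, inverton group,
proximity type): gene in family vs not, against proximal in that stratum vs
not, over the universe of all annotated genes, with Bonferroni correction
over every table evaluated in the run.  The same machinery links inverton
groups to invertase groups, counting an inverton as linked when an
invertase of the group intersects it or lies within the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import GeneRecord, InvertonLocus

__all__ = [
    "PROXIMITY_TYPES",
    "GeneProximityRecord",
    "classify_gene_proximity",
    "classify_all_proximities",
    "fisher_exact_2x2",
    "odds_ratio",
    "enrich_gene_families",
    "extract_invertase_genes",
    "link_invertase_groups",
    "INVERTASE_KEYWORDS",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 5000
PROXIMITY_TYPES = ("intersecting", "regulatable", "non_regulatable")
INVERTASE_KEYWORDS = ("invertase", "integrase", "recombinase")


@dataclass(frozen=True)
class GeneProximityRecord:
    gene_id: str
    inverton_id: str
    proximity_type: str
    distance: int


def classify_gene_proximity(
    locus: InvertonLocus,
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> list[GeneProximityRecord]:
    """Classify every gene within ±window of an inverton.

    The window is measured from the outer IR bounds.  The read-through
    chain for the regulatable class is evaluated outward from the inverton
    on each side: the chain breaks at the first gene whose 5' end does not
    face the inverton, and every further gene on that side is
    non-regulatable regardless of its own orientation.
    """
    a, d = locus.span
    iid = locus.inverton_id
    contig_genes = sorted(
        (g for g in genes if g.contig_key == locus.contig_key),
        key=lambda g: (g.start, g.end),
    )
    out: list[GeneProximityRecord] = []

    right, left = [], []
    for g in contig_genes:
        if min(g.end, d) > max(g.start, a):
            out.append(GeneProximityRecord(g.gene_id, iid, "intersecting", 0))
        elif g.start >= d:
            right.append(g)
        else:
            left.append(g)

    # right side: 5' end faces the inverton iff the gene is on '+'
    chain_ok = True
    for g in right:  # ascending start = outward
        dist = g.start - d
        faces = g.strand == "+"
        if g.start < d + window:
            ptype = "regulatable" if (faces and chain_ok) else "non_regulatable"
            out.append(GeneProximityRecord(g.gene_id, iid, ptype, dist))
        chain_ok = chain_ok and faces

    # left side: 5' end faces the inverton iff the gene is on '-'
    chain_ok = True
    for g in reversed(left):  # descending end = outward
        dist = a - g.end
        faces = g.strand == "-"
        if g.end > a - window:
            ptype = "regulatable" if (faces and chain_ok) else "non_regulatable"
            out.append(GeneProximityRecord(g.gene_id, iid, ptype, dist))
        chain_ok = chain_ok and faces

    return out


def classify_all_proximities(
    loci: Sequence[InvertonLocus],
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> list[GeneProximityRecord]:
    out: list[GeneProximityRecord] = []
    for locus in loci:
        out.extend(classify_gene_proximity(locus, genes, window))
    return out


# ---------------------------------------------------------------------------
# Fisher exact and enrichment
# ---------------------------------------------------------------------------


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a·d)/(b·c); inf when only b·c is zero, 0 when only
    a·d is zero, NaN when both diagonals vanish."""
    num, den = a * d, b * c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` where p sums hypergeometric probabilities of
    all margin-fixed tables no more probable than the observed one.  The
    all-zero table has p = 1 and an undefined (NaN) odds ratio.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        return math.nan, 1.0
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio(a, b, c, d), float(p)


def _finish_enrichment(rows: list[dict], alpha: float = 0.05) -> pd.DataFrame:
    """Attach Bonferroni-adjusted p-values over all evaluated tables."""
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    m = len(df)
    df["p_adjusted"] = np.minimum(1.0, df["p_value"] * m)
    df["significant"] = df["p_adjusted"] < alpha
    df["n_tests"] = m
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def enrich_gene_families(
    proximity_records: Sequence[GeneProximityRecord],
    all_genes: Sequence[GeneRecord],
    inverton_groups: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-family enrichment per (annotation, inverton group, proximity
    type).

    The proximal set for a stratum is the deduplicated set of genes with at
    least one record of that type for an inverton of that group (a gene
    near several group members counts once).  The universe is all genes;
    annotations are evaluated in a stratum when they have at least one
    proximal member, and Bonferroni correction spans every table evaluated
    in the call.
    """
    gene_ann = {g.gene_id: g.annotation for g in all_genes}
    family_sizes: dict[str, int] = {}
    for g in all_genes:
        family_sizes[g.annotation] = family_sizes.get(g.annotation, 0) + 1
    n_genes = len(all_genes)

    proximal: dict[tuple[int, str], set[str]] = {}
    for rec in proximity_records:
        grp = inverton_groups.get(rec.inverton_id)
        if grp is None:
            continue
        proximal.setdefault((grp, rec.proximity_type), set()).add(rec.gene_id)

    rows = []
    for (grp, ptype), gene_set in sorted(proximal.items()):
        ann_counts: dict[str, int] = {}
        for gid in gene_set:
            ann = gene_ann.get(gid)
            if ann is None:
                continue
            ann_counts[ann] = ann_counts.get(ann, 0) + 1
        n_prox = len(gene_set)
        for ann, a in sorted(ann_counts.items()):
            b = family_sizes[ann] - a
            c = n_prox - a
            d = n_genes - family_sizes[ann] - c
            orat, p = fisher_exact_2x2(a, b, c, d)
            rows.append(
                {
                    "annotation": ann,
                    "inverton_group": grp,
                    "proximity_type": ptype,
                    "near_count": a,
                    "not_near_count": b,
                    "near_other_count": c,
                    "not_near_other_count": d,
                    "odds_ratio": orat,
                    "p_value": p,
                }
            )
    return _finish_enrichment(rows, alpha)


def extract_invertase_genes(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes whose annotation mentions invertase, integrase or recombinase
    (case-insensitive substring match), deduplicated, order preserved."""
    seen: set[str] = set()
    out = []
    for g in genes:
        ann = g.annotation.lower()
        if any(k in ann for k in INVERTASE_KEYWORDS) and g.gene_id not in seen:
            seen.add(g.gene_id)
            out.append(g)
    return out


def link_invertase_groups(
    loci: Sequence[InvertonLocus],
    inverton_groups: Mapping[str, int],
    invertase_genes: Sequence[GeneRecord],
    invertase_groups: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of invertase groups near inverton groups.

    An inverton is *proximal* to an invertase group when any invertase of
    the group intersects the inverton or lies within ±window of its outer
    IR bounds.  One 2x2 table per (inverton group, invertase group) pair
    over the universe of invertons, Fisher + Bonferroni.
    """
    if not invertase_genes:
        return pd.DataFrame()
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in invertase_genes:
        by_contig.setdefault(g.contig_key, []).append(g)

    # per inverton: set of proximal invertase groups
    prox_groups: dict[str, set[int]] = {}
    for locus in loci:
        a, d = locus.span
        groups = set()
        for g in by_contig.get(locus.contig_key, ()):
            if min(g.end, d + window) > max(g.start, a - window):
                vg = invertase_groups.get(g.gene_id)
                if vg is not None:
                    groups.add(vg)
        prox_groups[locus.inverton_id] = groups

    inv_ids = [l.inverton_id for l in loci]
    n_inv = len(inv_ids)
    all_inv_groups = sorted(set(inverton_groups.get(i) for i in inv_ids) - {None})
    all_vse_groups = sorted(set(invertase_groups.values()))

    rows = []
    for ig in all_inv_groups:
        in_group = [i for i in inv_ids if inverton_groups.get(i) == ig]
        out_group = [i for i in inv_ids if inverton_groups.get(i) != ig]
        for vg in all_vse_groups:
            a = sum(1 for i in in_group if vg in prox_groups[i])
            if a == 0:
                continue  # pair never observed together; not evaluated
            b = sum(1 for i in out_group if vg in prox_groups[i])
            c = len(in_group) - a
            d = len(out_group) - b
            orat, p = fisher_exact_2x2(a, b, c, d)
            rows.append(
                {
                    "inverton_group": ig,
                    "invertase_group": vg,
                    "in_group_proximal": a,
                    "out_group_proximal": b,
                    "in_group_not_proximal": c,
                    "out_group_not_proximal": d,
                    "odds_ratio": orat,
                    "p_value": p,
                    "members": ";".join(i for i in in_group if vg in prox_groups[i]),
                }
            )
    return _finish_enrichment(rows, alpha)
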