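"""Condition contrasts, longitudinal analysis and gene-regulation prediction.

Whether an inverton's orientation depends on growth condition is tested by
pooling paired-end forward/reverse counts (``Pe_F``/``Pe_R``; spanning
counts are not used downstream) across the samples of each condition and
applying a Fisher exact test to the 2x2 table ``[[F_A, R_A], [F_B, R_B]]``,
Bonferroni-corrected over all invertons tested.  An inverton significant
after correction is *directionally biased*.

Longitudinal behavior over k ordered timepoints is assessed by the same
contrast at every early/late split ([t1] vs rest, [t1,t2] vs rest, ...,
k-1 splits in total); an inverton is *time-dependent* when any split is
significant after correction.  Because the any-split rule multiplies the
opportunities for a false flag, the Bonferroni family spans invertons x
splits, keeping the family-wise error at the nominal level.
Carrier-attached and supernatant strata are analyzed independently by
filtering the sample set before calling.

Directionally biased invertons that contain a putative-promoter motif
instance strictly inside the invertible region yield gene-regulation
predictions: each regulatable neighbor is predicted upregulated in the
condition whose enriched orientation points the promoter toward the gene,
and downregulated in the other.  Predictions feed a final per-family
enrichment (families may be enriched for up- and downregulation at once).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneRecord, InvertonLocus, OrientationCounts, SampleMeta
from .motifs import MotifInstance
from .proximity import GeneProximityRecord, fisher_exact_2x2, _finish_enrichment

__all__ = [
    "bonferroni",
    "ContrastResult",
    "contrast_conditions",
    "LongitudinalResult",
    "longitudinal_contrasts",
    "RegulationPrediction",
    "predict_regulated_genes",
    "enrich_predictions",
]

logger = logging.getLogger(__name__)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p·m); m defaults to the count."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


@dataclass(frozen=True)
class ContrastResult:
    """Fisher contrast of one inverton's orientation between two conditions."""

    inverton_id: str
    pe_f_cond1: int
    pe_r_cond1: int
    pe_f_cond2: int
    pe_r_cond2: int
    odds_ratio: float
    p_value: float
    p_adjusted: float
    significant: bool
    direction: str  # orientation enriched in condition 1: forward|reverse|none
    label: str = ""


def _pool_by_condition(
    counts: Sequence[OrientationCounts],
    samples: set[str],
) -> dict[str, tuple[int, int]]:
    pooled: dict[str, tuple[int, int]] = {}
    for c in counts:
        if c.sample_id not in samples:
            continue
        f, r = pooled.get(c.inverton_id, (0, 0))
        pooled[c.inverton_id] = (f + c.pe_f, r + c.pe_r)
    return pooled


def contrast_conditions(
    counts: Sequence[OrientationCounts],
    meta: Mapping[str, SampleMeta],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    label: str | None = None,
) -> list[ContrastResult]:
    """Per-inverton Fisher contrast between two sample types.

    ``condition_a``/``condition_b`` name sample types in the metadata.
    Invertons with zero pooled reads in either condition are skipped (and
    logged); Bonferroni correction spans the invertons actually tested.
    """
    label = label or f"{condition_a}-vs-{condition_b}"
    samples_a = {s for s, m in meta.items() if m.sample_type == condition_a}
    samples_b = {s for s, m in meta.items() if m.sample_type == condition_b}
    pooled_a = _pool_by_condition(counts, samples_a)
    pooled_b = _pool_by_condition(counts, samples_b)

    tested = []
    for iid in sorted(set(pooled_a) | set(pooled_b)):
        fa, ra = pooled_a.get(iid, (0, 0))
        fb, rb = pooled_b.get(iid, (0, 0))
        if fa + ra == 0 or fb + rb == 0:
            logger.info("skipping %s: zero reads in one condition", iid)
            continue
        tested.append((iid, fa, ra, fb, rb))

    if not tested:
        return []
    pvals, orats = [], []
    for _, fa, ra, fb, rb in tested:
        orat, p = fisher_exact_2x2(fa, ra, fb, rb)
        orats.append(orat)
        pvals.append(p)
    padj = bonferroni(pvals)

    out = []
    for (iid, fa, ra, fb, rb), orat, p, pa in zip(tested, orats, pvals, padj):
        ratio_a = ra / (fa + ra)
        ratio_b = rb / (fb + rb)
        if ratio_a > ratio_b:
            direction = "reverse"
        elif ratio_a < ratio_b:
            direction = "forward"
        else:
            direction = "none"
        out.append(
            ContrastResult(
                inverton_id=iid,
                pe_f_cond1=fa,
                pe_r_cond1=ra,
                pe_f_cond2=fb,
                pe_r_cond2=rb,
                odds_ratio=orat,
                p_value=p,
                p_adjusted=float(pa),
                significant=bool(pa < alpha),
                direction=direction,
                label=label,
            )
        )
    return out


@dataclass(frozen=True)
class LongitudinalResult:
    """All early/late split contrasts for one inverton, plus per-timepoint
    inversion ratios for trend inspection."""

    inverton_id: str
    splits: tuple[ContrastResult, ...]
    time_dependent: bool
    timepoint_ratios: Mapping[str, float]


def longitudinal_contrasts(
    counts: Sequence[OrientationCounts],
    meta: Mapping[str, SampleMeta],
    timepoint_order: Sequence[str] | None = None,
    sample_types: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[LongitudinalResult]:
    """Early-vs-late contrasts over all k-1 split points of k ordered
    timepoints; an inverton is time-dependent when any split is significant
    after per-split Bonferroni correction over invertons.

    ``sample_types`` restricts the samples considered (e.g. analyzing
    carrier-attached and supernatant cultures independently).  The
    Bonferroni family is all (inverton, split) tests evaluated in the call.
    """
    use_meta = {
        s: m
        for s, m in meta.items()
        if sample_types is None or m.sample_type in sample_types
    }
    if timepoint_order is None:
        ordered = sorted(
            {(m.timepoint_order, m.timepoint) for m in use_meta.values() if m.timepoint}
        )
        timepoint_order = [t for _, t in ordered]
    k = len(timepoint_order)
    if k < 2:
        raise ValueError("need at least 2 ordered timepoints")

    tp_samples = {
        tp: {s for s, m in use_meta.items() if m.timepoint == tp}
        for tp in timepoint_order
    }
    pooled_by_tp = {tp: _pool_by_condition(counts, tp_samples[tp]) for tp in timepoint_order}
    inverton_ids = sorted({c.inverton_id for c in counts})

    split_tables = []  # (label, [(iid, fa, ra, fb, rb), ...])
    for cut in range(1, k):
        early, late = timepoint_order[:cut], timepoint_order[cut:]
        label = f"[{','.join(early)}]-vs-[{','.join(late)}]"
        tested = []
        for iid in inverton_ids:
            fa = sum(pooled_by_tp[tp].get(iid, (0, 0))[0] for tp in early)
            ra = sum(pooled_by_tp[tp].get(iid, (0, 0))[1] for tp in early)
            fb = sum(pooled_by_tp[tp].get(iid, (0, 0))[0] for tp in late)
            rb = sum(pooled_by_tp[tp].get(iid, (0, 0))[1] for tp in late)
            if fa + ra == 0 or fb + rb == 0:
                continue
            tested.append((iid, fa, ra, fb, rb))
        split_tables.append((label, tested))

    m_total = sum(len(t) for _, t in split_tables)
    per_split: list[list[ContrastResult]] = []
    for label, tested in split_tables:
        results = []
        if tested:
            stats = [fisher_exact_2x2(fa, ra, fb, rb) for _, fa, ra, fb, rb in tested]
            padj = bonferroni([p for _, p in stats], m=m_total)
            for (iid, fa, ra, fb, rb), (orat, p), pa in zip(tested, stats, padj):
                ra_frac = ra / (fa + ra)
                rb_frac = rb / (fb + rb)
                direction = (
                    "reverse" if ra_frac > rb_frac else "forward" if ra_frac < rb_frac else "none"
                )
                results.append(
                    ContrastResult(iid, fa, ra, fb, rb, orat, p, float(pa), bool(pa < alpha), direction, label)
                )
        per_split.append(results)

    out = []
    for iid in inverton_ids:
        splits = tuple(
            r for split in per_split for r in split if r.inverton_id == iid
        )
        ratios = {}
        for tp in timepoint_order:
            f, r = pooled_by_tp[tp].get(iid, (0, 0))
            ratios[tp] = r / (f + r) if f + r else math.nan
        out.append(
            LongitudinalResult(
                inverton_id=iid,
                splits=splits,
                time_dependent=any(s.significant for s in splits),
                timepoint_ratios=ratios,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Regulation predictions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulationPrediction:
    gene_id: str
    inverton_id: str
    motif_id: str
    predicted_up: str  # condition label with predicted upregulation
    contrast_label: str
    direction: str  # orientation enriched in condition 1


def predict_regulated_genes(
    contrasts: Sequence[ContrastResult],
    promoter_instances: Sequence[MotifInstance],
    proximity_records: Sequence[GeneProximityRecord],
    loci: Mapping[str, InvertonLocus],
    genes: Mapping[str, GeneRecord],
    condition_names: tuple[str, str],
) -> list[RegulationPrediction]:
    """Predict genes modulated by flipping of directionally biased invertons.

    Requires, per prediction: a significant contrast for the inverton; a
    putative-promoter instance strictly inside its invertible region (only
    the interior flips, so instances overlapping the IRs are excluded); and
    a regulatable gene.  Geometry: on the reference (forward orientation)
    the promoter's strand either already points at the gene — then the gene
    is predicted up in the condition enriched for the forward orientation —
    or it points away and flipping aims it at the gene, predicting
    upregulation in the reverse-enriched condition.  A gene in a
    read-through chain shares the prediction of its chain.
    """
    cond1, cond2 = condition_names
    sig = {c.inverton_id: c for c in contrasts if c.significant and c.direction != "none"}
    prox_by_inv: dict[str, list[GeneProximityRecord]] = {}
    for rec in proximity_records:
        if rec.proximity_type == "regulatable":
            prox_by_inv.setdefault(rec.inverton_id, []).append(rec)

    out = []
    for iid, contrast in sorted(sig.items()):
        locus = loci.get(iid)
        if locus is None:
            continue
        b, c = locus.invertible_region
        inside = [
            m
            for m in promoter_instances
            if m.contig_key == locus.contig_key and b <= m.start and m.end <= c
        ]
        for m in inside:
            if m.strand not in ("+", "-"):
                logger.info("skipping instance with indeterminate strand in %s", iid)
                continue
            for rec in prox_by_inv.get(iid, ()):
                gene = genes.get(rec.gene_id)
                if gene is None:
                    continue
                facing = "+" if gene.start >= locus.span[1] else "-"
                # orientation in which the promoter points at the gene
                points_in_forward = m.strand == facing
                fwd_enriched_cond = cond1 if contrast.direction == "forward" else cond2
                rev_enriched_cond = cond2 if contrast.direction == "forward" else cond1
                predicted_up = (
                    fwd_enriched_cond if points_in_forward else rev_enriched_cond
                )
                out.append(
                    RegulationPrediction(
                        gene_id=rec.gene_id,
                        inverton_id=iid,
                        motif_id=m.motif_id,
                        predicted_up=predicted_up,
                        contrast_label=contrast.label,
                        direction=contrast.direction,
                    )
                )
    return out


def enrich_predictions(
    predictions: Sequence[RegulationPrediction],
    all_genes: Sequence[GeneRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (annotation, predicted-up condition) Fisher enrichment of
    regulation predictions over the gene universe.  A family can be
    enriched in both directions when both exceed background."""
    if not predictions:
        return pd.DataFrame()
    gene_ann = {g.gene_id: g.annotation for g in all_genes}
    family_sizes: dict[str, int] = {}
    for g in all_genes:
        family_sizes[g.annotation] = family_sizes.get(g.annotation, 0) + 1
    n_genes = len(all_genes)

    by_cond: dict[str, set[str]] = {}
    for p in predictions:
        by_cond.setdefault(p.predicted_up, set()).add(p.gene_id)

    rows = []
    for cond, gene_set in sorted(by_cond.items()):
        ann_counts: dict[str, int] = {}
        for gid in gene_set:
            ann = gene_ann.get(gid)
            if ann is not None:
                ann_counts[ann] = ann_counts.get(ann, 0) + 1
        n_pred = len(gene_set)
        for ann, a in sorted(ann_counts.items()):
            b = family_sizes[ann] - a
            c = n_pred - a
            d = n_genes - family_sizes[ann] - c
            orat, p = fisher_exact_2x2(a, b, c, d)
            rows.append(
                {
                    "annotation": ann,
                    "predicted_up": cond,
                    "up_in_family": a,
                    "not_up_in_family": b,
                    "up_other": c,
                    "not_up_other": d,
                    "odds_ratio": orat,
                    "p_value": p,
                }
            )
    return _finish_enrichment(rows, alpha)
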