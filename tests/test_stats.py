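"""Condition contrasts, longitudinal splits, regulation-prediction geometry."""

import math

import numpy as np
import pytest

from invertonkit.core import (
    GeneRecord,
    InvertonLocus,
    OrientationCounts,
    SampleMeta,
)
from invertonkit.motifs import MotifInstance
from invertonkit.proximity import GeneProximityRecord, classify_gene_proximity
from invertonkit.stats import (
    ContrastResult,
    bonferroni,
    contrast_conditions,
    enrich_predictions,
    longitudinal_contrasts,
    predict_regulated_genes,
)

IID = "S-1__0:1000-1020-1480-1500"
LOCUS = InvertonLocus("S-1__0", 1000, 1020, 1480, 1500)


def _counts(sample, pe_f, pe_r, iid=IID):
    return OrientationCounts(iid, sample, pe_f=pe_f, pe_r=pe_r)


def _meta(**kwargs):
    return {
        s: SampleMeta(s, t, timepoint=tp, timepoint_order=o)
        for s, (t, tp, o) in kwargs.items()
    }


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni([0.0001], m=146)[0] == pytest.approx(0.0146)
        assert bonferroni([0.001], m=100)[0] == pytest.approx(0.1)
        assert bonferroni([1.0], m=50)[0] == 1.0

    def test_default_m_is_count(self):
        adj = bonferroni([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.09])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


class TestContrasts:
    def _basic_meta(self):
        return _meta(
            a1=("isolate", "", 0),
            a2=("isolate", "", 0),
            b1=("mouse_stool", "", 0),
        )

    def test_clear_difference_significant_reverse_in_a(self):
        counts = [
            _counts("a1", 25, 25),
            _counts("a2", 25, 25),
            _counts("b1", 100, 0),
        ]
        (res,) = contrast_conditions(counts, self._basic_meta(), "isolate", "mouse_stool")
        assert res.significant
        assert res.direction == "reverse"  # reverse-enriched in condition 1
        assert (res.pe_f_cond1, res.pe_r_cond1) == (50, 50)

    def test_identical_counts_p_one(self):
        counts = [_counts("a1", 30, 10), _counts("b1", 30, 10)]
        (res,) = contrast_conditions(counts, self._basic_meta(), "isolate", "mouse_stool")
        assert res.p_value == 1.0 and not res.significant
        assert res.direction == "none"

    def test_zero_reads_condition_skipped(self):
        counts = [_counts("a1", 30, 10)]
        res = contrast_conditions(counts, self._basic_meta(), "isolate", "mouse_stool")
        assert res == []

    def test_label_swap_antisymmetry(self):
        counts = [_counts("a1", 40, 10), _counts("b1", 15, 35)]
        meta = self._basic_meta()
        (ab,) = contrast_conditions(counts, meta, "isolate", "mouse_stool")
        (ba,) = contrast_conditions(counts, meta, "mouse_stool", "isolate")
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.odds_ratio == pytest.approx(1 / ba.odds_ratio)
        assert {ab.direction, ba.direction} == {"forward", "reverse"}

    def test_type_one_error_controlled(self):
        """Null simulation: same true ratio in both conditions, 200
        invertons; Bonferroni keeps family-wise false positives rare."""
        rng = np.random.default_rng(77)
        meta = self._basic_meta()
        false_families = 0
        for rep in range(40):
            counts = []
            for i in range(200):
                iid = f"S-1__0:{10*i+1}-{10*i+3}-{10*i+6}-{10*i+8}"
                for s in ("a1", "a2", "b1"):
                    f = int(rng.binomial(60, 0.7))
                    counts.append(_counts(s, f, 60 - f, iid))
            res = contrast_conditions(counts, meta, "isolate", "mouse_stool")
            if any(r.significant for r in res):
                false_families += 1
        assert false_families <= 6  # FWER <= 0.05 plus binomial slack


class TestLongitudinal:
    def _tp_meta(self, labels):
        return {
            f"s{t}": SampleMeta(f"s{t}", "mouse_stool", timepoint=lab, timepoint_order=t)
            for t, lab in enumerate(labels)
        }

    def test_number_of_splits(self):
        labels = ["SC1", "SC2", "SC3", "SC4", "SC5"]
        meta = self._tp_meta(labels)
        counts = [
            OrientationCounts(IID, f"s{t}", pe_f=20, pe_r=20) for t in range(5)
        ]
        (res,) = longitudinal_contrasts(counts, meta, timepoint_order=labels)
        assert len(res.splits) == 4
        assert res.splits[0].label == "[SC1]-vs-[SC2,SC3,SC4,SC5]"
        assert res.splits[-1].label == "[SC1,SC2,SC3,SC4]-vs-[SC5]"

    def test_six_passages_five_splits(self):
        labels = [f"P{i}" for i in range(1, 7)]
        meta = self._tp_meta(labels)
        counts = [
            OrientationCounts(IID, f"s{t}", pe_f=20, pe_r=20) for t in range(6)
        ]
        (res,) = longitudinal_contrasts(counts, meta, timepoint_order=labels)
        assert len(res.splits) == 5
        assert res.splits[-1].label == "[P1,P2,P3,P4,P5]-vs-[P6]"

    def test_single_timepoint_error(self):
        meta = self._tp_meta(["SC1"])
        with pytest.raises(ValueError, match="at least 2"):
            longitudinal_contrasts([], meta, timepoint_order=["SC1"])

    def test_monotone_shift_flagged(self):
        labels = ["SC1", "SC2", "SC3", "SC4", "SC5"]
        meta = self._tp_meta(labels)
        rng = np.random.default_rng(5)
        rhos = [0.0, 0.225, 0.45, 0.675, 0.9]
        counts = []
        for t, rho in enumerate(rhos):
            r = int(rng.binomial(500, rho))
            counts.append(OrientationCounts(IID, f"s{t}", pe_f=500 - r, pe_r=r))
        (res,) = longitudinal_contrasts(counts, meta, timepoint_order=labels)
        assert res.time_dependent
        ratios = [res.timepoint_ratios[l] for l in labels]
        assert ratios[0] < 0.05 and ratios[-1] > 0.8

    def test_timepoint_ratios_nan_when_absent(self):
        labels = ["SC1", "SC2"]
        meta = self._tp_meta(labels)
        counts = [OrientationCounts(IID, "s0", pe_f=10, pe_r=10)]
        (res,) = longitudinal_contrasts(counts, meta, timepoint_order=labels)
        assert math.isnan(res.timepoint_ratios["SC2"])
        assert not res.time_dependent  # no testable split

    def test_strata_filtering(self):
        labels = ["P1", "P2"]
        meta = {
            "c0": SampleMeta("c0", "mixed_carrier", timepoint="P1", timepoint_order=0),
            "c1": SampleMeta("c1", "mixed_carrier", timepoint="P2", timepoint_order=1),
            "s0": SampleMeta("s0", "mixed_supernatant", timepoint="P1", timepoint_order=0),
            "s1": SampleMeta("s1", "mixed_supernatant", timepoint="P2", timepoint_order=1),
        }
        counts = [
            OrientationCounts(IID, "c0", pe_f=100, pe_r=0),
            OrientationCounts(IID, "c1", pe_f=0, pe_r=100),
            OrientationCounts(IID, "s0", pe_f=50, pe_r=50),
            OrientationCounts(IID, "s1", pe_f=50, pe_r=50),
        ]
        (carrier,) = longitudinal_contrasts(
            counts, meta, timepoint_order=labels, sample_types=["mixed_carrier"]
        )
        (supern,) = longitudinal_contrasts(
            counts, meta, timepoint_order=labels, sample_types=["mixed_supernatant"]
        )
        assert carrier.time_dependent and not supern.time_dependent


class TestPredictions:
    def _fixture(self, direction="reverse", promoter_strand="+"):
        """Inverton with an interior promoter instance and a read-through
        chain of two regulatable genes to its right."""
        genes = [
            GeneRecord("S-1__0", 1600, 2000, "+", "g1", "famA"),
            GeneRecord("S-1__0", 2100, 2600, "+", "g2", "famA"),
        ]
        prox = classify_gene_proximity(LOCUS, genes)
        assert {r.proximity_type for r in prox} == {"regulatable"}
        contrast = ContrastResult(
            inverton_id=IID,
            pe_f_cond1=50, pe_r_cond1=50, pe_f_cond2=100, pe_r_cond2=0,
            odds_ratio=0.0, p_value=1e-12, p_adjusted=1e-10,
            significant=True, direction=direction, label="isolate-vs-mouse_stool",
        )
        inst = MotifInstance("S-1__0", 1100, 1130, promoter_strand, "prom1", 1e-10)
        preds = predict_regulated_genes(
            [contrast], [inst], prox, {IID: LOCUS},
            {g.gene_id: g for g in genes}, ("isolate", "mouse_stool"),
        )
        return preds, genes

    def test_chain_of_two_genes_both_predicted(self):
        preds, _ = self._fixture()
        assert {p.gene_id for p in preds} == {"g1", "g2"}
        assert len({p.predicted_up for p in preds}) == 1

    @pytest.mark.parametrize(
        "direction,strand,expected_up",
        [
            # '+' promoter points at the right-side genes already in forward
            # orientation -> up in the forward-enriched condition
            ("forward", "+", "isolate"),
            ("reverse", "+", "mouse_stool"),
            # '-' promoter needs the flip to point at the genes -> up in the
            # reverse-enriched condition
            ("forward", "-", "mouse_stool"),
            ("reverse", "-", "isolate"),
        ],
    )
    def test_geometry(self, direction, strand, expected_up):
        preds, _ = self._fixture(direction=direction, promoter_strand=strand)
        assert preds and all(p.predicted_up == expected_up for p in preds)

    def test_no_significant_contrast_no_prediction(self):
        genes = [GeneRecord("S-1__0", 1600, 2000, "+", "g1", "famA")]
        prox = classify_gene_proximity(LOCUS, genes)
        contrast = ContrastResult(IID, 50, 50, 55, 45, 1.2, 0.5, 1.0, False, "reverse")
        inst = MotifInstance("S-1__0", 1100, 1130, "+", "prom1", 1e-10)
        assert (
            predict_regulated_genes(
                [contrast], [inst], prox, {IID: LOCUS},
                {g.gene_id: g for g in genes}, ("a", "b"),
            )
            == []
        )

    def test_instance_overlapping_ir_excluded(self):
        genes = [GeneRecord("S-1__0", 1600, 2000, "+", "g1", "famA")]
        prox = classify_gene_proximity(LOCUS, genes)
        contrast = ContrastResult(IID, 50, 50, 100, 0, 0.0, 1e-12, 1e-10, True, "reverse")
        straddles_ir = MotifInstance("S-1__0", 1010, 1040, "+", "prom1", 1e-10)
        assert (
            predict_regulated_genes(
                [contrast], [straddles_ir], prox, {IID: LOCUS},
                {g.gene_id: g for g in genes}, ("a", "b"),
            )
            == []
        )

    def test_enrich_predictions_concentrated_family(self):
        preds, genes = self._fixture()
        universe = genes + [
            GeneRecord("S-1__0", 10000 + 1000 * i, 10400 + 1000 * i, "+", f"bg{i}", f"famB{i}")
            for i in range(40)
        ]
        df = enrich_predictions(preds, universe)
        row = df.iloc[0]
        assert row.annotation == "famA" and row.odds_ratio == math.inf
        assert row.significant

    def test_enrich_predictions_empty(self):
        assert enrich_predictions([], []).empty
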