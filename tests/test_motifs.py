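"""PWM scanning, exact p-values, nearest-gene relations, permutation nulls."""

import itertools
import math

import numpy as np
import pytest

from invertonkit.core import GeneRecord
from invertonkit.motifs import (
    PWM,
    MotifInstance,
    annotate_nearest_genes,
    call_putative_promoter,
    nearest_gene,
    permutation_null,
    promoter_consistency_count,
    promoter_orientation_test,
    read_meme_motifs,
    scan_genome,
    score_distribution,
)
from invertonkit.motifs import _discretized_scores, _tail_pvalues
from invertonkit.simulate import make_genome


def _consensus_pwm(consensus: str, motif_id: str = "m", eps: float = 1e-9) -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), eps)
    for i, ch in enumerate(consensus):
        m[i, idx[ch]] = 1 - 3 * eps
    return PWM(motif_id, m)


class TestExactPValues:
    @pytest.mark.parametrize("seed", range(4))
    def test_dp_equals_enumeration(self, seed):
        """For short motifs the DP tail probabilities equal exhaustive
        enumeration over all 4^L words."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 7))
        pwm = PWM("t", rng.dirichlet(np.ones(4) * 1.5, size=L), rng.dirichlet(np.ones(4) * 5))
        q, _ = _discretized_scores(pwm)
        pmf, off, _ = score_distribution(pwm)
        tails = _tail_pvalues(pmf)
        word_scores = {}
        for word in itertools.product(range(4), repeat=L):
            s = sum(int(q[i, b]) for i, b in enumerate(word))
            p = math.prod(pwm.background[b] for b in word)
            word_scores[s] = word_scores.get(s, 0.0) + p
        for s in word_scores:
            enum_tail = sum(p for ss, p in word_scores.items() if ss >= s)
            assert tails[s - off] == pytest.approx(enum_tail, abs=1e-12)

    def test_pwm_validation(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.0, 0.0]]))  # zero entries
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.3, 0.3, 0.3, 0.3]]))  # rows must sum to 1


class TestScan:
    def test_consensus_hit_probability(self):
        pwm = _consensus_pwm("AACGT")
        hits = scan_genome(pwm, {"X__0": "GGGGGAACGTGGGGG"}, p_cutoff=0.002)
        assert [(h.start, h.strand) for h in hits] == [(5, "+")]
        assert hits[0].p_value == pytest.approx(0.25**5)

    def test_cutoff_respected(self):
        pwm = _consensus_pwm("AACGT")
        # exact hit probability 1/4^5 ~ 9.8e-4 is above a 1e-8 cutoff
        assert scan_genome(pwm, {"X__0": "GGGGGAACGTGGGGG"}, p_cutoff=1e-8) == []

    def test_no_hits_in_homopolymer(self):
        # best window of poly-T scores one chance match, p = 1-(3/4)^4 > 0.5
        pwm = _consensus_pwm("ACGT")
        assert scan_genome(pwm, {"X__0": "T" * 100}, p_cutoff=0.5) == []

    def test_palindromic_motif_hits_both_strands(self):
        pwm = _consensus_pwm("ACGT")  # self-reverse-complementary
        hits = scan_genome(pwm, {"X__0": "GGGACGTGGG"}, p_cutoff=0.01)
        assert {(h.start, h.strand) for h in hits} == {(3, "+"), (3, "-")}
        assert hits[0].p_value == pytest.approx(hits[1].p_value)

    def test_short_contig_skipped_and_n_never_matches(self):
        pwm = _consensus_pwm("AACGT")
        assert scan_genome(pwm, {"X__0": "ACG"}, p_cutoff=0.5) == []
        assert scan_genome(pwm, {"X__0": "TTAANGTTT"}, p_cutoff=0.5) == []

    def test_meme_minimal_roundtrip(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
            "MOTIF mot1\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 10 E= 1e-5\n"
            "0.9 0.05 0.03 0.02\n0.1 0.7 0.1 0.1\n0.25 0.25 0.25 0.25\n"
        )
        path = tmp_path / "motifs.meme"
        path.write_text(text)
        (pwm,) = read_meme_motifs(path)
        assert pwm.motif_id == "mot1" and len(pwm) == 3
        assert pwm.background[0] == pytest.approx(0.3)
        assert pwm.matrix[0, 0] == pytest.approx(0.9, abs=1e-3)


class TestNearestGene:
    GENES = [
        GeneRecord("X__0", 200, 500, "+", "g1"),
        GeneRecord("X__0", 700, 900, "+", "g2"),
    ]

    def _inst(self, start, end, strand="+", contig="X__0"):
        return MotifInstance(contig, start, end, strand, "m", 0.001)

    def test_upstream_by_distance(self):
        rel = nearest_gene(self._inst(100, 110), self.GENES)
        assert rel.gene_id == "g1" and rel.distance == 90
        assert rel.placement == "upstream" and rel.same_strand

    def test_overlap_distance_zero(self):
        rel = nearest_gene(self._inst(450, 460), self.GENES)
        assert rel.placement == "overlapping" and rel.distance == 0

    def test_equidistant_tie_smaller_start(self):
        rel = nearest_gene(self._inst(595, 605), self.GENES)
        assert rel.gene_id == "g1"  # both at distance 95

    def test_minus_strand_gene_flips_placement(self):
        genes = [GeneRecord("X__0", 200, 500, "-", "g1")]
        assert nearest_gene(self._inst(100, 110), genes).placement == "downstream"
        assert nearest_gene(self._inst(600, 610), genes).placement == "upstream"

    def test_no_genes_on_contig(self):
        assert nearest_gene(self._inst(0, 10, contig="Y__0"), self.GENES) is None

    def test_consistency_count(self):
        instances = [
            self._inst(100, 110, "+"),   # upstream g1, same strand -> consistent
            self._inst(520, 530, "+"),   # downstream g1 (distance 20), same strand
            self._inst(660, 670, "+"),   # upstream g2 (distance 30), same strand
            self._inst(100, 110, "-"),   # upstream g1, opposite strand
            self._inst(450, 460, "+"),   # overlapping
        ]
        assert promoter_consistency_count(instances, self.GENES) == 2
        assert promoter_consistency_count(instances, self.GENES, mode="downstream") == 1


class TestPermutationNulls:
    def _setup(self, n_inst=30, seed=0):
        rng = np.random.default_rng(seed)
        genome = {"X__0": make_genome(50000, 0.5, rng)}
        genes = []
        pos = 1000
        while pos < 48000:
            length = int(rng.integers(300, 900))
            genes.append(
                GeneRecord("X__0", pos, pos + length, rng.choice(["+", "-"]), f"g{pos}")
            )
            pos += length + int(rng.integers(200, 800))
        instances = []
        for i in range(n_inst):
            s = int(rng.integers(0, 49980))
            instances.append(
                MotifInstance("X__0", s, s + 12, rng.choice(["+", "-"]), "m", 1e-9)
            )
        return instances, genes, genome

    def test_determinism(self):
        instances, genes, genome = self._setup()
        for kind in ("shuffle_loci", "permute_motif_strand", "permute_gene_strand"):
            a = permutation_null(instances, genes, genome, kind, n_samples=50, seed=5)
            b = permutation_null(instances, genes, genome, kind, n_samples=50, seed=5)
            assert np.array_equal(a, b)

    def test_unknown_kind(self):
        instances, genes, genome = self._setup()
        with pytest.raises(ValueError, match="unknown null kind"):
            permutation_null(instances, genes, genome, "bogus", 10, 0)

    def test_contig_shorter_than_motif_error(self):
        genes = [GeneRecord("X__0", 1, 5, "+", "g")]
        inst = [MotifInstance("X__0", 0, 12, "+", "m", 1e-9)]
        with pytest.raises(ValueError, match="shorter than a motif"):
            permutation_null(inst, genes, {"X__0": "ACGTACGT"}, "shuffle_loci", 5, 0)

    def test_gene_strand_null_binomial(self):
        """With every instance upstream/same-strand of its own gene, the
        gene-strand null is Binomial(n_instances, 1/2)."""
        genes, instances = [], []
        for i in range(40):
            base = 2000 * i
            genes.append(GeneRecord("X__0", base + 500, base + 1000, "+", f"g{i}"))
            instances.append(MotifInstance("X__0", base + 400, base + 412, "+", "m", 1e-9))
        genome = {"X__0": "A" * 80000}
        null = permutation_null(instances, genes, genome, "permute_gene_strand", 4000, seed=3)
        mean, var = null.mean(), null.var()
        assert abs(mean - 20) < 0.5
        assert abs(var - 10) < 1.5

    def test_motif_strand_null_binomial_over_upstream_instances(self):
        instances, genes, genome = self._setup(seed=9)
        instances = annotate_nearest_genes(instances, genes)
        n_up = sum(
            1 for m in instances if m.nearest and m.nearest.placement == "upstream"
        )
        null = permutation_null(instances, genes, genome, "permute_motif_strand", 4000, seed=3)
        assert abs(null.mean() - n_up / 2) < 0.5

    def test_shuffle_loci_mostly_not_consistent(self):
        """Shuffling loci on a gene-dense contig leaves only a small
        consistent fraction (most placements land inside genes)."""
        instances, genes, genome = self._setup(seed=13)
        null = permutation_null(instances, genes, genome, "shuffle_loci", 300, seed=1)
        assert null.mean() < len(instances) * 0.5


class TestPromoterCall:
    def test_call_requires_all_three_nulls(self):
        rng = np.random.default_rng(0)
        lo = rng.integers(0, 10, 10000)
        nulls_pass = {k: lo for k in ("a", "b", "c")}
        call = call_putative_promoter(50, nulls_pass)
        assert call.called and all(v == 10000 for v in call.exceedance.values())

        # fails in exactly one null (echoes the borderline case where two
        # nulls clear the bar and the third does not)
        mixed = {"a": lo, "b": lo, "c": np.full(10000, 50)}
        call = call_putative_promoter(50, mixed)
        assert not call.called
        assert call.exceedance["c"] == 0

    def test_observed_at_median_not_called(self):
        null = np.concatenate([np.zeros(5000), np.full(5000, 10)])
        call = call_putative_promoter(5, {k: null for k in "abc"})
        assert not call.called

    def test_exceedance_boundary_9990(self):
        null = np.concatenate([np.zeros(9990), np.full(10, 99)])
        call = call_putative_promoter(1, {k: null for k in "abc"})
        assert call.called  # strictly above exactly 9990 of 10000
        null = np.concatenate([np.zeros(9989), np.full(11, 99)])
        call = call_putative_promoter(1, {k: null for k in "abc"})
        assert not call.called

    def test_unequal_null_lengths_error(self):
        with pytest.raises(ValueError, match="equal lengths"):
            call_putative_promoter(1, {"a": np.zeros(10), "b": np.zeros(9), "c": np.zeros(10)})

    def test_orientation_test_prefers_gene_aligned_strand(self):
        """When all instances are upstream but on the opposite strand, the
        reverse-complement orientation is the promoter-like one."""
        genes, instances = [], []
        for i in range(25):
            base = 3000 * i
            genes.append(GeneRecord("X__0", base + 500, base + 1200, "+", f"g{i}"))
            instances.append(MotifInstance("X__0", base + 400, base + 412, "-", "m", 1e-9))
        genome = {"X__0": "A" * 80000}
        res = promoter_orientation_test(instances, genes, genome, n_samples=500, seed=2)
        assert res.orientation == "revcomp"
        assert res.observed == 25
        assert res.called
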