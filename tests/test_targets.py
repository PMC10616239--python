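import numpy as np
import pytest

from cernapipe.models import FeatureAnnotation, TargetRelation, ValidationError
from cernapipe.targets import (
    antisense_complementarity,
    intersect_predictions,
    interval_gap,
    predict_antisense,
    predict_cis,
    predict_seed_targets,
    predict_trans,
    reverse_complement,
    seed_site,
)

from conftest import make_matrix


def feat(fid, start, end, chrom="chr1", strand="+", biotype="mRNA"):
    return FeatureAnnotation(fid, chrom, start, end, strand, biotype, end - start)


class TestCis:
    def test_gap_at_radius_included(self):
        lnc = feat("l1", 1000, 2000, biotype="lncRNA")
        gene = feat("g1", 12000, 13000)
        (rel,) = predict_cis([lnc], [gene], radius_bp=10_000)
        assert rel.score == 10_000.0

    def test_gap_one_past_radius_excluded(self):
        lnc = feat("l1", 1000, 2000, biotype="lncRNA")
        gene = feat("g1", 12001, 13000)
        assert predict_cis([lnc], [gene], radius_bp=10_000) == []

    def test_overlap_counts_as_zero_gap(self):
        lnc = feat("l1", 1000, 2000, biotype="lncRNA")
        gene = feat("g1", 1500, 2500)
        (rel,) = predict_cis([lnc], [gene])
        assert rel.score == 0.0

    def test_different_chromosomes_never_cis(self):
        lnc = feat("l1", 0, 100, chrom="chr1", biotype="lncRNA")
        gene = feat("g1", 0, 100, chrom="chr2")
        assert predict_cis([lnc], [gene]) == []

    def test_matches_quadratic_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        lncs, genes = [], []
        for chrom in ("chr1", "chr2"):
            for i in range(50):
                s = int(rng.integers(0, 500_000))
                lncs.append(feat(f"l_{chrom}_{i}", s, s + int(rng.integers(200, 2000)),
                                 chrom=chrom, biotype="lncRNA"))
                s = int(rng.integers(0, 500_000))
                genes.append(feat(f"g_{chrom}_{i}", s, s + int(rng.integers(200, 3000)),
                                  chrom=chrom))
        got = {(r.regulator_id, r.target_id, r.score) for r in predict_cis(lncs, genes)}
        expected = set()
        for l in lncs:
            for g in genes:
                gap = interval_gap(l, g)
                if gap is not None and gap <= 10_000:
                    expected.add((l.feature_id, g.feature_id, float(gap)))
        assert got == expected

    def test_symmetric_under_role_swap(self):
        rng = np.random.default_rng(9)
        starts = rng.integers(0, 100_000, size=40)
        a = [feat(f"a{i}", int(starts[i]), int(starts[i]) + 500) for i in range(20)]
        b = [feat(f"b{i}", int(starts[20 + i]), int(starts[20 + i]) + 500)
             for i in range(20)]
        fwd = {(r.regulator_id, r.target_id) for r in predict_cis(a, b)}
        rev = {(r.target_id, r.regulator_id) for r in predict_cis(b, a)}
        assert fwd == rev


class TestAntisense:
    def test_same_strand_overlap_not_candidate(self):
        lnc = feat("l1", 0, 400, strand="+", biotype="lncRNA")
        gene = feat("g1", 200, 600, strand="+")
        assert predict_antisense([lnc], [gene]) == []

    def test_opposite_strand_overlap_without_sequences_scores_length(self):
        lnc = feat("l1", 0, 400, strand="+", biotype="lncRNA")
        gene = feat("g1", 300, 700, strand="-")
        (rel,) = predict_antisense([lnc], [gene])
        assert rel.score == 100.0

    def test_perfect_reverse_complement_scores_one(self):
        genomic = "ACGUACGUACGUACGUACGU"
        lnc = feat("l1", 0, 20, strand="+", biotype="lncRNA")
        gene = feat("g1", 0, 20, strand="-")
        (rel,) = predict_antisense(
            [lnc], [gene], {"l1": genomic}, {"g1": reverse_complement(genomic)}
        )
        assert rel.score == 1.0

    def test_partial_complementarity_counted_positionwise(self):
        """60% complementary overlap is kept at the 0.5 cut with score 0.6."""
        rng = np.random.default_rng(10)
        n = 100
        plus = "".join(rng.choice(list("ACGU"), size=n))
        minus = list(reverse_complement(plus).replace("T", "U"))
        bad = {"A": "C", "G": "A", "C": "A", "U": "C"}
        spoil = rng.choice(n, size=40, replace=False)  # transcript indices
        for j in spoil:
            minus[j] = bad[plus[n - 1 - j]]  # break pairing with the facing base
        minus_transcript = "".join(minus)
        # oracle: count pairing positions directly
        expected = antisense_complementarity(plus, minus_transcript)
        assert expected == pytest.approx(0.6)
        lnc = feat("l1", 0, n, strand="+", biotype="lncRNA")
        gene = feat("g1", 0, n, strand="-")
        (rel,) = predict_antisense([lnc], [gene], {"l1": plus}, {"g1": minus_transcript})
        assert rel.score == pytest.approx(0.6)
        assert predict_antisense(
            [lnc], [gene], {"l1": plus}, {"g1": minus_transcript}, min_complementarity=0.7
        ) == []

    def test_sequence_shorter_than_span_rejected(self):
        lnc = feat("l1", 0, 400, strand="+", biotype="lncRNA")
        gene = feat("g1", 200, 600, strand="-")
        with pytest.raises(ValidationError, match="shorter"):
            predict_antisense([lnc], [gene], {"l1": "ACGU"}, {"g1": "ACGU" * 100})


class TestTrans:
    def test_identical_vectors_retained(self, samples6):
        lnc = make_matrix([[1, 2, 3, 4, 5, 6]], layer="lncRNA", features=["l1"],
                          samples=samples6, unit="FPKM")
        gene = make_matrix([[1, 2, 3, 4, 5, 6]], features=["g1"], samples=samples6,
                           unit="FPKM")
        (rel,) = predict_trans(lnc, gene)
        assert rel.score == pytest.approx(1.0)

    def test_orthogonal_vectors_excluded(self, samples6):
        lnc = make_matrix([[2, 0, 2, 0, 2, 0]], layer="lncRNA", features=["l1"],
                          samples=samples6, unit="FPKM")
        gene = make_matrix([[2, 2, 0, 0, 2, 2]], features=["g1"], samples=samples6,
                           unit="FPKM")
        assert predict_trans(lnc, gene) == []

    def test_matches_all_pairs_pearson_oracle(self, samples6):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(11)
        lvals = rng.uniform(0, 100, size=(8, 6))
        gvals = rng.uniform(0, 100, size=(10, 6))
        lvals[0] = gvals[0] * 2.0 + 1.0  # plant one strong pair
        lnc = make_matrix(lvals, layer="lncRNA", unit="FPKM",
                          features=[f"l{i}" for i in range(8)], samples=samples6)
        gene = make_matrix(gvals, unit="FPKM",
                           features=[f"g{i}" for i in range(10)], samples=samples6)
        got = {(r.regulator_id, r.target_id) for r in predict_trans(lnc, gene)}
        expected = set()
        for i in range(8):
            for j in range(10):
                r, p = pearsonr(lvals[i], gvals[j])
                if abs(r) >= 0.9 and p <= 0.05:
                    expected.add((f"l{i}", f"g{j}"))
        assert got == expected and ("l0", "g0") in got

    def test_no_thresholds_returns_all_nonconstant_pairs(self, samples6):
        rng = np.random.default_rng(12)
        lnc = make_matrix(rng.uniform(1, 9, (3, 6)), layer="lncRNA", unit="FPKM",
                          samples=samples6)
        gene = make_matrix(rng.uniform(1, 9, (4, 6)), unit="FPKM",
                           features=[f"g{i}" for i in range(4)], samples=samples6)
        rels = predict_trans(lnc, gene, r_threshold=0.0, p_threshold=1.0)
        assert len(rels) == 12


class TestSeedMatch:
    def test_let7_style_example(self):
        """miRNA 2-8 seed GAGGUAG; its reverse complement CUACCUC is the site."""
        assert seed_site("UGAGGUAGUAGGUUGUAUAGUU") == "CUACCUC"
        mirnas = {"let7": "UGAGGUAGUAGGUUGUAUAGUU"}
        utrs = {"utr1": "AAAACUACCUCAAAA"}
        (rel,) = predict_seed_targets(mirnas, utrs)
        assert (rel.regulator_id, rel.target_id, rel.score) == ("let7", "utr1", 1.0)

    def test_no_site_no_relation(self):
        assert predict_seed_targets(
            {"let7": "UGAGGUAGUAGGUUGUAUAGUU"}, {"utr1": "A" * 50}
        ) == []

    def test_two_copies_score_two(self):
        region = "GGGCUACCUCGGG"
        assert predict_seed_targets(
            {"let7": "UGAGGUAGUAGGUUGUAUAGUU"}, {"utr1": region * 2}
        )[0].score == 2.0

    def test_dna_and_rna_alphabets_equivalent(self):
        rels_rna = predict_seed_targets(
            {"m": "UGAGGUAGUAGGUUGUAUAGUU"}, {"u": "AACUACCUCAA"}
        )
        rels_dna = predict_seed_targets(
            {"m": "TGAGGTAGTAGGTTGTATAGTT"}, {"u": "AACTACCTCAA"}
        )
        assert [(r.regulator_id, r.target_id, r.score) for r in rels_rna] == [
            (r.regulator_id, r.target_id, r.score) for r in rels_dna
        ]

    def test_invalid_base_rejected(self):
        with pytest.raises(ValidationError, match="invalid base"):
            predict_seed_targets({"m": "UGAGGUAGXAGG"}, {"u": "ACGU" * 10})


class TestIntersect:
    def rels(self, pairs):
        return [TargetRelation(a, b, "seed_match", 1.0) for a, b in pairs]

    def test_disjoint_empty(self):
        assert intersect_predictions(
            self.rels([("m1", "t1")]), self.rels([("m2", "t2")])
        ) == []

    def test_idempotent_on_identical_inputs(self):
        rels = self.rels([("m1", "t1"), ("m2", "t2")])
        got = intersect_predictions(rels, rels)
        assert {(r.regulator_id, r.target_id) for r in got} == {("m1", "t1"), ("m2", "t2")}
        assert all(r.mechanism == "provided" for r in got)

    def test_planted_overlap_recovered_exactly(self):
        rng = np.random.default_rng(13)
        overlap = [(f"m{i}", f"t{i}") for i in range(10)]
        extra_a = [(f"ma{i}", f"ta{i}") for i in range(90)]
        extra_b = [(f"mb{i}", f"tb{i}") for i in range(90)]
        a = self.rels(overlap + extra_a)
        b = self.rels(extra_b + overlap)
        got = intersect_predictions(a, b)
        assert {(r.regulator_id, r.target_id) for r in got} == set(overlap)
        assert got == sorted(got, key=lambda r: (r.regulator_id, r.target_id))
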