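from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import rankdata

from cernapipe.cerna import (
    assemble_network,
    hypergeom_shared_test,
    pearson_screen,
    spearman_screen,
)
from cernapipe.hypergeom import hypergeom_upper_tail
from cernapipe.models import CeRNAPair, MiRNACeRNAEdge, TargetRelation, ValidationError

from conftest import make_matrix


def rel(mir, target):
    return TargetRelation(mir, target, "provided", 0.0)


def enumeration_upper_tail(k, N, K, n):
    """Oracle: P[X >= k] by enumerating all C(N, n) draws."""
    marked = set(range(K))
    hits = sum(
        1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return hits / comb(N, n)


class TestSpearmanScreen:
    def mats(self, mir_rows, cer_rows, samples, layer="lncRNA"):
        mir = make_matrix(mir_rows, layer="miRNA", unit="TPM",
                          features=[f"m{i}" for i in range(len(mir_rows))],
                          samples=samples)
        cer = make_matrix(cer_rows, layer=layer, unit="FPKM",
                          features=[f"c{i}" for i in range(len(cer_rows))],
                          samples=samples)
        return mir, cer

    def test_perfect_anticorrelation_retained(self, samples6):
        mir, cer = self.mats([[6, 5, 4, 3, 2, 1]], [[10, 20, 30, 40, 50, 60]], samples6)
        (edge,) = spearman_screen(mir, cer, [rel("m0", "c0")])
        assert edge.spearman_rho == pytest.approx(-1.0)

    def test_identical_vectors_rejected(self, samples6):
        mir, cer = self.mats([[1, 2, 3, 4, 5, 6]], [[1, 2, 3, 4, 5, 6]], samples6)
        assert spearman_screen(mir, cer, [rel("m0", "c0")]) == []

    def test_ties_use_average_ranks(self, samples6):
        """rho with ties equals the rank-then-Pearson oracle to 1e-12."""
        mir_row = [5.0, 5.0, 3.0, 2.0, 2.0, 1.0]
        cer_row = [1.0, 2.0, 2.0, 4.0, 5.0, 5.0]
        mir, cer = self.mats([mir_row], [cer_row], samples6)
        (edge,) = spearman_screen(mir, cer, [rel("m0", "c0")], rho_threshold=1.0)
        oracle = np.corrcoef(rankdata(mir_row), rankdata(cer_row))[0, 1]
        assert edge.spearman_rho == pytest.approx(oracle, abs=1e-12)

    def test_only_listed_relations_evaluated(self, samples6):
        mir, cer = self.mats(
            [[6, 5, 4, 3, 2, 1], [6, 5, 4, 3, 2, 1]],
            [[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]],
            samples6,
        )
        edges = spearman_screen(mir, cer, [rel("m0", "c1")])
        assert [(e.mirna_id, e.cerna_id) for e in edges] == [("m0", "c1")]

    def test_invariant_under_monotone_transform(self, samples6):
        rng = np.random.default_rng(21)
        mir_rows = rng.uniform(1, 100, (4, 6))
        cer_rows = rng.uniform(1, 100, (4, 6))
        relations = [rel(f"m{i}", f"c{j}") for i in range(4) for j in range(4)]
        mir, cer = self.mats(mir_rows, cer_rows, samples6)
        mir_t, cer_t = self.mats(np.exp(mir_rows / 20), cer_rows**3, samples6)
        e1 = spearman_screen(mir, cer, relations, rho_threshold=1.0)
        e2 = spearman_screen(mir_t, cer_t, relations, rho_threshold=1.0)
        for a, b in zip(e1, e2):
            assert a.spearman_rho == pytest.approx(b.spearman_rho, abs=1e-12)


class TestPearsonScreen:
    def test_identical_vectors_survive(self, samples6):
        lnc = make_matrix([[1, 2, 3, 4, 5, 6]], layer="lncRNA", unit="FPKM",
                          features=["l0"], samples=samples6)
        mrna = make_matrix([[2, 4, 6, 8, 10, 12]], unit="FPKM",
                           features=["g0"], samples=samples6)
        (pair,) = pearson_screen(lnc, mrna, [("l0", "g0")])
        assert pair.pearson_r == pytest.approx(1.0)

    def test_exactly_point_nine_rejected(self, samples6):
        """'Greater than 0.9' is strict: a pair at exactly r=0.9 fails."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rng = np.random.default_rng(22)
        q = rng.standard_normal(6)
        xc = x - x.mean()
        q = q - q.mean()
        q -= (q @ xc) / (xc @ xc) * xc
        q *= np.linalg.norm(xc) / np.linalg.norm(q)
        y = 0.9 * xc + np.sqrt(1 - 0.81) * q  # corr(x, y) = 0.9 exactly
        y -= y.min()
        r_exact = float(np.corrcoef(x, y)[0, 1])
        assert r_exact == pytest.approx(0.9, abs=1e-12)
        lnc = make_matrix([x], layer="lncRNA", unit="FPKM", features=["l0"],
                          samples=samples6)
        mrna = make_matrix([y], unit="FPKM", features=["g0"], samples=samples6)
        assert pearson_screen(lnc, mrna, [("l0", "g0")], r_threshold=r_exact) == []
        (pair,) = pearson_screen(lnc, mrna, [("l0", "g0")], r_threshold=0.8999)
        assert pair.pearson_r == pytest.approx(0.9)

    def test_survivors_match_all_pairs_oracle(self, samples6):
        rng = np.random.default_rng(23)
        lv = rng.uniform(0, 50, (6, 6))
        gv = rng.uniform(0, 50, (7, 6))
        lnc = make_matrix(lv, layer="lncRNA", unit="FPKM",
                          features=[f"l{i}" for i in range(6)], samples=samples6)
        mrna = make_matrix(gv, unit="FPKM",
                           features=[f"g{j}" for j in range(7)], samples=samples6)
        cands = [(f"l{i}", f"g{j}") for i in range(6) for j in range(7)]
        got = {(p.lncrna_id, p.mrna_id) for p in pearson_screen(lnc, mrna, cands, 0.3)}
        expected = {
            (f"l{i}", f"g{j}")
            for i in range(6)
            for j in range(7)
            if np.corrcoef(lv[i], gv[j])[0, 1] > 0.3
        }
        assert got == expected


class TestHypergeomSharedTest:
    def edges_for(self, lnc_regs, mrna_regs, universe):
        edges = []
        for m in universe:
            if m in lnc_regs:
                edges.append(MiRNACeRNAEdge(m, "l0", "lncRNA", -0.9))
            if m in mrna_regs:
                edges.append(MiRNACeRNAEdge(m, "g0", "mRNA", -0.9))
        return edges

    def test_no_shared_mirnas_p_one(self):
        universe = {f"m{i}" for i in range(10)}
        edges = self.edges_for({"m0", "m1"}, {"m2", "m3"}, universe)
        pair = hypergeom_shared_test(CeRNAPair("l0", "g0"), edges, universe)
        assert pair.k_shared == 0 and pair.hypergeom_p == 1.0

    def test_worked_example_seven_over_210(self):
        """N=10, K=3, n=4, k=3: p = C(3,3) C(7,1) / C(10,4) = 7/210."""
        universe = {f"m{i}" for i in range(10)}
        lnc_regs = {"m0", "m1", "m2"}
        mrna_regs = {"m0", "m1", "m2", "m3"}
        edges = self.edges_for(lnc_regs, mrna_regs, universe)
        pair = hypergeom_shared_test(CeRNAPair("l0", "g0"), edges, universe)
        assert pair.hypergeom_p == pytest.approx(7 / 210, abs=1e-12)
        assert pair.hypergeom_p == pytest.approx(
            enumeration_upper_tail(3, 10, 3, 4), abs=1e-12
        )

    def test_saturated_regulator_set_p_one(self):
        universe = {f"m{i}" for i in range(6)}
        edges = self.edges_for(universe, {"m0", "m1"}, universe)
        pair = hypergeom_shared_test(CeRNAPair("l0", "g0"), edges, universe)
        assert pair.k_shared == pair.n_mrna
        assert pair.hypergeom_p == pytest.approx(1.0, abs=1e-12)

    def test_p_monotone_in_k(self):
        for N, K, n in [(12, 5, 6), (10, 4, 4), (8, 8, 3)]:
            ps = [hypergeom_upper_tail(k, N, K, n) for k in range(min(K, n) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_regulators_outside_universe_rejected(self):
        edges = self.edges_for({"m0"}, {"m0"}, {"m0", "m9"})
        with pytest.raises(ValidationError):
            hypergeom_shared_test(CeRNAPair("l0", "g0"), edges, set())


class TestAssembleNetwork:
    def minimal_inputs(self, p=0.01):
        edges = [
            MiRNACeRNAEdge("m0", "l0", "lncRNA", -0.95),
            MiRNACeRNAEdge("m0", "g0", "mRNA", -0.9),
        ]
        pair = CeRNAPair(
            "l0", "g0", pearson_r=0.97, shared_mirnas=frozenset({"m0"}),
            k_shared=1, K_lnc=1, n_mrna=1, N_universe=20, hypergeom_p=p,
        )
        return edges, [pair]

    def test_minimal_triplet_three_nodes_three_edges(self):
        edges, pairs = self.minimal_inputs()
        net = assemble_network(edges, pairs)
        assert net.nodes == {"m0": "miRNA", "l0": "lncRNA", "g0": "mRNA"}
        assert len(net.edges) == 3
        types = sorted(e[2] for e in net.edges)
        assert types == ["cerna_pair", "mirna_target", "mirna_target"]

    def test_non_final_pair_gives_empty_network(self):
        edges, pairs = self.minimal_inputs(p=0.2)
        net = assemble_network(edges, pairs, p_threshold=0.05)
        assert net.nodes == {} and net.edges == []

    def test_no_pairs_empty_network(self):
        net = assemble_network([], [])
        assert net.nodes == {} and net.edges == []

    def test_mirna_edges_only_for_shared_mirnas_of_final_pairs(self):
        edges, pairs = self.minimal_inputs()
        edges.append(MiRNACeRNAEdge("m1", "l0", "lncRNA", -0.99))  # not shared
        net = assemble_network(edges, pairs)
        assert "m1" not in net.nodes
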