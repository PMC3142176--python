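import itertools

import numpy as np
import pytest
from scipy import stats

from popgenkit import neutrality as nt
from popgenkit.locus import classify_sites
from tests.conftest import (
    make_locus,
    oracle_tajima_d,
    oracle_wall_b_q,
    oracle_zns,
)


def random_binary_matrix(n, S, seed):
    rng = np.random.default_rng(seed)
    while True:
        m = (rng.random((n, S)) < rng.uniform(0.1, 0.5, S)).astype(np.int8)
        counts = m.sum(axis=0)
        if ((counts > 0) & (counts < n)).all():
            return m


class TestTajimaD:
    def test_constants_frozen_oracle(self):
        # n = 10 constants computed independently from the 1989 formulas
        c = nt.tajima_constants(10)
        assert c["a1"] == pytest.approx(2.8289682539682537)
        assert c["a2"] == pytest.approx(1.5397677311665408)
        assert c["e1"] == pytest.approx(0.019060533801591818, rel=1e-9)
        assert c["e2"] == pytest.approx(0.00494892776989633, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force(self, seed):
        m = random_binary_matrix(8, 12, seed)
        assert nt.tajima_d_matrix(m) == pytest.approx(
            oracle_tajima_d(m), rel=1e-10
        )

    def test_undefined_without_sites(self):
        m = np.zeros((5, 0), dtype=np.int8)
        assert np.isnan(nt.tajima_d_matrix(m))


class TestZnS:
    def test_hand_case_perfect_ld(self):
        # two sites in complete LD: r^2 = 1 for the pair
        m = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        assert nt.kelly_zns_matrix(m) == pytest.approx(1.0)

    def test_hand_case_one_third(self):
        # frequencies 1/2, 1/2; one double carrier out of 4:
        # D = 1/4 - 1/4 = 0?  Use known r^2 = 1/3 configuration:
        # x = (0,0,1,1), y = (0,1,1,1): p1=1/2, p2=3/4, p11=1/2
        # D = 1/2 - 3/8 = 1/8; r^2 = (1/64)/(1/4 * 3/16) = 1/3
        m = np.array([[0, 0], [0, 1], [1, 1], [1, 1]], dtype=np.int8)
        assert nt.kelly_zns_matrix(m) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_brute_force(self, seed):
        m = random_binary_matrix(10, 8, seed)
        assert nt.kelly_zns_matrix(m) == pytest.approx(
            oracle_zns(m), rel=1e-10
        )


class TestWallBQ:
    def test_hand_counts(self):
        # sites 1 and 2 induce the same bipartition {2,3}; site 3 differs
        m = np.array(
            [[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 0]], dtype=np.int8
        )
        B, Q, bp, A = nt.wall_b_q_matrix(m)
        assert bp == 1 and A == 1
        assert B == pytest.approx(1 / 2)
        assert Q == pytest.approx(2 / 3)

    def test_complement_coding_identified(self):
        # second site is the complement labeling of the first
        m = np.array([[0, 1], [0, 1], [1, 0], [1, 0]], dtype=np.int8)
        B, Q, bp, A = nt.wall_b_q_matrix(m)
        assert bp == 1 and B == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [6, 7])
    def test_matches_brute_force(self, seed):
        m = random_binary_matrix(9, 10, seed)
        B, Q, _, _ = nt.wall_b_q_matrix(m)
        ob, oq = oracle_wall_b_q(m)
        assert B == pytest.approx(ob)
        assert Q == pytest.approx(oq)


class TestBiallelicMatrix:
    def test_coding_and_positions(self, tiny_locus):
        m, pos = nt.biallelic_matrix(tiny_locus)
        assert pos.tolist() == [3, 4, 9, 12]
        assert (m.sum(axis=0) == np.array([1, 1, 1, 1])).all()  # major = 0

    def test_exclude_singletons(self, tiny_locus):
        m, pos = nt.biallelic_matrix(tiny_locus, exclude_singletons=True)
        assert len(pos) == 0


class TestMK:
    def test_counts_and_fisher(self, tiny_annotation):
        # ingroup (3 seqs) + outgroup: fixed syn difference at pos 6
        # (ATG vs ATA is nonsyn; use codon 2 AAA vs AAG syn at pos 9),
        # polymorphic nonsyn at pos 4
        rows = [
            "ACGATGAAATTT",
            "ACGCTGAAATTT",
            "ACGATGAAATTT",
            "ACGATGAAGTTT",  # outgroup: AAG at codon 2 (synonymous vs AAA)
        ]
        locus = make_locus(
            rows, annotation=tiny_annotation,
            species=["ingroup", "ingroup", "ingroup", "sister"],
        )
        sites = classify_sites(locus)
        res = nt.mk_test(locus, sites, "s4")
        # Ps=0, Pn=1, Ds=1, Dn=0 -> zero margin is impossible here:
        # columns sums: syn column 0+1, nonsyn 1+0 -> fine
        assert res.details["table"] == [[0, 1], [1, 0]]
        table = np.array(res.details["table"])
        _, expected_p = stats.fisher_exact(table)
        assert res.p_value == pytest.approx(expected_p)

    def test_zero_margin_flagged(self, tiny_locus):
        # no outgroup divergence at all -> D row is zero
        rows = ["ACGATGAAATTT", "ACGCTGAAATTT", "ACGATGAAATTT",
                "ACGATGAAATTT"]
        locus = make_locus(
            rows, annotation=tiny_locus.annotation,
            species=["ingroup", "ingroup", "ingroup", "sister"],
        )
        sites = classify_sites(locus)
        res = nt.mk_test(locus, sites, "s4")
        assert not res.defined
        assert res.details["flag"] == "zero margin"

    def test_fisher_exact_enumeration_oracle(self):
        # independent check of the scipy two-sided Fisher p used by mk_test:
        # enumerate hypergeometric outcomes for table [[2, 15], [14, 3]]
        table = [[2, 15], [14, 3]]
        _, p = stats.fisher_exact(table)
        r1, r2 = 17, 17
        c1 = 16
        from math import comb

        total = comb(r1 + r2, c1)
        prob = {
            a: comb(r1, a) * comb(r2, c1 - a) / total
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        p_obs = prob[2]
        p_enum = sum(v for v in prob.values() if v <= p_obs + 1e-12)
        assert p == pytest.approx(p_enum, rel=1e-9)


class TestHKA:
    def test_symmetric_two_locus_no_deviation(self):
        # identical loci: observed = expected exactly -> X^2 = 0, p = 1
        loci = [
            {"S": 10, "K": 0.05, "N": 1000, "n": 10},
            {"S": 10, "K": 0.05, "N": 1000, "n": 10},
        ]
        res = nt.hka_test(loci)
        assert res.value == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_moment_equations_satisfied(self):
        loci = [
            {"S": 20, "K": 0.08, "N": 1500, "n": 12},
            {"S": 5, "K": 0.06, "N": 800, "n": 12},
            {"S": 11, "K": 0.04, "N": 1200, "n": 8},
        ]
        res = nt.hka_test(loci)
        th = np.array(res.details["theta_hat"])
        T = res.details["T_hat"]
        a1 = np.array(
            [sum(1 / i for i in range(1, x["n"])) for x in loci]
        )
        S = np.array([x["S"] for x in loci], dtype=float)
        D = np.array([x["K"] * x["N"] for x in loci])
        # moment conditions: sum E[S] = sum S and sum E[D] = sum D
        assert np.sum(th * a1) == pytest.approx(S.sum(), rel=1e-8)
        assert np.sum(th * (T + 1)) == pytest.approx(D.sum(), rel=1e-8)
        assert res.details["df"] == 2

    def test_deviant_locus_detected(self):
        loci = [
            {"S": 2, "K": 0.10, "N": 1000, "n": 10},   # low S, high D
            {"S": 30, "K": 0.02, "N": 1000, "n": 10},  # high S, low D
        ]
        res = nt.hka_test(loci)
        assert res.p_value < 0.01

    def test_needs_two_loci(self):
        with pytest.raises(ValueError):
            nt.hka_test([{"S": 1, "K": 0.1, "N": 100, "n": 4}])


class TestSubsetSearch:
    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n, S = 7, 6
        m = (rng.random((n, S)) < 0.4).astype(np.int8)
        i = int(rng.integers(2, n + 1))
        j = int(rng.integers(0, S))

        def exhaustive(matrix, i, j):
            for r in range(i, n + 1):
                for combo in itertools.combinations(range(n), r):
                    sub = matrix[list(combo)]
                    seg = np.sum(
                        (sub.sum(axis=0) > 0) & (sub.sum(axis=0) < r)
                    )
                    if seg <= j:
                        return True
            return False

        assert nt._subset_exists(m, i, j) == exhaustive(m, i, j)

    def test_trivial_cases(self):
        m = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
        assert nt._subset_exists(m, 1, 0)
        assert nt._subset_exists(m, 3, 2)
        assert not nt._subset_exists(m, 3, 0)


class TestHaplotypeTest:
    def test_probability_bounds_and_determinism(self):
        r1 = nt.haplotype_test(8, 6, 0.0, 4, 1, L=300, reps=1000, seed=3)
        r2 = nt.haplotype_test(8, 6, 0.0, 4, 1, L=300, reps=1000, seed=3)
        assert 0.0 <= r1.value <= 1.0
        assert r1.value == r2.value

    def test_certain_subset_gives_p_one(self):
        # i = 1 always satisfiable; any replicate qualifies
        r = nt.haplotype_test(6, 4, 0.0, 1, 0, L=200, reps=1000, seed=1)
        assert r.value == 1.0

    def test_rejects_small_reps(self):
        with pytest.raises(ValueError):
            nt.haplotype_test(6, 4, 0.0, 3, 1, reps=10)
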