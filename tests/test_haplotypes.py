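import numpy as np
import pytest

from popgenkit import haplotypes as hp
from tests.conftest import make_locus


class TestK2P:
    def test_closed_form(self):
        # P = 0.1 (transitions), Q = 0.05 (transversions) over 100 sites:
        # d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) = 0.170236...
        x = np.array(list("A" * 100))
        y = x.copy()
        y[:10] = "G"        # 10 transitions
        y[10:15] = "C"      # 5 transversions
        d = hp.k2p_distance(x, y)
        expected = -0.5 * np.log(1 - 2 * 0.1 - 0.05) - 0.25 * np.log(
            1 - 2 * 0.05
        )
        assert d == pytest.approx(expected)
        assert d == pytest.approx(0.1702, abs=1e-4)

    def test_identical_zero(self):
        x = np.array(list("ACGTACGT"))
        assert hp.k2p_distance(x, x) == 0.0

    def test_saturation_error_and_inf(self):
        x = np.array(list("AAAA"))
        y = np.array(list("GGGG"))
        with pytest.raises(hp.SaturatedDistanceError):
            hp.k2p_distance(x, y)
        assert hp.k2p_distance(x, y, on_saturation="inf") == float("inf")

    def test_gaps_excluded_pairwise(self):
        x = np.array(list("ACG-"))
        y = np.array(list("ACGT"))
        assert hp.k2p_distance(x, y) == 0.0


class TestNJTree:
    def _locus(self):
        rows = [
            "AAAAAAAAAAAAAAAAAAAA",
            "AAAAAAAAAAAAAAAAAAGG",
            "CCCCAAAAAAAAAAAAAAAA",
            "CCCCAAAAAAAAAAAAAAGG"[:20],
        ]
        rows[3] = "CCCCTTAAAAAAAAAAAAAA"
        return make_locus(rows)

    def test_tree_has_all_tips(self):
        tree = hp.k2p_nj_tree(self._locus(), bootstrap=50, seed=1)
        tips = {t.name for t in tree.tree.tips()}
        assert tips == {"s1", "s2", "s3", "s4"}

    def test_clear_split_gets_high_support(self):
        tree = hp.k2p_nj_tree(self._locus(), bootstrap=100, seed=2)
        # s1+s2 vs s3+s4 split (4 fixed differences) should be recovered
        key = frozenset({"s1", "s2"})
        alt = frozenset({"s3", "s4"})
        support = tree.support.get(key, tree.support.get(alt))
        assert support is not None and support >= 90

    def test_newick_contains_support(self):
        tree = hp.k2p_nj_tree(self._locus(), bootstrap=50, seed=3)
        nwk = tree.newick()
        assert nwk.count("s1") == 1
        assert ";" in nwk

    def test_needs_three_sequences(self):
        with pytest.raises(ValueError):
            hp.k2p_nj_tree(make_locus(["AC", "AG"]))


class TestKstFst:
    def _grouped_locus(self):
        # two groups of 2; 4 fixed differences between, 1 polymorphism in B
        rows = [
            "AAAAAAAAAA",
            "AAAAAAAAAA",
            "GGGGAAAAAA",
            "GGGGAAAAAT",
        ]
        return make_locus(rows, groups=["A", "A", "B", "B"])

    def test_kst_hand_value(self):
        locus = self._grouped_locus()
        res = hp.group_differentiation(locus, permutations=100, seed=1)
        # within A: 0; within B: 1/10; weighted Ks = 1/20
        # Kt over all 6 pairs: (0 + 4/10*4 + 5/10 + 1/10)/6 = 11/30... compute:
        # pairs: (1,2):0 (1,3):4 (1,4):5 (2,3):4 (2,4):5 (3,4):1 over 10 sites
        kt = (0 + 0.4 + 0.5 + 0.4 + 0.5 + 0.1) / 6
        ks = 0.5 * 0 + 0.5 * 0.1
        assert res.kst == pytest.approx(1 - ks / kt)

    def test_fst_hsm_hand_value(self):
        locus = self._grouped_locus()
        res = hp.group_differentiation(
            locus, permutations=100, seed=1, fst_variant="hsm"
        )
        hw = (0 + 0.1) / 2
        hb = (0.4 + 0.5 + 0.4 + 0.5) / 4
        assert res.fst == pytest.approx(1 - hw / hb)

    def test_strong_structure_significant(self):
        # 4 + 4 sequences: with 2 + 2 the label permutation null has only
        # 3 distinct splits and the smallest achievable p is ~1/3
        rows = ["AAAAAAAAAA"] * 4 + ["GGGGAAAAAA"] * 4
        locus = make_locus(rows, groups=["A"] * 4 + ["B"] * 4)
        res = hp.group_differentiation(locus, permutations=400, seed=4)
        assert res.p_value is not None and res.p_value < 0.05

    def test_dxy_two_groups(self):
        locus = self._grouped_locus()
        res = hp.group_differentiation(locus, permutations=50, seed=2)
        assert res.dxy == pytest.approx((0.4 + 0.5 + 0.4 + 0.5) / 4)


class TestGroupContrast:
    def test_fixed_shared_private_hand_case(self):
        rows = [
            "AAAAACAAAT",
            "AAAAACAAGT",
            "GAAAACAAAT",
            "GAAAATAAGA",
        ]
        # site 1: fixed A/G between groups; site 6: private poly in B (C/T);
        # site 9: shared polymorphism (A/G in both); site 10: private B (T/A)
        locus = make_locus(rows, groups=["A", "A", "B", "B"])
        res = hp.group_contrast(locus)
        assert res.fixed_differences == 1
        assert res.shared_polymorphisms == 1
        assert res.private_polymorphisms == {"A": 0, "B": 2}

    def test_requires_two_groups(self):
        locus = make_locus(["ACGT", "ACGA"], groups=["A", "A"])
        with pytest.raises(ValueError):
            hp.group_contrast(locus)


class TestDeltaG:
    def test_exact_mann_whitney_separated(self):
        # {-1,-2,-3} vs {-4,-5,-6}: complete separation, U = 0,
        # exact two-sided p = 2/C(6,3) * ... = 0.1
        table = hp.DeltaGTable(
            values={"a": -1, "b": -2, "c": -3, "d": -4, "e": -5, "f": -6},
            groups={"a": "X", "b": "X", "c": "X",
                    "d": "Y", "e": "Y", "f": "Y"},
        )
        res = hp.deltaG_group_test(table)
        assert res.p_value == pytest.approx(0.1)
        assert res.method.startswith("exact")

    def test_no_difference_p_one(self):
        table = hp.DeltaGTable(
            values={"a": -1, "b": -3, "c": -5, "d": -2, "e": -4, "f": -6},
            groups={"a": "X", "b": "X", "c": "X",
                    "d": "Y", "e": "Y", "f": "Y"},
        )
        res = hp.deltaG_group_test(table)
        assert res.p_value > 0.5

    def test_positive_deltag_warned(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="popgenkit"):
            hp.DeltaGTable(values={"a": 1.0}, groups={"a": "X"})
        assert any("positive" in r.message for r in caplog.records)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hp.DeltaGTable(values={"a": float("nan")}, groups={"a": "X"})

    def test_read_table(self, tmp_path):
        p = tmp_path / "dg.tsv"
        p.write_text("id\tdeltaG\tgroup\na\t-12.5\tX\nb\t-10.0\tY\n")
        table = hp.read_deltag_table(str(p))
        assert table.values == {"a": -12.5, "b": -10.0}
        assert table.groups == {"a": "X", "b": "Y"}
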