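import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from popgenkit import codon as cd
from popgenkit import synthetic
from popgenkit.locus import RegionAnnotation, Segment
from tests.conftest import make_locus


def small_alignment(seed=0, n_sites=40, taxa=3):
    rng = np.random.default_rng(seed)
    tree = "(t1:0.1,t2:0.15,t3:0.2);"
    data, truth = synthetic.gen_codon(
        tree=tree, n_sites=n_sites, kappa=2.0,
        site_classes=[(0.3, 1.0)], seed=seed,
    )
    return data


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        pi = np.full(61, 1 / 61)
        Q = cd.codon_rate_matrix(pi, 2.0, 1.0, 0.5)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61))
        Q = cd.codon_rate_matrix(pi, 3.0, 1.0, 0.2)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_multi_step_changes_zero(self):
        pi = np.full(61, 1 / 61)
        Q = cd.codon_rate_matrix(pi, 2.0, 1.0, 0.5)
        for i, j in [(0, 30), (5, 50)]:
            ci, cjc = cd.CODONS[i], cd.CODONS[j]
            ndiff = sum(a != b for a, b in zip(ci, cjc))
            if ndiff > 1:
                assert Q[i, j] == 0.0

    def test_transition_matches_expm(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        Q = cd.codon_rate_matrix(pi, 2.5, 1.0, 0.3)
        Q /= -np.sum(pi * np.diag(Q))
        eig = cd._Eigens(Q, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.abs(eig.transition(t) - expm(Q * t)).max() < 1e-10

    def test_hky_stationary(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        Q = cd.hky_rate_matrix(pi, 4.0)
        eig = cd._Eigens(Q, pi)
        P = eig.transition(100.0)
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-8)


class TestBruteForceLikelihood:
    def test_pruning_matches_explicit_sum(self):
        """Felsenstein pruning vs an explicit sum over root states for a
        3-taxon star tree, via matrix exponentials (tolerance 1e-6 rel)."""
        data = small_alignment(seed=3, n_sites=5)
        tree = cd.PhyloTree(newick="(t1:0.1,t2:0.15,t3:0.2);")
        pi = data.f3x4()
        kappa, omega = 2.0, 0.4
        Q = cd.codon_rate_matrix(pi, kappa, 1.0, omega)
        Q /= -np.sum(pi * np.diag(Q))
        bls = {t: bl for t, bl in zip(["t1", "t2", "t3"], [0.1, 0.15, 0.2])}
        Ps = {t: expm(Q * bl) for t, bl in bls.items()}
        order = [data.taxa.index(t) for t in ["t1", "t2", "t3"]]
        ll_oracle = 0.0
        for s in range(data.n_sites):
            states = [data.codons[k, s] for k in order]
            site_l = sum(
                pi[r]
                * Ps["t1"][r, states[0]]
                * Ps["t2"][r, states[1]]
                * Ps["t3"][r, states[2]]
                for r in range(61)
            )
            ll_oracle += np.log(site_l)

        # package path: evaluate the likelihood at the same parameters
        spec = cd._ModelSpec("M0", {})
        patterns, _, counts = cd._compress_patterns(data.codons[order])
        x = np.array([0.1, 0.15, 0.2, kappa, omega])
        ll = cd._loglik_codon(
            x, spec, tree, patterns, counts, pi, n_branch=3
        )
        assert ll == pytest.approx(ll_oracle, rel=1e-6)


class TestModelSpecs:
    def test_beta_discretization_mean(self):
        om = cd._beta_discretized(2.0, 2.0, 10)
        assert np.all((om > 0) & (om < 1))
        assert np.mean(om) == pytest.approx(0.5, abs=0.01)

    def test_m8_proportions_sum_to_one(self):
        spec = cd._ModelSpec("M8", {})
        rates, props, _ = spec.classes(np.array([2.0, 0.5, 1.5, 0.9, 2.5]))
        assert len(rates) == 11
        assert props.sum() == pytest.approx(1.0)
        assert rates[-1][1] == 2.5

    def test_dual_alpha_mean_one(self):
        spec = cd._ModelSpec("Dual3x3", {})
        x = np.array([2.0, 0.5, 1.0, 2.0, 0.3, 0.5,
                      0.05, 0.3, 1.0, 0.3, 0.5])
        rates, props, params = spec.classes(x)
        alphas = np.array(params["alphas"])
        pa = np.array(params["alpha_props"])
        assert np.sum(pa * alphas) == pytest.approx(1.0)
        assert len(rates) == 9
        assert props.sum() == pytest.approx(1.0)


class TestFits:
    def test_m3_k1_equals_m0(self):
        data = small_alignment(seed=9, n_sites=60)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        m0 = cd.fit_model(data, tree, "M0", restarts=2, tol=1e-10)
        m3 = cd.fit_model(data, tree, "M3", restarts=2, tol=1e-10,
                          options={"m3_classes": 1})
        assert m3.log_likelihood == pytest.approx(
            m0.log_likelihood, abs=1e-3
        )

    def test_m8_at_least_m7(self):
        data = small_alignment(seed=10, n_sites=60)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        m7 = cd.fit_model(data, tree, "M7", restarts=1)
        m8 = cd.fit_model(data, tree, "M8", restarts=3, tol=1e-8)
        assert m8.log_likelihood >= m7.log_likelihood - 1e-4

    def test_identical_sequences_flagged(self):
        codons = np.tile(
            np.array([0, 5, 10, 20, 30, 40]), (3, 1)
        )
        data = cd.CodonAlignment(taxa=["t1", "t2", "t3"], codons=codons)
        fit = cd.fit_model(data, "(t1:0.1,t2:0.1,t3:0.1);", "M0", restarts=1)
        assert any("unidentifiable" in f for f in fit.flags)
        # likelihood at t ~ 0 is just sum log pi over the shared sequence
        assert fit.log_likelihood == pytest.approx(
            cd.degenerate_loglik(data, data.f3x4()), abs=1e-2
        )

    def test_tree_taxa_mismatch(self):
        data = small_alignment()
        with pytest.raises(cd.CodonDataError):
            cd.fit_model(data, "(a:0.1,b:0.1,c:0.1);", "M0")


class TestLRT:
    def test_chi_square_p(self):
        data = small_alignment(seed=11, n_sites=50)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        m0 = cd.fit_model(data, tree, "M0", restarts=1)
        m3 = cd.fit_model(data, tree, "M3", restarts=1)
        res = cd.lrt(m0, m3, 4)
        from scipy import stats

        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, 4)
        )

    def test_negative_within_tolerance_clamped(self):
        data = small_alignment(seed=12, n_sites=30)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        fit = cd.fit_model(data, tree, "M0", restarts=1)
        import copy

        worse = copy.copy(fit)
        worse.log_likelihood = fit.log_likelihood - 1e-5
        res = cd.lrt(fit, worse, 1)
        assert res.statistic == 0.0
        assert any("clamped" in f for f in res.flags)

    def test_different_data_rejected(self):
        d1 = small_alignment(seed=1)
        d2 = small_alignment(seed=2)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        f1 = cd.fit_model(d1, tree, "M0", restarts=1)
        f2 = cd.fit_model(d2, tree, "M0", restarts=1)
        with pytest.raises(ValueError):
            cd.lrt(f1, f2, 4)


class TestPosteriors:
    def test_rows_sum_to_one(self):
        data = small_alignment(seed=13, n_sites=40)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        m3 = cd.fit_model(data, tree, "M3", restarts=1)
        post = m3.posteriors()
        assert post.shape == (40, 3)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_m8_positive_class_is_last(self):
        data = small_alignment(seed=14, n_sites=40)
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        m8 = cd.fit_model(data, tree, "M8", restarts=1)
        res = cd.site_posteriors(m8)
        assert res["positive_class_columns"] == [10]


class TestBuildCodonData:
    def _locus(self, rows):
        ann = RegionAnnotation(
            [
                Segment("f", 1, 2, "flank"),
                Segment("e", 3, 8, "exon", 0),
                Segment("i", 9, 12, "intron"),
            ]
        )
        return make_locus(rows, annotation=ann)

    def test_extraction(self):
        rows = ["GGATGAAATTTT", "GGATGAAGTTTT"]
        data, nc = cd.build_codon_data(self._locus(rows))
        assert data.n_sites == 2
        assert data.codons[0, 0] == cd.CODON_INDEX["ATG"]
        assert data.codons[1, 1] == cd.CODON_INDEX["AAG"]
        assert nc.n_sites == 6  # 2 flank + 4 intron columns

    def test_stop_codon_names_taxon_and_position(self):
        rows = ["GGATGTAATTTT", "GGATGAAATTTT"]
        with pytest.raises(cd.CodonDataError, match="s1") as err:
            cd.build_codon_data(self._locus(rows))
        assert "TAA" in str(err.value)

    def test_gap_codon_column_dropped_whole(self):
        rows = ["GGATGA-ATTTT", "GGATGAAATTTT"]
        data, _ = cd.build_codon_data(self._locus(rows))
        assert data.n_sites == 1  # second codon dropped entirely

    def test_f3x4_valid_distribution(self):
        data = small_alignment()
        pi = data.f3x4()
        assert pi.shape == (61,)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()


class TestZetaModels:
    def _data(self):
        data = small_alignment(seed=20, n_sites=50)
        rng = np.random.default_rng(1)
        base = rng.integers(0, 4, size=60)
        sites = np.tile(base, (3, 1))
        for i in range(3):
            idx = rng.choice(60, size=3, replace=False)
            sites[i, idx] = (sites[i, idx] + 1) % 4
        nc = cd.NucAlignment(taxa=data.taxa, sites=sites)
        return data, nc

    def test_null_nested_in_alt(self):
        data, nc = self._data()
        tree = "(t1:0.1,t2:0.15,t3:0.2);"
        null = cd.fit_model(data, tree, "ZetaNull", noncoding=nc, restarts=1)
        alt = cd.fit_model(data, tree, "ZetaAlt", noncoding=nc, restarts=1)
        assert alt.log_likelihood >= null.log_likelihood - 1e-4
        assert null.params["zeta1"] == 1.0
        assert alt.params["zeta1"] >= 1.0

    def test_requires_noncoding(self):
        data, _ = self._data()
        with pytest.raises(cd.CodonDataError):
            cd.fit_model(data, "(t1:0.1,t2:0.15,t3:0.2);", "ZetaNull")
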