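import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit

import corb
from corb.estimate import IntegrationConfig, constrained_sigma_update
from corb.model_core import build_spec, make_pattern


@pytest.fixture(scope="module")
def tiny_rtm_data():
    """50 persons, 6 items, D=3 orthogonal truth."""
    s = corb.make_clear_structure(2, 3)
    Sigma = np.diag([1.0, 0.7, 0.9])
    beta = np.linspace(-1, 1, 6)
    data, theta = corb.generate_responses(s, beta, Sigma, 50, seed=9)
    return s, data, beta, Sigma


class TestIntegrationConfig:
    def test_gh_weights_normalized(self):
        z, logw = IntegrationConfig(scheme="gauss_hermite_product").resolve(2)
        assert z.shape == (225, 2)
        assert np.exp(logw).sum() == pytest.approx(1.0)
        # second moment of the rule reproduces the standard normal
        assert (np.exp(logw)[:, None] * z**2).sum(axis=0) == pytest.approx(
            np.ones(2), abs=1e-10
        )

    def test_qmc_reproducible_and_sized(self):
        c = IntegrationConfig(scheme="qmc", n_points=256, seed=5)
        z1, _ = c.resolve(4)
        z2, _ = c.resolve(4)
        assert z1.shape == (256, 4)
        assert np.array_equal(z1, z2)
        z3, _ = IntegrationConfig(scheme="qmc", n_points=256, seed=6).resolve(4)
        assert not np.array_equal(z1, z3)

    def test_auto_switches_scheme(self):
        assert IntegrationConfig().describe(3)["scheme"] == "gauss_hermite_product"
        assert IntegrationConfig().describe(4)["scheme"] == "qmc"

    def test_product_limited_to_low_dim(self):
        with pytest.raises(ValueError):
            IntegrationConfig(scheme="gauss_hermite_product").resolve(5)


class TestConstrainedSigmaUpdate:
    def test_free_pattern_returns_moment_matrix(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        M = A @ A.T + 0.5 * np.eye(4)
        S = constrained_sigma_update(M, make_pattern("CORB", 4))
        assert np.allclose(S, M)

    def test_diagonal_pattern_returns_diagonal(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((3, 3))
        M = A @ A.T + 0.5 * np.eye(3)
        S = constrained_sigma_update(M, make_pattern("RTM", 3))
        assert np.allclose(S, np.diag(np.diag(M)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_etm_matches_brute_force_optimizer(self, seed):
        """Fisher scoring vs an independent numerical optimizer of the
        constrained normal likelihood, random D=3 moment matrices."""
        rng = np.random.default_rng(seed)
        # moment matrices on the latent-variance scale of the study
        M = corb.random_pd_cov(3, variance_range=(0.3, 4.0), seed=rng)
        pattern = make_pattern("ETM", 3)
        S = constrained_sigma_update(M, pattern)
        assert S[1, 2] == 0.0

        idx = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2)]

        def unpack(v):
            Sig = np.zeros((3, 3))
            for val, (i, j) in zip(v, idx):
                Sig[i, j] = Sig[j, i] = val
            return Sig

        def negll(v):
            Sig = unpack(v)
            try:
                L = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return 1e10
            logdet = 2 * np.log(np.diag(L)).sum()
            return logdet + np.trace(np.linalg.solve(Sig, M))

        x0 = [M[i, j] for i, j in idx]
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert np.abs(S - unpack(res.x)).max() < 1e-6

    def test_srm_tie_produces_equal_variances(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        M = A @ A.T + 0.3 * np.eye(3)
        S = constrained_sigma_update(M, make_pattern("SRM", 3))
        assert S[1, 1] == pytest.approx(S[2, 2])
        assert S[0, 1] == 0.0 and S[0, 2] == 0.0

    def test_floor_reported(self):
        M = np.diag([1.0, -0.5, 1.0])  # invalid moment matrix forces flooring
        S, info = constrained_sigma_update(
            M, make_pattern("RTM", 3), return_info=True
        )
        assert info["floored"]
        assert np.linalg.eigvalsh(S).min() >= 1e-6 - 1e-12


class TestFit:
    def test_rtm_matches_direct_optimizer(self, tiny_rtm_data):
        """EM solution vs direct numerical maximization of the marginal
        likelihood (same quadrature), 50 persons, 6 items, D=3."""
        s, data, *_ = tiny_rtm_data
        spec = build_spec(s, "RTM", reduced=False)
        integ = IntegrationConfig(nodes_per_dim=11)
        res = corb.fit(data, spec, integration=integ, tol=1e-8, param_tol=1e-6)
        assert res.converged

        z, logw = integ.resolve(3)

        def negll(x):
            beta, logv = x[:6], x[6:]
            Sigma = np.diag(np.exp(logv))
            return -corb.marginal_loglik(data, beta, Sigma, spec, integ)

        x0 = np.concatenate([np.zeros(6), np.zeros(3)])
        opt = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"maxiter": 40000, "xatol": 1e-8,
                                         "fatol": 1e-10, "adaptive": True})
        assert res.loglik == pytest.approx(-opt.fun, abs=1e-3)

    def test_em_monotone_loglik(self, tiny_rtm_data):
        s, data, *_ = tiny_rtm_data
        spec = build_spec(s, "RTM", reduced=False)
        res = corb.fit(data, spec, accelerate=False, max_iter=200)
        h = np.array(res.history)
        assert (np.diff(h) >= -1e-6).all()

    def test_reproducible_bit_for_bit(self, small_corb_fixture):
        s, data, *_ = small_corb_fixture
        spec = build_spec(s, "CORB")
        integ = IntegrationConfig(scheme="qmc", n_points=512, seed=3)
        r1 = corb.fit(data, spec, integration=integ, max_iter=40)
        r2 = corb.fit(data, spec, integration=integ, max_iter=40)
        assert r1.loglik == r2.loglik
        assert np.array_equal(r1.Sigma_hat, r2.Sigma_hat)
        assert np.array_equal(r1.beta_hat, r2.beta_hat)

    def test_partition_invariance_of_deviance(self, small_corb_fixture):
        """Two different witness partitions parameterize the same model."""
        s, data, *_ = small_corb_fixture
        B = corb.scoring_matrix(s)
        rep = corb.check_identification(B)
        items1 = [x[0] for x in rep.partition.sets]
        # a different independent row set: replace the last anchor
        from corb.identify import ItemPartition, cmatrix
        alt = None
        for j in range(s.n_items - 1, -1, -1):
            if j in items1:
                continue
            cand = items1[:-1] + [j]
            if abs(np.linalg.det(cmatrix(B, ItemPartition.singletons(cand)))) > 1e-9:
                alt = cand
                break
        assert alt is not None
        spec1 = build_spec(s, "CORB", partition=ItemPartition.singletons(items1))
        spec2 = build_spec(s, "CORB", partition=ItemPartition.singletons(alt))
        integ = IntegrationConfig(scheme="gauss_hermite_product", nodes_per_dim=7)
        f1 = corb.fit(data, spec1, integration=integ, tol=1e-8, param_tol=1e-6,
                      max_iter=800)
        f2 = corb.fit(data, spec2, integration=integ, tol=1e-8, param_tol=1e-6,
                      max_iter=800)
        assert f1.deviance == pytest.approx(f2.deviance, abs=1e-3)
        # and the expanded difficulties agree on the common scale
        assert np.abs(f1.beta_hat - f2.beta_hat).max() < 5e-3

    def test_sorb_nests_rtm(self, small_corb_fixture):
        """The subdimensional oblique model frees the specific block, so it
        can only improve on the orthogonal testlet model."""
        s, data, *_ = small_corb_fixture
        integ = IntegrationConfig(scheme="qmc", n_points=512, seed=4)
        fits = corb.fit_hierarchy(
            data, {f: build_spec(s, f) for f in ("RTM", "SORB")},
            integration=integ, max_iter=300,
        )
        assert fits["SORB"].deviance <= fits["RTM"].deviance + 1e-3
        Sig = fits["SORB"].Sigma_hat
        assert np.allclose(Sig[0, 1:], 0.0)  # general orthogonal to specifics
        chi2, df, p = corb.lrt(fits["SORB"], fits["RTM"])
        assert df == 3

    def test_refuses_unidentified_spec(self, clear33):
        from corb.structures import full_design_matrix, scoring_matrix
        from corb.model_core import ModelSpec, make_pattern
        B = scoring_matrix(clear33)
        spec = ModelSpec("CORB", B, full_design_matrix(9), make_pattern("CORB", 4))
        data, _ = corb.generate_responses(clear33, np.zeros(9), np.eye(4), 30, seed=0)
        with pytest.raises(ValueError, match="not identified"):
            corb.fit(data, spec)

    def test_missing_data_handled(self, small_corb_fixture):
        s, data, *_ = small_corb_fixture
        X = data.X.copy()
        rng = np.random.default_rng(0)
        mask = rng.random(X.shape) < 0.1
        X[mask] = np.nan
        data_miss = corb.ResponseData(X)
        spec = build_spec(s, "CORB")
        res = corb.fit(data_miss, spec,
                       integration=IntegrationConfig(scheme="qmc", n_points=512, seed=1),
                       max_iter=300)
        assert np.isfinite(res.loglik)
        assert res.loglik > -np.inf


class TestEAP:
    def test_single_item_matches_grid_oracle(self):
        """D=1-like check via a 2-dimensional RTM with one informative
        response, against a dense-grid posterior mean."""
        s = corb.make_clear_structure(2, 1)
        spec = build_spec(s, "RTM", reduced=False)
        data = corb.ResponseData(np.array([[1.0, 1.0]]))
        from corb.estimate import FitResult
        res = FitResult(
            spec=spec, beta_hat=np.zeros(2), beta_reduced=np.zeros(2),
            mu_hat=np.zeros(3), Sigma_hat=np.diag([1.0, 1.0, 1.0]),
            loglik=0.0, n_free=5, n_persons=1, converged=True, n_iter=1,
        )
        table = corb.eap_scores(data, res,
                                IntegrationConfig(nodes_per_dim=31))
        # grid oracle for the general dimension: posterior over theta_g with
        # the two specifics integrated out on a dense grid
        grid = np.linspace(-6, 6, 201)
        G, S1, S2 = np.meshgrid(grid, grid, grid, indexing="ij")
        like = expit(G + S1) * expit(G + S2)
        prior = np.exp(-0.5 * (G**2 + S1**2 + S2**2))
        post = like * prior
        eap_g = (G * post).sum() / post.sum()
        assert table.eap[0, 0] == pytest.approx(eap_g, abs=1e-4)

    def test_complement_symmetry(self, small_corb_fixture):
        """Flipping all responses with zero difficulties negates the EAPs."""
        s, *_ = small_corb_fixture
        spec = build_spec(s, "RTM", reduced=False)
        Sigma = np.diag([1.0, 0.8, 0.9, 1.1])
        from corb.estimate import FitResult
        res = FitResult(
            spec=spec, beta_hat=np.zeros(s.n_items),
            beta_reduced=np.zeros(s.n_items), mu_hat=np.zeros(4),
            Sigma_hat=Sigma, loglik=0.0, n_free=1, n_persons=4,
            converged=True, n_iter=1,
        )
        rng = np.random.default_rng(4)
        X = (rng.random((4, s.n_items)) < 0.5).astype(float)
        # symmetric quadrature nodes make the symmetry exact
        integ = IntegrationConfig(scheme="gauss_hermite_product", nodes_per_dim=7)
        t1 = corb.eap_scores(corb.ResponseData(X), res, integ)
        t2 = corb.eap_scores(corb.ResponseData(1.0 - X), res, integ)
        assert np.allclose(t1.eap, -t2.eap, atol=1e-10)

    def test_eap_shrinks_with_vanishing_variance(self):
        s = corb.make_clear_structure(2, 2)
        spec = build_spec(s, "RTM", reduced=False)
        X = np.ones((1, 4))
        from corb.estimate import FitResult
        norms = []
        for v in (1.0, 0.1, 0.01):
            res = FitResult(
                spec=spec, beta_hat=np.zeros(4), beta_reduced=np.zeros(4),
                mu_hat=np.zeros(3), Sigma_hat=np.eye(3) * v, loglik=0.0,
                n_free=1, n_persons=1, converged=True, n_iter=1,
            )
            t = corb.eap_scores(corb.ResponseData(X), res)
            norms.append(np.abs(t.eap).max())
        assert norms[0] > norms[1] > norms[2]

    def test_reliability_limits(self):
        pv = np.ones((10, 2))
        # no information: posterior variance equals the prior variance
        rel = corb.eap_reliability(
            corb.EAPTable(np.zeros((10, 2)), np.sqrt(pv), np.zeros(2)),
            np.diag([1.0, 1.0]),
        )
        assert np.allclose(rel, 0.0)
        rel2 = corb.eap_reliability(
            corb.EAPTable(np.zeros((10, 2)), np.zeros((10, 2)), np.zeros(2)),
            np.diag([1.0, 1.0]),
        )
        assert np.allclose(rel2, 1.0)

    def test_longer_tests_not_less_reliable(self):
        """Nested designs: more items per factor cannot reduce reliability.

        Scored at the true generating parameters so the comparison reflects
        the information content of the designs, not estimation noise."""
        from corb.estimate import FitResult
        rels = []
        Sigma = np.diag([1.0, 0.8, 0.9])
        for m in (5, 10):
            s = corb.make_g_structure(2, m, 1)
            beta = np.linspace(-1.5, 1.5, s.n_items)
            data, _ = corb.generate_responses(s, beta, Sigma, 300, seed=8)
            spec = build_spec(s, "RTM", reduced=False)
            res = FitResult(
                spec=spec, beta_hat=beta, beta_reduced=beta,
                mu_hat=np.zeros(3), Sigma_hat=Sigma, loglik=0.0,
                n_free=1, n_persons=300, converged=True, n_iter=1,
            )
            rels.append(corb.eap_scores(data, res).reliability)
        assert (rels[1] >= rels[0]).all()


class TestLrt:
    def test_df_for_hierarchy(self, small_corb_fixture):
        s, data, *_ = small_corb_fixture
        integ = IntegrationConfig(scheme="qmc", n_points=512, seed=2)
        specs = {f: build_spec(s, f) for f in ("RTM", "ETM", "CORB")}
        fits = corb.fit_hierarchy(data, specs, integration=integ, max_iter=300)
        chi2, df, p = corb.lrt(fits["CORB"], fits["RTM"])
        assert df == 6 and chi2 >= 0 and 0 <= p <= 1
        chi2, df, p = corb.lrt(fits["CORB"], fits["ETM"])
        assert df == 3
        chi2, df, p = corb.lrt(fits["CORB"], fits["CORB"])
        assert chi2 == pytest.approx(0.0, abs=1e-9) and p == 1.0

    def test_gsm_not_nested(self, small_corb_fixture):
        s, data, *_ = small_corb_fixture
        # strip to the clear part so the subdimension model applies
        clear = corb.make_clear_structure(3, 3)
        datac = corb.ResponseData(data.X[:, 2:])
        integ = IntegrationConfig(seed=2)
        g = corb.fit(datac, build_spec(clear, "GSM", excluded=3),
                     integration=integ, max_iter=150)
        r = corb.fit(datac, build_spec(clear, "RTM"), integration=integ,
                     max_iter=150)
        with pytest.raises(ValueError, match="information criteria"):
            corb.lrt(r, g)


class TestGsmGather:
    def test_gather_covers_all_entries(self):
        s = corb.make_clear_structure(3, 4)
        Sigma = np.diag([1.0, 0.9, 0.7, 1.1])
        beta = np.linspace(-1, 1, s.n_items)
        data, _ = corb.generate_responses(s, beta, Sigma, 400, seed=12)
        fits = [
            corb.fit(data, build_spec(s, "GSM", excluded=k),
                     integration=IntegrationConfig(seed=1), max_iter=300)
            for k in (1, 2, 3)
        ]
        g = corb.gsm_gather(fits)
        assert g.Sigma.shape == (4, 4)
        assert (g.entry_counts[np.ix_([1, 2, 3], [1, 2, 3])] > 0).all()
        assert g.max_duplicate_discrepancy < 0.2
        assert g.max_implied_discrepancy < 0.5

    def test_missing_pair_detected(self):
        s = corb.make_clear_structure(4, 2)
        Sigma = np.eye(5)
        data, _ = corb.generate_responses(s, np.zeros(8), Sigma, 150, seed=3)
        fits = [
            corb.fit(data, build_spec(s, "GSM", excluded=k),
                     integration=IntegrationConfig(scheme="qmc",
                                                   n_points=256, seed=1),
                     max_iter=60)
            for k in (1, 1, 2)
        ]
        with pytest.raises(ValueError, match="distinct"):
            corb.gsm_gather(fits)
        with pytest.raises(ValueError, match="not covered"):
            corb.gsm_gather(fits[1:])
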