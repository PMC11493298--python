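"""OLS/GLS estimators, eigenvector augmentation, REML, association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from structcorr import (
    CovarianceMatrix,
    association_test,
    augment_with_eigenvectors,
    build_felsenstein_tree,
    fit_gls,
    fit_ols,
    reml_profile_loglik,
    reml_variance_components,
    shared_path_matrix,
    simulate_bm,
    simulate_pure_birth,
)


def random_psd(rng, n):
    A = rng.normal(size=(n, n))
    M = A @ A.T
    return CovarianceMatrix((M + M.T) / 2, [f"s{i}" for i in range(n)])


def spectral_slope(sigma, x, y, J=0, weighted=False):
    """The truncated (weighted) spectral sum for a single-predictor fit."""
    lam, V = sigma.eigenvalues, sigma.eigenvectors
    xr, yr = V.T @ x, V.T @ y
    w = 1.0 / lam if weighted else np.ones_like(lam)
    return np.sum((w * xr * yr)[J:]) / np.sum((w * xr * xr)[J:])


class TestOLS:
    def test_exact_fit(self):
        x = np.arange(10.0)
        y = 2.0 * x
        f = fit_ols(y, pd.DataFrame({"intercept": np.ones(10), "x": x}))
        assert f.params["x"] == pytest.approx(2.0)
        assert f.scale == pytest.approx(0.0, abs=1e-20)

    def test_duplicated_column_rank_error(self, rng):
        x = rng.normal(size=12)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ols(rng.normal(size=12), X)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(size=25)
        X = sm.add_constant(x)
        ours, theirs = fit_ols(y, X), sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params, theirs.params)
        np.testing.assert_allclose(ours.bse, theirs.bse)
        np.testing.assert_allclose(ours.pvalues, theirs.pvalues)


class TestSpectralIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_four_forms(self, seed):
        """Matrix OLS/GLS with and without eigenvector covariates equal the
        corresponding (truncated, weighted) spectral sums exactly."""
        rng = np.random.default_rng(seed)
        n, J = 30, 4
        sigma = random_psd(rng, n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert fit_ols(y, x).params.iloc[0] == pytest.approx(
            spectral_slope(sigma, x, y), abs=1e-8
        )
        assert fit_gls(y, x, sigma).params.iloc[0] == pytest.approx(
            spectral_slope(sigma, x, y, weighted=True), abs=1e-8
        )
        Xa = augment_with_eigenvectors(x, sigma, J)
        assert fit_ols(y, Xa).params.iloc[0] == pytest.approx(
            spectral_slope(sigma, x, y, J=J), abs=1e-8
        )
        assert fit_gls(y, Xa, sigma).params.iloc[0] == pytest.approx(
            spectral_slope(sigma, x, y, J=J, weighted=True), abs=1e-8
        )


class TestGLS:
    def test_identity_sigma_equals_ols(self, rng):
        n = 20
        sigma = CovarianceMatrix(np.eye(n), [f"s{i}" for i in range(n)])
        x, y = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame({"i": np.ones(n), "x": x})
        a, b = fit_ols(y, X), fit_gls(y, X, sigma)
        np.testing.assert_allclose(a.params, b.params, atol=1e-10)
        np.testing.assert_allclose(a.pvalues, b.pvalues, atol=1e-10)

    def test_large_environmental_noise_approaches_ols(self, rng):
        n = 25
        sigma = random_psd(rng, n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        X = pd.DataFrame({"i": np.ones(n), "x": x})
        ols = fit_ols(y, X).params
        gls = fit_gls(y, X, sigma, sigma_g2=1.0, sigma_e2=1e8).params
        np.testing.assert_allclose(gls, ols, rtol=1e-4)

    def test_deep_divergence_inflates_se_of_between_clade_predictor(self):
        tree = build_felsenstein_tree(20, 0.5, 2.0)
        sigma = shared_path_matrix(tree)
        c1 = np.array([1.0 if l.startswith("c1_") else -1.0 for l in sigma.labels])
        rng = np.random.default_rng(3)
        y = simulate_bm(tree, 1.0, rng).to_numpy()
        X = pd.DataFrame({"i": np.ones(40), "x": c1})
        assert fit_gls(y, X, sigma).bse["x"] > fit_ols(y, X).bse["x"]

    def test_eigenvector_orthogonal_predictor_unchanged(self, rng):
        """Adding eigenvector covariates leaves the slope alone when x is
        orthogonal to the eigenvectors added (exact in OLS)."""
        n, J = 20, 3
        sigma = random_psd(rng, n)
        V = sigma.eigenvectors
        x = V[:, J:] @ rng.normal(size=n - J)  # orthogonal to v_1..v_J
        y = rng.normal(size=n)
        b0 = fit_ols(y, x).params.iloc[0]
        bJ = fit_ols(y, augment_with_eigenvectors(x, sigma, J)).params.iloc[0]
        assert bJ == pytest.approx(b0, abs=1e-10)


class TestAugment:
    def test_zero_eigenvectors_unchanged(self, rng):
        sigma = random_psd(rng, 10)
        x = rng.normal(size=10)
        out = augment_with_eigenvectors(x, sigma, 0)
        assert out.shape == (10, 1)

    def test_too_many_eigenvectors_rejected(self, rng):
        sigma = random_psd(rng, 10)
        with pytest.raises(ValueError):
            augment_with_eigenvectors(rng.normal(size=10), sigma, 10)


class TestREML:
    def tree_sigma(self, n=100, seed=5):
        return shared_path_matrix(simulate_pure_birth(n, 1.0, np.random.default_rng(seed)))

    def sample(self, sigma, sg2, se2, rng):
        n = sigma.n
        lam, V = sigma.eigenvalues, sigma.eigenvectors
        z = V @ (np.sqrt(sg2 * lam) * rng.normal(size=n))
        return z + np.sqrt(se2) * rng.normal(size=n)

    def test_pure_genetic_data_hits_lower_boundary(self):
        sigma = self.tree_sigma()
        rng = np.random.default_rng(6)
        y = self.sample(sigma, 1.0, 0.0, rng)
        res = reml_variance_components(y, np.ones((sigma.n, 1)), sigma)
        assert res.boundary and res.phi == pytest.approx(1e-6)
        assert res.sigma_e2 / res.sigma_g2 < 1e-5

    def test_recovery_and_optimality(self):
        sigma = self.tree_sigma()
        rng = np.random.default_rng(7)
        X = np.ones((sigma.n, 1))
        ests = []
        for _ in range(40):
            y = self.sample(sigma, 1.0, 1.0, rng)
            res = reml_variance_components(y, X, sigma)
            ests.append((res.sigma_g2, res.sigma_e2))
            for phi in np.exp(rng.uniform(np.log(1e-6), np.log(1e6), size=5)):
                assert res.loglik >= reml_profile_loglik(y, X, sigma, phi) - 1e-6
        med = np.median(ests, axis=0)
        assert med[0] == pytest.approx(1.0, rel=0.3)
        assert med[1] == pytest.approx(1.0, rel=0.3)

    def test_identity_sigma_not_identifiable(self, rng):
        sigma = CovarianceMatrix(2.0 * np.eye(30), [f"s{i}" for i in range(30)])
        with pytest.raises(ValueError, match="identifiable"):
            reml_variance_components(rng.normal(size=30), np.ones((30, 1)), sigma)


class TestAssociationTest:
    def test_ols_matches_fit_ols(self, rng):
        n = 30
        x, y = rng.normal(size=n), rng.normal(size=n)
        f1 = association_test(y, x, None, J=0, method="ols")
        f2 = fit_ols(y, pd.DataFrame({"intercept": np.ones(n), "x": x}))
        assert f1.pvalues["x"] == pytest.approx(f2.pvalues["x"])

    def test_predictor_equal_to_covariate_rank_error(self, rng):
        sigma = random_psd(rng, 20)
        y = rng.normal(size=20)
        x = sigma.eigenvectors[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            association_test(y, x, sigma, J=1, method="gls")

    def test_series_alignment_and_label_mismatch(self, rng):
        sigma = random_psd(rng, 5)
        y = pd.Series(rng.normal(size=5), index=sigma.labels[::-1])
        x = pd.Series(rng.normal(size=5), index=sigma.labels)
        association_test(y, x, sigma, J=0, method="gls")  # aligned, no raise
        bad = pd.Series(rng.normal(size=5), index=list("vwxyz"))
        with pytest.raises(KeyError):
            association_test(bad, x, sigma, J=0, method="gls")

    def test_excessive_J_rejected(self, rng):
        sigma = random_psd(rng, 10)
        with pytest.raises(ValueError, match="J"):
            association_test(
                rng.normal(size=10), rng.normal(size=10), sigma, J=8, method="gls"
            )

    def test_null_gls_pvalues_uniform(self):
        """Correctly specified PGLS null: slope p-values are uniform."""
        tree = simulate_pure_birth(40, 1.0, np.random.default_rng(8))
        sigma = shared_path_matrix(tree)
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            x = simulate_bm(tree, 1.0, rng)
            y = simulate_bm(tree, 1.0, rng)
            ps.append(association_test(y, x, sigma, J=0, method="gls").pvalues["x"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("n", [50, 200])
    def test_consistency_under_true_effect(self, n):
        """All four corrections recover a true slope on average."""
        tree = simulate_pure_birth(n, 1.0, np.random.default_rng(10))
        sigma = shared_path_matrix(tree)
        rng = np.random.default_rng(11)
        beta = 0.7
        est = {m: [] for m in ["ols", "gls"]}
        est_aug = {m: [] for m in ["ols", "gls"]}
        for _ in range(30):
            x = simulate_bm(tree, 1.0, rng)
            y = beta * x + simulate_bm(tree, 1.0, rng)
            for m in est:
                est[m].append(association_test(y, x, sigma, 0, m).params["x"])
                est_aug[m].append(association_test(y, x, sigma, 2, m).params["x"])
        for m in est:
            assert np.mean(est[m]) == pytest.approx(beta, abs=0.15)
            assert np.mean(est_aug[m]) == pytest.approx(beta, abs=0.15)

    def test_lmm_estimates_components(self):
        tree = simulate_pure_birth(80, 1.0, np.random.default_rng(12))
        sigma = shared_path_matrix(tree)
        rng = np.random.default_rng(13)
        lam, V = sigma.eigenvalues, sigma.eigenvectors
        y = V @ (np.sqrt(lam) * rng.normal(size=80)) + rng.normal(size=80)
        x = rng.normal(size=80)
        fit = association_test(y, x, sigma, J=0, method="lmm")
        assert fit.method == "lmm"
        assert fit.sigma_g2 is not None and fit.sigma_e2 is not None
        assert 0.2 < fit.sigma_g2 < 5.0
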