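import numpy as np
import pytest

from longde.design import StudyDesign
from longde.gee import fit_gee_exchangeable, robust_sandwich, small_sample_covariance
from longde.simulate import GeneParams, simulate_dataset


def _sim_gene(design, alpha=0.2, sigma2_b=0.3, seed=5, mean=80.0, beta7=1.0):
    beta = np.zeros(design.n_coef)
    beta[0] = np.log(mean)
    if design.n_coef == 8:
        beta[7] = beta7
    p = GeneParams(beta=beta, alpha=alpha, sigma2_b=sigma2_b)
    return simulate_dataset([p], design, seed=seed).counts[0]


class TestFit:
    def test_one_observation_per_subject_equals_glm(self, rng):
        # exchangeable correlation is vacuous with singleton clusters
        import statsmodels.api as sm

        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1]))
        fit = fit_gee_exchangeable(y, (X, np.arange(n)))
        glm = sm.GLM(np.asarray(y, float), X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coef, glm.params, atol=1e-8)

    def test_intercept_only_mean_matching(self):
        X = np.ones((2, 1))
        fit = fit_gee_exchangeable([1, 3], (X, np.array([0, 1])))
        assert fit.coef[0] == pytest.approx(np.log(2.0))

    def test_matches_statsmodels_gee(self, design10):
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable
        from statsmodels.genmod.families import Poisson

        y = _sim_gene(design10)
        fit = fit_gee_exchangeable(y, design10)
        ref = sm.GEE(
            np.asarray(y, float), design10.design_matrix(),
            groups=design10.subject_index, family=Poisson(),
            cov_struct=Exchangeable(),
        ).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.robust_cov, ref.cov_robust, atol=1e-10)

    def test_rho_matches_residual_icc(self, design10):
        # exchangeable rho tracks the intraclass correlation of Pearson residuals
        y = _sim_gene(design10, sigma2_b=0.5, seed=6)
        fit = fit_gee_exchangeable(y, design10)
        mu = np.exp(design10.design_matrix() @ fit.coef)
        e = (y - mu) / np.sqrt(fit.phi * mu)
        E = e.reshape(design10.n_subjects, 4)
        num, cnt = 0.0, 0
        for i in range(E.shape[0]):
            for j in range(4):
                for k in range(j + 1, 4):
                    num += E[i, j] * E[i, k]
                    cnt += 1
        icc = num / cnt
        assert fit.rho == pytest.approx(icc, abs=0.1)

    def test_rho_within_valid_range(self, design5):
        for seed in range(4):
            fit = fit_gee_exchangeable(_sim_gene(design5, seed=seed), design5)
            assert -1 / 3 < fit.rho < 1
            assert fit.phi > 0


class TestSandwich:
    def test_hand_computed_two_subject_toy(self):
        # intercept-only Poisson, counts (1, 3): bread 4, meat 2, var 2/16
        X = np.ones((2, 1))
        fit = fit_gee_exchangeable([1, 3], (X, np.array([0, 1])))
        assert fit.robust_cov[0, 0] == pytest.approx(0.125)

    def test_zero_residuals_give_zero_covariance(self):
        X = np.ones((4, 1))
        fit = fit_gee_exchangeable([5, 5, 5, 5], (X, np.arange(4)))
        assert robust_sandwich(fit)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_numeric_score_outer_product(self, rng):
        # sandwich meat equals the outer product of per-cluster numeric
        # score contributions on a 3-subject toy
        X = np.column_stack([np.ones(6), [0, 0, 1, 1, 0, 1.0]])
        subj = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([3, 4, 6, 9, 2, 8])
        fit = fit_gee_exchangeable(y, (X, subj))
        mu = np.exp(X @ fit.coef)
        rho, phi = fit.rho, fit.phi
        A = np.zeros((2, 2))
        M = np.zeros((2, 2))
        R = (1 - rho) * np.eye(2) + rho
        Rinv = np.linalg.inv(R)
        for i in range(3):
            sl = slice(2 * i, 2 * i + 2)
            D = mu[sl, None] * X[sl]
            Vinv = (
                np.diag(1 / np.sqrt(mu[sl])) @ Rinv @ np.diag(1 / np.sqrt(mu[sl]))
            ) / phi
            s = D.T @ Vinv @ (y[sl] - mu[sl])
            A += D.T @ Vinv @ D
            M += np.outer(s, s)
        expected = np.linalg.inv(A) @ M @ np.linalg.inv(A)
        np.testing.assert_allclose(fit.robust_cov, expected, atol=1e-6)


class TestSmallSampleCorrection:
    def test_inflates_variances_on_small_toys(self):
        d = StudyDesign.balanced(2)  # 4 subjects
        inflated = 0
        total = 0
        for seed in range(6):
            y = _sim_gene(d, seed=seed, sigma2_b=0.2, beta7=0.0)
            fit = fit_gee_exchangeable(y, d)
            if fit.corrected_cov is None:
                continue
            ratio = np.diag(fit.corrected_cov) / np.diag(fit.robust_cov)
            inflated += np.sum(ratio >= 1.0)
            total += len(ratio)
        assert inflated / total > 0.8

    def test_converges_to_robust_with_many_subjects(self):
        # with many subjects the pooled, leverage-adjusted estimator and the
        # plain sandwich estimate the same quantity; individual elements are
        # MC-noisy, so compare total variance averaged over replicates
        d = StudyDesign.balanced(100)  # 200 subjects
        ratios = []
        for seed in range(5):
            y = _sim_gene(d, seed=seed, alpha=0.02, mean=30.0, sigma2_b=0.05,
                          beta7=0.0)
            fit = fit_gee_exchangeable(y, d)
            ratios.append(np.trace(fit.corrected_cov) / np.trace(fit.robust_cov))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_identical_subjects_pool_to_common_covariance(self):
        # identical clusters with identical residuals: the pooled per-subject
        # covariance reproduces each subject's own cross-product
        X = np.tile([[1.0], [1.0]], (3, 1))
        subj = np.repeat(np.arange(3), 2)
        y = np.tile([2, 6], 3)
        fit = fit_gee_exchangeable(y, (X, subj))
        # residual cross-products identical across subjects -> corrected
        # covariance = robust covariance scaled by the (I-H)^-1 inflation only
        assert fit.corrected_cov[0, 0] >= fit.robust_cov[0, 0]

    def test_coef_invariant_across_covariance_choices(self, design5):
        y = _sim_gene(design5, seed=9)
        fit = fit_gee_exchangeable(y, design5)
        # one coefficient vector, three covariances
        for which in ("naive", "robust", "wang-long"):
            cov = fit.covariance(which)
            assert cov.shape == (8, 8)
            evals = np.linalg.eigvalsh(cov)
            assert np.all(evals > -1e-8)
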