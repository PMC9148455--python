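import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as t_dist

from longde.contrasts import (
    TEST_NAMES,
    bh_adjust,
    contrast_matrix,
    f_test_satterthwaite,
    lrt_test,
    reduced_design,
    wald_chisq_test,
)
from longde.design import StudyDesign
from longde.lmm import fit_lmm_reml
from longde.results import FitResult


class TestContrastMatrices:
    def test_ranks(self):
        expected = {"between": 4, "within": 3, "interaction": 3, "global": 7}
        for name, rank in expected.items():
            spec = contrast_matrix(name)
            assert spec.rank == rank
            assert np.linalg.matrix_rank(spec.L) == rank

    def test_interaction_selects_positions_5_6_7(self):
        L = contrast_matrix("interaction").L
        expected = np.zeros((3, 8))
        expected[0, 5] = expected[1, 6] = expected[2, 7] = 1.0
        np.testing.assert_array_equal(L, expected)

    def test_within_annihilates_its_null_space(self):
        L = contrast_matrix("within").L
        beta = np.zeros(8)
        beta[2], beta[5] = 0.4, -0.4  # b2 + b5 = 0
        beta[3], beta[6] = -0.1, 0.1
        beta[4], beta[7] = 0.9, -0.9
        np.testing.assert_allclose(L @ beta, np.zeros(3), atol=1e-12)

    def test_between_spans_e1_e5_e6_e7(self):
        L = contrast_matrix("between").L
        alt = np.zeros((4, 8))
        alt[0, 1] = alt[1, 5] = alt[2, 6] = alt[3, 7] = 1.0
        assert np.linalg.matrix_rank(np.vstack([L, alt])) == 4

    def test_all_contrasts_annihilate_null_truth(self):
        beta_null = np.array([3.2, 0, 0, 0, 0, 0, 0, 0])
        for name in TEST_NAMES:
            L = contrast_matrix(name).L
            np.testing.assert_allclose(L @ beta_null, 0.0, atol=1e-12)

    def test_de_truth_detected_by_relevant_contrasts(self):
        beta_de = np.array([3.2, 0, 0, 0, 0, 1 / 3, 2 / 3, 1.0])
        for name in ("interaction", "global", "within"):
            L = contrast_matrix(name).L
            assert np.any(np.abs(L @ beta_de) > 1e-9)

    def test_reference_group_within_option(self):
        L = contrast_matrix("within", within_group="reference").L
        expected = np.zeros((3, 8))
        expected[0, 2] = expected[1, 3] = expected[2, 4] = 1.0
        np.testing.assert_array_equal(L, expected)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            contrast_matrix("sideways")


class TestReducedDesign:
    def test_interaction_reduction_drops_interaction_columns(self):
        d = StudyDesign.balanced(3)
        X = d.design_matrix()
        L = contrast_matrix("interaction").L
        Xr = reduced_design(X, L)
        assert Xr.shape == (X.shape[0], 5)
        # column space of Xr equals span of the non-interaction columns
        both = np.hstack([Xr, X[:, :5]])
        assert np.linalg.matrix_rank(both) == 5

    def test_reduction_nests_inside_full_model(self):
        d = StudyDesign.balanced(3)
        X = d.design_matrix()
        for name in TEST_NAMES:
            L = contrast_matrix(name).L
            Xr = reduced_design(X, L)
            assert Xr.shape[1] == 8 - L.shape[0]
            # reduced columns live in the full column space
            aug = np.linalg.matrix_rank(np.hstack([X, Xr]))
            assert aug == np.linalg.matrix_rank(X)

    def test_null_beta_means_representable_in_reduced_model(self):
        d = StudyDesign.balanced(3)
        X = d.design_matrix()
        L = contrast_matrix("between").L
        beta = np.zeros(8)
        beta[0], beta[2] = 2.0, 0.7  # satisfies L beta = 0
        Xr = reduced_design(X, L)
        target = X @ beta
        coef, res, *_ = np.linalg.lstsq(Xr, target, rcond=None)
        assert np.allclose(Xr @ coef, target, atol=1e-10)


class TestWald:
    def test_single_contrast_hand_value(self):
        tr = wald_chisq_test([2.0], np.array([[1.0]]), np.array([[1.0]]))
        assert tr.statistic == pytest.approx(4.0)
        assert tr.pvalue == pytest.approx(0.0455, abs=2e-4)

    def test_two_df_closed_form(self):
        tr = wald_chisq_test([1.0, 1.0], np.eye(2), np.eye(2))
        assert tr.statistic == pytest.approx(2.0)
        assert tr.pvalue == pytest.approx(np.exp(-1.0))

    def test_null_estimate_gives_p_one(self):
        tr = wald_chisq_test([0.0, 0.0], np.eye(2), np.eye(2))
        assert tr.statistic == 0.0 and tr.pvalue == 1.0


class TestFTest:
    def _fit(self, n=8, seed=0):
        X = np.zeros((2 * n, 2))
        X[:, 0] = 1.0
        X[1::2, 1] = 1.0
        subj = np.repeat(np.arange(n), 2)
        rng = np.random.default_rng(seed)
        y = 0.3 * X[:, 1] + rng.normal(0, 1.0, n)[subj] + rng.normal(0, 0.5, 2 * n)
        return fit_lmm_reml(y, (X, subj)), y, X, subj

    def test_f1_equals_squared_t_and_paired_t_p(self):
        from scipy.stats import ttest_rel

        fit, y, X, subj = self._fit()
        L = np.array([[0.0, 1.0]])
        tr = f_test_satterthwaite(fit, L)
        diffs = y[1::2] - y[0::2]
        t_res = ttest_rel(y[1::2], y[0::2])
        assert tr.statistic == pytest.approx(t_res.statistic**2, rel=1e-4)
        assert tr.df2 == pytest.approx(len(diffs) - 1, rel=0.02)
        assert tr.pvalue == pytest.approx(t_res.pvalue, rel=0.02)

    def test_converges_to_wald_at_large_df(self):
        fit, *_ = self._fit()
        L = np.array([[0.0, 1.0]])
        tr_f = f_test_satterthwaite(fit, L)
        # manually evaluate the F tail at huge df: approaches chi2/rank tail
        from scipy.stats import chi2, f as f_dist

        W = tr_f.statistic * 1  # rank 1
        p_chi = chi2.sf(W, 1)
        p_f_large = f_dist.sf(W, 1, 1e4)
        assert abs(p_f_large - p_chi) < 1e-3

    def test_nonconverged_fit_not_computable(self):
        bad = FitResult(method="lmm", coef=np.zeros(2), coef_cov=None,
                        sigma2_b=0, dispersion=0, loglik=np.nan, converged=False)
        tr = f_test_satterthwaite(bad, np.array([[0.0, 1.0]]))
        assert not tr.computable and np.isnan(tr.pvalue)


class TestLrt:
    def _fit(self, ll, conv=True):
        return FitResult(method="nbmm-agq", coef=np.zeros(8), coef_cov=None,
                         sigma2_b=0.1, dispersion=0.1, loglik=ll, converged=conv)

    def test_hand_value(self):
        tr = lrt_test(self._fit(-100.0), self._fit(-102.0), df=3)
        assert tr.statistic == pytest.approx(4.0)
        assert tr.pvalue == pytest.approx(0.2615, abs=2e-4)

    def test_equal_logliks(self):
        tr = lrt_test(self._fit(-50.0), self._fit(-50.0), df=2)
        assert tr.statistic == 0.0 and tr.pvalue == 1.0

    def test_nonconverged_reduced_not_computable(self):
        tr = lrt_test(self._fit(-100.0), self._fit(-99.0, conv=False), df=3)
        assert not tr.computable

    def test_reduced_above_full_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            tr = lrt_test(self._fit(-100.0), self._fit(-99.0), df=3)
        assert tr.statistic == 0.0


class TestBH:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_nan_excluded_and_reinserted(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_idempotent(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # order preservation: sorting by p sorts adjusted values
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
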