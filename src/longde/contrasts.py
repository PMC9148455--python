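"""Multiple-DF hypothesis tests over the eight-coefficient longitudinal model.

Four joint null hypotheses are tested per gene, each expressed as a
full-row-rank contrast matrix L over (b0..b7):

* between:     no group difference at any timepoint
               (b1 = b1+b5 = b1+b6 = b1+b7 = 0), rank 4
* within:      no change over time in the treatment group
               (b2+b5 = b3+b6 = b4+b7 = 0), rank 3 — the additional pairwise
               differences in the full hypothesis list are linear
               combinations of these rows
* interaction: no group-by-time interaction (b5 = b6 = b7 = 0), rank 3
* global:      no nonzero coefficient beyond the intercept, rank 7

Inference: Wald chi-square (GEE), F with Satterthwaite denominator DF (LMM
and NB pseudo-likelihood), or likelihood-ratio tests against a reduced model
(NB mixed model by quadrature).  Benjamini-Hochberg adjustment is applied
per test across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.stats import chi2, f as f_dist
from statsmodels.stats.multitest import multipletests

from .lmm import satterthwaite_df
from .results import FitResult

__all__ = [
    "ContrastSpec",
    "TestResult",
    "TEST_NAMES",
    "contrast_matrix",
    "reduced_design",
    "wald_chisq_test",
    "f_test_satterthwaite",
    "lrt_test",
    "bh_adjust",
]

TEST_NAMES = ("between", "within", "interaction", "global")


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    L: np.ndarray

    @property
    def rank(self) -> int:
        return self.L.shape[0]


@dataclass
class TestResult:
    """Outcome of one multiple-DF test for one gene."""

    test: str
    statistic: float
    df1: float
    df2: float  # inf for chi-square / LRT
    pvalue: float
    computable: bool = True
    gene: str | None = None
    padj: float | None = None


def _e(k: int, p: int = 8) -> np.ndarray:
    v = np.zeros(p)
    v[k] = 1.0
    return v


def contrast_matrix(test_name: str, n_coef: int = 8, within_group: str = "treatment"
                    ) -> ContrastSpec:
    """Contrast matrix for one of the four named multiple-DF tests.

    ``within_group`` selects whose time-profile the within-subject test
    targets: "treatment" tests b_t + b_interaction per timepoint, "reference"
    tests the control-group time effects alone.
    """
    if n_coef != 8:
        raise ValueError("contrasts are defined for the 4-timepoint, 8-coefficient model")
    p = n_coef
    if test_name == "between":
        rows = [_e(1), _e(1) + _e(5), _e(1) + _e(6), _e(1) + _e(7)]
    elif test_name == "within":
        if within_group == "treatment":
            rows = [_e(2) + _e(5), _e(3) + _e(6), _e(4) + _e(7)]
        elif within_group == "reference":
            rows = [_e(2), _e(3), _e(4)]
        else:
            raise ValueError("within_group must be 'treatment' or 'reference'")
    elif test_name == "interaction":
        rows = [_e(5), _e(6), _e(7)]
    elif test_name == "global":
        rows = [_e(k) for k in range(1, p)]
    else:
        raise ValueError(f"unknown test {test_name!r}")
    L = np.stack(rows)
    assert np.linalg.matrix_rank(L) == L.shape[0]
    return ContrastSpec(test_name, L)


def reduced_design(X: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Design matrix of the reduced model under H0: L beta = 0.

    The column space is reparameterized so the contrast rows become leading
    coefficients, which are then dropped — needed because the between and
    within hypotheses are not coordinate-dropping in the reference coding.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q, p = L.shape
    N = null_space(L)  # p x (p - q)
    T = np.vstack([L, N.T])
    if np.linalg.matrix_rank(T) < p:
        raise ValueError("contrast matrix does not admit a full reparameterization")
    return (X @ np.linalg.inv(T))[:, q:]


def wald_chisq_test(beta, cov, L, test_name: str = "contrast") -> TestResult:
    """Wald chi-square test of H0: L beta = 0 with the supplied covariance."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    beta = np.asarray(beta, dtype=float)
    est = L @ beta
    V = L @ cov @ L.T
    q = L.shape[0]
    try:
        W = float(est @ np.linalg.solve(V, est))
        df = q
    except np.linalg.LinAlgError:
        warnings.warn("singular contrast covariance; using pseudo-inverse",
                      RuntimeWarning)
        W = float(est @ np.linalg.pinv(V) @ est)
        df = int(np.linalg.matrix_rank(V))
    W = max(W, 0.0)
    return TestResult(
        test=test_name, statistic=W, df1=df, df2=np.inf,
        pvalue=float(chi2.sf(W, df)),
    )


def f_test_satterthwaite(fit: FitResult, L, test_name: str = "contrast") -> TestResult:
    """F test of H0: L beta = 0 with Satterthwaite denominator DF."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    if not fit.converged or fit.coef_cov is None:
        return TestResult(test=test_name, statistic=np.nan, df1=q, df2=np.nan,
                          pvalue=np.nan, computable=False)
    wald = wald_chisq_test(fit.coef, fit.coef_cov, L, test_name)
    F = wald.statistic / q
    ddf = satterthwaite_df(fit, L)
    return TestResult(
        test=test_name, statistic=float(F), df1=q, df2=float(ddf),
        pvalue=float(f_dist.sf(F, q, ddf)),
    )


def lrt_test(full: FitResult, reduced: FitResult, df: int,
             test_name: str = "contrast") -> TestResult:
    """Likelihood-ratio test from nested full/reduced fits.

    Non-converged component models make the test non-computable so that
    reduced-model failures are accounted for; a reduced log-likelihood above
    the full one signals an optimization failure and clips the statistic at
    zero.
    """
    if not (full.converged and reduced.converged):
        return TestResult(test=test_name, statistic=np.nan, df1=df, df2=np.inf,
                          pvalue=np.nan, computable=False)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        warnings.warn(
            f"reduced model log-likelihood exceeds full by {-stat / 2:.3g}; "
            "clipping LRT statistic at 0", RuntimeWarning,
        )
    stat = max(stat, 0.0)
    return TestResult(test=test_name, statistic=float(stat), df1=df, df2=np.inf,
                      pvalue=float(chi2.sf(stat, df)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (non-computable genes) are excluded from the adjustment
    and reinserted as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
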