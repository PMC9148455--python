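"""Linear mixed model with a single subject random intercept, fitted by REML.

The model for one gene's (transformed) expression vector y is

    y = X beta + Z b + eps,   b ~ N(0, sigma2_b I),  eps ~ N(0, sigma2_e W^-1)

with Z the subject incidence matrix and W optional known diagonal weights
(identity for the plain LMM; working weights in the pseudo-likelihood NB
fit).  Estimation profiles the REML criterion over the variance ratio
lambda = sigma2_b / sigma2_e, exploiting the closed-form inverse and
determinant of each subject's compound-symmetric covariance block.

Satterthwaite denominator degrees of freedom for contrasts are obtained by
the delta method on (sigma2_b, sigma2_e), with the variance-parameter
covariance taken from the numerically differentiated REML information, and
multi-row contrasts aggregated through the eigen-decomposition of the
contrast covariance (the lmerTest-style construction).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .results import FitResult, VarParamInfo

__all__ = ["LMMSolver", "fit_lmm_reml", "satterthwaite_df"]

# boundary-fit criterion: ICC below this is a singular fit
_SINGULAR_ICC = 1e-6
_LOG_LAMBDA_BOUNDS = (-13.0, 13.0)


class LMMSolver:
    """Reusable REML solver bound to one design (many genes share it)."""

    def __init__(self, X: np.ndarray, subject_index: np.ndarray):
        X = np.asarray(X, dtype=float)
        subject_index = np.asarray(subject_index)
        order = np.argsort(subject_index, kind="stable")
        self.order = order
        self.X = X[order]
        self.subject = subject_index[order]
        # reduceat boundaries of the contiguous subject blocks
        self.starts = np.concatenate([[0], np.where(np.diff(self.subject) != 0)[0] + 1])
        self.n, self.p = X.shape
        self.n_subjects = len(self.starts)
        if self.n <= self.p:
            raise ValueError("need more samples than fixed-effect coefficients")

    # -- block algebra -------------------------------------------------
    def _pieces(self, y, w):
        """Per-subject sums needed by the compound-symmetry Woodbury identity."""
        Xw = self.X * w[:, None]
        s = np.add.reduceat(w, self.starts)  # (S,)
        xw = np.add.reduceat(Xw, self.starts, axis=0)  # (S, p)
        yw = np.add.reduceat(w * y, self.starts)  # (S,)
        XtWX = self.X.T @ Xw
        XtWy = Xw.T @ y
        ytWy = float(np.dot(w * y, y))
        return s, xw, yw, XtWX, XtWy, ytWy

    def _gls(self, lam, pieces):
        s, xw, yw, XtWX, XtWy, ytWy = pieces
        c = lam / (1.0 + lam * s)  # (S,)
        A = XtWX - (xw * c[:, None]).T @ xw
        rhs = XtWy - xw.T @ (c * yw)
        yMy = ytWy - float(np.dot(c * yw, yw))
        beta = np.linalg.solve(A, rhs)
        rss = yMy - float(beta @ rhs)
        return A, beta, max(rss, 1e-300)

    def _profile_deviance(self, lam, pieces, logw_sum):
        s = pieces[0]
        A, beta, rss = self._gls(lam, pieces)
        df = self.n - self.p
        sigma2 = rss / df
        _, logdetA = np.linalg.slogdet(A)
        dev = (
            df * np.log(sigma2)
            + np.sum(np.log1p(lam * s))
            - logw_sum
            + logdetA
            + df * (1.0 + np.log(2.0 * np.pi))
        )
        return dev, A, beta, sigma2

    def reml_deviance(self, theta, y, w=None):
        """-2 * restricted log-likelihood at theta = (sigma2_b, sigma2_e)."""
        y = np.asarray(y, dtype=float)[self.order]
        w = np.ones(self.n) if w is None else np.asarray(w, dtype=float)[self.order]
        pieces = self._pieces(y, w)
        sigma2_b, sigma2_e = theta
        lam = sigma2_b / sigma2_e
        s = pieces[0]
        A, beta, rss = self._gls(lam, pieces)
        df = self.n - self.p
        _, logdetA = np.linalg.slogdet(A)
        return (
            df * np.log(sigma2_e)
            + np.sum(np.log1p(lam * s))
            - np.sum(np.log(w))
            + logdetA
            + rss / sigma2_e
            + df * np.log(2.0 * np.pi)
        )

    # -- fitting -------------------------------------------------------
    def fit(self, y, weights=None, method_tag="lmm") -> FitResult:
        y_in = np.asarray(y, dtype=float)
        y = y_in[self.order]
        if weights is None:
            w = np.ones(self.n)
        else:
            w = np.asarray(weights, dtype=float)[self.order]
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
        if np.ptp(y) == 0:
            # constant response: variance components unidentifiable
            beta = np.zeros(self.p)
            beta[0] = y[0]
            return FitResult(
                method=method_tag, coef=beta, coef_cov=np.zeros((self.p, self.p)),
                sigma2_b=0.0, dispersion=0.0, loglik=np.nan,
                converged=False, singular=True,
            )
        pieces = self._pieces(y, w)
        logw_sum = float(np.sum(np.log(w)))

        def dev_of_u(u):
            return self._profile_deviance(np.exp(u), pieces, logw_sum)[0]

        res = minimize_scalar(dev_of_u, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
                              options={"xatol": 1e-10})
        dev0 = self._profile_deviance(0.0, pieces, logw_sum)[0]
        if dev0 <= res.fun:
            lam = 0.0
            dev = dev0
        else:
            lam = float(np.exp(res.x))
            dev = float(res.fun)
        A, beta, rss = self._gls(lam, pieces)
        sigma2_e = rss / (self.n - self.p)
        sigma2_b = lam * sigma2_e
        coef_cov = sigma2_e * np.linalg.inv(A)
        icc = lam / (1.0 + lam)
        singular = icc < _SINGULAR_ICC

        solver = self

        def cov_beta_fn(theta):
            lam_t = theta[0] / theta[1]
            A_t, _, _ = solver._gls(lam_t, pieces)
            return theta[1] * np.linalg.inv(A_t)

        theta = np.array([sigma2_b, sigma2_e])
        vcov_theta = self._theta_vcov(theta, pieces, logw_sum)
        varinfo = VarParamInfo(
            theta=theta, vcov=vcov_theta, cov_beta_fn=cov_beta_fn,
            residual_df=float(self.n - self.p),
        )
        return FitResult(
            method=method_tag, coef=beta, coef_cov=coef_cov,
            sigma2_b=float(sigma2_b), dispersion=float(sigma2_e),
            loglik=-0.5 * dev, converged=True, singular=bool(singular),
            n_iter=int(getattr(res, "nfev", 0) or 0), varinfo=varinfo,
            extras={"blup": self._blup(lam, y, w, beta)},
        )

    def _blup(self, lam, y_sorted, w_sorted, beta):
        """Empirical-Bayes subject intercepts, ordered by subject label code."""
        r = y_sorted - self.X @ beta
        wr = np.add.reduceat(w_sorted * r, self.starts)
        s = np.add.reduceat(w_sorted, self.starts)
        return lam / (1.0 + lam * s) * wr

    def _theta_vcov(self, theta, pieces, logw_sum):
        """Asymptotic covariance of (sigma2_b, sigma2_e) from the REML Hessian."""

        def neg2ll(th):
            lam_t = max(th[0], 0.0) / th[1]
            s = pieces[0]
            A, _, rss = self._gls(lam_t, pieces)
            df = self.n - self.p
            _, logdetA = np.linalg.slogdet(A)
            return (
                df * np.log(th[1]) + np.sum(np.log1p(lam_t * s)) - logw_sum
                + logdetA + rss / th[1]
            )

        H = np.zeros((2, 2))
        h = np.array([max(t, 1e-8) * 1e-4 for t in theta])
        f0 = neg2ll(theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                if i == j:
                    if theta[i] - h[i] < 0:
                        fpp = neg2ll(theta + 2 * ei)
                        fp = neg2ll(theta + ei)
                        H[i, i] = (fpp - 2 * fp + f0) / h[i] ** 2
                    else:
                        H[i, i] = (neg2ll(theta + ei) - 2 * f0 + neg2ll(theta - ei)) / h[i] ** 2
                else:
                    lo_i = max(theta[i] - h[i], 0.0)
                    lo_j = max(theta[j] - h[j], 0.0)
                    tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                    tpm = theta.copy(); tpm[i] += h[i]; tpm[j] = lo_j
                    tmp = theta.copy(); tmp[i] = lo_i; tmp[j] += h[j]
                    tmm = theta.copy(); tmm[i] = lo_i; tmm[j] = lo_j
                    di = tpp[i] - tmm[i]
                    dj = tpp[j] - tmm[j]
                    H[i, j] = H[j, i] = (
                        neg2ll(tpp) - neg2ll(tpm) - neg2ll(tmp) + neg2ll(tmm)
                    ) / (di * dj)
        # vcov(theta) = inverse of 0.5 * Hessian of -2 loglik
        try:
            V = np.linalg.inv(0.5 * H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)
        return V


def fit_lmm_reml(y, design, weights=None) -> FitResult:
    """Fit the random-intercept LMM to one response vector by REML.

    ``design`` is a :class:`~longde.design.StudyDesign` (or a pre-built
    ``LMMSolver``).  Returns a :class:`FitResult` whose ``varinfo`` feeds
    :func:`satterthwaite_df`.
    """
    if isinstance(design, LMMSolver):
        solver = design
    else:
        from .design import design_parts

        solver = LMMSolver(*design_parts(design))
    return solver.fit(y, weights=weights)


def satterthwaite_df(fit: FitResult, L: np.ndarray) -> float:
    """Satterthwaite denominator degrees of freedom for contrast matrix L.

    Single-row contrasts use 2 f^2 / Var(f) with f = l' C(theta) l via the
    delta method; multi-row contrasts are combined through the
    eigen-decomposition of L C L'.  Falls back to the residual degrees of
    freedom when the variance-parameter covariance is unusable (e.g. a
    boundary fit).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    info = fit.varinfo
    if info is None:
        raise ValueError("fit carries no variance-parameter information")
    fallback = info.residual_df
    if fit.singular or not np.all(np.isfinite(info.vcov)):
        return fallback
    C = fit.coef_cov
    Phi = L @ C @ L.T
    q = L.shape[0]

    def df_one(l):
        def f(th):
            return float(l @ info.cov_beta_fn(th) @ l)

        f0 = float(l @ C @ l)
        g = info.gradient(f)
        denom = float(g @ info.vcov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return fallback
        return 2.0 * f0**2 / denom

    if q == 1:
        nu = df_one(L[0])
        return float(np.clip(nu, 1.0, fallback)) if np.isfinite(nu) else fallback

    evals, evecs = np.linalg.eigh(Phi)
    E = 0.0
    for m in range(q):
        if evals[m] <= 0:
            continue
        l_m = L.T @ evecs[:, m]
        nu_m = df_one(l_m)
        if nu_m > 2.0:
            E += nu_m / (nu_m - 2.0)
    if E <= q:
        return fallback
    nu = 2.0 * E / (E - q)
    return float(np.clip(nu, 1.0, fallback))
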