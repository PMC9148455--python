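"""Negative binomial mixed models with a subject random intercept.

Two estimation routes for the model

    y_ij | b_i ~ NB(mu_ij, alpha),  log mu_ij = x_ij' beta + offset_ij + b_i,
    b_i ~ N(0, sigma2_b)

* **Adaptive Gauss-Hermite quadrature (AGQ)**: the subject-level integrals of
  the marginal likelihood are evaluated on Gauss-Hermite nodes recentred at
  each subject's posterior mode and rescaled by the local curvature; one node
  reproduces the Laplace approximation.  Maximum likelihood in
  (beta, log alpha, log sigma2_b) by quasi-Newton, with the score computed
  through the Fisher identity (posterior expectation of the joint-likelihood
  score under the same quadrature rule).

* **Pseudo-likelihood (PL)**: iterative linearization to a weighted linear
  mixed model on the working response z = eta + (y - mu)/mu with weights
  mu/(1 + alpha mu), alternating with a Pearson chi-square dispersion update.
  The final weighted LMM carries the variance-parameter information needed
  for Satterthwaite F tests.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln

from .lmm import LMMSolver
from .results import FitResult

__all__ = ["AGQFitter", "nbmm_loglik_agq", "fit_nbmm_agq", "fit_nbmm_pl"]

_LOG_ALPHA_BOUNDS = (-12.0, 8.0)
_LOG_S2_BOUNDS = (-23.0, 5.0)
_SINGULAR_S2 = 1e-8


def _nb_logpmf(y, mu, r):
    """log NB(y; mean mu, size r), Var = mu + mu^2/r."""
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        - r * np.log1p(mu / r) + y * (np.log(mu) - np.log(r + mu))
    )


def _poisson_glm(X, y, offset, max_iter=100, tol=1e-10):
    """Poisson log-link Newton fit with offset and step-halving.

    Started from the least-squares fit of log(y + 0.5) - offset, which keeps
    the iteration stable on arbitrary (e.g. rotated, intercept-free) designs.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)

    def negll(b):
        eta = np.clip(X @ b + offset, -700, 700)
        return float(np.sum(np.exp(eta)) - np.dot(y, eta))

    f0 = negll(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -300, 300)
        mu = np.exp(eta)
        A = (X * mu[:, None]).T @ X + 1e-10 * np.eye(p)
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            f1 = negll(beta + t * step)
            if f1 <= f0 + 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if not np.isfinite(f1):
            break
        if np.max(np.abs(t * step)) < tol or abs(f0 - f1) < 1e-12 * (1 + abs(f0)):
            f0 = f1
            break
        f0 = f1
    return beta


class AGQFitter:
    """Adaptive Gauss-Hermite NB mixed-model fitter bound to one design."""

    def __init__(self, X, subject_index, offset=None, n_nodes: int = 11):
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        X = np.asarray(X, dtype=float)
        subject_index = np.asarray(subject_index)
        order = np.argsort(subject_index, kind="stable")
        self.order = order
        self.X = X[order]
        self.subject = subject_index[order]
        self.starts = np.concatenate([[0], np.where(np.diff(self.subject) != 0)[0] + 1])
        self.sample_subj = np.repeat(
            np.arange(len(self.starts)), np.diff(np.append(self.starts, len(order)))
        )
        self.n, self.p = X.shape
        self.S = len(self.starts)
        self.offset = (
            np.zeros(self.n) if offset is None else np.asarray(offset, dtype=float)[order]
        )
        t, w = hermgauss(n_nodes)
        self.nodes, self.logw = t, np.log(w)
        self.n_nodes = n_nodes

    # -- posterior modes ----------------------------------------------
    def _modes(self, y, mu0, r, s2, n_iter=40):
        """Per-subject Newton for the mode of the joint log-density in b."""
        b = np.zeros(self.S)
        inv_s2 = 1.0 / s2
        for _ in range(n_iter):
            mu = mu0 * np.exp(b[self.sample_subj])
            frac = mu / (r + mu)
            u1 = np.add.reduceat(y - (y + r) * frac, self.starts) - b * inv_s2
            u2 = -np.add.reduceat((y + r) * r * mu / (r + mu) ** 2, self.starts) - inv_s2
            step = np.clip(u1 / u2, -3.0, 3.0)
            b = b - step
            if np.max(np.abs(step)) < 1e-12:
                break
        mu = mu0 * np.exp(b[self.sample_subj])
        h = np.add.reduceat((y + r) * r * mu / (r + mu) ** 2, self.starts) + inv_s2
        return b, h

    def loglik(self, y, beta, alpha, sigma2_b, grad: bool = False):
        """Marginal log-likelihood (and optionally its score in
        (beta, log alpha, log sigma2_b)) by adaptive quadrature."""
        y = np.asarray(y, dtype=float)[self.order]
        r = 1.0 / alpha
        s2 = max(sigma2_b, 1e-300)
        eta0 = np.clip(self.X @ beta + self.offset, -300, 300)
        mu0 = np.exp(eta0)
        if sigma2_b == 0.0:
            lp = _nb_logpmf(y, mu0, r)
            ll = float(lp.sum())
            if not grad:
                return ll
            raise NotImplementedError("gradient at the sigma2_b = 0 boundary")
        b_hat, h = self._modes(y, mu0, r, s2)
        sig = 1.0 / np.sqrt(h)
        t = self.nodes
        b_nodes = b_hat[:, None] + np.sqrt(2.0) * sig[:, None] * t[None, :]  # (S,K)
        bb = b_nodes[self.sample_subj]  # (n,K)
        mu = mu0[:, None] * np.exp(bb)
        lp = _nb_logpmf(y[:, None], mu, r)
        G = np.add.reduceat(lp, self.starts, axis=0)
        G += -0.5 * b_nodes**2 / s2 - 0.5 * np.log(2.0 * np.pi * s2)
        Q = G + t[None, :] ** 2 + self.logw[None, :]
        qmax = Q.max(axis=1, keepdims=True)
        sumexp = np.exp(Q - qmax).sum(axis=1)
        ll_i = qmax[:, 0] + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(sig)
        ll = float(ll_i.sum())
        if not grad:
            return ll
        # posterior node weights, Fisher-identity score
        omega = np.exp(Q - qmax) / sumexp[:, None]  # (S,K)
        om_n = omega[self.sample_subj]  # (n,K)
        frac = mu / (r + mu)
        s_mu = y[:, None] - (y[:, None] + r) * frac  # d/d eta
        g_beta = self.X.T @ (om_n * s_mu).sum(axis=1)
        dig = digamma(y + r)[:, None] - digamma(r)
        d_r = dig + np.log(r) + 1.0 - np.log(r + mu) - (y[:, None] + r) / (r + mu)
        g_logalpha = float(-r * (om_n * d_r).sum())
        Eb2 = (omega * b_nodes**2).sum(axis=1)
        g_logs2 = float(np.sum(Eb2 / (2.0 * s2) - 0.5))
        return ll, np.concatenate([g_beta, [g_logalpha, g_logs2]])

    # -- maximum likelihood -------------------------------------------
    def fit(self, y, start=None, maxfun: int = 500, compute_cov: bool = True) -> FitResult:
        y = np.asarray(y, dtype=float)[self.order]
        if y.sum() == 0:
            return FitResult(
                method="nbmm-agq", coef=np.full(self.p, np.nan), coef_cov=None,
                sigma2_b=0.0, dispersion=np.nan, loglik=np.nan,
                converged=False, singular=True,
            )
        if start is None:
            beta0 = _poisson_glm(self.X, y, self.offset)
            mu = np.exp(np.clip(self.X @ beta0 + self.offset, -30, 30))
            pearson = float(np.sum(((y - mu) ** 2 - mu) / mu**2))
            alpha0 = np.clip(pearson / max(self.n - self.p, 1), 1e-3, 10.0)
            d = np.add.reduceat((y - mu) / mu, self.starts) / np.add.reduceat(
                np.ones(self.n), self.starts
            )
            s20 = np.clip(np.var(d), 1e-3, 2.0)
            start = np.concatenate([beta0, [np.log(alpha0), np.log(s20)]])
        theta0 = np.asarray(start, dtype=float)

        def negloglik(theta):
            beta = theta[: self.p]
            alpha = np.exp(theta[self.p])
            s2 = np.exp(theta[self.p + 1])
            try:
                ll, g = self._loglik_sorted(y, beta, alpha, s2)
            except FloatingPointError:
                return np.inf, np.zeros_like(theta)
            return -ll, -g

        bounds = [(None, None)] * self.p + [_LOG_ALPHA_BOUNDS, _LOG_S2_BOUNDS]
        res = minimize(
            negloglik, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": maxfun, "ftol": 1e-12, "gtol": 1e-6},
        )
        beta = res.x[: self.p]
        alpha = float(np.exp(res.x[self.p]))
        s2 = float(np.exp(res.x[self.p + 1]))
        converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
        singular = s2 < _SINGULAR_S2 or res.x[self.p + 1] <= _LOG_S2_BOUNDS[0] + 1e-6
        cov = None
        if compute_cov and converged:
            cov = self._coef_cov(y, res.x)
        return FitResult(
            method="nbmm-agq", coef=beta, coef_cov=cov, sigma2_b=s2,
            dispersion=alpha, loglik=float(-res.fun), converged=converged,
            singular=bool(singular), n_iter=int(res.nfev),
        )

    def _loglik_sorted(self, y_sorted, beta, alpha, s2):
        """loglik+score for an already subject-sorted response."""
        r = 1.0 / alpha
        eta0 = np.clip(self.X @ beta + self.offset, -300, 300)
        mu0 = np.exp(eta0)
        b_hat, h = self._modes(y_sorted, mu0, r, s2)
        sig = 1.0 / np.sqrt(h)
        t = self.nodes
        b_nodes = b_hat[:, None] + np.sqrt(2.0) * sig[:, None] * t[None, :]
        bb = b_nodes[self.sample_subj]
        mu = mu0[:, None] * np.exp(bb)
        lp = _nb_logpmf(y_sorted[:, None], mu, r)
        G = np.add.reduceat(lp, self.starts, axis=0)
        G += -0.5 * b_nodes**2 / s2 - 0.5 * np.log(2.0 * np.pi * s2)
        Q = G + t[None, :] ** 2 + self.logw[None, :]
        qmax = Q.max(axis=1, keepdims=True)
        ex = np.exp(Q - qmax)
        sumexp = ex.sum(axis=1)
        ll = float((qmax[:, 0] + np.log(sumexp) + 0.5 * np.log(2.0) + np.log(sig)).sum())
        omega = ex / sumexp[:, None]
        om_n = omega[self.sample_subj]
        frac = mu / (r + mu)
        s_mu = y_sorted[:, None] - (y_sorted[:, None] + r) * frac
        g_beta = self.X.T @ (om_n * s_mu).sum(axis=1)
        dig = digamma(y_sorted + r)[:, None] - digamma(r)
        d_r = dig + np.log(r) + 1.0 - np.log(r + mu) - (y_sorted[:, None] + r) / (r + mu)
        g_logalpha = float(-r * (om_n * d_r).sum())
        Eb2 = (omega * b_nodes**2).sum(axis=1)
        g_logs2 = float(np.sum(Eb2 / (2.0 * s2) - 0.5))
        return ll, np.concatenate([g_beta, [g_logalpha, g_logs2]])

    def _coef_cov(self, y_sorted, theta_hat, rel_step=1e-5):
        """Observed-information covariance by differencing the score."""
        k = len(theta_hat)
        H = np.zeros((k, k))
        for j in range(k):
            h = rel_step * max(abs(theta_hat[j]), 1.0)
            tp = theta_hat.copy()
            tp[j] += h
            tm = theta_hat.copy()
            tm[j] -= h
            _, gp = self._loglik_sorted(y_sorted, tp[: self.p], np.exp(tp[self.p]),
                                        np.exp(tp[self.p + 1]))
            _, gm = self._loglik_sorted(y_sorted, tm[: self.p], np.exp(tm[self.p]),
                                        np.exp(tm[self.p + 1]))
            H[:, j] = -(gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov_full = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        cov = cov_full[: self.p, : self.p]
        return 0.5 * (cov + cov.T)


def _make_fitter(design, offsets, n_nodes):
    from .design import design_parts

    X, subj = design_parts(design)
    return AGQFitter(X, subj, offsets, n_nodes)


def nbmm_loglik_agq(y, design, offsets, beta, alpha, sigma2_b, n_nodes: int = 11):
    """Marginal NB mixed-model log-likelihood by adaptive quadrature.

    ``sigma2_b = 0`` returns the plain NB GLM log-likelihood; ``n_nodes = 1``
    reproduces the Laplace approximation.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if sigma2_b < 0:
        raise ValueError("sigma2_b must be >= 0")
    fitter = _make_fitter(design, offsets, n_nodes)
    return fitter.loglik(
        np.asarray(y, dtype=float), np.asarray(beta, dtype=float),
        float(alpha), float(sigma2_b),
    )


def fit_nbmm_agq(y, design, offsets=None, n_nodes: int = 11, compute_cov: bool = True
                 ) -> FitResult:
    """Maximum-likelihood NB mixed-model fit by adaptive quadrature."""
    return _make_fitter(design, offsets, n_nodes).fit(y, compute_cov=compute_cov)


# ---------------------------------------------------------------------------
# pseudo-likelihood
# ---------------------------------------------------------------------------

def fit_nbmm_pl(y, design, offsets=None, tol: float = 1e-8, max_iter: int = 200,
                alpha_floor: float = 1e-8) -> FitResult:
    """NB mixed model by pseudo-likelihood (iterative weighted LMM).

    Alternates (i) the working response z = eta + (y - mu)/mu with weights
    mu / (1 + alpha mu), (ii) a weighted REML LMM fit for (beta, sigma2_b),
    and (iii) a Pearson chi-square update of alpha, until the relative change
    in (beta, sigma2_b, alpha) drops below ``tol``.  The returned fit carries
    the working LMM's variance-parameter information so Satterthwaite-based
    F tests apply.
    """
    from .design import design_parts

    X, subj = design_parts(design)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_subjects = len(np.unique(subj))
    offset = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    if y.sum() == 0 or np.ptp(y) == 0:
        return FitResult(
            method="nbmm-pl", coef=np.full(p, np.nan), coef_cov=None,
            sigma2_b=0.0, dispersion=np.nan, loglik=np.nan,
            converged=False, singular=True,
        )
    solver = LMMSolver(X, subj)

    beta = _poisson_glm(X, y, offset)
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    alpha = float(np.clip(np.sum(((y - mu) ** 2 - mu) / mu**2) / max(n - p, 1),
                          alpha_floor, 100.0))
    b = np.zeros(n_subjects)
    sigma2_b = 0.0
    lfit = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + offset + b[subj], -30, 30)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        w = mu / (1.0 + alpha * mu)
        lfit = solver.fit(z, weights=w, method_tag="nbmm-pl")
        if not lfit.converged:
            break
        new_beta = lfit.coef
        new_s2 = lfit.sigma2_b  # working response lives on the link scale
        b = lfit.extras["blup"]
        mu = np.exp(np.clip(X @ new_beta + offset + b[subj], -30, 30))
        alpha_new = _pearson_alpha(y, mu, n - p, alpha_floor)
        delta = max(
            np.max(np.abs(new_beta - beta)) / (1.0 + np.max(np.abs(beta))),
            abs(new_s2 - sigma2_b) / (1.0 + abs(sigma2_b)),
            abs(alpha_new - alpha) / (1.0 + abs(alpha)),
        )
        beta, sigma2_b, alpha = new_beta, float(new_s2), float(alpha_new)
        if delta < tol:
            converged = True
            break
    if lfit is None or lfit.coef_cov is None:
        return FitResult(
            method="nbmm-pl", coef=np.full(p, np.nan), coef_cov=None,
            sigma2_b=0.0, dispersion=np.nan, loglik=np.nan,
            converged=False, singular=True,
        )
    return FitResult(
        method="nbmm-pl", coef=beta, coef_cov=lfit.coef_cov,
        sigma2_b=float(sigma2_b), dispersion=float(alpha),
        loglik=lfit.loglik, converged=bool(converged),
        singular=bool(lfit.singular), n_iter=it, varinfo=lfit.varinfo,
        extras={"phi": lfit.dispersion},
    )


def _pearson_alpha(y, mu, dof, floor):
    """Solve sum (y-mu)^2 / (mu (1+alpha mu)) = dof for alpha."""
    resid2 = (y - mu) ** 2

    def g(a):
        return float(np.sum(resid2 / (mu * (1.0 + a * mu))) - dof)

    if g(floor) <= 0:
        return floor
    hi = 100.0
    if g(hi) > 0:
        return hi
    return brentq(g, floor, hi, xtol=1e-12, rtol=1e-10)
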