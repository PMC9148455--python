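"""Generalized estimating equations for overdispersed longitudinal counts.

Marginal Poisson model with log link, an extra scale parameter phi in the
variance (Var = phi * mu), exchangeable working correlation within subjects,
and log-size-factor offsets.  Coefficient covariance comes in three flavours:

* naive (model-based)  A^-1 with A = sum_i D_i' V_i^-1 D_i
* robust sandwich      A^-1 M A^-1,  M = sum_i D_i' V_i^-1 e_i e_i' V_i^-1 D_i
* small-sample corrected (Wang & Long): the per-subject residual
  cross-product is replaced by a pooled-across-subjects covariance and each
  contribution is inflated by the leverage adjustment (I - H_i)^-1, which
  counters the downward bias of the plain sandwich with few subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nbmm import _poisson_glm

__all__ = ["GeeFit", "fit_gee_exchangeable", "robust_sandwich", "small_sample_covariance"]


@dataclass
class GeeFit:
    """Fitted exchangeable-GEE model for one gene."""

    coef: np.ndarray
    naive_cov: np.ndarray
    robust_cov: np.ndarray | None
    corrected_cov: np.ndarray | None
    phi: float
    rho: float
    converged: bool
    n_iter: int
    # per-subject pieces kept for the covariance estimators
    _internals: dict = field(default_factory=dict, repr=False)

    def covariance(self, which: str = "wang-long") -> np.ndarray:
        cov = {
            "naive": self.naive_cov,
            "robust": self.robust_cov,
            "wang-long": self.corrected_cov,
        }.get(which)
        if cov is None:
            raise ValueError(f"unknown or unavailable covariance {which!r}")
        return cov


def _blocks(subject_index):
    order = np.argsort(subject_index, kind="stable")
    s = np.asarray(subject_index)[order]
    starts = np.concatenate([[0], np.where(np.diff(s) != 0)[0] + 1])
    ends = np.append(starts[1:], len(s))
    return order, starts, ends


def fit_gee_exchangeable(
    y, design, offsets=None, max_iter: int = 100, tol: float = 1e-10
) -> GeeFit:
    """Fit the marginal Poisson-scale GEE with exchangeable working correlation.

    Iterates IRLS-type solves of the estimating equations with moment updates
    of the scale phi (Pearson chi-square / (N - p)) and the exchangeable
    correlation rho (average cross-product of Pearson residuals within
    subjects).  Coefficient estimates are invariant to phi.
    """
    from .design import design_parts

    X, subj = design_parts(design)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offsets is None else np.asarray(offsets, dtype=float)
    order, starts, ends = _blocks(subj)
    Xs, ys, offs = X[order], y[order], offset[order]
    m = ends - starts  # cluster sizes
    n_pairs = float(np.sum(m * (m - 1)))

    beta = _poisson_glm(Xs, ys, offs)
    rho, phi = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xs @ beta + offs, -30, 30)
        mu = np.exp(eta)
        e = (ys - mu) / np.sqrt(mu)  # Pearson residuals (variance function mu)
        phi = float(np.sum(e**2) / max(n - p, 1))
        if n_pairs > 0:
            sums = np.add.reduceat(e, starts)
            sq = np.add.reduceat(e**2, starts)
            cross = float(np.sum(sums**2 - sq))
            rho = cross / (phi * max(n_pairs - p, 1.0))
            m_max = int(m.max())
            lo = -1.0 / (m_max - 1) + 1e-6 if m_max > 1 else -0.999
            rho = float(np.clip(rho, lo, 0.999))
        # R^-1 = c1 (I - c2 J) on each cluster
        c1 = 1.0 / (1.0 - rho)
        c2 = rho / (1.0 + (m - 1) * rho)  # per cluster
        c2s = np.repeat(c2, m)
        # D = diag(mu) X, A^{-1/2} = diag(1/sqrt(mu)) -> Xt = sqrt(mu) X
        sq_mu = np.sqrt(mu)
        Xt = Xs * sq_mu[:, None]
        r = ys - mu
        u = r / sq_mu
        # bread and score with phi left out (it cancels in the update)
        xt_sums = np.add.reduceat(Xt, starts, axis=0)  # per-cluster column sums
        u_sums = np.add.reduceat(u, starts)
        A = c1 * (Xt.T @ Xt - (xt_sums * c2[:, None]).T @ xt_sums)
        g = c1 * (Xt.T @ u - xt_sums.T @ (c2 * u_sums))
        step = np.linalg.solve(A, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = np.clip(Xs @ beta + offs, -30, 30)
    mu = np.exp(eta)
    e = (ys - mu) / np.sqrt(mu)
    phi = float(np.sum(e**2) / max(n - p, 1))
    c1 = 1.0 / (1.0 - rho)
    c2 = rho / (1.0 + (m - 1) * rho)
    sq_mu = np.sqrt(mu)
    Xt = Xs * sq_mu[:, None]
    xt_sums = np.add.reduceat(Xt, starts, axis=0)
    A = c1 * (Xt.T @ Xt - (xt_sums * c2[:, None]).T @ xt_sums) / phi
    naive = np.linalg.inv(A)
    fit = GeeFit(
        coef=beta, naive_cov=naive, robust_cov=None, corrected_cov=None,
        phi=phi, rho=float(rho), converged=converged, n_iter=it,
        _internals={
            "Xs": Xs, "ys": ys, "mu": mu, "starts": starts, "ends": ends,
            "c1": c1, "c2": c2, "phi": phi, "A": A, "naive": naive,
        },
    )
    fit.robust_cov = robust_sandwich(fit)
    if len(starts) >= 3:
        fit.corrected_cov = small_sample_covariance(fit)
    return fit


def _subject_matrices(fit: GeeFit):
    """Yield (D_i, Vinv_i, e_i) per subject from the stored internals."""
    ii = fit._internals
    Xs, ys, mu = ii["Xs"], ii["ys"], ii["mu"]
    starts, ends = ii["starts"], ii["ends"]
    c1, c2, phi = ii["c1"], ii["c2"], ii["phi"]
    for i, (a, b) in enumerate(zip(starts, ends)):
        mu_i = mu[a:b]
        D = mu_i[:, None] * Xs[a:b]
        mi = b - a
        Rinv = c1 * (np.eye(mi) - c2[i] * np.ones((mi, mi)))
        Ainv_sqrt = np.diag(1.0 / np.sqrt(mu_i))
        Vinv = Ainv_sqrt @ Rinv @ Ainv_sqrt / phi
        yield D, Vinv, ys[a:b] - mu_i, mu_i


def robust_sandwich(fit: GeeFit) -> np.ndarray:
    """Robust sandwich covariance A^-1 M A^-1 over subject clusters."""
    if not fit.converged:
        warnings.warn("sandwich requested for a non-converged GEE fit", RuntimeWarning)
    A = fit._internals["A"]
    p = A.shape[0]
    M = np.zeros((p, p))
    for D, Vinv, e, _ in _subject_matrices(fit):
        s = D.T @ Vinv @ e
        M += np.outer(s, s)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ M @ Ainv
    return 0.5 * (cov + cov.T)


def small_sample_covariance(fit: GeeFit) -> np.ndarray:
    """Wang-Long bias-corrected, pooled-covariance sandwich estimator.

    Residual cross-products are first inflated per subject by (I - H_i)^-1
    with H_i = D_i A^-1 D_i' V_i^-1 (the cluster-leverage bias adjustment),
    then pooled across subjects on the standardized scale to borrow strength
    when single-subject cross-products are noisy.  Requires a common cluster
    size for pooling; unequal clusters fall back to the unpooled
    bias-corrected form with a warning.
    """
    ii = fit._internals
    A = ii["A"]
    Ainv = np.linalg.inv(A)
    p = A.shape[0]
    subj = list(_subject_matrices(fit))
    sizes = {d[0].shape[0] for d in subj}
    pooled = len(sizes) == 1
    if not pooled:
        warnings.warn(
            "unequal cluster sizes: pooled covariance unavailable, "
            "using unpooled bias-corrected sandwich", RuntimeWarning
        )
    e_adj, scales = [], []
    for D, Vinv, e, mu_i in subj:
        H = D @ Ainv @ D.T @ Vinv
        mi = len(e)
        try:
            ei = np.linalg.solve(np.eye(mi) - H, e)
        except np.linalg.LinAlgError:
            warnings.warn("(I - H_i) singular; using uncorrected residuals",
                          RuntimeWarning)
            ei = e
        e_adj.append(ei)
        scales.append(np.sqrt(mu_i))
    M = np.zeros((p, p))
    if pooled:
        # pooled standardized covariance of the adjusted residuals
        Z = np.stack([ei / s for ei, s in zip(e_adj, scales)])  # (S, m)
        Rbar = Z.T @ Z / len(subj)
        for (D, Vinv, _, mu_i) in subj:
            s = np.sqrt(mu_i)
            Sigma = (s[:, None] * Rbar) * s[None, :]
            B = D.T @ Vinv
            M += B @ Sigma @ B.T
    else:
        for (D, Vinv, _, _), ei in zip(subj, e_adj):
            s = D.T @ Vinv @ ei
            M += np.outer(s, s)
    cov = Ainv @ M @ Ainv
    return 0.5 * (cov + cov.T)
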