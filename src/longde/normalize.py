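"""Library-size normalization and variance stabilization for count matrices.

Provides median-of-ratios size factors (used downstream as log offsets in the
count models), CPM computation, a method-of-moments dispersion trend fit
``alpha(mu) = a0 + a1/mu``, and the closed-form variance-stabilizing
transformation (VST) implied by that trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "DispersionTrend",
    "median_ratio_size_factors",
    "cpm_matrix",
    "fit_dispersion_trend",
    "vst_transform",
    "log2_transform",
]

_A0_FLOOR = 1e-8


@dataclass(frozen=True)
class DispersionTrend:
    """Mean-dispersion trend alpha(mu) = a0 + a1 / mu.

    a0 is the asymptotic (large-mean) dispersion; a1 captures the Poisson-like
    excess at small means.
    """

    a0: float
    a1: float

    def __post_init__(self):
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("trend coefficients must be >= 0")
        if self.a0 == 0 and self.a1 == 0:
            raise ValueError("trend cannot be identically zero")

    def alpha(self, mu):
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts.astype(float)
    return np.asarray(counts, dtype=float)


def median_ratio_size_factors(counts, rescale_geomean: bool = True) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample, the size factor is the median over reference genes
    (genes with no zero count) of the ratio of that sample's count to the
    gene's geometric mean across samples.  By default factors are rescaled so
    their geometric mean is one.
    """
    c = _counts_array(counts)
    ref = np.all(c > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts; supply a pseudo-reference "
            "or filter samples before computing size factors"
        )
    logc = np.log(c[ref])
    log_geomean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geomean, axis=0))
    if rescale_geomean:
        sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def cpm_matrix(counts) -> np.ndarray:
    """Counts per million against each sample's library size (column sum)."""
    c = _counts_array(counts)
    lib = c.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return c / lib * 1e6


def fit_dispersion_trend(counts, size_factors=None) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu from per-gene method-of-moments estimates.

    Per gene, normalized counts q = k/s give mu_hat = mean(q) and a moment
    dispersion estimate (s^2 - mu_hat * mean(1/s)) / mu_hat^2; the estimates
    are regressed on 1/mu_hat by robust (Huber) least squares.  Negative
    fitted components are clipped to a small positive floor.
    """
    c = _counts_array(counts)
    if size_factors is None:
        size_factors = median_ratio_size_factors(c)
    s = np.asarray(size_factors, dtype=float)
    q = c / s
    mu = q.mean(axis=1)
    ok = mu > 0
    if c.shape[0] < 50:
        warnings.warn("dispersion trend fit with < 50 genes is unreliable", RuntimeWarning)
    var = q.var(axis=1, ddof=1)
    inv_s_mean = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (var - mu * inv_s_mean) / mu**2
    mu, alpha_hat = mu[ok], alpha_hat[ok]
    if alpha_hat.size == 0 or np.all(alpha_hat <= 0):
        warnings.warn("all dispersion estimates <= 0; returning near-Poisson trend",
                      RuntimeWarning)
        return DispersionTrend(_A0_FLOOR, 0.0)
    import statsmodels.api as sm

    exog = np.column_stack([np.ones_like(mu), 1.0 / mu])
    fit = sm.RLM(alpha_hat, exog, M=sm.robust.norms.HuberT()).fit()
    a0 = max(float(fit.params[0]), _A0_FLOOR)
    a1 = max(float(fit.params[1]), 0.0)
    return DispersionTrend(a0, a1)


def vst_transform(counts, size_factors=None, trend: DispersionTrend | None = None):
    """Closed-form VST of size-factor-normalized counts.

    Integrating 1/sqrt(v(mu)) under v(mu) = mu + alpha(mu) mu^2 with the
    a0 + a1/mu trend gives, up to affine constants,

        f(x) = (2 / ln 2) * asinh( sqrt( a0 * x / (1 + a1) ) )

    which is monotone and approaches log2(x) + const for large x.  Counts are
    divided by their size factors before transforming, so library-size
    effects are removed.
    """
    c = _counts_array(counts)
    if size_factors is None:
        size_factors = median_ratio_size_factors(c)
    if trend is None:
        trend = fit_dispersion_trend(c, size_factors)
    x = c / np.asarray(size_factors, dtype=float)
    a0 = max(trend.a0, _A0_FLOOR)
    return (2.0 / np.log(2.0)) * np.arcsinh(np.sqrt(a0 * x / (1.0 + trend.a1)))


def log2_transform(counts, size_factors=None, pseudocount: float = 0.5):
    """log2(normalized count + pseudocount) fallback transform."""
    c = _counts_array(counts)
    if size_factors is None:
        size_factors = median_ratio_size_factors(c)
    return np.log2(c / np.asarray(size_factors, dtype=float) + pseudocount)
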