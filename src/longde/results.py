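"""Shared result containers for the per-gene model fitters."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FitResult", "VarParamInfo"]


@dataclass
class VarParamInfo:
    """Variance-parameter estimates and their asymptotic covariance.

    ``theta`` holds the variance parameters on their natural scale (e.g.
    (sigma2_b, sigma2_e) for the LMM); ``vcov`` their asymptotic covariance
    (inverse REML information); ``cov_beta_fn`` maps theta to the implied
    coefficient covariance so that Satterthwaite gradients can be taken.
    """

    theta: np.ndarray
    vcov: np.ndarray
    cov_beta_fn: Callable[[np.ndarray], np.ndarray]
    residual_df: float

    def gradient(self, f: Callable[[np.ndarray], float], rel_step: float = 1e-4):
        """Central-difference gradient of a scalar function of theta."""
        th = self.theta
        g = np.zeros_like(th)
        for k in range(len(th)):
            h = rel_step * max(abs(th[k]), 1e-10)
            tp, tm = th.copy(), th.copy()
            tp[k] += h
            tm[k] = max(tm[k] - h, 0.0)
            g[k] = (f(tp) - f(tm)) / (tp[k] - tm[k])
        return g


@dataclass
class FitResult:
    """One fitted gene-level model."""

    method: str
    coef: np.ndarray
    coef_cov: np.ndarray | None
    sigma2_b: float
    dispersion: float  # residual variance (LMM) or NB dispersion (NBMM)
    loglik: float
    converged: bool
    singular: bool = False
    n_iter: int = 0
    varinfo: VarParamInfo | None = None
    extras: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return bool(self.converged)
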