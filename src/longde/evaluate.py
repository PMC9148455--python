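"""FDR / power / convergence metrics and downstream expression-profile clustering.

Turns per-gene multiple-DF test outcomes plus simulation truth into the
benchmark metrics — empirical FDR (FP / declared positives), power
(TP / truth-DE genes), and convergence rates — averaged over replicate
datasets, and provides the predicted-expression hierarchical clustering used
to summarize longitudinal profiles (correlation distance, complete linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "EvalSummary",
    "fdr_power",
    "convergence_rate",
    "aggregate_replicates",
    "predicted_expression",
    "hierarchical_cluster",
]


@dataclass
class EvalSummary:
    """FDR/power/convergence for one method-test-sample-size cell."""

    method: str
    test: str
    n_per_group: int
    fdr: float
    power: float
    convergence_failure_rate: float = 0.0
    reduced_failure_rate: float = 0.0
    n_replicates: int = 1


def fdr_power(padj, is_de, alpha: float = 0.05) -> tuple[float, float]:
    """Empirical FDR and power at the adjusted-p threshold ``alpha``.

    Genes with missing adjusted p-values (non-computable tests) are excluded
    from both numerators and denominators.  With zero declared positives the
    FDR is 0 (the max(1, declared) convention); with zero truth-DE genes the
    power is NaN.
    """
    padj = np.asarray(padj, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    if padj.shape != is_de.shape:
        raise ValueError("padj and truth labels must align")
    ok = np.isfinite(padj)
    declared = ok & (padj < alpha)
    fp = int(np.sum(declared & ~is_de))
    tp = int(np.sum(declared & is_de))
    fdr = fp / max(1, fp + tp)
    n_de = int(np.sum(is_de & ok))
    power = tp / n_de if n_de > 0 else np.nan
    return float(fdr), float(power)


def convergence_rate(fits) -> tuple[float, float]:
    """(full-model failure rate, reduced-model-only failure rate).

    ``fits`` is an iterable of objects with ``converged`` and, optionally, a
    ``reduced_failed`` flag in ``extras`` marking genes whose full model
    converged but at least one reduced model did not.
    """
    fits = list(fits)
    if not fits:
        return 0.0, 0.0
    n = len(fits)
    full_fail = sum(1 for f in fits if not f.converged)
    reduced_fail = sum(
        1
        for f in fits
        if f.converged and getattr(f, "extras", {}).get("reduced_failed", False)
    )
    return full_fail / n, reduced_fail / n


def aggregate_replicates(summaries: list[EvalSummary]) -> EvalSummary:
    """Arithmetic mean of the metrics across replicate datasets."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    keys = {(s.method, s.test, s.n_per_group) for s in summaries}
    if len(keys) > 1:
        raise ValueError("summaries mix methods/tests/sample sizes")
    method, test, npg = keys.pop()

    def mean(attr):
        vals = [getattr(s, attr) for s in summaries]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    return EvalSummary(
        method=method, test=test, n_per_group=npg,
        fdr=mean("fdr"), power=mean("power"),
        convergence_failure_rate=mean("convergence_failure_rate"),
        reduced_failure_rate=mean("reduced_failure_rate"),
        n_replicates=sum(s.n_replicates for s in summaries),
    )


def predicted_expression(fit, design, group: int, timepoints=None) -> np.ndarray:
    """Fixed-effect predicted expression (link scale) at each timepoint.

    The subject random intercept is set to zero, so the prediction is the
    population-level profile of the chosen group.
    """
    if timepoints is None:
        timepoints = range(1, design.n_timepoints + 1)
    rows = np.stack([design.design_row(group, t) for t in timepoints])
    return rows @ fit.coef


def hierarchical_cluster(profiles, k: int = 7, scale_rows: bool = True) -> np.ndarray:
    """Cluster expression profiles by correlation distance, complete linkage.

    Rows are per-gene predicted profiles over timepoints; they are centred
    and scaled before clustering (heatmap-style row scaling).  Constant rows
    (undefined correlation) are dropped and reported as label 0.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least two profiles")
    sd = P.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant profile(s) dropped from clustering",
                      RuntimeWarning)
    labels = np.zeros(P.shape[0], dtype=int)
    Pk = P[keep]
    if scale_rows:
        Pk = (Pk - Pk.mean(axis=1, keepdims=True)) / Pk.std(axis=1, keepdims=True)
    if Pk.shape[0] < 2:
        labels[keep] = 1
        return labels
    Z = linkage(Pk, method="complete", metric="correlation")
    labels[keep] = fcluster(Z, t=min(k, Pk.shape[0]), criterion="maxclust")
    return labels


def summary_frame(summaries: list[EvalSummary]) -> pd.DataFrame:
    """Tidy table (method x test x n_per_group) of the evaluation metrics."""
    return pd.DataFrame(
        [
            {
                "method": s.method,
                "test": s.test,
                "n_per_group": s.n_per_group,
                "fdr": s.fdr,
                "power": s.power,
                "convergence_failure_rate": s.convergence_failure_rate,
                "reduced_failure_rate": s.reduced_failure_rate,
                "n_replicates": s.n_replicates,
            }
            for s in summaries
        ]
    )
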