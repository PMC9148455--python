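"""End-to-end orchestration: simulate -> normalize -> fit -> test -> evaluate.

The unit of work is one simulated (or loaded) count matrix plus its study
design.  ``fit_and_test`` runs one estimation method over every gene and
produces tidy per-gene fit and test tables; ``run_simulation_study`` repeats
that over replicate datasets and aggregates FDR/power/convergence, mirroring
the benchmark procedure (BH adjustment per test across genes, threshold
0.05, metrics averaged over replicates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import (
    TEST_NAMES,
    bh_adjust,
    contrast_matrix,
    f_test_satterthwaite,
    lrt_test,
    reduced_design,
    wald_chisq_test,
)
from .design import StudyDesign
from .evaluate import EvalSummary, aggregate_replicates, fdr_power
from .gee import fit_gee_exchangeable
from .lmm import LMMSolver
from .nbmm import AGQFitter, fit_nbmm_pl
from .normalize import fit_dispersion_trend, log2_transform, median_ratio_size_factors, vst_transform
from .simulate import (
    CountMatrix,
    SurrogateParamDistribution,
    assign_de_effects,
    cpm_filter,
    draw_gene_params,
    simulate_dataset,
    truth_table,
)

logger = logging.getLogger("longde")

METHODS = ("lmm", "gee", "nbmm-agq", "nbmm-pl")

__all__ = ["METHODS", "fit_and_test", "run_simulation_study", "SimulationConfig"]


def _contrasts(tests, within_group):
    return {t: contrast_matrix(t, within_group=within_group) for t in tests}


def fit_and_test(
    counts: CountMatrix,
    design: StudyDesign,
    method: str,
    tests=TEST_NAMES,
    size_factors=None,
    gee_cov: str = "wang-long",
    n_nodes: int = 11,
    transform: str = "vst",
    within_group: str = "treatment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one method to every gene and run the requested multiple-DF tests.

    Returns (fits, tests) tidy DataFrames.  Test p-values are BH-adjusted
    per test across genes; genes whose model (or, for LRTs, any reduced
    model) failed are flagged non-computable rather than dropped silently.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    Y = counts.counts
    genes = counts.gene_ids
    if size_factors is None:
        size_factors = median_ratio_size_factors(Y)
    offsets = np.log(size_factors)
    specs = _contrasts(tests, within_group)
    X = design.design_matrix()

    fit_rows, test_rows = [], []

    if method == "lmm":
        trend = fit_dispersion_trend(Y, size_factors)
        if transform == "vst":
            Z = vst_transform(Y, size_factors, trend)
        elif transform == "log2":
            Z = log2_transform(Y, size_factors)
        else:
            raise ValueError("transform must be 'vst' or 'log2'")
        solver = LMMSolver(X, design.subject_index)
        for g, gene in enumerate(genes):
            fit = solver.fit(Z[g])
            fit_rows.append(_fit_row(gene, fit))
            for name, spec in specs.items():
                tr = f_test_satterthwaite(fit, spec.L, name)
                test_rows.append(_test_row(gene, tr))

    elif method == "nbmm-pl":
        for g, gene in enumerate(genes):
            fit = fit_nbmm_pl(Y[g], design, offsets)
            fit_rows.append(_fit_row(gene, fit))
            for name, spec in specs.items():
                tr = f_test_satterthwaite(fit, spec.L, name)
                test_rows.append(_test_row(gene, tr))

    elif method == "gee":
        for g, gene in enumerate(genes):
            fit = fit_gee_exchangeable(Y[g], design, offsets)
            row = {
                "gene": gene, "method": "gee", "converged": fit.converged,
                "singular": False, "sigma2_b": np.nan, "dispersion": fit.phi,
                "loglik": np.nan, "n_iter": fit.n_iter, "rho": fit.rho,
            }
            row.update({f"coef{k}": c for k, c in enumerate(fit.coef)})
            fit_rows.append(row)
            cov = None
            if fit.converged:
                try:
                    cov = fit.covariance(gee_cov)
                except ValueError:
                    cov = fit.robust_cov
            for name, spec in specs.items():
                if cov is None:
                    test_rows.append(
                        dict(gene=gene, test=name, statistic=np.nan, df1=spec.rank,
                             df2=np.inf, pvalue=np.nan, computable=False)
                    )
                else:
                    tr = wald_chisq_test(fit.coef, cov, spec.L, name)
                    test_rows.append(_test_row(gene, tr))

    else:  # nbmm-agq with LRTs
        full_fitter = AGQFitter(X, design.subject_index, offsets, n_nodes)
        reduced_fitters = {
            name: AGQFitter(reduced_design(X, spec.L), design.subject_index,
                            offsets, n_nodes)
            for name, spec in specs.items()
        }
        for g, gene in enumerate(genes):
            y = Y[g]
            fit = full_fitter.fit(y, compute_cov=False)
            reduced_failed = False
            for name, spec in specs.items():
                if not fit.converged:
                    test_rows.append(
                        dict(gene=gene, test=name, statistic=np.nan, df1=spec.rank,
                             df2=np.inf, pvalue=np.nan, computable=False)
                    )
                    continue
                rfit = reduced_fitters[name].fit(y, compute_cov=False)
                tr = lrt_test(fit, rfit, spec.rank, name)
                if not tr.computable:
                    reduced_failed = True
                test_rows.append(_test_row(gene, tr))
            fit.extras["reduced_failed"] = reduced_failed
            fit_rows.append(_fit_row(gene, fit))

    fits = pd.DataFrame(fit_rows)
    tests_df = pd.DataFrame(test_rows)
    tests_df["padj"] = np.nan
    for name in specs:
        m = tests_df["test"] == name
        tests_df.loc[m, "padj"] = bh_adjust(tests_df.loc[m, "pvalue"].to_numpy())
    return fits, tests_df


def _fit_row(gene, fit):
    row = {
        "gene": gene, "method": fit.method, "converged": fit.converged,
        "singular": fit.singular, "sigma2_b": fit.sigma2_b,
        "dispersion": fit.dispersion, "loglik": fit.loglik, "n_iter": fit.n_iter,
        "reduced_failed": fit.extras.get("reduced_failed", False),
    }
    coef = fit.coef if fit.coef is not None else []
    row.update({f"coef{k}": c for k, c in enumerate(coef)})
    return row


def _test_row(gene, tr):
    return dict(
        gene=gene, test=tr.test, statistic=tr.statistic, df1=tr.df1, df2=tr.df2,
        pvalue=tr.pvalue, computable=tr.computable,
    )


@dataclass
class SimulationConfig:
    """Settings for one simulation-benchmark run."""

    n_genes: int = 2000
    n_per_group: int = 10
    n_timepoints: int = 4
    n_datasets: int = 3
    prop_de: float = 0.2
    methods: tuple = ("lmm",)
    tests: tuple = TEST_NAMES
    alpha: float = 0.05
    seed: int = 0
    gee_cov: str = "wang-long"
    n_nodes: int = 11
    transform: str = "vst"
    cpm_threshold: float = 1.0
    effect_sign_rule: str = "shared"
    dist: SurrogateParamDistribution = field(default_factory=SurrogateParamDistribution)


def simulate_replicate(cfg: SimulationConfig, seed) -> tuple[CountMatrix, pd.DataFrame, StudyDesign]:
    """One filtered replicate dataset plus its truth table."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_params, s_de, s_counts = ss.spawn(3)
    design = StudyDesign.balanced(cfg.n_per_group, cfg.n_timepoints)
    params = draw_gene_params(cfg.n_genes, cfg.dist, np.random.default_rng(s_params))
    params = assign_de_effects(params, cfg.prop_de, cfg.effect_sign_rule,
                               np.random.default_rng(s_de))
    counts = simulate_dataset(params, design, np.random.default_rng(s_counts))
    truth = truth_table(params, counts.gene_ids)
    filtered, keep = cpm_filter(counts, cfg.cpm_threshold, min_samples=cfg.n_per_group)
    truth = truth.loc[keep].reset_index(drop=True)
    return filtered, truth, design


def run_simulation_study(cfg: SimulationConfig, writer=None):
    """Simulate ``n_datasets`` replicates, run every method/test, and average
    FDR, power and convergence rates across replicates.

    Returns (summary DataFrame, per-replicate detail list).  ``writer``, if
    given, is called with (replicate index, stage name, DataFrame) for
    artifact persistence.
    """
    from .evaluate import summary_frame

    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.n_datasets)
    per_rep: dict[tuple, list[EvalSummary]] = {}
    details = []
    for r in range(cfg.n_datasets):
        counts, truth, design = simulate_replicate(cfg, rep_seeds[r])
        logger.info("replicate %d: %d genes after filtering", r + 1, counts.n_genes)
        if writer:
            writer(r, "counts", counts.to_frame())
            writer(r, "truth", truth)
        is_de = truth.set_index("gene")["is_de"]
        for method in cfg.methods:
            fits, tests_df = fit_and_test(
                counts, design, method, tests=cfg.tests, gee_cov=cfg.gee_cov,
                n_nodes=cfg.n_nodes, transform=cfg.transform,
            )
            if writer:
                writer(r, f"fits_{method}", fits)
                writer(r, f"tests_{method}", tests_df)
            n_genes = len(fits)
            full_fail = float((~fits["converged"]).mean()) if n_genes else 0.0
            red_fail = (
                float((fits["converged"] & fits.get("reduced_failed", False)).mean())
                if n_genes else 0.0
            )
            logger.info("replicate %d %s: %.1f%% non-converged", r + 1, method,
                        100 * full_fail)
            for name in cfg.tests:
                sub = tests_df[tests_df["test"] == name]
                labels = is_de.reindex(sub["gene"]).to_numpy(dtype=bool)
                fdr, power = fdr_power(sub["padj"].to_numpy(), labels, cfg.alpha)
                summ = EvalSummary(
                    method=method, test=name, n_per_group=cfg.n_per_group,
                    fdr=fdr, power=power, convergence_failure_rate=full_fail,
                    reduced_failure_rate=red_fail,
                )
                per_rep.setdefault((method, name), []).append(summ)
            details.append((r, method, fits, tests_df))
    summaries = [aggregate_replicates(v) for v in per_rep.values()]
    return summary_frame(summaries), details
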