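"""Negative-binomial random-intercept count simulator for two-group longitudinal designs.

Counts for gene g, subject i, observation j follow

    Y_gij ~ NB(mu_gij, alpha_g),      Var(Y) = mu + alpha * mu^2
    log mu_gij = x_ij' beta_g + b_gi,  b_gi ~ N(0, sigma2_b_g)

with the eight-coefficient reference-coded design of
:class:`~longde.design.StudyDesign`.  Gene-level generative parameters
(mean CPM, dispersion, random-intercept variance) are drawn from a
surrogate empirical distribution (or a user-supplied triplet table), and a
configurable fraction of genes receives group-by-time interaction effects
of increasing magnitude (|b5|, |b6|, |b7|) = (1/3, 2/3, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import StudyDesign

__all__ = [
    "GeneParams",
    "CountMatrix",
    "SurrogateParamDistribution",
    "draw_gene_params",
    "assign_de_effects",
    "simulate_dataset",
    "cpm_filter",
    "TOTAL_LIBRARY_SIZE",
]

#: Expected total library size used to convert CPM into expected counts.
TOTAL_LIBRARY_SIZE = 25_000_000


@dataclass(frozen=True)
class GeneParams:
    """Generative truth for one gene.

    beta is on the natural-log scale; alpha is the NB dispersion
    (Var = mu + alpha mu^2); sigma2_b the subject random-intercept variance.
    """

    beta: np.ndarray
    alpha: float
    sigma2_b: float
    is_de: bool = False

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        if not self.alpha >= 0:
            raise ValueError("alpha must be >= 0")
        if not self.sigma2_b >= 0:
            raise ValueError("sigma2_b must be >= 0")


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with per-sample library sizes."""

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    size_factors: np.ndarray | None = None
    #: genes whose linear predictor overflowed during simulation (counts set
    #: to the clipped-mean draw and flagged here rather than crashing)
    overflow_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)):
                raise ValueError("counts must be integral")
            c = c.astype(np.int64)
        self.counts = c
        self.gene_ids = np.asarray(self.gene_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if len(self.gene_ids) != c.shape[0] or len(self.sample_ids) != c.shape[1]:
            raise ValueError("gene_ids/sample_ids do not match counts shape")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SurrogateParamDistribution:
    """Distribution of (mean CPM, dispersion, random-intercept variance) triplets.

    Two modes:

    * parametric surrogate (default): log2 mean-CPM ~ Normal(cpm_log2_mean,
      cpm_log2_sd^2) truncated below at ``cpm_floor``; dispersion follows the
      mean-dependent trend ``a0 + a1 / mean_count`` jittered by multiplicative
      log-normal noise; sigma2_b is log-normal.  The trend reproduces the
      typical bulk RNA-seq mean-dispersion decay; the sigma2_b scale covers
      common within-subject ICC ranges.
    * empirical: triplets resampled with replacement from a user table
      (columns mean_cpm, alpha, sigma2_b), mirroring resampling from real
      repeated-measures datasets.
    """

    triplets: pd.DataFrame | None = None
    cpm_log2_mean: float = 3.0
    cpm_log2_sd: float = 2.0
    cpm_floor: float = 0.1
    trend_a0: float = 0.05
    trend_a1: float = 2.0
    alpha_jitter_sdlog: float = 0.4
    sigma2_b_meanlog: float = float(np.log(0.2))
    sigma2_b_sdlog: float = 0.8

    def __post_init__(self):
        if self.triplets is not None:
            t = self.triplets
            required = {"mean_cpm", "alpha", "sigma2_b"}
            if not required.issubset(t.columns):
                raise ValueError(f"triplet table needs columns {sorted(required)}")
            if (t["mean_cpm"] <= 0).any() or (t["alpha"] <= 0).any() or (
                t["sigma2_b"] < 0
            ).any():
                raise ValueError("triplets must satisfy cpm>0, alpha>0, sigma2_b>=0")
        else:
            if self.cpm_log2_sd <= 0 or self.cpm_floor <= 0:
                raise ValueError("invalid surrogate CPM settings")
            if self.trend_a0 < 0 or self.trend_a1 < 0:
                raise ValueError("dispersion trend coefficients must be >= 0")

    @classmethod
    def from_triplet_tsv(cls, path) -> "SurrogateParamDistribution":
        return cls(triplets=pd.read_csv(path, sep="\t"))

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n triplets (mean_cpm, alpha, sigma2_b)."""
        if self.triplets is not None:
            idx = rng.integers(0, len(self.triplets), size=n)
            t = self.triplets.iloc[idx]
            return (
                t["mean_cpm"].to_numpy(float),
                t["alpha"].to_numpy(float),
                t["sigma2_b"].to_numpy(float),
            )
        # truncated draw: redraw values below the CPM floor
        log2cpm = rng.normal(self.cpm_log2_mean, self.cpm_log2_sd, size=n)
        cpm = 2.0 ** log2cpm
        low = cpm <= self.cpm_floor
        while low.any():
            cpm[low] = 2.0 ** rng.normal(self.cpm_log2_mean, self.cpm_log2_sd, size=low.sum())
            low = cpm <= self.cpm_floor
        mean_count = cpm * (TOTAL_LIBRARY_SIZE / 1e6)
        alpha = (self.trend_a0 + self.trend_a1 / mean_count) * rng.lognormal(
            0.0, self.alpha_jitter_sdlog, size=n
        )
        sigma2_b = rng.lognormal(self.sigma2_b_meanlog, self.sigma2_b_sdlog, size=n)
        return cpm, alpha, sigma2_b


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_gene_params(
    n_genes: int,
    dist: SurrogateParamDistribution | None = None,
    seed=None,
) -> list[GeneParams]:
    """Draw per-gene generative parameters.

    The drawn mean-CPM values are rescaled to sum to one million across the
    dataset and multiplied by the 25-million total library size; the log of
    that expected count becomes the intercept beta_0.  All other coefficients
    start at zero (null genes) until :func:`assign_de_effects` runs.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    dist = dist or SurrogateParamDistribution()
    rng = _as_rng(seed)
    cpm, alpha, sigma2_b = dist.sample(n_genes, rng)
    scaled_cpm = cpm / cpm.sum() * 1e6
    beta0 = np.log(scaled_cpm * TOTAL_LIBRARY_SIZE / 1e6)
    params = []
    for g in range(n_genes):
        beta = np.zeros(8)
        beta[0] = beta0[g]
        params.append(
            GeneParams(beta=beta, alpha=float(alpha[g]), sigma2_b=float(sigma2_b[g]))
        )
    return params


#: interaction effect magnitudes at timepoints 2, 3, 4
DE_EFFECT_SIZES = (1.0 / 3.0, 2.0 / 3.0, 1.0)


def assign_de_effects(
    params: list[GeneParams],
    prop_de: float = 0.2,
    effect_sign_rule: str = "shared",
    seed=None,
) -> list[GeneParams]:
    """Flag a fraction of genes as differentially expressed.

    DE genes receive group-by-time interaction effects (|b5|, |b6|, |b7|) =
    (1/3, 2/3, 1); all other non-intercept coefficients stay zero.  Signs
    follow ``effect_sign_rule``: "shared" draws one Rademacher sign per gene
    applied to all three effects (monotone time trend); "independent" draws a
    sign per effect.
    """
    if not 0.0 <= prop_de <= 1.0:
        raise ValueError("prop_de must be in [0, 1]")
    if effect_sign_rule not in ("shared", "independent"):
        raise ValueError("effect_sign_rule must be 'shared' or 'independent'")
    rng = _as_rng(seed)
    n = len(params)
    n_de = int(round(prop_de * n))
    de_idx = set(rng.choice(n, size=n_de, replace=False).tolist())
    out = []
    for g, p in enumerate(params):
        beta = p.beta.copy()
        beta[5:8] = 0.0
        if g in de_idx:
            if effect_sign_rule == "shared":
                signs = np.full(3, rng.choice([-1.0, 1.0]))
            else:
                signs = rng.choice([-1.0, 1.0], size=3)
            beta[5:8] = signs * np.asarray(DE_EFFECT_SIZES)
        out.append(replace(p, beta=beta, is_de=g in de_idx))
    return out


# exp() arguments above this exceed the sampler's feasible mean range
_ETA_MAX = 30.0


def simulate_dataset(
    params: list[GeneParams],
    design: StudyDesign,
    seed=None,
    library_factor_range: tuple[float, float] | None = None,
) -> CountMatrix:
    """Simulate one count matrix from gene parameters and a study design.

    Per gene: subject random intercepts b_i ~ N(0, sigma2_b); the mean is
    exp(x'beta + b_i) (times an optional per-sample library factor); counts
    are NB with size 1/alpha (exact Poisson when alpha == 0).  Genes whose
    linear predictor overflows are clipped and recorded in
    ``CountMatrix.overflow_genes`` instead of raising.
    """
    rng = _as_rng(seed)
    X = design.design_matrix()
    n_genes = len(params)
    n_samples = design.n_samples
    beta = np.stack([p.beta for p in params])  # (G, p)
    alpha = np.array([p.alpha for p in params])  # (G,)
    sigma_b = np.sqrt(np.array([p.sigma2_b for p in params]))  # (G,)

    b = rng.normal(size=(n_genes, design.n_subjects)) * sigma_b[:, None]
    eta = beta @ X.T + b[:, design.subject_index]
    if library_factor_range is not None:
        lo, hi = library_factor_range
        eta = eta + np.log(rng.uniform(lo, hi, size=n_samples))[None, :]

    overflow = np.where(np.any(eta > _ETA_MAX, axis=1))[0]
    if overflow.size:
        warnings.warn(
            f"{overflow.size} gene(s) had overflowing means; clipped and flagged",
            RuntimeWarning,
        )
        eta = np.minimum(eta, _ETA_MAX)
    mu = np.exp(eta)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    pois = alpha == 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = (1.0 / alpha[nb])[:, None]
        p = size / (size + mu[nb])
        counts[nb] = rng.negative_binomial(size, p)

    gene_ids = np.array([f"gene_{g + 1:05d}" for g in range(n_genes)])
    return CountMatrix(counts, gene_ids, design.sample_ids.copy(), overflow_genes=overflow)


def truth_table(params: list[GeneParams], gene_ids=None) -> pd.DataFrame:
    """Truth labels per gene (is_de plus the interaction coefficients)."""
    if gene_ids is None:
        gene_ids = [f"gene_{g + 1:05d}" for g in range(len(params))]
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "is_de": [p.is_de for p in params],
            "beta5": [p.beta[5] for p in params],
            "beta6": [p.beta[6] for p in params],
            "beta7": [p.beta[7] for p in params],
            "alpha": [p.alpha for p in params],
            "sigma2_b": [p.sigma2_b for p in params],
        }
    )


def cpm_filter(
    counts: CountMatrix, cpm_threshold: float = 1.0, min_samples: int | None = None
) -> tuple[CountMatrix, np.ndarray]:
    """Remove lowly expressed genes.

    Keeps genes with CPM > ``cpm_threshold`` in at least ``min_samples``
    samples (the standard rule uses the number of samples in one
    group-by-timepoint cell).  CPM is computed against the library sizes of
    the unfiltered matrix.  Returns the filtered matrix and the boolean keep
    mask aligned to the input genes.
    """
    if cpm_threshold <= 0:
        raise ValueError("cpm_threshold must be > 0")
    if min_samples is None:
        min_samples = 1
    if not 1 <= min_samples <= counts.n_samples:
        raise ValueError("min_samples out of range")
    lib = counts.library_sizes.astype(float)
    if np.any(lib == 0):
        raise ValueError("zero library size; cannot compute CPM")
    cpm = counts.counts / lib * 1e6
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("CPM filter removed every gene", RuntimeWarning)
    filtered = CountMatrix(
        counts.counts[keep],
        counts.gene_ids[keep],
        counts.sample_ids.copy(),
        overflow_genes=np.array(
            [i for i, g in enumerate(np.where(keep)[0]) if g in set(counts.overflow_genes)],
            dtype=int,
        ),
    )
    return filtered, keep
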