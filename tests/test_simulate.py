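import numpy as np
import pandas as pd
import pytest

from longde.design import StudyDesign
from longde.simulate import (
    CountMatrix,
    GeneParams,
    SurrogateParamDistribution,
    assign_de_effects,
    cpm_filter,
    draw_gene_params,
    simulate_dataset,
)


class TestDrawGeneParams:
    def test_intercept_scaling_rule(self):
        # one gene: its scaled CPM is 1e6, beta0 = log(1e6 * 25e6 / 1e6)
        params = draw_gene_params(1, seed=0)
        assert params[0].beta[0] == pytest.approx(np.log(25e6))

    def test_intercept_from_known_cpm_share(self):
        # two genes with equal CPM draws -> scaled CPM 5e5 each -> log(1.25e7)
        table = pd.DataFrame(
            {"mean_cpm": [10.0], "alpha": [0.1], "sigma2_b": [0.2]}
        )
        dist = SurrogateParamDistribution(triplets=table)
        params = draw_gene_params(2, dist, seed=0)
        for p in params:
            assert p.beta[0] == pytest.approx(np.log(0.5e6 * 25))

    def test_seeded_determinism(self):
        a = draw_gene_params(50, seed=42)
        b = draw_gene_params(50, seed=42)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.beta, pb.beta)
            assert pa.alpha == pb.alpha and pa.sigma2_b == pb.sigma2_b

    def test_all_effects_null_before_de_assignment(self):
        params = draw_gene_params(200, seed=1)
        assert len(params) == 200
        for p in params:
            np.testing.assert_array_equal(p.beta[1:], np.zeros(7))
            assert p.alpha > 0 and p.sigma2_b >= 0 and not p.is_de


class TestAssignDeEffects:
    def test_exact_de_count(self):
        params = draw_gene_params(100, seed=2)
        out = assign_de_effects(params, prop_de=0.2, seed=3)
        assert sum(p.is_de for p in out) == 20

    def test_zero_prop_de(self):
        params = assign_de_effects(draw_gene_params(30, seed=2), 0.0, seed=3)
        assert not any(p.is_de for p in params)

    def test_effect_sizes_and_shared_sign(self):
        params = assign_de_effects(draw_gene_params(50, seed=4), 1.0, seed=5)
        for p in params:
            mags = np.abs(p.beta[5:8])
            np.testing.assert_allclose(mags, [1 / 3, 2 / 3, 1.0])
            signs = np.sign(p.beta[5:8])
            assert len(set(signs)) == 1  # one Rademacher sign per gene
            np.testing.assert_array_equal(p.beta[1:5], np.zeros(4))

    def test_is_de_iff_nonzero_interactions(self):
        params = assign_de_effects(draw_gene_params(80, seed=6), 0.25, seed=7)
        for p in params:
            assert p.is_de == bool(np.any(p.beta[5:8] != 0))


class TestSimulateDataset:
    def test_poisson_limit_mean(self):
        d = StudyDesign(
            subject_ids=np.arange(10_000), group=np.zeros(10_000, int),
            time=np.ones(10_000, int),
        )
        beta = np.zeros(2)
        beta[0] = np.log(250.0)
        p = GeneParams(beta=beta, alpha=0.0, sigma2_b=0.0)
        cm = _simulate_flat(p, d, seed=8)
        m = cm.counts[0].mean()
        se = np.sqrt(250.0 / 10_000)
        assert abs(m - 250.0) < 3 * se

    def test_nb_variance_identity(self):
        d = StudyDesign(
            subject_ids=np.arange(10_000), group=np.zeros(10_000, int),
            time=np.ones(10_000, int),
        )
        beta = np.zeros(2)
        beta[0] = np.log(100.0)
        p = GeneParams(beta=beta, alpha=0.5, sigma2_b=0.0)
        cm = _simulate_flat(p, d, seed=9)
        v = cm.counts[0].var()
        # Var = mu + alpha mu^2 = 5100; MC tolerance from 4th-moment spread
        assert v == pytest.approx(5100, rel=0.15)

    def test_poisson_index_of_dispersion(self):
        d = StudyDesign(
            subject_ids=np.arange(10_000), group=np.zeros(10_000, int),
            time=np.ones(10_000, int),
        )
        beta = np.zeros(2)
        beta[0] = np.log(50.0)
        p = GeneParams(beta=beta, alpha=0.0, sigma2_b=0.0)
        cm = _simulate_flat(p, d, seed=10)
        y = cm.counts[0]
        assert y.var() / y.mean() == pytest.approx(1.0, abs=0.1)

    def test_interaction_effect_mean_ratio(self):
        # beta7 = 1 shifts the treatment/time-4 mean by e relative to control
        d = StudyDesign.balanced(2)
        beta = np.zeros(8)
        beta[0], beta[7] = np.log(100.0), 1.0
        p = GeneParams(beta=beta, alpha=0.1, sigma2_b=0.0)
        X = d.design_matrix()
        mu = np.exp(X @ beta)
        treat_t4 = mu[(d.group == 1) & (d.time == 4)]
        ctrl_t4 = mu[(d.group == 0) & (d.time == 4)]
        assert treat_t4[0] / ctrl_t4[0] == pytest.approx(np.e)

    def test_seed_reproducibility_and_divergence(self, design5):
        params = assign_de_effects(draw_gene_params(40, seed=1), 0.2, seed=2)
        a = simulate_dataset(params, design5, seed=3)
        b = simulate_dataset(params, design5, seed=3)
        c = simulate_dataset(params, design5, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert np.any(a.counts != c.counts)

    def test_null_gene_marginal_mean_invariant_across_cells(self, rng):
        d = StudyDesign.balanced(200)
        beta = np.zeros(8)
        beta[0] = np.log(100.0)
        p = GeneParams(beta=beta, alpha=0.2, sigma2_b=0.3)
        cm = simulate_dataset([p], d, seed=11)
        y = cm.counts[0]
        cell_means = [
            y[(d.group == g) & (d.time == t)].mean()
            for g in (0, 1) for t in range(1, 5)
        ]
        grand = y.mean()
        for m in cell_means:
            assert abs(m - grand) / grand < 0.25

    def test_within_subject_correlation_increases_with_sigma2b(self):
        d = StudyDesign.balanced(600, n_timepoints=2)
        cors = []
        for s2 in (0.0, 0.3, 1.0):
            beta = np.zeros(4)
            beta[0] = np.log(200.0)
            p = GeneParams(beta=beta, alpha=0.05, sigma2_b=s2)
            cm = simulate_dataset([p], d, seed=12)
            y = np.log1p(cm.counts[0].astype(float)).reshape(-1, 2)
            cors.append(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
        assert cors[0] < cors[1] < cors[2]

    def test_overflow_flagged_not_crashed(self, design5):
        beta = np.zeros(8)
        beta[0] = 100.0  # exp overflow territory
        p = GeneParams(beta=beta, alpha=0.1, sigma2_b=0.0)
        with pytest.warns(RuntimeWarning, match="overflow"):
            cm = simulate_dataset([p], design5, seed=13)
        assert 0 in cm.overflow_genes


def _simulate_flat(p, design, seed):
    return simulate_dataset([p], design, seed=seed)


class TestCpmFilter:
    def _matrix(self, row):
        # pad with a constant gene so library sizes are controlled separately
        counts = np.array([row], dtype=np.int64)
        return CountMatrix(counts, np.array(["g1"]), np.array([f"s{i}" for i in range(len(row))]))

    def test_all_zero_gene_removed(self):
        counts = np.array([[0, 0, 0, 0], [10 ** 6] * 4])
        cm = CountMatrix(counts, np.array(["g0", "g1"]), np.array(list("abcd")))
        filtered, keep = cpm_filter(cm, 1.0, min_samples=1)
        assert not keep[0] and keep[1]

    def test_threshold_and_min_samples_hand_case(self):
        # library sizes ~1e6 per sample; gene (2,2,2,0) has CPM ~2 in 3 samples
        filler = np.full(4, 10 ** 6 - 1, dtype=np.int64)
        counts = np.vstack([[2, 2, 2, 0], filler - [1, 1, 1, -1]])
        cm = CountMatrix(counts, np.array(["g0", "fill"]), np.array(list("abcd")))
        assert np.allclose(cm.library_sizes, 10 ** 6)
        _, keep3 = cpm_filter(cm, 1.0, min_samples=3)
        assert keep3[0]
        _, keep4 = cpm_filter(cm, 1.0, min_samples=4)
        assert not keep4[0]

    def test_empty_result_warns(self):
        cm = CountMatrix(
            np.array([[1, 1], [1, 1]]), np.array(["a", "b"]), np.array(["s1", "s2"])
        )
        with pytest.warns(RuntimeWarning, match="every gene"):
            filtered, keep = cpm_filter(cm, 1e6, min_samples=1)
        assert filtered.n_genes == 0
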