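import numpy as np
import pytest

from flimma.data_model import AnalysisConfig, ValidationError
from flimma.fed_linear_voom import (
    TrendCurve,
    fit_trend,
    global_fit,
    global_sigma,
    local_normal_equations,
    local_sse,
    local_voom_weights,
)
from flimma.federation import ClientState, FederatedNetwork, pool_clients, run_flimma
from flimma.secure_masking import aggregate_denoise, mask_real
from flimma.synthetic_data import SimulationSpec, generate_dataset, split_cohorts


class TestNormalEquations:
    def test_single_sample_identity(self):
        XtX, XtY = local_normal_equations(
            np.array([[1.0]]), np.array([[3.5]])
        )
        assert XtX[0] == pytest.approx(1.0)
        assert XtY[0] == pytest.approx(3.5)

    def test_unit_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(4, 6))
        a = local_normal_equations(X, Y)
        b = local_normal_equations(X, Y, np.ones_like(Y))
        assert np.allclose(a[0], b[0]) and np.allclose(a[1], b[1])

    def test_three_client_denoised_sum_equals_pooled_product(self):
        """Masked aggregation of per-client blocks reproduces the pooled
        X^T W X / X^T W Y within the Gaussian-scheme rounding bound."""
        rng = np.random.default_rng(1)
        Xs = [rng.normal(size=(5, 3)) for _ in range(3)]
        Ys = [rng.normal(size=(7, 5)) for _ in range(3)]
        Ws = [rng.uniform(0.5, 2.0, size=(7, 5)) for _ in range(3)]
        blocks = [local_normal_equations(x, y, w) for x, y, w in zip(Xs, Ys, Ws)]
        pairs = [mask_real(b[0], 1e12, rng) for b in blocks]
        out = aggregate_denoise([a for a, _ in pairs], [b for _, b in pairs])
        Xp = np.vstack(Xs)
        Yp = np.hstack(Ys)
        Wp = np.hstack(Ws)
        pooled = local_normal_equations(Xp, Yp, Wp)[0]
        assert np.abs(out - pooled).max() <= 1e-6

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            local_normal_equations(
                np.ones((2, 1)), np.ones((1, 2)), np.array([[1.0, 0.0]])
            )


class TestGlobalFit:
    def test_intercept_only_model_gives_weighted_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(3, 8))
        w = rng.uniform(0.5, 2.0, size=(3, 8))
        X = np.ones((8, 1))
        XtWX, XtWY = local_normal_equations(X, y, w)
        beta, _ = global_fit(XtWX, XtWY)
        expected = (w * y).sum(axis=1) / w.sum(axis=1)
        assert np.allclose(beta[:, 0], expected)

    def test_matches_brute_force_least_squares(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(12), rng.integers(0, 2, 12), rng.normal(size=12)])
        Y = rng.normal(size=(5, 12))
        XtWX, XtWY = local_normal_equations(X, Y)
        beta, se = global_fit(XtWX, XtWY)
        for g in range(5):
            ref, *_ = np.linalg.lstsq(X, Y[g], rcond=None)
            assert np.abs(beta[g] - ref).max() <= 1e-8
        assert np.allclose(se**2, np.diag(np.linalg.inv(X.T @ X)), atol=1e-10)

    def test_orthonormal_design_gives_unit_unscaled_se(self):
        X = np.eye(3)
        XtWX, XtWY = local_normal_equations(X, np.ones((2, 3)))
        _, se = global_fit(XtWX, XtWY)
        assert np.allclose(se, 1.0)

    def test_singular_system_reported(self):
        XtWX = np.zeros((2, 2, 2))
        with pytest.raises(ValidationError, match="singular|ill-conditioned"):
            global_fit(XtWX, np.zeros((2, 2)))


class TestSseAndSigma:
    def test_perfect_fit_contributes_zero(self):
        X = np.ones((3, 1))
        beta = np.array([[2.0]])
        Y = np.full((1, 3), 2.0)
        assert local_sse(X, beta, Y)[0] == pytest.approx(0.0)

    def test_hand_summed_residuals(self):
        X = np.ones((2, 1))
        beta = np.array([[0.0]])
        Y = np.array([[1.0, -1.0]])
        assert local_sse(X, beta, Y)[0] == pytest.approx(2.0)

    def test_sigma_hand_arithmetic(self):
        sigma, df = global_sigma(np.array([8.0]), 10, 2)
        assert sigma[0] == pytest.approx(1.0) and df == 8

    def test_three_client_sse_equals_pooled(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(9), rng.normal(size=9)])
        Y = rng.normal(size=(6, 9))
        beta = np.linalg.lstsq(X, Y.T, rcond=None)[0].T
        parts = [
            local_sse(X[i::3], beta, Y[:, i::3]) for i in range(3)
        ]
        pooled = local_sse(X, beta, Y)
        assert np.abs(np.sum(parts, axis=0) - pooled).max() <= 1e-10

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValidationError):
            global_sigma(np.array([1.0]), 2, 2)


class TestTrend:
    def test_constant_sigma_gives_constant_curve(self):
        rng = np.random.default_rng(5)
        amean = rng.uniform(0, 10, 50)
        trend = fit_trend(amean, np.full(50, 0.25), 20.0)
        assert np.allclose(trend(np.linspace(-5, 30, 7)), 0.5, atol=1e-6)

    def test_decreasing_variance_gives_decreasing_bulk(self):
        rng = np.random.default_rng(6)
        amean = np.sort(rng.uniform(0, 10, 300))
        sigma = np.exp(-0.3 * amean) + rng.normal(0, 0.01, 300) ** 2
        trend = fit_trend(amean, sigma, 20.0)
        xs = np.linspace(np.quantile(trend.x, 0.1), np.quantile(trend.x, 0.9), 20)
        ys = trend(xs)
        assert np.sum(np.diff(ys) < 1e-9) >= 15  # decreasing over the bulk

    def test_degenerate_x_range_falls_back_to_median(self):
        trend = fit_trend(np.full(20, 3.0), np.full(20, 0.09), 20.0)
        assert trend(np.array([0.0]))[0] == pytest.approx(0.3)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            fit_trend(np.arange(5.0), np.ones(5), 20.0)


class TestVoomWeights:
    def test_constant_trend_gives_constant_weights(self):
        trend = TrendCurve(np.array([0.0, 10.0]), np.array([0.5, 0.5]))
        X = np.ones((4, 1))
        beta = np.array([[1.0], [2.0]])
        w = local_voom_weights(X, beta, np.full(4, 1e6), trend)
        assert np.allclose(w, 0.5**-4)

    def test_decreasing_trend_gives_larger_weight_at_higher_count(self):
        trend = TrendCurve(np.array([0.0, 10.0]), np.array([1.0, 0.2]))
        X = np.ones((1, 1))
        beta = np.array([[2.0], [8.0]])
        w = local_voom_weights(X, beta, np.array([1e6]), trend)
        assert w[1, 0] > w[0, 0]

    def test_weights_clamped_and_bounded(self):
        trend = TrendCurve(np.array([2.0, 4.0]), np.array([0.4, 0.2]))
        X = np.ones((3, 1))
        beta = np.array([[-50.0], [50.0]])
        w = local_voom_weights(X, beta, np.full(3, 1e6), trend)
        assert np.all(np.isfinite(w)) and np.all(w > 0)
        assert w.max() <= 0.2**-4 + 1e-12


class TestTwoPass:
    def test_planted_fold_change_recovered(self):
        """On a large balanced simulation the fitted coefficient of a
        planted DE gene approaches its true log2 fold change."""
        spec = SimulationSpec(n_genes=300, n_samples=200, de_fraction=0.2, seed=21)
        cm, dm, truth = generate_dataset(spec)
        cfg = AnalysisConfig(coefficient="group", seed=1, masking=False)
        table = run_flimma([(cm, dm)], cfg)
        pos = {g: i for i, g in enumerate(truth.gene_ids)}
        kept_de = [
            (table.log_fc[j], truth.true_lfc[pos[g]])
            for j, g in enumerate(table.gene_ids)
            if truth.is_de[pos[g]]
        ]
        est = np.array([e for e, _ in kept_de])
        true = np.array([t for _, t in kept_de])
        # log-CPM offsets shrink |logFC| slightly; direction and magnitude
        # must still track the planted effect closely
        assert np.all(np.sign(est) == np.sign(true))
        assert np.mean(np.abs(est - true)) < 0.3
        assert np.corrcoef(est, true)[0, 1] > 0.98

    def test_all_outputs_finite(self, small_cohorts, config):
        table = run_flimma(small_cohorts, config)
        for arr in (table.log_fc, table.ave_expr, table.t_mod,
                    table.p_value, table.adj_p_value):
            assert np.all(np.isfinite(arr))

    def test_beta_sigma_partition_invariant(self, small_dataset):
        from flimma.federation import run_flimma_detailed

        cm, dm, truth = small_dataset
        cohorts = split_cohorts(cm, dm, truth, [1, 2], seed=3)
        cfg = AnalysisConfig(coefficient="group", seed=1, masking=False)
        fed = run_flimma_detailed(cohorts, cfg)
        pooled = run_flimma_detailed([pool_clients(cohorts)], cfg)
        assert fed.gene_ids == pooled.gene_ids
        assert np.abs(fed.state.beta - pooled.state.beta).max() <= 1e-6
        assert np.abs(fed.state.sigma - pooled.state.sigma).max() <= 1e-6
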