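import numpy as np
import pytest
from scipy import stats

from flimma.data_model import AnalysisConfig, DEResultTable, ValidationError
from flimma.federation import pool_clients, run_flimma
from flimma.meta_baselines import (
    CohortResult,
    cohort_results,
    combine_fold_changes,
    evaluate,
    fisher_combine,
    meta_table,
    rank_product,
    rem_combine,
    stouffer_combine,
)
from flimma.synthetic_data import SimulationSpec, generate_dataset, split_cohorts


def cohort(log_fc, p, se=None, n=10):
    log_fc = np.asarray(log_fc, float)
    p = np.asarray(p, float)
    if se is None:
        se = np.ones_like(log_fc)
    return CohortResult(
        gene_ids=[f"g{i}" for i in range(log_fc.size)],
        log_fc=log_fc,
        p_value=p,
        effect_se=np.asarray(se, float),
        n_samples=n,
    )


class TestFisher:
    def test_all_null_consistent_direction(self):
        p = fisher_combine([cohort([1, 1], [1, 1]), cohort([1, 1], [1, 1])])
        assert np.allclose(p, 1.0)

    def test_matches_chi_square_tail(self):
        # two cohorts, one-sided p = 0.025 each, same (up) direction
        c = cohort([2.0], [0.05])
        p = fisher_combine([c, c])
        chi2 = -2 * 2 * np.log(0.025)
        expected = min(1.0, 2 * stats.chi2.sf(chi2, df=4))
        assert p[0] == pytest.approx(expected, rel=1e-12)

    def test_cohort_order_invariance(self):
        rng = np.random.default_rng(0)
        cs = [
            cohort(rng.normal(size=6), rng.uniform(0.001, 1, 6)) for _ in range(3)
        ]
        assert np.allclose(fisher_combine(cs), fisher_combine(cs[::-1]))

    def test_opposite_directions_do_not_reinforce(self):
        up = cohort([2.0], [0.01])
        down = cohort([-2.0], [0.01])
        assert fisher_combine([up, down])[0] > fisher_combine([up, up])[0]


class TestStouffer:
    def test_two_equal_cohorts_cancel(self):
        p0 = 2 * stats.norm.sf(1.96)
        up = cohort([1.0], [p0])
        down = cohort([-1.0], [p0])
        assert stouffer_combine([up, down])[0] == pytest.approx(1.0, abs=1e-9)

    def test_three_unequal_cohorts_match_direct_formula(self):
        ps = [0.03, 0.2, 0.6]
        fcs = [1.0, 1.0, -1.0]
        ns = [10, 40, 90]
        cs = [cohort([f], [p], n=n) for f, p, n in zip(fcs, ps, ns)]
        w = np.sqrt(ns)
        z = np.array([stats.norm.isf(p / 2) * np.sign(f) for p, f in zip(ps, fcs)])
        Z = (w * z).sum() / np.sqrt((w**2).sum())
        assert stouffer_combine(cs)[0] == pytest.approx(
            2 * stats.norm.sf(abs(Z)), rel=1e-12
        )


class TestREM:
    def test_identical_effects_have_zero_heterogeneity(self):
        c = cohort([2.0, -1.0], [0.1, 0.1], se=[0.5, 0.5])
        effect, p = rem_combine([c, c, c])
        assert np.allclose(effect, [2.0, -1.0])

    def test_dersimonian_laird_toy(self):
        # e = (1, 3), v = (1, 1): Q = 2, tau2 = (2-1)/(2-1) = 1,
        # w* = 1/2 each -> effect 2, se = 1, p = 2(1-Phi(2))
        a = cohort([1.0], [0.5], se=[1.0])
        b = cohort([3.0], [0.5], se=[1.0])
        effect, p = rem_combine([a, b])
        assert effect[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-12)

    def test_tau2_never_negative_reduces_to_fixed_effects(self):
        # identical effects: Q = 0 -> tau2 clamped at 0, inverse-variance weights
        a = cohort([1.0], [0.5], se=[1.0])
        b = cohort([1.0], [0.5], se=[2.0])
        effect, _ = rem_combine([a, b])
        w = np.array([1.0, 1 / 4.0])
        assert effect[0] == pytest.approx((w @ [1.0, 1.0]) / w.sum())

    def test_single_cohort_rejected(self):
        with pytest.raises(ValidationError):
            rem_combine([cohort([1.0], [0.5])])


class TestRankProduct:
    def test_consistent_top_gene_is_most_significant(self):
        rng = np.random.default_rng(5)
        fc = rng.normal(size=(3, 12))
        fc[:, 0] = 5.0  # top-ranked "up" in every cohort
        cs = [cohort(f, np.full(12, 0.5)) for f in fc]
        p_up, _ = rank_product(cs, n_perm=300, rng=np.random.default_rng(1))
        assert p_up[0] == p_up.min()

    def test_matches_exhaustive_enumeration_on_tiny_case(self):
        """5 genes x 2 cohorts: the permutation p-value agrees with exact
        enumeration of all within-cohort rank shuffles."""
        import itertools

        fc = np.array([[2.0, 1.0, 0.0, -1.0, -2.0],
                       [1.5, 2.5, -0.5, 0.5, -1.5]])
        cs = [cohort(f, np.full(5, 0.5)) for f in fc]
        p_up, _ = rank_product(cs, n_perm=4000, rng=np.random.default_rng(2))
        ranks = np.array([stats.rankdata(-f) for f in fc])
        obs = np.log(ranks).mean(axis=0)
        null = []
        base = np.arange(1.0, 6.0)
        for perm1 in itertools.permutations(base):
            for perm2 in itertools.permutations(base):
                null.extend(np.log([perm1, perm2]).mean(axis=0))
        null = np.sort(null)
        exact = (np.searchsorted(null, obs, side="right") + 1) / (len(null) + 1)
        # Monte-Carlo agreement within 3 binomial SEs
        n_eff = 4000 * 5
        se = np.sqrt(exact * (1 - exact) / n_eff)
        assert np.all(np.abs(p_up - exact) <= 3 * se + 1e-3)

    def test_up_down_symmetry(self):
        rng = np.random.default_rng(6)
        fc = rng.normal(size=(2, 8))
        cs = [cohort(f, np.full(8, 0.5)) for f in fc]
        p_up, p_down = rank_product(cs, n_perm=200, rng=np.random.default_rng(3))
        cs_neg = [cohort(-f, np.full(8, 0.5)) for f in fc]
        q_up, q_down = rank_product(cs_neg, n_perm=200, rng=np.random.default_rng(3))
        assert np.allclose(p_up, q_down) and np.allclose(p_down, q_up)


class TestFoldChangeCombination:
    def test_mean_and_invariance(self):
        a, b = cohort([1.0], [0.5]), cohort([3.0], [0.5])
        assert combine_fold_changes([a, b])[0] == pytest.approx(2.0)
        assert combine_fold_changes([b, a])[0] == pytest.approx(2.0)
        assert combine_fold_changes([a])[0] == pytest.approx(1.0)


class TestEvaluate:
    def make_table(self, p, lfc):
        n = len(p)
        p = np.asarray(p, float)
        return DEResultTable(
            [f"g{i}" for i in range(n)], np.asarray(lfc, float),
            np.zeros(n), np.zeros(n), p, p,
        )

    def test_identical_tables_score_perfectly(self):
        t = self.make_table([0.001, 0.2, 0.6], [2.0, 0.1, -0.2])
        rep = evaluate(t, t)
        assert rep.rmse == 0.0 and rep.f1 == 1.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.fp == rep.fn == 0

    def test_inverted_ranking_gives_spearman_minus_one(self):
        truth = self.make_table([0.1, 0.2, 0.3, 0.4], [0, 0, 0, 0])
        cand = self.make_table([0.4, 0.3, 0.2, 0.1], [0, 0, 0, 0])
        assert evaluate(cand, truth).spearman_rho == pytest.approx(-1.0)

    def test_hand_computed_confusion_matrix(self):
        # truth calls g0, g1; candidate calls g1, g2 -> TP=1, FP=1, FN=1
        truth = self.make_table([0.01, 0.01, 0.01, 0.5, 0.5, 0.5],
                                [2, 2, 0.5, 2, 0, 0])
        cand = self.make_table([0.5, 0.01, 0.01, 0.5, 0.5, 0.5],
                               [2, 2, 2, 2, 0, 0])
        rep = evaluate(cand, truth)
        assert rep.fp == 1 and rep.fn == 1
        assert rep.precision == pytest.approx(0.5)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(0.5)

    def test_gene_universe_mismatch_rejected(self):
        a = self.make_table([0.1], [0.0])
        b = self.make_table([0.1, 0.2], [0.0, 0.0])
        with pytest.raises(ValidationError):
            evaluate(a, b)


class TestConsistencyAmplification:
    def test_identical_cohorts_strengthen_small_p(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p0 = float(rng.uniform(1e-6, 0.05))
            c = cohort([1.0], [p0])
            assert fisher_combine([c, c])[0] <= p0
            assert stouffer_combine([c, c])[0] <= p0


class TestFlimmaVsMeta:
    def test_federated_pipeline_dominates_meta_methods_on_f1(self, small_dataset):
        """On a balanced split the federated run reproduces the pooled
        oracle exactly (F1 = 1), while each meta-method can at best tie."""
        cm, dm, truth = small_dataset
        cohorts = split_cohorts(cm, dm, truth, [1, 1, 1], seed=5)
        cfg = AnalysisConfig(coefficient="group", seed=1, masking=False)
        oracle = run_flimma([pool_clients(cohorts)], cfg)
        fed = run_flimma(cohorts, cfg)
        rep_fed = evaluate(fed, oracle, cfg)
        assert rep_fed.f1 == pytest.approx(1.0)
        locals_ = cohort_results(cohorts, cfg)
        shared = locals_[0].gene_ids
        oracle_shared = oracle.subset(shared)
        for method in ("fisher", "stouffer", "rem"):
            tab = meta_table(locals_, method)
            rep = evaluate(tab, oracle_shared, cfg)
            assert rep.f1 <= rep_fed.f1 + 1e-12
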