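"""Variable-rates model: likelihoods, RJ-MCMC, stepping stone, post-processing."""

import math

import numpy as np
import pytest

from mosaicbrain import pgls
from mosaicbrain import varrates as vr
from mosaicbrain.synthetic import (
    random_tree, simulate_bm, simulate_vr_scenario, _clade_of_size,
)
from mosaicbrain.trees import read_tree


class TestScalarMap:
    def test_validation(self):
        with pytest.raises(ValueError):
            vr.ScalarMap([("edge", 1, 2.0)])
        with pytest.raises(ValueError):
            vr.ScalarMap([("branch", 1, -1.0)])

    def test_overlapping_assignments_multiply(self, three_tip_tree):
        t = three_tip_tree
        inner = next(i for i in range(1, t.n_nodes)
                     if not t.is_tip(i))
        tip_a = next(i for i in t.tip_indices if t.labels[i] == "A")
        m = vr.ScalarMap([("clade", inner, 2.0),
                          ("branch", tip_a, 3.0)]).effective_multipliers(t)
        assert m[tip_a] == pytest.approx(6.0)
        assert m[inner] == pytest.approx(2.0)


class TestVRLoglik:
    def test_unit_scalars_equal_null_bm_likelihood(self, rng):
        tree = random_tree(20, seed=2, scale_to_height=1.0)
        x = simulate_bm(tree, 1.0, seed=rng).values
        y = 1 + x + simulate_bm(tree, 0.5, seed=rng).values
        X = np.column_stack([np.ones(20), x])
        fit = pgls.fit_pgls(y, X, tree, lam=1.0)
        ll = vr.vr_loglik(y, X, tree, vr.ScalarMap(), fit.beta, fit.sigma2)
        assert ll == pytest.approx(fit.loglik, abs=1e-10)

    def test_terminal_branch_scaling_hand_values(self, three_tip_tree):
        t = three_tip_tree
        tip_c = next(i for i in t.tip_indices if t.labels[i] == "C")
        m = vr.ScalarMap([("branch", tip_c, 4.0)]).effective_multipliers(t)
        E, order = t.tip_membership(["A", "B", "C"])
        V = E.T @ ((t.lengths * m)[:, None] * E)
        # C's depth goes from 2 to 8 (its 2-My branch x4); A,B untouched
        assert V[2, 2] == pytest.approx(8.0)
        assert V[0, 0] == pytest.approx(2.0)
        assert V[0, 1] == pytest.approx(1.0)

    def test_global_scalar_sigma2_tradeoff_invariance(self, rng):
        tree = random_tree(12, seed=5, scale_to_height=1.0)
        y = simulate_bm(tree, 1.0, seed=rng).values
        X = np.ones((12, 1))
        beta = np.array([y.mean()])
        root_children = tree.children[0]
        c = 3.7
        smap = vr.ScalarMap([("clade", e, c) for e in root_children])
        ll_scaled = vr.vr_loglik(y, X, tree, smap, beta, 1.0 / c)
        ll_plain = vr.vr_loglik(y, X, tree, vr.ScalarMap(), beta, 1.0)
        assert ll_scaled == pytest.approx(ll_plain, abs=1e-9)

    def test_prior_predictive_never_breaks_psd(self):
        """Pushing random prior draws of scalar maps through the likelihood
        never raises (the covariance stays numerically PD)."""
        tree = random_tree(20, seed=8, scale_to_height=100.0)
        rng = np.random.default_rng(0)
        x = simulate_bm(tree, 0.01, seed=rng).values
        y = 0.3 + x + simulate_bm(tree, 0.0003, seed=rng).values
        X = np.column_stack([np.ones(20), x])
        targets = [("branch", e) for e in range(1, tree.n_nodes)]
        targets += [("clade", e) for e in range(1, tree.n_nodes)
                    if not tree.is_tip(e)]
        for _ in range(1000):
            k = rng.poisson(1.0)
            chosen = rng.choice(len(targets), size=min(k, len(targets)),
                                replace=False)
            smap = vr.ScalarMap([(targets[i][0], targets[i][1],
                                  float(np.exp(rng.normal(0, 1))))
                                 for i in chosen])
            ll = vr.vr_loglik(y, X, tree, smap, np.array([0.3, 1.0]), 3e-4)
            assert np.isfinite(ll)


class TestBayesFactor:
    @pytest.mark.parametrize("m,n0,bf,label", [
        (-100.0, -110.0, 20.0, "very strong"),
        (-100.0, -100.0, 0.0, "none"),
        (-100.0, -103.5, 7.0, "strong"),
    ])
    def test_formula_and_labels(self, m, n0, bf, label):
        out = vr.bayes_factor(m, n0)
        assert out.bf == pytest.approx(bf)
        assert out.support == label


class TestSteppingStone:
    def test_constant_likelihood_returns_log_constant(self, rng):
        """The null model's collapsed likelihood is a single constant, so the
        stepping-stone estimate equals it exactly for any stone count."""
        tree = random_tree(10, seed=1, scale_to_height=1.0)
        y = simulate_bm(tree, 1.0, seed=rng).values
        X = np.ones((10, 1))
        exact = vr.marginal_loglik_null(y, X, tree)
        for K in (4, 32):
            est = vr.stepping_stone(y, X, tree, model="null", n_stones=K)
            assert est.log_mlh == pytest.approx(exact, abs=1e-12)
            assert est.mc_se == 0.0

    def test_powers_schedule_monotone_in_unit_interval(self):
        p = vr.ss_powers(32, 0.4)
        assert p[0] == 0.0 and p[-1] == 1.0
        assert np.all(np.diff(p) > 0)

    def test_estimate_matches_quadrature_oracle(self):
        from mosaicbrain.benchmarks import _vr_marginal_by_quadrature
        tree = read_tree("((A:1,B:1):1,C:2):0;")
        y = np.array([1.0, 1.3, 0.2])
        X = np.ones((3, 1))
        prior = vr.VRPrior(p_on=0.05)
        exact = _vr_marginal_by_quadrature(y, X, tree, prior, n_grid=32)
        est = vr.stepping_stone(y, X, tree, model="vr", prior=prior,
                                n_stones=10, n_per_stone=400,
                                warmup_per_stone=200, posterior_warmup=500,
                                thin=2, seed=5)
        assert est.log_mlh == pytest.approx(exact, abs=0.5)

    def test_stone_counts_agree_within_mc_error(self):
        tree = read_tree("((A:1,B:1):1,C:2):0;")
        y = np.array([0.4, -0.2, 1.1])
        X = np.ones((3, 1))
        prior = vr.VRPrior(p_on=0.05)
        ests = [vr.stepping_stone(y, X, tree, model="vr", prior=prior,
                                  n_stones=K, n_per_stone=400,
                                  warmup_per_stone=200, posterior_warmup=500,
                                  thin=2, seed=9)
                for K in (10, 50)]
        se = math.hypot(ests[0].mc_se, ests[1].mc_se)
        assert abs(ests[0].log_mlh - ests[1].log_mlh) <= max(2 * se, 0.2)


class TestRunVRMCMC:
    def test_null_data_median_scalars_near_one(self):
        """Homogeneous BM: the posterior stays sparse, so per-branch median
        effective scalars sit at 1 for nearly every branch."""
        hits = total = 0
        for rep in range(3):
            tree, y, X, _ = simulate_vr_scenario(n_tips=48, rate_factor=1.0,
                                                 seed=200 + rep)
            post = vr.run_vr_mcmc(y, X, tree, n_iter=30_000, burnin=6000,
                                  sample_interval=40, seed=rep)
            med = post.branch_scalar_stat("median")[1:]
            hits += int(np.mean((med >= 0.5) & (med <= 2.0)) >= 0.95)
            total += 1
        assert hits >= 2

    def test_clade_rate_recovery(self):
        detected = 0
        for rep in range(3):
            tree, y, X, node = simulate_vr_scenario(rate_factor=10.0,
                                                    seed=300 + rep)
            post = vr.run_vr_mcmc(y, X, tree, n_iter=40_000, burnin=8000,
                                  sample_interval=40, seed=rep)
            m = post.branch_scalar_stat("mean")
            ce = set(tree.clade_edges(node))
            inside = np.mean([m[e] for e in range(1, tree.n_nodes) if e in ce])
            outside = np.mean([m[e] for e in range(1, tree.n_nodes)
                               if e not in ce])
            detected += int(inside > outside)
        assert detected >= 2

    def test_acceptance_rates_reported(self):
        tree, y, X, _ = simulate_vr_scenario(n_tips=24, rate_factor=1.0, seed=7)
        post = vr.run_vr_mcmc(y, X, tree, n_iter=10_000, burnin=2000,
                              sample_interval=40, seed=0)
        assert set(post.acceptance) == {"add", "delete", "resize"}


class TestPostProcessing:
    def _posterior_with(self, tree, samples):
        mult = np.array(samples, dtype=float)
        n = len(mult)
        return vr.VRPosterior(tree=tree, multipliers=mult,
                              n_scalars=np.zeros(n, dtype=int),
                              loglik=np.zeros(n), beta=np.zeros((n, 1)),
                              sigma2=np.ones(n), acceptance={}, chain={})

    def test_constant_scalar_doubles_one_branch(self, three_tip_tree):
        t = three_tip_tree
        m = np.ones(t.n_nodes)
        m[1] = 2.0
        post = self._posterior_with(t, [m, m, m])
        scaled = vr.scaled_branch_lengths(post, "mean")
        assert scaled.lengths[1] == pytest.approx(2 * t.lengths[1])
        assert np.allclose(scaled.lengths[2:], t.lengths[2:])

    def test_no_scalars_identity_tree(self, three_tip_tree):
        t = three_tip_tree
        post = self._posterior_with(t, [np.ones(t.n_nodes)] * 5)
        scaled = vr.scaled_branch_lengths(post, "median")
        assert np.allclose(scaled.lengths, t.lengths)

    def test_mean_vs_median_order_statistics(self, three_tip_tree):
        t = three_tip_tree
        samples = []
        for r in (1.0, 2.0, 9.0):
            m = np.ones(t.n_nodes)
            m[1] = r
            samples.append(m)
        post = self._posterior_with(t, samples)
        assert vr.scaled_branch_lengths(post, "mean").lengths[1] == \
            pytest.approx(4 * t.lengths[1])
        assert vr.scaled_branch_lengths(post, "median").lengths[1] == \
            pytest.approx(2 * t.lengths[1])

    def test_rank_deviant_branches(self, three_tip_tree):
        t = three_tip_tree
        m = np.ones(t.n_nodes)
        m[2] = 5.0
        post = self._posterior_with(t, [m])
        scaled = vr.scaled_branch_lengths(post, "mean")
        top = vr.rank_deviant_branches(scaled, t, k=2)
        assert top[0][0] == 2 and top[0][1] == pytest.approx(5.0)
        # all-ones case: nothing exceeds ratio 1
        ident = vr.scaled_branch_lengths(
            self._posterior_with(t, [np.ones(t.n_nodes)]), "mean")
        ratios = [r for _, r in vr.rank_deviant_branches(ident, t, k=10)]
        assert all(r == pytest.approx(1.0) for r in ratios)

    def test_recovered_clade_stem_ranks_high(self):
        tree, y, X, node = simulate_vr_scenario(rate_factor=10.0, seed=17)
        post = vr.run_vr_mcmc(y, X, tree, n_iter=40_000, burnin=8000,
                              sample_interval=40, seed=2)
        scaled = vr.scaled_branch_lengths(post, "mean")
        top = [e for e, _ in vr.rank_deviant_branches(scaled, tree, k=6)]
        assert set(top) & set(tree.clade_edges(node).tolist())

    def test_compare_scalars_identity_slope(self):
        x = np.linspace(1, 3, 30)
        out = vr.compare_scalars(x, x)
        assert out.slope == pytest.approx(1.0)

    def test_compare_independent_scalars_mostly_insignificant(self, rng):
        hits = 0
        for _ in range(20):
            a, b = rng.lognormal(0, 0.3, 30), rng.lognormal(0, 0.3, 30)
            hits += int(abs(vr.compare_scalars(a, b).tstat) < 2)
        assert hits >= 14
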