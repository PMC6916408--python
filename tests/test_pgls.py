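"""PGLS engine: oracle equivalence, lambda handling, tests and power check."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicbrain import pgls
from mosaicbrain.synthetic import random_tree, simulate_bm
from mosaicbrain.trees import phylo_vcv, read_tree, write_tree


def _star_tree(n, depth=1.0):
    newick = "(" + ",".join(f"t{i}:{depth}" for i in range(n)) + "):0;"
    return read_tree(newick)


class TestFitPGLS:
    def test_lambda_zero_on_unit_depth_tree_equals_ols(self, rng):
        tree = random_tree(30, seed=8, scale_to_height=1.0)
        x = rng.standard_normal(30)
        y = 1.0 + 2.0 * x + rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x])
        fit = pgls.fit_pgls(y, X, tree, lam=0.0)
        ols = stats.linregress(x, y)
        assert fit.beta[1] == pytest.approx(ols.slope, abs=1e-8)
        assert fit.tstat[1] == pytest.approx(ols.slope / ols.stderr, abs=1e-8)

    def test_star_phylogeny_equals_ols(self, rng):
        tree = _star_tree(25)
        x = rng.standard_normal(25)
        y = 0.5 - 1.5 * x + rng.standard_normal(25)
        X = np.column_stack([np.ones(25), x])
        fit = pgls.fit_pgls(y, X, tree, lam=1.0)
        ols = stats.linregress(x, y)
        assert fit.beta[1] == pytest.approx(ols.slope, abs=1e-8)
        assert fit.pvalue[1] == pytest.approx(ols.pvalue, abs=1e-8)

    def test_matches_r_nlme_gls_oracle(self, tmp_path):
        """Fixed-lambda=1 coefficients/t/logLik and free-lambda estimate agree
        with R's nlme::gls + ape corPagel on the same data."""
        tree = random_tree(25, seed=11, scale_to_height=1.0)
        rng = np.random.default_rng(3)
        x = simulate_bm(tree, 1.0, seed=rng)
        y = 0.7 + 0.5 * x + simulate_bm(tree, 0.4, seed=rng)
        df = pd.DataFrame({"species": x.index, "x": x.values, "y": y.values})
        df.to_csv(tmp_path / "d.csv", index=False)
        write_tree(tree, tmp_path / "t.nwk")
        rcode = textwrap.dedent("""
            suppressMessages({library(ape); library(nlme)})
            tree <- read.tree("t.nwk")
            d <- read.csv("d.csv"); rownames(d) <- d$species
            f1 <- gls(y ~ x, data=d, method="ML",
                      correlation=corPagel(1, phy=tree, form=~species, fixed=TRUE))
            tt <- summary(f1)$tTable
            f2 <- gls(y ~ x, data=d, method="ML",
                      correlation=corPagel(0.5, phy=tree, form=~species, fixed=FALSE))
            cat(tt[2,1], tt[2,3], logLik(f1), f2$modelStruct$corStruct[1], "\\n")
        """)
        res = subprocess.run(["Rscript", "-e", rcode], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        slope_r, t_r, ll_r, lam_r = map(float, res.stdout.split())
        X = np.column_stack([np.ones(25), x.values])
        fit = pgls.fit_pgls(y.values, X, tree, lam=1.0)
        free = pgls.fit_pgls(y.values, X, tree, lam="free")
        assert fit.beta[1] == pytest.approx(slope_r, abs=1e-6)
        assert fit.tstat[1] == pytest.approx(t_r, abs=1e-5)
        assert fit.loglik == pytest.approx(ll_r, abs=1e-4)
        assert free.lam == pytest.approx(lam_r, abs=1e-3)

    def test_scale_equivariance(self, rng):
        tree = random_tree(20, seed=2, scale_to_height=1.0)
        x = simulate_bm(tree, 1.0, seed=rng).values
        y = 0.2 + x + simulate_bm(tree, 0.3, seed=rng).values
        X = np.column_stack([np.ones(20), x])
        f1 = pgls.fit_pgls(y, X, tree, lam="free")
        f2 = pgls.fit_pgls(3.7 * y, X, tree, lam="free")
        assert np.allclose(f2.beta, 3.7 * f1.beta)
        assert np.allclose(f2.tstat, f1.tstat, atol=1e-6)
        assert f2.lam == pytest.approx(f1.lam, abs=1e-4)

    def test_loglik_local_optimality(self, rng):
        """ML point beats a grid of perturbed (beta, sigma2) under the full
        multivariate-normal density."""
        from mosaicbrain.varrates import ScalarMap, vr_loglik
        tree = random_tree(15, seed=5, scale_to_height=1.0)
        x = simulate_bm(tree, 1.0, seed=rng).values
        y = 1.0 + 0.5 * x + simulate_bm(tree, 0.5, seed=rng).values
        X = np.column_stack([np.ones(15), x])
        fit = pgls.fit_pgls(y, X, tree, lam=1.0)
        best = vr_loglik(y, X, tree, ScalarMap(), fit.beta, fit.sigma2)
        assert best == pytest.approx(fit.loglik, abs=1e-9)
        for db in (-0.05, 0.05):
            for ds_ in (0.8, 1.25):
                ll = vr_loglik(y, X, tree, ScalarMap(),
                               fit.beta + db, fit.sigma2 * ds_)
                assert ll <= best + 1e-10

    def test_collinear_design_raises(self, rng):
        tree = random_tree(10, seed=1)
        x = rng.standard_normal(10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            pgls.fit_pgls(rng.standard_normal(10), X, tree, lam=1.0)


class TestPhyloTTest:
    def test_group_must_be_binary_and_populated(self, rng):
        tree = random_tree(10, seed=0)
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="binary"):
            pgls.phylo_ttest(y, None, np.arange(10), tree)
        g = np.zeros(10)
        g[0] = 1
        with pytest.raises(ValueError, match="at least 2"):
            pgls.phylo_ttest(y, None, g, tree)

    def test_group_coefficient_is_last_column(self, rng):
        tree = random_tree(24, seed=3, scale_to_height=1.0)
        x = simulate_bm(tree, 1.0, seed=rng).values
        g = (np.arange(24) < 8).astype(float)
        y = x + 0.9 * g + simulate_bm(tree, 0.05, seed=rng).values
        fit = pgls.phylo_ttest(y, x, g, tree, lam=1.0)
        assert fit.columns[-1] == "group"
        assert fit.beta[-1] == pytest.approx(0.9, abs=0.5)


class TestLRTAndAIC:
    def test_equal_logliks(self, rng):
        tree = random_tree(20, seed=6, scale_to_height=1.0)
        y = simulate_bm(tree, 1.0, seed=rng).values
        X = np.ones((20, 1))
        f_fixed = pgls.fit_pgls(y, X, tree, lam=1.0)
        f_free = pgls.fit_pgls(y, X, tree, lam="free")
        t = pgls.lr_test(f_fixed, f_free)
        assert t.statistic >= 0
        assert 0 < t.pvalue <= 1

    def test_chi2_example_value(self):
        # logLik -52 vs -50 -> stat 4 -> p ~ 0.0455
        assert stats.chi2.sf(4.0, df=1) == pytest.approx(0.0455, abs=2e-4)
        f = pgls.PGLSFit(beta=np.zeros(1), se=np.ones(1), tstat=np.zeros(1),
                         pvalue=np.ones(1), sigma2=1.0, lam=1.0,
                         lambda_free=False, loglik=-52.0, n=10, k=1,
                         columns=["i"], y=np.zeros(10), X=np.zeros((10, 1)))
        g = pgls.PGLSFit(beta=np.zeros(1), se=np.ones(1), tstat=np.zeros(1),
                         pvalue=np.ones(1), sigma2=1.0, lam=0.8,
                         lambda_free=True, loglik=-50.0, n=10, k=1,
                         columns=["i"], y=np.zeros(10), X=np.zeros((10, 1)))
        t = pgls.lr_test(f, g)
        assert t.statistic == pytest.approx(4.0)
        assert t.pvalue == pytest.approx(0.0455, abs=2e-4)

    def test_non_nested_designs_rejected(self, rng):
        tree = random_tree(12, seed=9)
        y = rng.standard_normal(12)
        f1 = pgls.fit_pgls(y, np.ones((12, 1)), tree, lam=1.0)
        f2 = pgls.fit_pgls(y, np.column_stack([np.ones(12), rng.standard_normal(12)]),
                           tree, lam="free")
        with pytest.raises(ValueError, match="same response and design"):
            pgls.lr_test(f1, f2)

    def test_lr_null_distribution_rejection_rate(self, rng):
        """Data simulated at lambda=1 then tested: LRT rejects at <= alpha
        plus Monte-Carlo error (the statistic is a chi2 boundary mixture)."""
        tree = random_tree(40, seed=14, scale_to_height=1.0)
        rej = 0
        reps = 120
        for _ in range(reps):
            y = simulate_bm(tree, 1.0, seed=rng).values
            f0 = pgls.fit_pgls(y, np.ones((40, 1)), tree, lam=1.0)
            f1 = pgls.fit_pgls(y, np.ones((40, 1)), tree, lam="free")
            rej += int(pgls.lr_test(f0, f1).pvalue < 0.05)
        assert rej / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_aic_formula_and_delta(self):
        f = pgls.PGLSFit(beta=np.zeros(2), se=np.ones(2), tstat=np.zeros(2),
                         pvalue=np.ones(2), sigma2=1.0, lam=1.0,
                         lambda_free=False, loglik=-10.0, n=10, k=2,
                         columns=["a", "b"])
        # k_total = 2 betas + sigma2 = 3 -> AIC = 6 + 20 = 26
        assert pgls.aic(f) == pytest.approx(26.0)
        assert pgls.delta_aic(f, f) == 0.0


class TestResidualsAndOLS:
    def test_perfect_fit_zero_residuals(self):
        tree = _star_tree(6)
        x = np.arange(6.0)
        y = 2.0 + 3.0 * x
        fit = pgls.fit_pgls(y, np.column_stack([np.ones(6), x]), tree, lam=1.0)
        assert np.allclose(pgls.phylo_residuals(fit), 0.0, atol=1e-10)

    def test_intercept_only_unit_tree_residuals_are_centered(self, rng):
        tree = _star_tree(12)
        y = rng.standard_normal(12)
        fit = pgls.fit_pgls(y, np.ones((12, 1)), tree, lam=0.0)
        assert np.allclose(pgls.phylo_residuals(fit), y - y.mean(), atol=1e-10)

    def test_residuals_match_whitening_oracle(self, rng):
        tree = random_tree(10, seed=4, scale_to_height=1.0)
        x = simulate_bm(tree, 1.0, seed=rng).values
        y = 0.3 + 0.8 * x + simulate_bm(tree, 0.2, seed=rng).values
        X = np.column_stack([np.ones(10), x])
        fit = pgls.fit_pgls(y, X, tree, lam=1.0)
        V = phylo_vcv(tree).matrix
        L = np.linalg.cholesky(V)
        beta = np.linalg.lstsq(np.linalg.solve(L, X),
                               np.linalg.solve(L, y), rcond=None)[0]
        assert np.allclose(pgls.phylo_residuals(fit), y - X @ beta, atol=1e-8)

    def test_ols_exact_line_and_errors(self, rng):
        x = np.arange(10.0)
        out = pgls.ols_fit(2 * x, x)
        assert out.slope == pytest.approx(2.0)
        assert out.pvalue < 1e-12
        with pytest.raises(ValueError, match="zero variance"):
            pgls.ols_fit(rng.standard_normal(5), np.ones(5))
        # normal-equations oracle on random points
        x = rng.standard_normal(20)
        y = 1 + 0.3 * x + rng.standard_normal(20)
        out = pgls.ols_fit(y, x)
        Xd = np.column_stack([np.ones(20), x])
        coef = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert out.intercept == pytest.approx(coef[0], abs=1e-10)
        assert out.slope == pytest.approx(coef[1], abs=1e-10)


class TestPMCPower:
    def test_null_self_comparison_power_near_alpha(self, rng):
        tree = random_tree(40, seed=21, scale_to_height=1.0)
        y = simulate_bm(tree, 1.0, seed=rng).values
        X = np.ones((40, 1))
        rep = pgls.pmc_power(tree, y, X, nsim=100, seed=1)
        # when lambda-hat ~ 1 the two generating models coincide
        if rep["lambda_free_hat"] > 0.95:
            assert abs(rep["power"] - 0.05) < 0.12

    def test_power_increases_with_tree_size(self):
        """Discriminating lambda=0.5 truth from lambda=1 is easier on a large
        tree than on a small one (the within-cetacean sample-size caveat)."""
        powers = {}
        for n, seed in ((96, 31), (16, 32)):
            tree = random_tree(n, seed=seed, scale_to_height=1.0)
            y = simulate_bm(tree, 1.0, lam=0.5, seed=77).values
            X = np.ones((n, 1))
            powers[n] = pgls.pmc_power(tree, y, X, nsim=100, seed=5)["power"]
        assert powers[96] > powers[16]
        assert powers[96] > 0.5

    def test_small_nsim_warns(self, rng):
        tree = random_tree(12, seed=2)
        y = simulate_bm(tree, 1.0, seed=rng).values
        with pytest.warns(UserWarning, match="nsim"):
            pgls.pmc_power(tree, y, np.ones((12, 1)), nsim=20, seed=0)
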