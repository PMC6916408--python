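"""Simulation studies that characterize the estimators under known truth.

Each function runs one self-contained experiment on synthetic data — the
study conditions (tree sizes, clade sizes, rates, shift sizes, replicate
counts) are fixed defaults of this module — and returns a small dict of
summary numbers.  They power both the test suite and the results-reproduction
script, so every reported number is recomputed from scratch by the package
itself.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np
from scipy import special, stats

from . import pgls, phylo_mixed, synthetic, varrates
from .trees import phylo_vcv, apply_lambda

__all__ = [
    "pgls_whitening_agreement", "vr_unit_scalar_agreement",
    "stepping_stone_accuracy", "grade_shift_recovery", "lambda_recovery",
    "animal_model_coverage", "ttest_type1_error", "bf_calibration",
    "vr_seed_reproducibility",
]


# ---------------------------------------------------------------------------
# Oracle agreement


def _whitened_ols(y, X, V):
    """Independent GLS oracle: explicit Cholesky whitening, then textbook OLS
    normal equations on the whitened system, with the ML Gaussian loglik."""
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
    resid = yw - Xw @ beta
    n = len(y)
    sigma2 = resid @ resid / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2)
                     + 2 * np.sum(np.log(np.diag(L))) + n)
    return beta, loglik


def pgls_whitening_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |beta| and |logLik| deviation between the PGLS fitter and the
    whitening oracle over random 5-15-tip instances at lambda = 1."""
    rng = np.random.default_rng(seed)
    dev_beta = dev_ll = 0.0
    for i in range(n_instances):
        n = int(rng.integers(5, 16))
        tree = synthetic.random_tree(n, seed=int(rng.integers(2 ** 31)),
                                     scale_to_height=1.0)
        x = synthetic.simulate_bm(tree, 1.0, seed=rng).values
        y = 1.0 + 0.5 * x + synthetic.simulate_bm(tree, 0.5, seed=rng).values
        X = np.column_stack([np.ones(n), x])
        fit = pgls.fit_pgls(y, X, tree, lam=1.0)
        V = phylo_vcv(tree).matrix
        beta_o, ll_o = _whitened_ols(y, X, V)
        dev_beta = max(dev_beta, float(np.max(np.abs(fit.beta - beta_o))))
        dev_ll = max(dev_ll, abs(fit.loglik - ll_o))
    return {"max_beta_deviation": dev_beta, "max_loglik_deviation": dev_ll,
            "n": n_instances}


def vr_unit_scalar_agreement(seed: int = 0) -> dict:
    """|vr_loglik(all scalars 1) - PGLS lambda=1 logLik| at the ML optimum."""
    rng = np.random.default_rng(seed)
    tree = synthetic.random_tree(24, seed=seed, scale_to_height=100.0)
    x = synthetic.simulate_bm(tree, 0.01, seed=rng).values
    y = 0.3 + x + synthetic.simulate_bm(tree, 0.0003, seed=rng).values
    X = np.column_stack([np.ones(24), x])
    fit = pgls.fit_pgls(y, X, tree, lam=1.0)
    ll = varrates.vr_loglik(y, X, tree, varrates.ScalarMap(), fit.beta, fit.sigma2)
    return {"abs_deviation": abs(ll - fit.loglik), "n": 24}


# ---------------------------------------------------------------------------
# Stepping stone vs quadrature oracle


def _vr_marginal_by_quadrature(y, X, tree, prior, n_grid=40, max_scalars=2):
    """Brute-force oracle for the VR marginal likelihood on a tiny tree:
    enumerate scalar configurations up to ``max_scalars`` active scalars and
    integrate each scalar value by Gauss-Hermite quadrature against its
    log-normal prior.  Truncation error is negligible for small p_on."""
    from itertools import combinations

    from mosaicbrain.varrates import _marginal_loglik, _scaled_vcv

    E, _ = tree.tip_membership()
    prior = prior.resolved(np.asarray(y, float),
                           np.asarray(X, float),
                           _scaled_vcv(E, tree.lengths, np.ones(tree.n_nodes)))
    targets = [("branch", e) for e in range(1, tree.n_nodes)]
    if prior.allow_clades:
        targets += [("clade", e) for e in range(1, tree.n_nodes)
                    if not tree.is_tip(e)]
    N = len(targets)
    p = prior.p_on if prior.p_on is not None else 1.0 / N
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_grid)
    s = prior.log_scalar_sd
    w_norm = weights / weights.sum()

    def cond_ml(active, logrs):
        smap = varrates.ScalarMap([(k, e, math.exp(lr))
                                   for (k, e), lr in zip(active, logrs)])
        m = smap.effective_multipliers(tree)
        return _marginal_loglik(y, X, _scaled_vcv(E, tree.lengths, m), prior)[0]

    pieces = [N * math.log1p(-p) + cond_ml([], [])]
    for k in range(1, max_scalars + 1):
        log_cfg = k * math.log(p) + (N - k) * math.log1p(-p)
        for active in combinations(targets, k):
            if k == 1:
                vals = [cond_ml(active, [s * z]) for z in nodes]
                integral = special.logsumexp(vals, b=w_norm)
            else:  # k == 2: tensor grid
                vals = [cond_ml(active, [s * z1, s * z2])
                        for z1 in nodes for z2 in nodes]
                wb = np.outer(w_norm, w_norm).ravel()
                integral = special.logsumexp(vals, b=wb)
            pieces.append(log_cfg + integral)
    return float(special.logsumexp(pieces))


def stepping_stone_accuracy(n_seeds: int = 10, seed: int = 0) -> dict:
    """Stepping-stone estimates vs the quadrature oracle on a 3-tip model.

    The model is a conjugate normal regression with a small scalar-
    configuration space, so the exact marginal is computable by enumeration +
    Gauss-Hermite integration; reports the worst |SS - exact| over seeds.
    """
    from .trees import read_tree
    tree = read_tree("((A:1,B:1):1,C:2):0;")
    rng = np.random.default_rng(seed)
    y = np.array([1.0, 1.3, 0.2])
    X = np.ones((3, 1))
    prior = varrates.VRPrior(p_on=0.05, log_scalar_sd=1.0)
    exact = _vr_marginal_by_quadrature(y, X, tree, prior, n_grid=32)
    errs = []
    for i in range(n_seeds):
        est = varrates.stepping_stone(y, X, tree, model="vr", prior=prior,
                                      n_stones=12, n_per_stone=400,
                                      warmup_per_stone=200, thin=2,
                                      posterior_warmup=500,
                                      seed=int(rng.integers(2 ** 31)))
        errs.append(abs(est.log_mlh - exact))
    return {"max_abs_error": float(max(errs)),
            "mean_abs_error": float(np.mean(errs)),
            "exact_log_mlh": exact, "n": n_seeds}


# ---------------------------------------------------------------------------
# Parameter recovery


def grade_shift_recovery(n_reps: int = 200, n_tips: int = 100,
                         delta: float = 0.3, seed: int = 0) -> dict:
    """Mean estimated clade intercept shift under a known shift ``delta``."""
    rng = np.random.default_rng(seed)
    cfg = synthetic.SimConfig(delta_cx=delta, delta_cb=delta)
    est = []
    for i in range(n_reps):
        tree = synthetic.random_tree(n_tips, seed=int(rng.integers(2 ** 31)),
                                     scale_to_height=100.0)
        node = synthetic._clade_of_size(tree, 17)
        taxa = [tree.labels[j] for j in tree.descendant_tips(node)]
        tab, _ = synthetic.simulate_components(tree, cfg, clade_taxa=taxa,
                                               seed=int(rng.integers(2 ** 31)))
        fit = pgls.phylo_ttest(tab.log_cx, tab.log_rob, tab.is_clade,
                               tree, lam=1.0)
        est.append(fit.beta[-1])
    return {"true_delta": delta, "mean_estimate": float(np.mean(est)),
            "bias": float(np.mean(est) - delta),
            "sd": float(np.std(est)), "n": n_reps}


def lambda_recovery(n_reps: int = 100, n_tips: int = 200, seed: int = 0,
                    lambdas=(0.0, 0.5, 1.0)) -> dict:
    """Mean freely-estimated lambda when the truth is 0, 0.5 or 1."""
    rng = np.random.default_rng(seed)
    out = {}
    for lam in lambdas:
        hats = []
        for i in range(n_reps):
            tree = synthetic.random_tree(
                n_tips, seed=int(rng.integers(2 ** 31)), scale_to_height=1.0)
            y = synthetic.simulate_bm(tree, 1.0, lam=lam, seed=rng).values
            fit = pgls.fit_pgls(y, np.ones((n_tips, 1)), tree, lam="free")
            hats.append(fit.lam)
        out[f"lambda_{lam}"] = {"mean_estimate": float(np.mean(hats)),
                                "bias": float(np.mean(hats) - lam),
                                "n": n_reps}
    return out


def animal_model_coverage(n_reps: int = 50, n_species: int = 50,
                          n_per_species: int = 3, slope: float = 0.65,
                          seed: int = 0) -> dict:
    """Fraction of replicates whose 95% credible interval covers the true
    fixed-effect slope (phylogenetic heritability ~ 0.5)."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_reps):
        tree = synthetic.random_tree(n_species,
                                     seed=int(rng.integers(2 ** 31)),
                                     scale_to_height=1.0)
        x = synthetic.simulate_bm(tree, 1.0, seed=rng)
        a = synthetic.simulate_bm(tree, 0.3, seed=rng)
        rows = []
        for sp in x.index:
            for j in range(n_per_species):
                rows.append({"species": sp, "x": x[sp],
                             "y": 1.0 + slope * x[sp] + a[sp]
                             + math.sqrt(0.3) * rng.standard_normal()})
        df = pd.DataFrame(rows)
        post = phylo_mixed.fit_animal_model(
            df, "y", ["x"], tree, n_iter=6000, burnin=1000, thin=5,
            seed=int(rng.integers(2 ** 31)))
        s = phylo_mixed.summarize_posterior(post.fixed[:, 1])
        hits += int(s["CI_lower"] <= slope <= s["CI_upper"])
    return {"coverage": hits / n_reps, "nominal": 0.95,
            "true_slope": slope, "n": n_reps}


# ---------------------------------------------------------------------------
# Error calibration


def ttest_type1_error(n_reps: int = 500, n_tips: int = 100,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the phylogenetic t-test when the clade shift is 0."""
    rng = np.random.default_rng(seed)
    cfg = synthetic.SimConfig(delta_cx=0.0, delta_cb=0.0)
    rej = 0
    for i in range(n_reps):
        tree = synthetic.random_tree(n_tips, seed=int(rng.integers(2 ** 31)),
                                     scale_to_height=100.0)
        node = synthetic._clade_of_size(tree, 17)
        taxa = [tree.labels[j] for j in tree.descendant_tips(node)]
        tab, _ = synthetic.simulate_components(tree, cfg, clade_taxa=taxa,
                                               seed=int(rng.integers(2 ** 31)))
        fit = pgls.phylo_ttest(tab.log_cx, tab.log_rob, tab.is_clade,
                               tree, lam=1.0)
        rej += int(fit.pvalue[-1] < alpha)
    rate = rej / n_reps
    half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_reps)
    return {"type1_rate": rate, "nominal": alpha,
            "binomial_ci": [alpha - half, alpha + half], "n": n_reps}


# ---------------------------------------------------------------------------
# Bayes-factor calibration and reproducibility


def _scenario_bf(seed: int, rate_factor: float, ss_kwargs=None) -> float:
    tree, y, X, node = synthetic.simulate_vr_scenario(
        n_tips=64, clade_size=16, rate_factor=rate_factor, seed=seed)
    kw = dict(n_stones=12, n_per_stone=500, warmup_per_stone=300, thin=3)
    kw.update(ss_kwargs or {})
    ssv = varrates.stepping_stone(y, X, tree, model="vr", seed=seed, **kw)
    ssn = varrates.stepping_stone(y, X, tree, model="null", seed=seed)
    return varrates.bayes_factor(ssv.log_mlh, ssn.log_mlh).bf


def bf_calibration(n_seeds: int = 10, seed: int = 0) -> dict:
    """Bayes-factor behaviour on 64-tip data: a x10 clade rate scalar should
    earn very strong support (BF > 10), homogeneous BM should not (BF < 5)."""
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(2 ** 31)) for _ in range(n_seeds)]
    bf_het = [_scenario_bf(s, 10.0) for s in seeds]
    bf_hom = [_scenario_bf(s, 1.0) for s in seeds]
    return {
        "heterogeneous_bf": bf_het, "homogeneous_bf": bf_hom,
        "frac_detected": float(np.mean([b > 10 for b in bf_het])),
        "frac_controlled": float(np.mean([b < 5 for b in bf_hom])),
        "n": n_seeds,
    }


def vr_seed_reproducibility(seed: int = 0, n_iter: int = 60_000) -> dict:
    """Correlation of per-branch posterior-mean scalars across two chains
    with different seeds on one fixed heterogeneous dataset."""
    tree, y, X, node = synthetic.simulate_vr_scenario(rate_factor=10.0,
                                                      seed=seed)
    posts = [varrates.run_vr_mcmc(y, X, tree, n_iter=n_iter,
                                  burnin=n_iter // 4, sample_interval=60,
                                  seed=seed + 1 + i) for i in range(2)]
    m1, m2 = (p.branch_scalar_stat("mean")[1:] for p in posts)
    r = float(np.corrcoef(m1, m2)[0, 1])
    return {"scalar_correlation": r, "n": len(m1)}
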