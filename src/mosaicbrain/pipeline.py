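"""End-to-end orchestration of the comparative analyses.

A :class:`RunConfig` (usually loaded from YAML) names the inputs (tree,
species-level trait table or individual records, optional ecological table),
the analysis stages to run, the lambda policy and the chain settings;
:func:`run_full_analysis` executes the stages, isolates per-stage failures,
and writes machine-readable TSV/JSON reports.  Deterministic stages are
bit-stable across reruns; stochastic stages are reproducible at fixed seed.

Stages
------
``dataset``      assemble/validate the analysis table, write the exclusion log
``grade_shifts`` phylogenetic t-tests of each component against the group flag
``coevolution``  CX ~ CB + RoB within-group scaling and residual-on-residual OLS
``mixed``        animal model over individual records
``varrates``     variable-rates RJ-MCMC + stepping-stone Bayes factor
``associations`` ecological-association PGLS suite
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import associations, dataset, pgls, phylo_mixed, varrates
from .trees import PhyloTree, phylo_vcv, read_tree, write_tree

__all__ = ["RunConfig", "run_full_analysis"]

_ALL_STAGES = ("dataset", "grade_shifts", "coevolution", "mixed",
               "varrates", "associations")


@dataclass
class RunConfig:
    """Configuration of one full analysis run (YAML-serializable)."""

    tree: str
    output_dir: str = "mosaicbrain_out"
    species_table: str | None = None
    individuals: str | None = None
    eco_table: str | None = None
    analyses: list = field(default_factory=lambda: list(_ALL_STAGES))
    lam: float | str = 1.0                 # lambda policy: value or "free"
    group_column: str = "is_clade"
    seed: int = 1
    mixed_chain: dict = field(default_factory=lambda: dict(
        n_iter=50_000, burnin=10_000, thin=20))
    varrates_chain: dict = field(default_factory=lambda: dict(
        n_iter=200_000, burnin=40_000, sample_interval=200))
    stepping_stone: dict = field(default_factory=lambda: dict(
        n_stones=16, n_per_stone=500))
    varrates_models: list = field(default_factory=lambda: [
        dict(response="log_cx", covariates=["log_rob"]),
        dict(response="log_cb", covariates=["log_rob"]),
    ])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fit_to_row(fit: pgls.PGLSFit, term: str) -> dict:
    j = fit.columns.index(term)
    return {"response": fit.response, "term": term,
            "beta": fit.beta[j], "se": fit.se[j], "t": fit.tstat[j],
            "p": fit.pvalue[j], "n": fit.n, "df": fit.df,
            "lambda": fit.lam, "logLik": fit.loglik, "AIC": fit.aic}


def run_full_analysis(config: RunConfig) -> dict:
    """Run the configured stages; returns the report bundle (also on disk).

    Stage failures are caught, logged into ``bundle["errors"]`` and the
    bundle is marked partial; remaining stages still run.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    rng_seed = int(config.seed)
    bundle = {"config": dataclasses.asdict(config), "errors": {}, "partial": False}
    log = dataset.ExclusionLog()

    tree = read_tree(config.tree)
    table = None
    individuals = None
    if config.individuals:
        individuals = dataset.read_individuals(config.individuals)
    if config.species_table:
        table = dataset._read_table(config.species_table)
    elif individuals is not None:
        if "cx_mass" not in individuals.columns:
            raise dataset.DatasetError(
                "species_table missing and individuals carry no raw masses")
        means = dataset.species_means(individuals)
        table = dataset.build_brain_table(means, log=log)

    def _stage(name, fn):
        if name not in config.analyses:
            return
        try:
            bundle[name] = fn()
        except Exception as exc:           # stage isolation is the contract
            bundle["errors"][name] = f"{type(exc).__name__}: {exc}"
            bundle["partial"] = True

    # ---- dataset ----------------------------------------------------------
    def do_dataset():
        if table is None:
            raise ValueError("no species_table or individuals input")
        eco = dataset.read_eco_table(config.eco_table) if config.eco_table else None
        merged = dataset.merge_traits(table, eco, tree, log=log)
        out = os.path.join(config.output_dir, "analysis_table.tsv")
        dataset.write_table(merged, out)
        log.to_json(os.path.join(config.output_dir, "exclusions.json"))
        return {"table": out, "n_species": len(merged),
                "n_excluded": len(log.species())}

    _stage("dataset", do_dataset)
    if table is not None and "species" in table.columns:
        analysis = table[table["species"].isin(tree.tip_labels)].reset_index(drop=True)
    else:
        analysis = None

    # ---- grade shifts -----------------------------------------------------
    def do_grade_shifts():
        rows = []
        g = analysis[config.group_column].to_numpy(float)
        species = list(analysis["species"])
        cov = phylo_vcv(associations._prune_to(tree, species), taxa_order=species)
        designs = [("log_cx", ["log_rob"]), ("log_cb", ["log_rob"]),
                   ("log_cx", ["log_cb"]), ("log_rob", [])]
        for resp, ctrl in designs:
            sub = analysis.dropna(subset=[resp] + ctrl)
            if len(sub) < len(analysis):
                continue
            C = np.column_stack([analysis[c] for c in ctrl]) if ctrl else None
            for lam in (config.lam, "free"):
                fit = pgls.phylo_ttest(analysis[resp].to_numpy(float), C, g,
                                       cov, lam=lam,
                                       covariate_names=ctrl, response=resp)
                row = _fit_to_row(fit, "group")
                row["controls"] = "+".join(ctrl) if ctrl else "(none)"
                rows.append((row, fit))
        report = pd.DataFrame([r for r, _ in rows])
        # likelihood-ratio tests pair consecutive fixed/free rows
        lrts = []
        for (r0, f0), (r1, f1) in zip(rows[::2], rows[1::2]):
            t = pgls.lr_test(f0, f1)
            lrts.append({"response": r0["response"], "controls": r0["controls"],
                         "statistic": t.statistic, "df": t.df, "p": t.pvalue})
        report.to_csv(os.path.join(config.output_dir, "grade_shifts.tsv"),
                      sep="\t", index=False)
        pd.DataFrame(lrts).to_csv(os.path.join(config.output_dir,
                                               "lambda_lrt.tsv"), sep="\t", index=False)
        return {"tests": report.to_dict("records"), "lrt": lrts}

    _stage("grade_shifts", do_grade_shifts)

    # ---- coevolution ------------------------------------------------------
    def do_coevolution():
        species = list(analysis["species"])
        cov = phylo_vcv(associations._prune_to(tree, species), taxa_order=species)
        X = np.column_stack([np.ones(len(analysis)), analysis["log_cb"],
                             analysis["log_rob"]])
        fit = pgls.fit_pgls(analysis["log_cx"].to_numpy(float), X, cov,
                            lam=config.lam,
                            columns=["intercept", "log_cb", "log_rob"],
                            response="log_cx")
        # residual-on-residual, both phylogenetically corrected
        rx = pgls.phylo_residuals(pgls.fit_pgls(
            analysis["log_cx"].to_numpy(float),
            np.column_stack([np.ones(len(analysis)), analysis["log_rob"]]),
            cov, lam=config.lam, columns=["intercept", "log_rob"]))
        rb = pgls.phylo_residuals(pgls.fit_pgls(
            analysis["log_cb"].to_numpy(float),
            np.column_stack([np.ones(len(analysis)), analysis["log_rob"]]),
            cov, lam=config.lam, columns=["intercept", "log_rob"]))
        ols = pgls.ols_fit(rx, rb)
        return {"cx_on_cb": _fit_to_row(fit, "log_cb"),
                "residual_ols": {"slope": ols.slope, "t": ols.tstat,
                                 "p": ols.pvalue, "n": ols.n}}

    _stage("coevolution", do_coevolution)

    # ---- mixed ------------------------------------------------------------
    def do_mixed():
        if individuals is None:
            raise ValueError("mixed stage needs individual-level input")
        ind = individuals.copy()
        for col, raw in (("log_cx", "cx_mass"), ("log_cb", "cb_mass")):
            if col not in ind.columns and raw in ind.columns:
                ind[col] = np.log10(ind[raw])
        if "log_rob" not in ind.columns and {"brain_mass", "cx_mass", "cb_mass"} <= set(ind.columns):
            ind["log_rob"] = np.log10(ind["brain_mass"] - ind["cx_mass"] - ind["cb_mass"])
        post = phylo_mixed.fit_animal_model(
            ind, "log_cx", ["log_cb", "log_rob"], tree,
            seed=rng_seed, **config.mixed_chain)
        summ = post.summary().reset_index()
        summ.to_csv(os.path.join(config.output_dir, "mixed_summary.tsv"),
                    sep="\t", index=False)
        ess = post.effective_sample_size()
        return {"summary": summ.to_dict("records"), "ess": ess,
                "ess_warning": [k for k, v in ess.items() if v < 200]}

    _stage("mixed", do_mixed)

    # ---- variable rates ---------------------------------------------------
    def do_varrates():
        species = list(analysis["species"])
        sub_tree = associations._prune_to(tree, species)
        out = {}
        for i, model in enumerate(config.varrates_models):
            resp, covs = model["response"], model["covariates"]
            y = analysis[resp].to_numpy(float)
            X = np.column_stack([np.ones(len(analysis))]
                                + [analysis[c] for c in covs])
            post = varrates.run_vr_mcmc(y, X, sub_tree, seed=rng_seed + i,
                                        taxa_order=species,
                                        **config.varrates_chain)
            ssv = varrates.stepping_stone(y, X, sub_tree, model="vr",
                                          seed=rng_seed + i, taxa_order=species,
                                          **config.stepping_stone)
            ssn = varrates.stepping_stone(y, X, sub_tree, model="null",
                                          seed=rng_seed + i, taxa_order=species)
            bf = varrates.bayes_factor(ssv.log_mlh, ssn.log_mlh)
            scaled = varrates.scaled_branch_lengths(post, "mean")
            write_tree(scaled, os.path.join(config.output_dir,
                                            f"scaled_{resp}.nwk"))
            trace = pd.DataFrame({
                "sample": np.arange(len(post.loglik)),
                "logLik": post.loglik, "n_scalars": post.n_scalars})
            trace.to_csv(os.path.join(config.output_dir, f"vr_trace_{resp}.tsv"),
                         sep="\t", index=False)
            out[resp] = {
                "bf": bf.bf, "support": bf.support,
                "log_mlh_vr": ssv.log_mlh, "log_mlh_null": ssn.log_mlh,
                "mc_se": ssv.mc_se,
                "acceptance": post.acceptance,
                "top_branches": varrates.rank_deviant_branches(scaled, sub_tree, 4),
                "mean_scalars": post.branch_scalar_stat("mean").tolist(),
                "median_scalars": post.branch_scalar_stat("median").tolist(),
            }
        return out

    _stage("varrates", do_varrates)

    # ---- associations -----------------------------------------------------
    def do_associations():
        eco_cols = [c for c in dataset.ECO_COLUMNS if c in analysis.columns]
        if not eco_cols:
            raise ValueError("no ecological columns present")
        report = associations.run_association_suite(
            analysis, tree, predictors=eco_cols, lam=config.lam)
        report.to_csv(os.path.join(config.output_dir, "associations.tsv"),
                      sep="\t", index=False)
        return report.drop(columns=["species"]).to_dict("records")

    _stage("associations", do_associations)

    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
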