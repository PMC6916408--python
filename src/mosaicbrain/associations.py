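"""Ecological-association suite: brain components vs ecology under PGLS.

Runs, for each requested brain component (log10 CX or CB) and each ecological
predictor (group size, social repertoire, diet breadth, latitude range,
maximum dive time, tonal range, tonal complexity), the regression

    component ~ RoB + predictor        (lambda fixed to 1 by default)

so every association is read conditional on the rest-of-brain size, plus the
whole-brain/body-mass designs.  Diet breadth is an ordinal 1-4 code entered
as a single numeric covariate (one slope); the 4 -> 3 category collapse used
when the top category is nearly empty is provided.  No multiple-testing
correction is applied; the report carries the number of tests run so nominal
p-values can be judged against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pgls
from .dataset import ECO_COLUMNS
from .trees import PhyloTree, phylo_vcv

__all__ = ["run_association_suite", "collapse_diet", "brain_body_models"]


def collapse_diet(diet):
    """Collapse the 4-level diet-breadth code to 3 levels (4 -> 3), used when
    the top category holds a single species."""
    arr = np.asarray(diet, dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (1, 2, 3, 4))
    if not ok.all():
        raise ValueError("diet breadth codes must lie in {1, 2, 3, 4}")
    out = np.where(arr == 4, 3, arr)
    if np.isscalar(diet) or np.ndim(diet) == 0:
        return float(out)
    return pd.Series(out, index=diet.index) if isinstance(diet, pd.Series) else out


def _fit_row(table, tree, response, predictors, control, lam, extra=()):
    """One PGLS row with listwise deletion; returns (fit, used_species)."""
    cols = [response] + list(control) + list(predictors) + list(extra)
    sub = table.dropna(subset=[c for c in cols if c in table.columns])
    need = [c for c in cols if c not in table.columns]
    if need:
        raise KeyError(f"missing columns: {need}")
    if len(sub) < len(control) + len(predictors) + len(extra) + 2:
        raise ValueError(f"too few complete species (n={len(sub)})")
    species = list(sub["species"])
    cov = phylo_vcv(_prune_to(tree, species), taxa_order=species)
    X = np.column_stack([np.ones(len(sub))]
                        + [sub[c].to_numpy(float) for c in list(control) + list(predictors) + list(extra)])
    names = ["intercept"] + list(control) + list(predictors) + list(extra)
    fit = pgls.fit_pgls(sub[response].to_numpy(float), X, cov, lam=lam,
                        columns=names, response=response)
    return fit, species


def _prune_to(tree: PhyloTree, species) -> PhyloTree:
    """Restrict the tree to the given tip set (drop everything else)."""
    keep = set(species)
    extra = keep - set(tree.tip_labels)
    if extra:
        raise ValueError(f"species not in tree: {sorted(extra)}")
    if keep == set(tree.tip_labels):
        return tree
    dtree = tree.to_dendropy()
    dtree.retain_taxa_with_labels(sorted(keep))
    return PhyloTree.from_dendropy(dtree)


def run_association_suite(table: pd.DataFrame, tree: PhyloTree,
                          responses=("log_cx", "log_cb"),
                          predictors=ECO_COLUMNS,
                          control=("log_rob",), lam=1.0,
                          joint: bool = False) -> pd.DataFrame:
    """PGLS of each response on each ecological predictor, controlling RoB.

    With ``joint=True`` the responses' controls are replaced by the full
    component set (CX, CB and RoB enter one multiple regression per response).
    Per-model failures (constant predictors, too few species) are recorded in
    the report and the suite continues.

    Returns a tidy frame: response, predictor, slope, t, p, n, df, lambda,
    error, n_tests.
    """
    rows = []
    for resp in responses:
        for pred in predictors:
            row = {"response": resp, "predictor": pred, "lambda_mode":
                   ("free" if lam == "free" else f"fixed({lam})")}
            ctrl = list(control)
            if joint:
                ctrl = [c for c in ("log_cx", "log_cb", "log_rob")
                        if c != resp]
            try:
                if pred in table.columns and table[pred].dropna().nunique() <= 1:
                    raise ValueError("predictor is constant across species")
                fit, species = _fit_row(table, tree, resp, [pred], ctrl, lam)
                j = fit.columns.index(pred)
                row.update(slope=fit.beta[j], se=fit.se[j], t=fit.tstat[j],
                           p=fit.pvalue[j], n=fit.n, df=fit.df,
                           lam=fit.lam, error=None,
                           species=",".join(sorted(species)))
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                row.update(slope=np.nan, se=np.nan, t=np.nan, p=np.nan,
                           n=0, df=0, lam=np.nan, error=str(exc), species="")
            rows.append(row)
    report = pd.DataFrame(rows)
    report["n_tests"] = int(report["error"].isna().sum())
    return report


def brain_body_models(table: pd.DataFrame, tree: PhyloTree, lam=1.0,
                      eco_predictors=()) -> dict:
    """Whole-brain designs: does component size or body mass track brain size?

    Fits (i) log brain ~ log body (optionally + one ecological trait each),
    (ii) log brain ~ log CB + log CX + log RoB + log body, and (iii) the same
    dropping body mass, with the AIC comparison of (ii) vs (iii).
    """
    out = {}
    fit_body, _ = _fit_row(table, tree, "log_brain", [], ["log_body"], lam)
    out["brain_body"] = fit_body
    for pred in eco_predictors:
        try:
            fit, _ = _fit_row(table, tree, "log_brain", [pred], ["log_body"], lam)
            out[f"brain_body_{pred}"] = fit
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            out[f"brain_body_{pred}"] = str(exc)
    comp = ["log_cb", "log_cx", "log_rob"]
    fit_full, _ = _fit_row(table, tree, "log_brain", comp, ["log_body"], lam)
    fit_nobody, _ = _fit_row(table, tree, "log_brain", comp, [], lam)
    out["brain_components_body"] = fit_full
    out["brain_components"] = fit_nobody
    # positive delta: the model without body mass fits better
    out["delta_aic_drop_body"] = pgls.delta_aic(fit_full, fit_nobody)
    return out
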