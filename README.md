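# mosaicbrain

Phylogenetic comparative analyses of **mosaic brain evolution**: do
individual brain components — cerebrum (CX) and cerebellum (CB) — shift
their scaling against the rest of the brain (RoB) in a focal clade, do they
co-evolve, and where on the phylogeny do their evolutionary rates change?

The package implements the full inferential chain used in comparative
neuroanatomy studies of this question (the motivating case: whales and
dolphins against terrestrial mammals), on any species-level trait table and
dated phylogeny:

- **Trees** — Newick/Nexus I/O, splicing a better-resolved donor clade into
  a backbone supertree with branch-length rescaling by the ratio of clade
  crown ages, and Brownian-motion covariance matrices
  V<sub>ij</sub> = shared root-to-MRCA path length, with Pagel's λ scaling
  of the off-diagonal.
- **PGLS** — maximum-likelihood generalized least squares
  y = Xβ + ε, ε ~ N(0, σ²V<sub>λ</sub>), with λ fixed or profiled over
  [0, 1]; grade-shift ("phylogenetic *t*") tests via a binary clade
  indicator; likelihood-ratio tests of λ; AIC = 2k − 2 logL; phylogenetic
  residuals; and a parametric-bootstrap power check for the λ contrast.
- **Phylogenetic mixed model** — a Gibbs-sampled Gaussian "animal model"
  over individual-level records with a species-level phylogenetic random
  effect, parameter-expanded priors, and P-mean / 95% CI / pMCMC summaries.
- **Variable rates** — a reversible-jump MCMC over branch- and clade-level
  multiplicative rate scalars on the Brownian process, stepping-stone
  marginal likelihoods, and Bayes factors
  BF = 2(logMLh<sub>VR</sub> − logMLh<sub>null</sub>) with the conventional
  5–10 "strong" / >10 "very strong" reading; posterior mean/median-scaled
  branch lengths and deviant-branch ranking.
- **Associations** — PGLS of each component on ecological predictors
  (group size, social repertoire, diet breadth, latitude range, dive time,
  tonal traits) controlling for RoB, and whole-brain/body designs with AIC
  comparison.
- **Synthetic data** — birth-death trees, BM(λ) traits, grade shifts,
  branch-rate scenarios and individual-level noise, so the entire chain is
  testable against known truth.

## Worked example

```python
import numpy as np
from mosaicbrain import pgls, synthetic

# a 141-species tree with a 17-species clade whose CX/CB sit 0.5 dex above
# the mammal-wide allometry on RoB
tree, table, truth = synthetic.mammal_like_scenario(seed=3)

fit = pgls.phylo_ttest(table.log_cx, table.log_rob, table.is_clade,
                       tree, lam=1.0)
print(f"clade shift = {fit.beta[-1]:.3f} dex, "
      f"t_{fit.df} = {fit.tstat[-1]:.3f}, p = {fit.pvalue[-1]:.2e}")
```

```
clade shift = 0.705 dex, t_138 = 7.490, p = 7.44e-12
```

The clade indicator's coefficient estimates the grade shift (truth here:
0.5 dex; single draws scatter around it, and the mean estimate over many
replicates is unbiased — see `scripts/acceptance.py`), and its *t*
statistic on n − k degrees
of freedom is the "phylogenetic t-test": the clade's components are larger
than the mammal-wide CX ~ RoB allometry predicts, after accounting for
shared ancestry.

Rate heterogeneity on the same kind of data:

```python
from mosaicbrain import varrates

tree, y, X, node = synthetic.simulate_vr_scenario(rate_factor=10.0, seed=1)
ss_vr  = varrates.stepping_stone(y, X, tree, model="vr", seed=1)
ss_null = varrates.stepping_stone(y, X, tree, model="null", seed=1)
print(varrates.bayes_factor(ss_vr.log_mlh, ss_null.log_mlh))
```

```
BayesFactorResult(bf=16.557803319257644, support='very strong')
```

A clade evolving at ×10 the background rate earns a decisive Bayes factor;
on homogeneous data the same comparison sits near 0.

## Command line

```bash
mosaicbrain synthetic --n-tips 141 --clade-size 17 --seed 1 --out sim/
mosaicbrain trees splice --backbone bb.nwk --donor donor.nwk \
    --anchor anchor.txt --out spliced.nwk
mosaicbrain dataset build --brain individuals.tsv --tree tree.nwk --out data/
mosaicbrain run --config analysis.yaml
```

`mosaicbrain run` executes the configured stages (dataset assembly, grade
shifts, co-evolution, mixed model, variable rates, associations) and writes
TSV/JSON reports plus scaled trees; identical configs and seeds give
identical outputs.

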