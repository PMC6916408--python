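# Methods

This note documents the models implemented in `mosaicbrain`, the choices
made where several defensible options existed, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## The scientific setting

Comparative neuroanatomy asks whether individual brain components — here the
cerebrum (CX) and cerebellum (CB) — evolve in lockstep with overall brain
size ("concerted" evolution) or can be targeted separately by selection
("mosaic" evolution). The canonical signatures of mosaic change are (i)
*grade shifts*: a clade sits above or below the allometric line that links a
component to the rest of the brain (RoB = brain − CX − CB, minus olfactory
bulbs where measured), and (ii) *rate heterogeneity*: branches or clades
where a component's Brownian-motion rate departs from the background.
`mosaicbrain` implements the full inferential chain for such questions on
any species-level trait table and dated phylogeny.

## PGLS with Pagel's lambda

The regression y = Xβ + ε, ε ~ N(0, σ²V_λ), where V is the Brownian-motion
expectation (V_ij = shared root-to-MRCA path length in My) and λ multiplies
the off-diagonal entries. Conventions:

- **σ² by maximum likelihood** (divisor n), so log-likelihoods, LRTs and AIC
  are mutually consistent. AIC = 2k_total − 2 logLik with k_total counting
  the regression coefficients, σ², and λ when freely estimated.
- **Standard errors** carry the n/(n−k) small-sample correction, and
  per-coefficient t statistics are referred to a t distribution with
  df = n − k (k = number of regression coefficients only; σ² and λ are not
  charged to the t-test df). These conventions reproduce `nlme::gls(...,
  method="ML")` with a Brownian/Pagel correlation to machine precision,
  which the test suite verifies by calling R directly.
- **λ estimation**: profile likelihood over [0, 1], coarse 11-point grid
  followed by bounded Brent refinement (xatol 1e-6) with the endpoints
  always re-checked; λ is restricted to [0, 1] because values above 1 can
  break positive-definiteness off ultrametric trees.
- **Grade shifts** ("phylogenetic t-tests") are the t statistic of a binary
  clade indicator added to the design; this is the standard reduction of a
  two-group comparison to a PGLS coefficient.
- The **PMC-style power check** is a parametric bootstrap: simulate under
  both fitted models (λ fixed vs free), refit both to every simulated
  dataset, and report P(LR under free-model truth > 95th percentile of LR
  under fixed-model truth).

## Phylogenetic mixed model (animal model)

For individual-level records, y_i = x_i'b + a_{s(i)} + e_i with species
effects a ~ N(0, σ²_phylo·A) (A = tip correlation from the tree, normalized
to unit mean diagonal so σ²_phylo is in trait units) and residuals e ~
N(0, σ²_e·I). The sampler is blocked Gibbs with parameter expansion on the
G side (a = α·u; α ~ N(0, 1000)): (b, u) are drawn jointly from their
multivariate-normal conditional, α from its scalar conditional, and both
variances from inverse-gamma conditionals. Priors follow the
parameter-expanded convention (G: V=1, ν=1, α_μ=0, α_V=1000; R: V=1,
ν=0.002; fixed effects N(0, 1e8)). Defaults are desk-scale — 50,000
iterations, 10,000 burn-in, thin 20 — and `MixedPosterior.
effective_sample_size()` is the convergence gate (aim for ESS ≥ 200).
Summaries are the posterior mean, the 2.5–97.5% quantile interval, and
pMCMC = 2·min(P(draw ≤ 0), P(draw ≥ 0)), floored at 1/n_draws.

## Variable-rates Brownian motion

Branches or whole clades carry multiplicative rate scalars r > 0; a branch's
effective scalar is the product of every assignment covering it, and the
covariance is rebuilt from the scaled branch lengths. Model space is
explored by reversible jump (add / delete / resize moves over candidate
targets = every branch plus every internal clade).

Design choices, made where the published model family leaves the details
open:

- **Collapsed regression parameters.** (β, σ²) are integrated out
  analytically under a conjugate normal-inverse-gamma prior
  (β ~ N(0, g·σ²·I), g = 1e4; σ² ~ IG(a₀, b₀)), so the RJ chain walks only
  over scalar configurations. This removes the hardest mixing problem
  (trans-dimensional moves entangled with σ²) and makes the null model's
  marginal likelihood *exact* — no sampling error on one side of every
  Bayes factor. β and σ² are drawn back from their exact conditional when
  posterior samples are reported.
- **σ² prior scale.** b₀ defaults to a₀ × (ML rate of the single-rate null
  fit), a unit-information choice shared by both models. A fixed absolute
  b₀ gives the variable-rates model a spurious degree of freedom: scalars
  can rescale the whole tree and let σ² drift toward the prior's preferred
  scale, inflating its marginal likelihood even on homogeneous data. With
  the data-scale prior the global-rescale direction has its optimum at 1
  for both models and Bayes factors on homogeneous data sit at ~0.
- **Configuration prior.** Each candidate target is independently active
  with probability 1/(number of targets) — one expected scalar a priori —
  and scalar values are log-normal(0, 1.5²): published rate scalars for
  this model family span one to two orders of magnitude, so the value
  prior must keep real tail mass at |log r| ≈ 2–4. Bayes factors are prior-sensitive; all of these are exposed
  in `VRPrior` and any reported BF is tied to them.
- **Identifiability.** The global scalar × σ² trade-off (scaling every
  branch by c and σ² by 1/c leaves the likelihood unchanged) is handled by
  the sparsity prior and data-scale σ² prior rather than a hard constraint;
  reported quantities are per-branch *effective* scalars, which are
  invariant to how a clade-wide rescaling is decomposed.

**Stepping-stone marginal likelihoods** use K = 16 power posteriors at
Beta(0.4, 1) quantile powers (dense near the prior). The chain warms up at
full power first — locating the correct scalar target is a needle-in-a-
haystack search that needs the untempered likelihood — then anneals
downward, each stone warm-starting the next; stone k averages
exp((β_k − β_{k−1})·logL) over the samples drawn at β_{k−1}. The Monte-Carlo
SE is the delta-method variance of each stone's log-mean, summed. Bayes
factors are reported as BF = 2·(logMLh_model − logMLh_null), with 5–10 read
as "strong" and >10 as "very strong" support.

Chain defaults (2×10⁵ RJ iterations, ~800 retained samples; 500 samples per
stone) are desk-scale; production-scale settings are one configuration
change.

## Synthetic data: what it emulates, and what it does not

The generator produces dated ultrametric trees (pure-birth, conditioned on
tip count; constant-rate birth-death via dendropy when extinction is
requested), BM(λ) traits, component tables (log RoB by BM; log CX and CB as
linear functions of log RoB plus clade grade/slope shifts and optionally
correlated BM residuals), branch-heterogeneous-rate scenarios, and
individual records (species mean + iid log-scale noise). The pure-birth
sampler deliberately runs one inter-event time past the final speciation so
terminal branches are strictly positive: stopping exactly at the n-th split
yields a zero-length cherry, an exactly singular covariance, and
numerically unstable likelihoods.

Default study conditions (chosen once, as field-realistic): 141-species
trees of height 100 My with a ~17-species marked clade (the shape of a
mammal-wide dataset with a whale-sized focal clade); BM rate 0.01/My for
log₁₀ RoB (~1 dex root-to-tip spread) and 3×10⁻⁴/My for component residuals
(~0.17 dex scatter about the allometry); grade shift 0.5 dex; within-species
noise 0.05 dex; rate-shift scenarios use 64 tips with a deep ~16-tip clade at
×10 rate. Under these conditions the synthetic grade-shift t statistics
fall in the 3.5–9 range, the scale reported for real mammal data.

What the generator does **not** emulate: measurement error correlated with
body size, missing data patterns, tree estimation error, non-Brownian
processes (OU, early-burst), and sampling biases in which species get
measured. Passing tests therefore certify the estimators under the model's
own assumptions, not robustness to their violation.

## Numerical conventions

- Covariance factorizations go through a guarded Cholesky that retries with
  a relative ridge (1e-12…1e-8 × mean diagonal) before declaring failure.
- Exclusion rule for component tables: a species is dropped when
  (brain − CX − CB)/brain ≤ 1e-3 — equality of components and whole brain
  up to floating-point noise means some component includes extra structures.
- Diet breadth enters regressions as a single ordinal slope (1–4, with an
  optional 4→3 collapse); dummy coding is deliberately not the default so
  each model reports one t statistic per trait.
- Tables are written at %.17g and read with correctly-rounded float parsing,
  so write/read cycles are bit-identical.
- Ultrametricity tolerance defaults to 1e-6 My; tree splicing rescales donor
  branch lengths by the ratio of clade crown ages and reports any residual
  attachment-age mismatch instead of silently absorbing it.

## Reproducing the published cetacean analysis

The pipeline reproduces the published per-model statistics when pointed at
the archived species trait table and the spliced dated phylogeny (deposited
in a public archive by the original authors; not redistributable here).
Place them at `data/empirical/brain_traits.tsv` and
`data/empirical/spliced_tree.nex` and run the acceptance test; without those
files that single test reports failure by design, while every synthetic
check still runs. The Bayes factors of the original variable-rates analyses
are additionally sensitive to undocumented priors of the original
implementation, so they are validated here as calibration properties
(detection of a ×10 clade shift, control on homogeneous data) rather than
as point targets.

## Known limitations

- REML, OU/EB correlation structures, and multi-response PGLS are out of
  scope; λ > 1 is not supported.
- The variable-rates sampler targets desk-scale problems (≤ a few hundred
  tips); the covariance rebuild is O(n²) per likelihood evaluation.
- pMCMC is a Monte-Carlo two-tailed sign probability, not a calibrated
  frequentist p-value.
- Stepping-stone estimates inherit prior sensitivity; compare models only
  under identical resolved priors.
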