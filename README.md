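# wingdiv

Comparative phylogenetics of wing-color evolution, lineage diversification,
and historical biogeography for small, well-sampled radiations — built
around the kind of question a tribe of brightly colored Neotropical
butterflies poses: did the dramatic shifts in wing color drive speciation,
or did the landscape (mountain uplift, the closing of an isthmus) do the
work?

The package is for comparative biologists with a time-calibrated
species-level phylogeny (Newick, branch lengths in Ma), per-species
continuous traits (optionally measured from specimen images), and
per-species geographic ranges over a handful of areas. Everything is also
runnable end-to-end on built-in synthetic data, so the full analysis is
testable without any download.

## What it computes

* **Color traits** (`color_traits`): per wing region, the mode of the R, G,
  B channels and of the per-pixel R+G+B sum over a mask — 16 traits across
  four regions — plus a lightness-independent index (OLS residuals of each
  channel on the region's lightness).
* **Trait evolution** (`trait_evolution`): Brownian motion
  `x_tip ~ N(alpha, sigma^2 * C)` with `C` the shared path-length matrix;
  relaxed rates (branch-specific multipliers), mean jumps on branches, or
  both, sampled by reversible-jump MCMC. Model choice by
  `AICM = 2*var(logL) - 2*mean(logL)` with a ΔAIC < 2 parsimony rule;
  ML ancestral states.
* **Tip-rate test** (`essim`): equal-splits statistic
  `ES_i = sum_j len(e_j) / 2^(k-j)` along each root-to-tip path, Pearson
  correlation of a trait with `log(1/ES)`, and a Brownian-simulation null
  (two-tailed, add-one p-value).
* **Diversification** (`diversification`): birth–death likelihoods for
  `lambda(t)`, `mu(t)` constant/exponential/linear in time or in an
  environmental covariate (paleoelevation, inter-continental
  connectivity), conditioned on crown age and survival; the
  constant-rates gamma statistic; the age–richness
  (method-of-moments) net diversification estimator; a migration-epoch
  connectivity curve `1 - exp(-rate)`.
* **Biogeography** (`biogeography`): time-stratified DEC and DIVALIKE over
  adjacency-connected ranges (default: up to 6 of 8 Neotropical areas),
  per-slice dispersal multipliers, optional centroid-distance penalty
  `(d_ij/mean)^-x`, ML fitting of `(d, e[, x])`, marginal ancestral
  ranges, and AIC comparison of eight dispersal-restriction hypotheses
  under both models.
* **Synthetic data** (`synthetic_data`): seeded generators for pure-birth
  and birth–death chronograms, BM traits with known shifts/jumps, DEC
  range histories (sharing the inference code's rate matrix), and
  wing-region pixel fixtures with a known modal color.

## Worked example

```python
import numpy as np
from wingdiv import synthetic_data as sd, diversification as dv, trait_evolution as te
from wingdiv.essim import essim_test
from wingdiv.phylo_core import branching_times

# a study-sized chronogram: 31 tips, pure birth at 0.12 / lineage / Ma
tree = sd.simulate_yule_tree(n_tips=31, lambda0=0.12, seed=11)
print(f"crown age: {branching_times(tree).crown_age:.2f} Ma")

# constant vs exponentially time-varying speciation
fits = [dv.fit_bd(tree, dv.RatesModel(lambda_form="constant"), seed=0, label="constant/zero"),
        dv.fit_bd(tree, dv.RatesModel(lambda_form="exponential"), seed=0, label="exponential/zero")]
print(dv.model_table(fits)[["Label", "Lambda0", "LambdaCoef", "Loglik", "AIC", "dAIC"]].round(3))
print(f"gamma = {dv.gamma_stat(tree):.3f}")

# a wing-color trait with one large jump on the stem of a 6-tip clade
base = sd.simulate_bm_trait(tree, 53.0, root_value=100.0, seed=4)
jump = 8 * float(np.std(list(base.values())))
traits = sd.simulate_bm_trait(tree, 53.0, root_value=100.0, jumps={37: jump}, seed=4)
post = te.rjmcmc_bm(tree, traits, "jumpBM", generations=1_250_000, thin=1000, seed=1)
print(f"posterior jump probability on the true branch: {post.jump_prob[37]:.2f}")

# is the trait associated with tip speciation rate?
res = essim_test(tree, traits, nsim=1000, seed=5)
print(f"ES-sim: rho = {res.rho:.2f}, p = {res.p_value:.2f}")
```

Output (the MCMC takes a minute or two):

```
crown age: 26.27 Ma
            Label  Lambda0  LambdaCoef  Loglik     AIC  dAIC
    constant/zero    0.095         NaN -97.217 196.434 0.000
 exponential/zero    0.086       0.012 -97.129 198.258 1.824
gamma = -0.300
posterior jump probability on the true branch: 1.00
ES-sim: rho = 0.48, p = 0.04
```

Reading it: the constant-rate model is preferred (the extra exponential
coefficient does not pay its 2-unit AIC penalty); the ML speciation rate is
0.095/Ma; gamma near zero is consistent with constant rates. The rjMCMC
puts posterior probability 1.0 on a color jump on exactly the branch where
one was simulated. The tip-rate correlation (rho = 0.48) reflects that the
jumped clade in this particular draw happens to sit on short terminal
branches — with 1,000 null simulations it is marginal (p = 0.04), the kind
of single-trait result the simulation null exists to keep honest.

A full configuration-driven run (`wingdiv run-all`, or
`wingdiv.pipeline.run_pipeline`) writes the report bundle — diversification
model table, per-trait model selection, per-trait tip-rate tests,
biogeographic hypothesis comparison, ancestral ranges, LTT coordinates, and
a manifest with every seed — to an output directory; sub-commands (`trees`,
`simulate`, `trait-evo`, `essim`, `divrates`, `biogeo`) expose each stage.
To analyze real data instead of synthetic, point `tree`, `trait_table`, and
`range_table` in the config at your files.

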