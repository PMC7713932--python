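# Methods

`wingdiv` implements a comparative-phylogenetics workflow for a small,
colorful Neotropical butterfly radiation: quantify wing color from specimen
images, model its evolution on a time-calibrated tree, test whether it is
associated with speciation rate, fit time- and environment-dependent
diversification models, and estimate ancestral geographic ranges under
dispersal–extinction–cladogenesis. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not establish.

## Conventions

Time is measured in millions of years (Ma) **before present**: the present
is 0 and the crown node carries the largest age. All rate coefficients
multiply time in this direction, so a speciation rate written
`lambda0 * exp(coef * t)` with a negative coefficient *rises* toward the
present. Trees are rooted, binary, and ultrametric; ultrametricity is
validated with a default tolerance of 1e-6 x crown age and violations are
rejected rather than silently stretched. Polytomies are rejected by default
(a flag resolves them randomly with zero-length edges for robustness
experiments).

## Wing-color traits

Color is summarized per wing region (whole forewing plus three
vein-delimited cells) as the **mode** of each 8-bit channel and of the
per-pixel channel sum ("total", 0–765) over the region mask — 16 traits.
Choices where the construction was open:

* *Total* is the mode of the per-pixel R+G+B sum (a genuine mode of a
  measured quantity), not the sum of the three channel modes.
* Ties in the mode break to the smallest value, making the statistic
  deterministic and order-independent.
* Species values are the arithmetic mean of specimen modes, rounded to two
  decimals; a config switch to pooled-pixel modes exists because the
  aggregation rule is not uniquely determined by the measurement protocol.
* *Lightness* of a region is its total mode / 3; the lightness-independent
  index is the OLS residual of each channel trait on lightness across
  species. Residuals sum to zero per trait by construction.

Camera/grayscale calibration is out of scope: synthetic fixtures are
calibrated by construction.

## Brownian trait models and reversible-jump MCMC

Four nested models: single-rate BM (rate `sigma2`, root state `alpha`);
relaxed BM (rBM1) with branch-specific rate multipliers, each shift scaling
its whole subtree; jump-BM with instantaneous mean displacements on
branches (applied at the rootward end, displacing the whole subtree — the
"pulse then drift" reading); and jump-rBM with both. The likelihood is the
multivariate normal with mean `alpha` plus summed path jumps and covariance
`sigma2` x shared scaled path length, evaluated by Felsenstein's pruning
recursion; a dense Cholesky path with per-configuration caching backs the
sampler for speed. Both are checked against each other and against
`scipy.stats.multivariate_normal` in tests.

Sampler priors (the source method leaves them unstated; all are
config-exposed):

* number of shifts and of jumps: Poisson(ln 2) truncated at the branch
  count, with the configuration uniform over branch subsets of that size;
* jump sizes: Normal(0, tau^2), tau = `proposal_width` x the Brownian SD
  accrued over a median-length branch at the data's ML rate (empirical-
  Bayes constant, so the prior does not drift with the sampled rate);
* rate multipliers: log-normal(0, 1); `p(sigma2) ~ 1/sigma2`; flat root.

Birth moves draw from the prior, so the acceptance ratio reduces to the
likelihood ratio times the Poisson count ratio and the birth/death
move-choice ratio — the uniform-placement prior cancels the placement
proposal exactly. The calibrated proposal width is 8 (it also scales the
jump-size random walk). Default chains: 1.25M generations, 25% burn-in,
thinned to 1,000 retained samples, two independent seeds recommended; an
effective-sample-size check on the log-likelihood warns (never fails) below
200. Jumps are reported on branches with posterior probability > 0.5.

Model selection uses the MCMC estimator of AIC,
`AICM = 2*var(logL) - 2*mean(logL)` (sample variance), lower is better,
with the parsimony rule: the best model wins unless a simpler model (order
BM, rBM1, jump-BM, jump-rBM) is within 2 units, in which case the simplest
such model is chosen; no model averaging. Ancestral states are GLS/ML
conditional expectations; reported variances include the GLS uncertainty of
the root state, so even a constant trait has positive reconstruction
variance.

## Tip-rate correlation test

The equal-splits statistic apportions each edge among its descendant tips,
halving at every split (summed ES equals total branch length — a tested
invariant). The test statistic is Pearson's rho between the untransformed
trait and `log(1/ES)`; the null simulates BM traits on the same tree at the
ML rate (default 1,000 simulations) and the two-tailed p-value uses the
add-one estimator, so p has resolution 1/(nsim+1) and is never 0. A
rank-based variant is available by flag. Type-I error at the 5% level is
verified to sit inside the 95% binomial interval over 500 null replicates.

## Birth–death diversification models

Speciation and extinction may each be constant, exponential, or linear in
time, or exponential/linear in an environmental covariate (paleoelevation
in km, or a connectivity probability). The likelihood of the branching
times conditions on the crown age and survival of both crown lineages. Two
functions are integrated from the present into the past with LSODA
(rtol 1e-9): the extinction probability
`E' = mu - (lambda+mu) E + lambda E^2` and the log single-lineage factor
`(log g)' = -(lambda + mu - 2 lambda E)`; then
`logL = sum log lambda(t_i) + 2 log g(t_1) + sum log g(t_i) - 2 log(1-E(t_1))`
(sums over non-root nodes). For constant lambda and mu = 0 this reduces to
the closed form `lambda^(n-2) exp(-lambda S)`, which is asserted in tests,
as are the nesting identities (exponential at coefficient 0 equals
constant; an environment-exponential model with a constant curve equals a
rescaled constant model).

Fitting is multi-start Nelder–Mead (10 starts, seeded jitter around the
pure-birth heuristic `(n-2)/S`), intercepts on the log scale. Parameter
counts include free parameters only: "zero extinction" is structural, not
an estimate at 0 (this is what makes the one- and two-parameter AIC
arithmetic come out right). Linear forms are floored at 0 with a warning —
they are kept available but are known to be fragile.

The connectivity covariate converts per-epoch migration rates (default
epoch boundaries 50, 41.1, 23.7, 8.7, 5.2, 0 Ma; rates must be
nondecreasing toward the present) into the per-Ma probability of at least
one migration event, `1 - exp(-rate)`, as a step curve; a "cumulative"
variant takes the running maximum toward the present. The default is the
per-Ma curve; both readings of "cumulative probability through time" are
implemented because the verbal description is ambiguous. Environment
curves interpolate linearly by default (cubic spline and step options).

The constant-rates gamma statistic follows the standard internode-interval
formula and is cross-checked against dendropy's independent
implementation. The method-of-moments net diversification estimator
(`ms_rate`) implements the stem form `log(n(1-eps)+eps)/t` (verified in
tests against brute-force inversion of the conditional expected richness)
and the corresponding crown closed form.

## Biogeography: DEC and DIVALIKE

Ranges are adjacency-connected area sets up to a maximum size (default 6 of
8 areas), encoded as bitmasks; the empty range is an absorbing anagenetic
state excluded from tip observations, node reports, and the root prior
(uniform over allowed non-empty ranges; a stationary-weighted alternative
is flagged). Connectivity is evaluated on the base adjacency graph in every
time slice — barriers act through dispersal multipliers, not state-space
pruning, keeping the state space constant across slices. Dispersal into
area `a` from range R is `d * sum_{b in R} m[b,a] * (dist[b,a]/mean)^-x`
with per-slice multiplier matrices `m` and an optional dimensionless
distance penalty (distances normalized by the mean pairwise centroid
distance; `x >= 0`). Extirpation removes one area at rate `e` when the
remainder is an allowed state.

Cladogenesis: DEC uses subset sympatry (one daughter keeps the parent
range, the other a single member area) plus vicariance with a singleton
daughter; DIVALIKE uses every vicariant bipartition into two allowed
ranges. Weights are equal within a parent and sum to one; daughter order
carries no meaning — the pruning likelihood symmetrizes over left/right.
Likelihoods propagate conditional vectors through dense matrix exponentials
(scaling-and-squaring; state counts here stay near 10^2, so the dense
approach is exact and fast), with branches segmented at time-slice
boundaries. Marginal ancestral ranges use the standard two-pass
root-to-tip conditioning. Both the likelihood and the marginals are tested
against an exhaustive scalar enumeration oracle on small trees.

Survival conditioning: the range-history simulator redraws any branch whose
range hits the empty set — i.e. it conditions each sampled lineage on
having survived, which is what observing extant tips implies. Whole-history
rejection is astronomically improbable at realistic extirpation rates
(singleton ranges lose their last area at rate `e` over hundreds of
lineage-Ma), so branch-level conditioning is the only workable reading. The
likelihood offers the exact counterpart (`condition_survival`): each branch
transition row renormalized over non-empty end states. The default
likelihood stays unconditioned — the field's convention, and the form
behind published hypothesis-comparison tables — but parameter-recovery
tests use the conditioned variant; without it the ML extirpation rate
collapses to zero on conditioned data (a measured, monotone profile, and a
known pathology of DEC extirpation estimates generally).

The eight dispersal hypotheses combine three ingredients: a distance
penalty (free exponent `x`), staged trans-isthmus multipliers across the
four default slices (32–23, 23–10, 10–7, 7–0 Ma; factors 0.1, 0.25, 0.5,
1.0), and an Andes barrier that strengthens with uplift (open, open,
sqrt(0.1), 0.1). The published per-epoch multiplier matrices are not
printed anywhere recoverable, so these defaults are explicit stand-ins and
fully replaceable via configuration; the centroid-distance matrix shipped
for the 8 Neotropical areas is likewise synthetic but rank-realistic and
marked as such.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the estimators assume:
pure-birth chronograms conditioned on tip count (~31 tips, ~28 Ma crown
age at the default 0.12/Ma rate), reconstructed birth–death trees with
time-varying rates via thinning (rejection on <2 survivors, retry budget
1,000), Brownian traits with known shifts and jumps, DEC histories sharing
the inference code's rate matrix and cladogenesis tables, and wing-region
pixel arrays whose masked majority pixel is a known modal color
(noise <= 45% keeps the majority argument valid).

One simulator detail matters statistically: after the n-th birth the
pure-birth simulator extends all pending branches by a fresh Exp(n*lambda)
draw. By renewal theory this is the age of the current n-lineage window at
a random inspection time (a uniform point in the *length-biased* interval
is exponential); a naive uniform fraction of an unbiased exponential halves
that window and visibly biases the constant-rates gamma statistic upward
(+0.16 measured over 2,000 trees).

What passing tests do **not** show about real data: the generators contain
no topological error or dating uncertainty, no measurement error beyond
salt-and-pepper pixel noise, no among-specimen phenotypic structure, no
biased geographic sampling, and rate values are homogeneous within their
specified classes. Recovery results are internal-consistency checks of the
estimators at realistic sizes, not evidence about any empirical system.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run everything at the study's
scale but with replicate counts chosen for a single-CPU desk run: 31-tip
trees throughout the trait analyses; 1.25M-generation chains for the jump
recovery demonstration and 40k-generation chains for the 20-chain null
calibration; 500 replicates for the tip-rate test's type-I error; 20
replicates of 50-tip, 8-area DEC recovery and 20 of 40-tip barrier
identification (14 and 8 in the faster acceptance script); 1,000 trees for
the gamma null. These sizes are the package's own defaults for its checks;
all are arguments, not constants.

## Known limitations

* No Ornstein–Uhlenbeck / early-burst models and no correlated-trait BM.
* No founder-event (+J) cladogenesis, by design.
* DEC extirpation is weakly identified; treat `e` point estimates with
  caution even under the conditioned likelihood.
* The rjMCMC explores jump placements on adjacent short branches slowly;
  posterior mass can legitimately split between a short stem and its
  child. Two-seed agreement is part of the test suite for the recovery
  fixture, not a general guarantee.
* Distance-penalty fits (`x` free) are slower and can sit at optimizer
  bounds on weakly informative data; such rows should be read as bounds,
  not estimates.
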