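"""Brownian-motion trait models: ML fitting, reversible-jump MCMC, ASR.

Four nested models of continuous trait evolution on a time-calibrated tree:

* **BM** — single-rate Brownian motion: rate ``sigma2`` (squared trait
  units per Ma) and root state ``alpha``.
* **rBM1** — relaxed BM: branch-specific rate multipliers introduced by
  "shift" events, each scaling its whole subtree.
* **jump-BM** — single rate, but the trait mean may jump by a finite
  amount on a branch, displacing the whole subtree.
* **jump-rBM** — shifts and jumps together.

The number and placement of shifts/jumps is sampled by reversible-jump
MCMC; models are compared with the MCMC estimator of AIC (AICM, Raftery's
posterior-log-likelihood moment formula), and a simpler model is preferred
whenever it comes within 2 AIC units of a more complex one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .phylo_core import Phylo

__all__ = [
    "BMParams",
    "RJPosterior",
    "MODEL_ORDER",
    "bm_vcv",
    "bm_loglik",
    "fit_bm_ml",
    "rjmcmc_bm",
    "aicm",
    "select_model",
    "asr_continuous",
]

#: simplicity order used for parsimony tie-breaks in model selection
MODEL_ORDER = ("BM", "rBM1", "jumpBM", "jumpRBM")


@dataclass(frozen=True)
class BMParams:
    sigma2: float
    alpha_root: float
    loglik: float = math.nan
    at_boundary: bool = False

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def _traits_vector(tree: Phylo, traits) -> np.ndarray:
    if isinstance(traits, dict):
        try:
            x = np.array([float(traits[nm]) for nm in tree.tip_names])
        except KeyError as exc:
            raise ValueError(f"trait missing for tip {exc}") from exc
    else:
        x = np.asarray(traits, dtype=float)
        if x.shape != (tree.n_tips,):
            raise ValueError("trait vector length must equal number of tips")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return x


def _effective_lengths(tree: Phylo, multipliers=None, shifts=None) -> np.ndarray:
    """Per-branch scaled lengths.  ``multipliers`` scales each branch
    directly; ``shifts`` (branch -> factor) scales a branch and all its
    descendants multiplicatively."""
    w = tree.edge_length.copy()
    if multipliers is not None:
        w = w * np.asarray(multipliers, dtype=float)
    if shifts:
        inherited = np.ones(tree.n_nodes)
        for v in range(tree.n_nodes - 2, -1, -1):
            p = tree.parent[v]
            inherited[v] = inherited[p] * shifts.get(v, 1.0)
        w = w * inherited
    w[tree.root] = 0.0
    return w


def _jump_offsets(tree: Phylo, jumps) -> np.ndarray:
    """Per-tip summed jump displacement along the root-to-tip path."""
    off = np.zeros(tree.n_nodes)
    if jumps:
        for v in range(tree.n_nodes - 2, -1, -1):
            off[v] = off[tree.parent[v]] + jumps.get(v, 0.0)
    return off[: tree.n_tips]


def bm_vcv(tree: Phylo, multipliers=None, shifts=None) -> np.ndarray:
    """Expected tip covariance (shared scaled path length) up to sigma2."""
    w = _effective_lengths(tree, multipliers, shifts)
    n = tree.n_tips
    C = np.zeros((n, n))
    for v in range(tree.n_nodes):
        if v == tree.root or w[v] == 0:
            continue
        tips = tree.clade_tips(v)
        C[np.ix_(tips, tips)] += w[v]
    return C


_LOG2PI = math.log(2.0 * math.pi)


def bm_loglik(tree: Phylo, traits, params: BMParams, *, multipliers=None,
              shifts=None, jumps=None) -> float:
    """Gaussian log-likelihood of tip traits under (jump/relaxed) BM.

    Mean of tip i is ``alpha_root`` plus the summed jumps on its root path;
    covariance is ``sigma2`` times the shared scaled path length.  Computed
    by Felsenstein's pruning recursion in O(n).
    """
    x = _traits_vector(tree, traits)
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0 for likelihood evaluation")
    if jumps:
        for b in jumps:
            if not (0 <= b < tree.n_nodes) or b == tree.root:
                raise ValueError(f"unknown branch id {b}")
        x = x - _jump_offsets(tree, jumps)
    w = _effective_lengths(tree, multipliers, shifts) * params.sigma2
    mu = np.empty(tree.n_nodes)
    var = np.empty(tree.n_nodes)
    mu[: tree.n_tips] = x
    var[: tree.n_tips] = w[: tree.n_tips]
    ll = 0.0
    for v in range(tree.n_tips, tree.n_nodes):
        a, b = tree.children[v]
        v1, v2 = var[a], var[b]
        tot = v1 + v2
        if tot <= 0:
            raise ValueError("zero-length cherry: singular covariance")
        d = mu[a] - mu[b]
        ll -= 0.5 * (_LOG2PI + math.log(tot) + d * d / tot)
        mu[v] = (mu[a] * v2 + mu[b] * v1) / tot
        var[v] = v1 * v2 / tot + w[v]
    # root contribution against the fixed root state
    v0 = var[tree.root]
    d0 = mu[tree.root] - params.alpha_root
    if v0 > 0:
        ll -= 0.5 * (_LOG2PI + math.log(v0) + d0 * d0 / v0)
    else:
        # var 0 only possible when the root merge already used all length
        raise ValueError("degenerate root variance")
    return float(ll)


def _dense_loglik_factory(tree: Phylo):
    """Cached dense-covariance evaluator used by the MCMC sampler.

    Returns ``f(x_adj, sigma2, alpha, shifts)`` computing the same quantity
    as :func:`bm_loglik`; the Cholesky factor is cached per shift
    configuration (keyed by the sorted shift items).
    """
    n = tree.n_tips
    edge_ids = [v for v in range(tree.n_nodes) if v != tree.root]
    masks = np.zeros((len(edge_ids), n))
    for k, v in enumerate(edge_ids):
        masks[k, tree.clade_tips(v)] = 1.0
    base_len = tree.edge_length[edge_ids]
    cache: dict = {}

    def factor(shifts_key, shifts):
        if len(cache) > 4096:
            cache.clear()
        if shifts_key not in cache:
            w = _effective_lengths(tree, None, shifts)[edge_ids]
            C = masks.T @ (w[:, None] * masks)
            cf = cho_factor(C, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            cache[shifts_key] = (cf, logdet)
        return cache[shifts_key]

    def loglik(x_adj, sigma2, alpha, shifts=None):
        key = tuple(sorted(shifts.items())) if shifts else ()
        cf, logdet = factor(key, shifts)
        r = x_adj - alpha
        quad = float(r @ cho_solve(cf, r))
        return -0.5 * (n * (_LOG2PI + math.log(sigma2)) + logdet + quad / sigma2)

    return loglik


def fit_bm_ml(tree: Phylo, traits) -> BMParams:
    """Analytic GLS/ML estimates of the single-rate BM parameters.

    ``alpha = (1'C^-1 x)/(1'C^-1 1)``, ``sigma2 = r'C^-1 r / n`` (the ML
    divisor), with C the unit-rate tip covariance.  A (near-)zero rate is
    flagged ``at_boundary``.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    x = _traits_vector(tree, traits)
    C = bm_vcv(tree)
    cf = cho_factor(C, lower=True)
    ones = np.ones(tree.n_tips)
    Ci1 = cho_solve(cf, ones)
    alpha = float(x @ Ci1 / (ones @ Ci1))
    r = x - alpha
    sigma2 = float(r @ cho_solve(cf, r) / tree.n_tips)
    at_boundary = sigma2 <= 1e-12 * max(1.0, float(np.var(x)))
    if at_boundary:
        return BMParams(sigma2=sigma2, alpha_root=alpha, loglik=math.inf,
                        at_boundary=True)
    ll = bm_loglik(tree, x, BMParams(sigma2=sigma2, alpha_root=alpha))
    return BMParams(sigma2=sigma2, alpha_root=alpha, loglik=ll)


# --------------------------------------------------------------------- #
# reversible-jump MCMC
# --------------------------------------------------------------------- #
@dataclass
class RJPosterior:
    """Thinned posterior sample from :func:`rjmcmc_bm`."""

    model: str
    branch_ids: list
    loglik_trace: np.ndarray
    sigma2_trace: np.ndarray
    alpha_trace: np.ndarray
    njumps_trace: np.ndarray
    nshifts_trace: np.ndarray
    jump_hits: np.ndarray   # retained-sample count per branch
    shift_hits: np.ndarray
    n_samples: int
    acceptance: dict = field(default_factory=dict)

    @property
    def jump_prob(self) -> dict:
        return {b: float(self.jump_hits[i]) / self.n_samples
                for i, b in enumerate(self.branch_ids)}

    @property
    def shift_prob(self) -> dict:
        return {b: float(self.shift_hits[i]) / self.n_samples
                for i, b in enumerate(self.branch_ids)}

    @property
    def mean_njumps(self) -> float:
        return float(self.njumps_trace.mean())

    def detected_jumps(self, threshold: float = 0.5) -> list:
        """Branches whose posterior jump probability exceeds ``threshold``
        (the reporting rule used for the empirical analysis)."""
        return [b for b, p in self.jump_prob.items() if p > threshold]

    def ess_loglik(self) -> float:
        return _ess(self.loglik_trace)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 1.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += 2.0 * acf[k]
    return float(n / max(s, 1.0))


def rjmcmc_bm(tree: Phylo, traits, model: str = "BM", *, generations: int = 100_000,
              thin: int = 100, seed: int = 0, proposal_width: float = 8.0,
              burnin: float = 0.25, prior_mean_events: float = math.log(2.0),
              ess_warn: float = 200.0) -> RJPosterior:
    """Reversible-jump MCMC over one of the four BM model spaces.

    Priors: the number of shifts and of jumps are each Poisson with mean
    ``prior_mean_events`` (truncated at the branch count); jump sizes are
    Normal(0, tau^2) with tau = ``proposal_width`` x the Brownian standard
    deviation accrued over a median-length branch at the data's ML rate;
    rate multipliers are log-normal(0, 1); ``p(sigma2) ~ 1/sigma2`` and the
    root state is flat.  Birth proposals draw from the prior, so the
    acceptance ratio reduces to the likelihood times the Poisson count
    ratio and the placement proposal ratio.

    ``proposal_width`` also scales the random-walk step on jump sizes; the
    calibrated default is 8.  Chains are seed-deterministic; a warning (not
    an error) is emitted when the log-likelihood ESS falls below
    ``ess_warn``.
    """
    if model not in MODEL_ORDER:
        raise ValueError(f"unknown model {model!r}")
    if generations < 10 * thin:
        raise ValueError("generations must be >= 10 * thin")
    if proposal_width <= 0:
        raise ValueError("proposal_width must be > 0")
    allow_shifts = model in ("rBM1", "jumpRBM")
    allow_jumps = model in ("jumpBM", "jumpRBM")
    rng = np.random.default_rng(seed)
    x = _traits_vector(tree, traits)
    ml = fit_bm_ml(tree, x)
    sigma2 = max(ml.sigma2, 1e-12)
    alpha = ml.alpha_root
    branch_ids = [v for v in range(tree.n_nodes) if v != tree.root]
    nb = len(branch_ids)
    med_len = float(np.median(tree.edge_length[branch_ids]))
    jump_sd = proposal_width * math.sqrt(sigma2 * max(med_len, 1e-12))
    dense_loglik = _dense_loglik_factory(tree)

    jumps: dict = {}
    shifts: dict = {}
    x_adj = x.copy()

    def cur_loglik(s2, a, sh, xa):
        return dense_loglik(xa, s2, a, sh)

    ll = cur_loglik(sigma2, alpha, shifts, x_adj)
    lam = prior_mean_events

    def log_pois(k):
        return k * math.log(lam) - math.lgamma(k + 1)

    def p_birth(k):
        # probability the birth/death move proposes a birth at count k
        if k == 0:
            return 1.0
        if k == nb:
            return 0.0
        return 0.5

    def birth_lr(k):
        # placement prior (uniform over branch subsets) cancels the
        # placement proposal exactly; size prior cancels the size proposal
        return log_pois(k + 1) - log_pois(k) + \
            math.log(1.0 - p_birth(k + 1)) - math.log(p_birth(k))

    def death_lr(k):
        return log_pois(k - 1) - log_pois(k) + \
            math.log(p_birth(k - 1)) - math.log(1.0 - p_birth(k))

    # proposal scales
    s2_step = 0.35
    alpha_step = 0.6 * math.sqrt(sigma2 * max(med_len, 1e-12))
    jump_step = jump_sd / 2.0
    shift_step = 0.5

    moves = ["sigma2", "alpha"]
    if allow_jumps:
        moves += ["jump_birthdeath", "jump_size"]
    if allow_shifts:
        moves += ["shift_birthdeath", "shift_mult"]
    accept = {m: 0 for m in moves}
    tries = {m: 0 for m in moves}

    n_burn = int(generations * burnin)
    keep_every = max(thin, 1)
    n_keep = (generations - n_burn) // keep_every
    ll_tr = np.empty(n_keep)
    s2_tr = np.empty(n_keep)
    a_tr = np.empty(n_keep)
    nj_tr = np.empty(n_keep, dtype=int)
    ns_tr = np.empty(n_keep, dtype=int)
    jump_hits = np.zeros(nb)
    shift_hits = np.zeros(nb)
    bindex = {b: i for i, b in enumerate(branch_ids)}
    kept = 0

    for g in range(generations):
        mv = moves[int(rng.integers(len(moves)))]
        tries[mv] += 1
        if mv == "sigma2":
            prop = sigma2 * math.exp(s2_step * rng.normal())
            ll_new = cur_loglik(prop, alpha, shifts, x_adj)
            # 1/sigma2 prior and log-scale proposal Jacobian cancel
            if math.log(rng.uniform()) < ll_new - ll:
                sigma2, ll = prop, ll_new
                accept[mv] += 1
        elif mv == "alpha":
            prop = alpha + alpha_step * rng.normal()
            ll_new = cur_loglik(sigma2, prop, shifts, x_adj)
            if math.log(rng.uniform()) < ll_new - ll:
                alpha, ll = prop, ll_new
                accept[mv] += 1
        elif mv == "jump_size" and jumps:
            b = list(jumps)[int(rng.integers(len(jumps)))]
            old = jumps[b]
            new = old + jump_step * rng.normal()
            jumps[b] = new
            xa = x - _jump_offsets(tree, jumps)
            ll_new = cur_loglik(sigma2, alpha, shifts, xa)
            lp = 0.5 * (old * old - new * new) / (jump_sd * jump_sd)
            if math.log(rng.uniform()) < ll_new - ll + lp:
                x_adj, ll = xa, ll_new
                accept[mv] += 1
            else:
                jumps[b] = old
        elif mv == "jump_birthdeath":
            k = len(jumps)
            birth = (k == 0) or (k < nb and rng.uniform() < 0.5)
            if birth:
                free = [b for b in branch_ids if b not in jumps]
                b = free[int(rng.integers(len(free)))]
                size = jump_sd * rng.normal()
                jumps[b] = size
                xa = x - _jump_offsets(tree, jumps)
                ll_new = cur_loglik(sigma2, alpha, shifts, xa)
                lr = ll_new - ll + birth_lr(k)
                if math.log(rng.uniform()) < lr:
                    x_adj, ll = xa, ll_new
                    accept[mv] += 1
                else:
                    del jumps[b]
            elif k > 0:
                b = list(jumps)[int(rng.integers(k))]
                size = jumps.pop(b)
                xa = x - _jump_offsets(tree, jumps)
                ll_new = cur_loglik(sigma2, alpha, shifts, xa)
                lr = ll_new - ll + death_lr(k)
                if math.log(rng.uniform()) < lr:
                    x_adj, ll = xa, ll_new
                    accept[mv] += 1
                else:
                    jumps[b] = size
        elif mv == "shift_mult" and shifts:
            b = list(shifts)[int(rng.integers(len(shifts)))]
            old = shifts[b]
            new = old * math.exp(shift_step * rng.normal())
            shifts[b] = new
            try:
                ll_new = cur_loglik(sigma2, alpha, shifts, x_adj)
            except np.linalg.LinAlgError:
                shifts[b] = old
                continue
            # log-normal(0,1) prior on multipliers; log-RW Jacobian cancels
            lp = 0.5 * (math.log(old) ** 2 - math.log(new) ** 2)
            if math.log(rng.uniform()) < ll_new - ll + lp:
                ll = ll_new
                accept[mv] += 1
            else:
                shifts[b] = old
        elif mv == "shift_birthdeath":
            k = len(shifts)
            birth = (k == 0) or (k < nb and rng.uniform() < 0.5)
            if birth:
                free = [b for b in branch_ids if b not in shifts]
                b = free[int(rng.integers(len(free)))]
                shifts[b] = math.exp(rng.normal())
                try:
                    ll_new = cur_loglik(sigma2, alpha, shifts, x_adj)
                except np.linalg.LinAlgError:
                    del shifts[b]
                    continue
                lr = ll_new - ll + birth_lr(k)
                if math.log(rng.uniform()) < lr:
                    ll = ll_new
                    accept[mv] += 1
                else:
                    del shifts[b]
            elif k > 0:
                b = list(shifts)[int(rng.integers(k))]
                old = shifts.pop(b)
                ll_new = cur_loglik(sigma2, alpha, shifts, x_adj)
                lr = ll_new - ll + death_lr(k)
                if math.log(rng.uniform()) < lr:
                    ll = ll_new
                    accept[mv] += 1
                else:
                    shifts[b] = old
        # record
        if g >= n_burn and (g - n_burn) % keep_every == 0 and kept < n_keep:
            ll_tr[kept] = ll
            s2_tr[kept] = sigma2
            a_tr[kept] = alpha
            nj_tr[kept] = len(jumps)
            ns_tr[kept] = len(shifts)
            for b in jumps:
                jump_hits[bindex[b]] += 1
            for b in shifts:
                shift_hits[bindex[b]] += 1
            kept += 1

    post = RJPosterior(
        model=model, branch_ids=branch_ids, loglik_trace=ll_tr[:kept],
        sigma2_trace=s2_tr[:kept], alpha_trace=a_tr[:kept],
        njumps_trace=nj_tr[:kept], nshifts_trace=ns_tr[:kept],
        jump_hits=jump_hits, shift_hits=shift_hits, n_samples=kept,
        acceptance={m: (accept[m] / tries[m] if tries[m] else math.nan)
                    for m in moves},
    )
    ess = post.ess_loglik()
    if ess < ess_warn:
        warnings.warn(
            f"log-likelihood ESS {ess:.0f} below {ess_warn:.0f}; "
            "consider a longer chain", RuntimeWarning, stacklevel=2)
    return post


def aicm(loglik_trace, *, min_length: int = 100) -> float:
    """AIC for MCMC samples: ``2*var(trace) - 2*mean(trace)``.

    Computed from the posterior sample of log-likelihoods (Raftery et al.'s
    moment estimator); lower is better.  A zero-variance trace degrades to
    ``-2*mean`` with a warning.
    """
    t = np.asarray(loglik_trace, dtype=float)
    if t.size < min_length:
        raise ValueError(f"trace too short (< {min_length})")
    v = float(np.var(t, ddof=1))
    if v == 0.0:
        warnings.warn("zero-variance log-likelihood trace", RuntimeWarning,
                      stacklevel=2)
    return 2.0 * v - 2.0 * float(t.mean())


def select_model(aic_values: dict, *, threshold: float = 2.0) -> str:
    """Best model by AIC with a parsimony tie-break.

    The lowest-AIC model wins unless a simpler model (in the order BM,
    rBM1, jump-BM, jump-rBM) lies within ``threshold`` AIC units of it, in
    which case the simplest such model is chosen.  No model averaging.
    """
    if not aic_values:
        raise ValueError("empty model set")
    for m in aic_values:
        if m not in MODEL_ORDER:
            raise ValueError(f"unknown model {m!r}")
    best = min(aic_values.values())
    for m in MODEL_ORDER:  # simplest first
        if m in aic_values and aic_values[m] <= best + threshold:
            return m
    raise AssertionError("unreachable")


def asr_continuous(tree: Phylo, traits, params: BMParams):
    """ML (GLS) ancestral state estimates and variances under single-rate BM.

    Conditional expectation of each internal node given the tips:
    ``alpha + c' C^-1 (x - alpha)`` with ``c`` the node-tip shared path
    lengths; the root estimate equals ``alpha``.  Returns
    ``(estimates, variances)`` dicts keyed by internal node id.
    """
    x = _traits_vector(tree, traits)
    C = bm_vcv(tree)
    cf = cho_factor(C, lower=True)
    resid = cho_solve(cf, x - params.alpha_root)
    ones = np.ones(tree.n_tips)
    Ci1 = cho_solve(cf, ones)
    alpha_var = 1.0 / float(ones @ Ci1)  # GLS uncertainty of the root state
    est, var = {}, {}
    ages = tree.node_ages()
    crown = tree.crown_age
    for v in range(tree.n_tips, tree.n_nodes):
        c = np.zeros(tree.n_tips)
        # shared path length of node v with tip i: depth of their MRCA,
        # which for a tip under v is v's own depth, else the MRCA depth
        node_depth = crown - ages[v]
        under = set(tree.clade_tips(v))
        for i in range(tree.n_tips):
            if i in under:
                c[i] = node_depth
            else:
                # walk up from v until the clade contains tip i
                u = v
                while i not in tree.clade_tips(u):
                    u = int(tree.parent[u])
                c[i] = crown - ages[u]
        est[v] = float(params.alpha_root + c @ resid)
        Cic = cho_solve(cf, c)
        # conditional variance plus the propagated root-state uncertainty
        w1 = 1.0 - float(c @ Ci1)
        var[v] = float(params.sigma2 * (node_depth - c @ Cic
                                        + w1 * w1 * alpha_var))
    return est, var
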