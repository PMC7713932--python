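"""Seeded generators for trees, traits, range histories, and wing images.

These simulators produce data with the statistical structure the analysis
modules assume — pure-birth and birth–death chronograms of roughly the
empirical size (~31 tips, ~28 Ma crown age), Brownian traits with optional
rate shifts and mean jumps, dispersal–extinction–cladogenesis range
histories over an explicit area adjacency graph, and wing-region pixel
arrays with a dominant modal color — so every downstream stage can be
exercised and calibrated without external downloads.

All generators are deterministic given a seed (or an explicit
``numpy.random.Generator``): the same configuration yields bit-identical
output.  The range simulator shares the rate matrix and cladogenesis
tables of :mod:`wingdiv.biogeography`, so inference recovery tests are
internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo_core import Phylo

__all__ = [
    "SimConfig",
    "WingRegionFixture",
    "simulate_yule_tree",
    "simulate_bd_tree",
    "simulate_bm_trait",
    "simulate_dec_history",
    "simulate_wing_region",
    "write_trait_table",
    "write_range_table",
]


@dataclass
class SimConfig:
    """Defaults mirror the empirical study system: a ~31-tip tribe with a
    ~28 Ma crown age diversifying at ~0.12 lineages/lineage/Ma and a wing
    trait evolving at sigma^2 ~ 53 squared trait units per Ma."""

    seed: int = 0
    n_tips: int = 31
    lambda0: float = 0.12
    mu0: float = 0.0
    trait_sigma2: float = 53.0
    jump_spec: list = field(default_factory=list)   # [(branch_id, size), ...]
    shift_spec: list = field(default_factory=list)  # [(branch_id, multiplier), ...]
    dec_params: tuple = (0.1, 0.02)                 # (d, e) per Ma

    def __post_init__(self):
        if self.lambda0 < 0 or self.mu0 < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class WingRegionFixture:
    """RGB pixel array + region mask with a known dominant (modal) color."""

    pixels: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray    # H x W bool
    true_mode: tuple    # (R, G, B)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------- #
# trees
# --------------------------------------------------------------------- #
def _assemble_tree(children, start, end, tip_order) -> Phylo:
    """Build a Phylo from forward-time branch records.

    ``children``: internal label -> (child, child); ``start[lab]`` /
    ``end[lab]``: forward times at which the branch above ``lab`` begins and
    ends (for tips, ``end`` is the present).  The root's branch length is 0.
    """
    n = len(tip_order)
    ids = {lab: i for i, lab in enumerate(tip_order)}
    parent = np.full(2 * n - 1, -1, dtype=int)
    length = np.zeros(2 * n - 1)
    counter = [n]

    child_set = {c for pair in children.values() for c in pair}
    root_lab = next(lab for lab in children if lab not in child_set)

    def assign(lab):
        if lab in ids:
            return ids[lab]
        a, b = children[lab]
        ia, ib = assign(a), assign(b)
        v = counter[0]
        counter[0] += 1
        ids[lab] = v
        parent[ia] = v
        parent[ib] = v
        return v

    assign(root_lab)
    for lab, v in ids.items():
        length[v] = 0.0 if lab == root_lab else end[lab] - start[lab]
    return Phylo([f"T{i+1}" for i in range(n)], parent, length)


def simulate_yule_tree(config: SimConfig | None = None, *, n_tips=None, lambda0=None,
                       seed=None, rng=None, return_events: bool = False):
    """Constant-rate pure-birth tree conditioned on tip count.

    Simulation starts at the crown split with 2 lineages and stops at the
    n-th birth; the stub beyond the last split is a fresh Exp(n*lambda)
    draw — the age of the current n-lineage window at a random inspection
    time (renewal theory: a uniform point inside the length-biased interval
    is exponential), which keeps the constant-rates gamma statistic
    centered on zero.  The tree is ultrametric with exactly ``n_tips``
    tips.  With ``return_events=True`` also returns
    ``{"crown_age", "branching_ages"}`` (ages in Ma before present).
    """
    if config is not None:
        n_tips = config.n_tips if n_tips is None else n_tips
        lambda0 = config.lambda0 if lambda0 is None else lambda0
        if seed is None and rng is None:
            seed = config.seed
    if n_tips is None or lambda0 is None:
        raise ValueError("n_tips and lambda0 required")
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if lambda0 <= 0:
        raise ValueError("lambda0 must be > 0")
    r = _as_rng(rng if rng is not None else seed)

    children = {"root": (0, 1)}
    start = {"root": 0.0, 0: 0.0, 1: 0.0}
    end = {"root": 0.0}
    split_times = [0.0]
    active = [0, 1]
    t = 0.0
    nxt = 2
    for k in range(2, n_tips):
        t += r.exponential(1.0 / (lambda0 * k))
        i = int(r.integers(k))
        lab = active[i]
        a, b = nxt, nxt + 1
        nxt += 2
        children[lab] = (a, b)
        end[lab] = t
        start[a] = start[b] = t
        split_times.append(t)
        active[i] = a
        active.append(b)
    t_end = t + r.exponential(1.0 / (lambda0 * n_tips))
    for lab in active:
        end[lab] = t_end
    tree = _assemble_tree(children, start, end, active)
    if return_events:
        ages = np.sort(t_end - np.asarray(split_times))[::-1]
        return tree, {"crown_age": float(t_end), "branching_ages": ages}
    return tree


def simulate_bd_tree(duration: float, lambda_fn, mu_fn, *, seed=None, rng=None,
                     max_retries: int = 1000, return_log: bool = False):
    """Reconstructed birth–death tree over a span of ``duration`` Ma.

    Forward simulation from a single origin lineage; time-inhomogeneous
    rates (functions of Ma *before present*) are honored by thinning
    against their maximum over the span.  Replicates whose reconstructed
    crown has fewer than 2 surviving descent lines are rejected and
    retried.  Extinct lineages are pruned, so the returned tree is
    ultrametric; its crown age is at most ``duration``.
    """
    r = _as_rng(rng if rng is not None else seed)
    grid = np.linspace(0.0, duration, 513)
    lmax = max(max(float(lambda_fn(t)) for t in grid), 1e-12)
    mmax = max(float(mu_fn(t)) for t in grid)
    total_max = lmax + mmax
    retry_log = []
    for attempt in range(max_retries):
        lineages = {0: {"birth": 0.0, "parent": None}}
        alive = [0]
        nxt = 1
        s = 0.0
        while alive:
            k = len(alive)
            s += r.exponential(1.0 / (total_max * k))
            if s >= duration:
                break
            age = duration - s
            lam, mu = float(lambda_fn(age)), float(mu_fn(age))
            u = r.uniform() * total_max
            i = int(r.integers(k))
            if u < lam:
                lab = alive[i]
                a, b = nxt, nxt + 1
                nxt += 2
                lineages[a] = {"birth": s, "parent": lab}
                lineages[b] = {"birth": s, "parent": lab}
                lineages[lab]["split"] = (a, b)
                lineages[lab]["split_time"] = s
                alive[i] = a
                alive.append(b)
            elif u < lam + mu:
                alive.pop(i)
            # thinning no-op otherwise
        if len(alive) < 2:
            retry_log.append(len(alive))
            continue
        tree = _reconstruct_bd(lineages, alive, duration)
        if tree is None:
            retry_log.append(len(alive))
            continue
        if return_log:
            return tree, {"attempts": attempt + 1, "rejected_survivor_counts": retry_log}
        return tree
    raise RuntimeError(f"no surviving replicate within {max_retries} retries")


def _reconstruct_bd(lineages, survivors, duration):
    survives = set()
    for lab in survivors:
        v = lab
        while v is not None and v not in survives:
            survives.add(v)
            v = lineages[v]["parent"]

    def surviving_children(lab):
        if "split" not in lineages[lab]:
            return []
        return [c for c in lineages[lab]["split"] if c in survives]

    def descend(lab):
        # skip unary (one-surviving-child) chains
        while True:
            cs = surviving_children(lab)
            if len(cs) == 1:
                lab = cs[0]
            else:
                return lab, cs

    crown_lab, cs = descend(0)
    if len(cs) != 2:
        return None
    children, start, end, tips = {}, {}, {}, []

    def build(lab, birth):
        bottom, cs2 = descend(lab)
        start[lab] = birth
        if not cs2:
            end[lab] = duration
            tips.append(lab)
            return lab
        t_split = lineages[bottom]["split_time"]
        end[lab] = t_split
        a = build(cs2[0], t_split)
        b = build(cs2[1], t_split)
        children[lab] = (a, b)
        return lab

    t_crown = lineages[crown_lab]["split_time"]
    ia = build(cs[0], t_crown)
    ib = build(cs[1], t_crown)
    children["crown"] = (ia, ib)
    start["crown"] = end["crown"] = t_crown
    order = sorted(tips)
    return _assemble_tree(children, start, end, order)


# --------------------------------------------------------------------- #
# traits
# --------------------------------------------------------------------- #
def simulate_bm_trait(tree: Phylo, sigma2: float, *, root_value: float = 0.0,
                      jumps=None, shifts=None, seed=None, rng=None) -> dict:
    """Brownian trait at the tips, with optional rate shifts and mean jumps.

    ``shifts`` maps a branch id (child node id) to a rate multiplier applied
    to that branch and, multiplicatively, to its descendants.  ``jumps``
    maps a branch id to a mean displacement added at the rootward end of the
    branch, displacing the whole subtree.  Returns ``{tip_name: value}``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    jumps = dict(jumps or {})
    shifts = dict(shifts or {})
    for b in list(jumps) + list(shifts):
        if not (0 <= b < tree.n_nodes) or b == tree.root:
            raise ValueError(f"unknown branch id {b}")
    r = _as_rng(rng if rng is not None else seed)
    x = np.zeros(tree.n_nodes)
    mult = np.ones(tree.n_nodes)
    x[tree.root] = root_value
    # parent ids always exceed child ids, so descending order is a preorder
    for v in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[v]
        mult[v] = mult[p] * shifts.get(v, 1.0)
        var = sigma2 * mult[v] * tree.edge_length[v]
        step = r.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
        x[v] = x[p] + jumps.get(v, 0.0) + step
    return {tree.tip_names[i]: float(x[i]) for i in range(tree.n_tips)}


# --------------------------------------------------------------------- #
# ranges
# --------------------------------------------------------------------- #
def simulate_dec_history(tree: Phylo, space, d: float, e: float, *,
                         model: str = "DEC", root_range=None, seed=None, rng=None,
                         multipliers=None, distances=None, x: float = 0.0,
                         max_retries: int = 1000, return_log: bool = False):
    """Simulate a range history with the inference module's own generator.

    Anagenetic events follow a continuous-time Markov chain with the rate
    matrix from :func:`wingdiv.biogeography.build_Q`; daughter ranges at
    nodes are drawn from :func:`wingdiv.biogeography.cladogenesis_weights`.
    A branch whose range hits the empty set (lineage-wide extirpation) is
    recorded and that branch's history redrawn — i.e. the history is
    conditioned on every sampled lineage surviving, matching the fact that
    the observed tips are extant; a branch failing ``max_retries`` draws
    aborts the replicate.

    Returns ``(tip_ranges, node_ranges)``: dicts of area bitmasks keyed by
    tip name / internal node id.  With ``return_log`` a third dict reports
    realized gain/loss event counts, the expected gain count integrated
    along the realized (accepted) trajectory, total lineage-time, and the
    number of rejected branch draws.
    """
    from .biogeography import build_Q, cladogenesis_weights

    r = _as_rng(rng if rng is not None else seed)
    if root_range is None:
        root_range = space.ranges[1]  # smallest singleton
    if root_range not in space.index:
        raise ValueError("root range not in state space")
    Q = np.asarray(build_Q(space, d, e, x=x, multipliers=multipliers,
                           distances=distances))
    gain_rate = np.zeros(len(space.ranges))
    sizes = np.array([bin(m).count("1") for m in space.ranges])
    for i in range(len(space.ranges)):
        gains = [Q[i, j] for j in range(len(space.ranges)) if sizes[j] > sizes[i]]
        gain_rate[i] = float(np.sum(gains))
    weights = cladogenesis_weights(space, model)

    log = {"gains": 0, "losses": 0, "expected_gains": 0.0, "lineage_time": 0.0,
           "rejected_branch_draws": 0}
    state = {tree.root: space.index[root_range]}
    for v in range(tree.n_nodes - 1, tree.n_tips - 1, -1):  # internals, root first
        opts = weights[space.ranges[state[v]]]
        probs = np.array([w for _, _, w in opts])
        pick = opts[int(r.choice(len(opts), p=probs / probs.sum()))]
        left, right = (pick[1], pick[0]) if r.uniform() < 0.5 else (pick[0], pick[1])
        for c, rng_mask in zip(tree.children[v], (left, right)):
            for attempt in range(max_retries):
                trial = {k: log[k] for k in log}
                si = _evolve_range(space.index[rng_mask], tree.edge_length[c], Q,
                                   sizes, gain_rate, r, trial)
                if space.ranges[si] != 0:
                    log.update(trial)
                    state[c] = si
                    break
                log["rejected_branch_draws"] += 1
            else:
                raise RuntimeError(
                    "branch never avoided range extinction within retry budget")
    tips = {tree.tip_names[i]: space.ranges[state[i]] for i in range(tree.n_tips)}
    nodes = {v: space.ranges[state[v]] for v in range(tree.n_tips, tree.n_nodes)}
    if return_log:
        return tips, nodes, log
    return tips, nodes


def _evolve_range(si, length, Q, sizes, gain_rate, r, log) -> int:
    t = 0.0
    while True:
        out = -Q[si, si]
        dwell = r.exponential(1.0 / out) if out > 0 else np.inf
        step = min(dwell, length - t)
        log["expected_gains"] += gain_rate[si] * step
        log["lineage_time"] += step
        t += dwell
        if t >= length or not np.isfinite(dwell):
            return si
        probs = np.maximum(Q[si].copy(), 0.0)
        probs[si] = 0.0
        j = int(r.choice(len(probs), p=probs / probs.sum()))
        log["gains" if sizes[j] > sizes[si] else "losses"] += 1
        si = j


# --------------------------------------------------------------------- #
# wing regions
# --------------------------------------------------------------------- #
def simulate_wing_region(true_mode, noise_fraction: float, shape=(64, 64), *,
                         seed=None, rng=None, mask=None) -> WingRegionFixture:
    """Pixel fixture whose masked region has a known modal color.

    Each masked pixel equals ``true_mode`` with probability
    ``1 - noise_fraction`` and is uniform random RGB otherwise; unmasked
    pixels are arbitrary background.  ``noise_fraction`` above 0.45 is
    rejected — the majority argument guaranteeing mode recovery would no
    longer hold.
    """
    if not (0.0 <= noise_fraction <= 0.45):
        raise ValueError("noise_fraction must be in [0, 0.45]")
    true_mode = tuple(int(c) for c in true_mode)
    if len(true_mode) != 3 or any(not (0 <= c <= 255) for c in true_mode):
        raise ValueError("true_mode must be an RGB triple in 0..255")
    r = _as_rng(rng if rng is not None else seed)
    H, W = shape
    pixels = np.empty((H, W, 3), dtype=np.uint8)
    pixels[..., 0], pixels[..., 1], pixels[..., 2] = true_mode
    if mask is None:
        mask = np.zeros((H, W), dtype=bool)
        mask[H // 8: H - H // 8, W // 8: W - W // 8] = True
    noisy = (r.uniform(size=(H, W)) < noise_fraction) & mask
    pixels[noisy] = r.integers(0, 256, size=(int(noisy.sum()), 3), dtype=np.uint8)
    bg = ~mask
    pixels[bg] = r.integers(0, 256, size=(int(bg.sum()), 3), dtype=np.uint8)
    return WingRegionFixture(pixels=pixels, mask=mask, true_mode=true_mode)


# --------------------------------------------------------------------- #
# writers
# --------------------------------------------------------------------- #
def write_trait_table(traits: dict, path, trait_name: str = "trait") -> None:
    """Tab-delimited (species, trait, value) long-format table."""
    with open(path, "w") as fh:
        fh.write("species\ttrait\tvalue\n")
        for sp, v in traits.items():
            fh.write(f"{sp}\t{trait_name}\t{v:.10g}\n")


def write_range_table(tip_ranges: dict, areas, path) -> None:
    """Tab-delimited presence/absence (species x areas, 0/1)."""
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(areas) + "\n")
        for sp, mask in tip_ranges.items():
            row = [(mask >> i) & 1 for i in range(len(areas))]
            fh.write(sp + "\t" + "\t".join(str(b) for b in row) + "\n")
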