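"""Time-stratified DEC and DIVALIKE ancestral-range estimation.

The model is a continuous-time Markov chain over geographic ranges — sets
of occupied areas encoded as bitmasks.  Anagenetic change along branches is
range expansion (dispersal rate ``d`` into an adjacent area, optionally
scaled by per-epoch multipliers and a centroid-distance penalty ``x``) and
range contraction (extirpation rate ``e``).  At nodes, cladogenetic
inheritance follows either the DEC event set (subset sympatry + vicariance
with a singleton daughter) or the DIVALIKE event set (all vicariant
bipartitions).  Dispersal-multiplier matrices can differ between time
slices, letting barrier hypotheses (mountain uplift, seaway closure) act
only during the epochs in which they existed.

The state space is restricted to adjacency-connected area sets up to a
maximum size; the empty range is an absorbing anagenetic state excluded
from tip observations and from the root prior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo_core import Phylo

__all__ = [
    "RangeStateSpace",
    "DECConfig",
    "DECParams",
    "build_state_space",
    "build_Q",
    "cladogenesis_weights",
    "dec_loglik",
    "fit_dec",
    "ancestral_ranges",
    "compare_hypotheses",
    "read_range_table",
]


# --------------------------------------------------------------------- #
# state space
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class RangeStateSpace:
    """Allowed geographic ranges as bitmasks over ordered areas.

    ``ranges[0]`` is always the empty range; the rest are the non-empty,
    adjacency-connected subsets of size <= ``max_size``, ordered by size
    then bitmask.  ``index`` maps bitmask -> position in ``ranges``.
    """

    areas: tuple
    adjacency: np.ndarray
    max_size: int
    ranges: tuple
    index: dict = field(hash=False, compare=False, default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.ranges)

    def label(self, mask: int) -> str:
        if mask == 0:
            return "-"
        return "+".join(a for i, a in enumerate(self.areas) if mask >> i & 1)

    def mask_of(self, area_names) -> int:
        m = 0
        for a in area_names:
            m |= 1 << self.areas.index(a)
        return m


def _connected(mask: int, adjacency: np.ndarray) -> bool:
    members = [i for i in range(adjacency.shape[0]) if mask >> i & 1]
    if len(members) <= 1:
        return True
    seen = {members[0]}
    stack = [members[0]]
    mset = set(members)
    while stack:
        v = stack.pop()
        for w in mset - seen:
            if adjacency[v, w]:
                seen.add(w)
                stack.append(w)
    return seen == mset


def build_state_space(areas, adjacency, max_size: int) -> RangeStateSpace:
    """Enumerate adjacency-connected area sets of size <= ``max_size``.

    Singletons are always connected, hence always allowed; the empty range
    is placed at index 0.
    """
    areas = tuple(areas)
    if not areas:
        raise ValueError("empty area list")
    k = len(areas)
    if not (1 <= max_size <= k):
        raise ValueError("max_size must be in 1..#areas")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (k, k) or not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be a symmetric #areas x #areas matrix")
    allowed = [0]
    for size in range(1, max_size + 1):
        masks = []
        for combo in itertools.combinations(range(k), size):
            m = sum(1 << i for i in combo)
            if _connected(m, adjacency):
                masks.append(m)
        allowed.extend(sorted(masks))
    index = {m: i for i, m in enumerate(allowed)}
    return RangeStateSpace(areas=areas, adjacency=adjacency, max_size=max_size,
                           ranges=tuple(allowed), index=index)


@dataclass
class DECConfig:
    """Time-slice structure and per-slice dispersal multipliers.

    ``slice_boundaries`` are Ma before present, strictly decreasing and
    ending at 0 (e.g. ``[32, 23, 10, 7, 0]`` defines 4 slices; the oldest
    boundary is treated as extending to the crown age if the tree is
    older).  ``multipliers[s]`` is the area x area factor matrix for slice
    ``s`` (oldest first); ``None`` means all ones.  ``distances`` is the
    centroid distance matrix in km, used only when the distance penalty
    exponent ``x`` is active.
    """

    slice_boundaries: list = field(default_factory=lambda: [np.inf, 0.0])
    multipliers: list | None = None
    distances: np.ndarray | None = None
    use_distance: bool = False

    def __post_init__(self):
        b = list(self.slice_boundaries)
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("slice boundaries must be strictly decreasing")
        if b[-1] != 0.0:
            raise ValueError("slice boundaries must end at 0 (the present)")
        self.slice_boundaries = b
        if self.multipliers is not None and len(self.multipliers) != self.n_slices:
            raise ValueError("need one multiplier matrix per slice")

    @property
    def n_slices(self) -> int:
        return len(self.slice_boundaries) - 1

    def slice_of(self, age: float) -> int:
        """Index of the slice containing ``age`` (ages beyond the oldest
        boundary fall into slice 0)."""
        b = self.slice_boundaries
        for s in range(self.n_slices):
            if age >= b[s + 1]:
                if s == 0 or age <= b[s]:
                    return s
        return self.n_slices - 1

    def multiplier(self, s: int):
        if self.multipliers is None:
            return None
        return self.multipliers[s]


@dataclass
class DECParams:
    d: float
    e: float
    x: float = 0.0

    def __post_init__(self):
        if self.d < 0 or self.e < 0 or self.x < 0:
            raise ValueError("d, e, x must be >= 0")


# --------------------------------------------------------------------- #
# rate matrix and cladogenesis
# --------------------------------------------------------------------- #
def build_Q(space: RangeStateSpace, d: float, e: float, *, x: float = 0.0,
            multipliers=None, distances=None) -> np.ndarray:
    """Anagenetic rate matrix over the full state space (empty included).

    Expansion: ``Q[R, R+{a}] = d * sum_{b in R} m[b,a] * (dist[b,a]/mean)^-x``
    for targets in the allowed set.  Contraction: ``Q[R, R-{a}] = e`` when
    the reduced range is allowed (the empty range is reachable from
    singletons and absorbing).  Rows sum to zero.
    """
    k = len(space.areas)
    n = space.n_states
    m = np.ones((k, k)) if multipliers is None else np.asarray(multipliers, dtype=float)
    if x > 0:
        if distances is None:
            raise ValueError("distance penalty requires a distance matrix")
        dist = np.asarray(distances, dtype=float)
        off = dist[~np.eye(k, dtype=bool)]
        if not np.all(np.isfinite(off)) or np.any(off <= 0):
            raise ValueError("distances must be positive and finite off-diagonal")
        dist_pen = (dist / off.mean()) ** (-x)
    else:
        dist_pen = np.ones((k, k))
    Q = np.zeros((n, n))
    for i, R in enumerate(space.ranges):
        if R == 0:
            continue
        members = [a for a in range(k) if R >> a & 1]
        for a in range(k):
            if R >> a & 1:
                tgt = R & ~(1 << a)
                j = space.index.get(tgt)
                if j is not None:
                    Q[i, j] += e
            else:
                tgt = R | (1 << a)
                j = space.index.get(tgt)
                if j is not None:
                    rate = d * sum(m[b, a] * dist_pen[b, a] for b in members)
                    Q[i, j] += rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def cladogenesis_weights(space: RangeStateSpace, model: str = "DEC") -> dict:
    """Per parent range, the list of (left, right, weight) daughter events.

    DEC: a single-area parent is inherited identically; a widespread parent
    splits by subset sympatry (one daughter keeps the full range, the other
    a single member area) or vicariance in which one daughter is a single
    area and the other the allowed remainder.  DIVALIKE: identity for
    singletons, else every vicariant bipartition into two allowed non-empty
    ranges.  Weights are equal across a parent's events and sum to 1;
    left/right labels carry no meaning (likelihoods symmetrize over them).
    """
    if model not in ("DEC", "DIVALIKE"):
        raise ValueError(f"unknown cladogenesis model {model!r}")
    k = len(space.areas)
    table = {}
    for R in space.ranges:
        if R == 0:
            continue
        members = [a for a in range(k) if R >> a & 1]
        if len(members) == 1:
            table[R] = [(R, R, 1.0)]
            continue
        events = []
        if model == "DEC":
            for a in members:
                events.append((R, 1 << a))  # subset sympatry
            for a in members:
                rem = R & ~(1 << a)
                if rem in space.index:
                    events.append((1 << a, rem))  # singleton vicariance
        else:  # DIVALIKE
            for split in _bipartitions(members):
                left = sum(1 << a for a in split[0])
                right = sum(1 << a for a in split[1])
                if left in space.index and right in space.index:
                    events.append((left, right))
        if not events:
            raise ValueError(f"range {space.label(R)} has no cladogenetic event")
        w = 1.0 / len(events)
        table[R] = [(l, r, w) for l, r in events]
    return table


def _bipartitions(members):
    """Unordered bipartitions of a set into two non-empty parts."""
    n = len(members)
    for bits in range(1, 2 ** (n - 1)):
        left = [members[i] for i in range(n) if bits >> i & 1]
        right = [m for m in members if m not in left]
        yield left, right


# --------------------------------------------------------------------- #
# likelihood
# --------------------------------------------------------------------- #
def _branch_matrix(space, config: DECConfig, params: DECParams,
                   child_age: float, parent_age: float, cache: dict,
                   condition_survival: bool = False) -> np.ndarray:
    """Transition probability matrix (rows = state at the older end) for a
    branch, as a product over its time-slice segments.

    With ``condition_survival`` each row is renormalized over non-empty
    end states, i.e. conditioned on the lineage not having been extirpated
    everywhere by the end of the branch (the empty range is absorbing, so
    a non-empty endpoint certifies the whole path avoided it)."""
    cuts = [b for b in config.slice_boundaries if child_age < b < parent_age]
    pts = [parent_age] + cuts + [child_age]
    P = None
    for hi, lo in zip(pts[:-1], pts[1:]):
        s = config.slice_of(0.5 * (hi + lo))
        key = ("Q", s)
        if key not in cache:
            cache[key] = build_Q(space, params.d, params.e, x=params.x,
                                 multipliers=config.multiplier(s),
                                 distances=config.distances)
        seg = expm(cache[key] * (hi - lo))
        P = seg if P is None else P @ seg
    if P is None:  # zero-length branch
        P = np.eye(space.n_states)
    if condition_survival:
        surv = 1.0 - P[:, 0]
        P = P.copy()
        P[:, 0] = 0.0
        ok = surv > 0
        P[ok] = P[ok] / surv[ok, None]
    return P


def _node_conditionals(tree: Phylo, tip_ranges: dict, space, config, params,
                       model: str, condition_survival: bool = False):
    """Postorder pass.  Returns (down, branch_P, log_scale) where
    ``down[v]`` is the conditional likelihood vector at node v *after*
    cladogenetic combination (for internals) or tip observation, and
    ``branch_P[v]`` the transition matrix along the branch above v."""
    n_states = space.n_states
    ages = tree.node_ages()
    weights = cladogenesis_weights(space, model)
    cache: dict = {}
    down = np.zeros((tree.n_nodes, n_states))
    branch_P = [None] * tree.n_nodes
    log_scale = 0.0
    for v in range(tree.n_nodes):
        if v < tree.n_tips:
            mask = tip_ranges[tree.tip_names[v]]
            if mask == 0 or mask not in space.index:
                raise ValueError(
                    f"tip {tree.tip_names[v]} has a disallowed range")
            down[v, space.index[mask]] = 1.0
        else:
            ca, cb = tree.children[v]
            la = branch_P[ca] @ down[ca] if branch_P[ca] is not None else down[ca]
            lb = branch_P[cb] @ down[cb] if branch_P[cb] is not None else down[cb]
            vec = np.zeros(n_states)
            for R, evs in weights.items():
                i = space.index[R]
                acc = 0.0
                for l, r, w in evs:
                    il, ir = space.index[l], space.index[r]
                    acc += w * 0.5 * (la[il] * lb[ir] + la[ir] * lb[il])
                vec[i] = acc
            down[v] = vec
        if v != tree.root:
            p = tree.parent[v]
            branch_P[v] = _branch_matrix(space, config, params,
                                         float(max(ages[v], 0.0)), float(ages[p]),
                                         cache, condition_survival)
        mx = down[v].max()
        if mx > 0 and (mx < 1e-100 or mx > 1e100):
            down[v] /= mx
            log_scale += np.log(mx)
    return down, branch_P, log_scale


def dec_loglik(tree: Phylo, tip_ranges: dict, space: RangeStateSpace,
               config: DECConfig, params: DECParams, model: str = "DEC", *,
               condition_survival: bool = False) -> float:
    """Log-likelihood of the tip ranges under (time-stratified) DEC/DIVALIKE.

    Pruning over the tree with slice-aware matrix exponentials along
    branches and cladogenetic mixing at nodes; the root is weighted
    uniformly over allowed non-empty ranges.  ``condition_survival``
    conditions every branch on the lineage escaping total extirpation —
    the exact counterpart of the survival conditioning applied by the
    range-history simulator, and the variant to use when estimating
    parameters from such conditioned histories (without it the
    extirpation rate is strongly biased toward zero).
    """
    down, _, log_scale = _node_conditionals(tree, tip_ranges, space, config,
                                            params, model, condition_survival)
    prior = np.zeros(space.n_states)
    prior[1:] = 1.0 / (space.n_states - 1)
    lik = float(prior @ down[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def fit_dec(tree: Phylo, tip_ranges: dict, space: RangeStateSpace,
            config: DECConfig, model: str = "DEC", *, n_starts: int = 4,
            seed: int = 0, d0: float = 0.05, e0: float = 0.05,
            condition_survival: bool = False):
    """Maximum-likelihood (d, e[, x]) for one hypothesis configuration.

    ``x`` is included as a free parameter only when
    ``config.use_distance``; multi-start Nelder–Mead on log-rates, with a
    deterministic seed for the start jitter.
    """
    rng = np.random.default_rng(seed)
    free_x = bool(config.use_distance)

    def unpack(theta):
        d, e = np.exp(theta[0]), np.exp(theta[1])
        x = float(np.exp(theta[2])) if free_x else 0.0
        return DECParams(d=d, e=e, x=x)

    def nll(theta):
        if np.any(np.abs(theta) > 12):
            return 1e10
        try:
            return -dec_loglik(tree, tip_ranges, space, config, unpack(theta),
                               model, condition_survival=condition_survival)
        except (ValueError, FloatingPointError):
            return 1e10

    base = np.log([d0, e0] + ([1.0] if free_x else []))
    best = None
    for s in range(n_starts):
        start = base if s == 0 else base + rng.normal(0, 1.0, size=base.size)
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    loglik = -float(best.fun)
    n_params = 3 if free_x else 2
    aic = 2 * n_params - 2 * loglik
    return params, {"loglik": loglik, "n_params": n_params, "aic": aic,
                    "converged": bool(best.fun < 1e9)}


def ancestral_ranges(tree: Phylo, tip_ranges: dict, space: RangeStateSpace,
                     config: DECConfig, params: DECParams,
                     model: str = "DEC") -> dict:
    """Marginal range probabilities at every internal node.

    Standard two-pass conditioning: the downward (postorder) conditionals
    are combined with an upward message that carries the likelihood of the
    rest of the tree through the parent's cladogenetic event and the
    branch's transition matrix.  Returns ``{node_id: probability vector}``
    over ``space.ranges`` (empty range has probability 0).
    """
    down, branch_P, _ = _node_conditionals(tree, tip_ranges, space, config,
                                           params, model)
    n_states = space.n_states
    weights = cladogenesis_weights(space, model)
    prior = np.zeros(n_states)
    prior[1:] = 1.0 / (n_states - 1)

    up = {tree.root: prior.copy()}
    out = {}
    # preorder: parents (larger ids) before children
    for v in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        marg = up[v] * down[v]
        tot = marg.sum()
        if tot <= 0:
            raise FloatingPointError("zero marginal at node; parameters degenerate")
        out[v] = marg / tot
        ca, cb = tree.children[v]
        la = branch_P[ca] @ down[ca] if branch_P[ca] is not None else down[ca]
        lb = branch_P[cb] @ down[cb] if branch_P[cb] is not None else down[cb]
        for child, sib_like in ((ca, lb), (cb, la)):
            msg = np.zeros(n_states)  # message at the top of the child branch
            for R, evs in weights.items():
                i = space.index[R]
                if up[v][i] == 0:
                    continue
                for l, r, w in evs:
                    il, ir = space.index[l], space.index[r]
                    msg[il] += up[v][i] * w * 0.5 * sib_like[ir]
                    msg[ir] += up[v][i] * w * 0.5 * sib_like[il]
            if branch_P[child] is not None:
                msg = branch_P[child].T @ msg
            mx = msg.max()
            up[child] = msg / mx if mx > 0 else msg
    return out


# --------------------------------------------------------------------- #
# hypothesis comparison
# --------------------------------------------------------------------- #
def compare_hypotheses(tree: Phylo, tip_ranges: dict, space: RangeStateSpace,
                       hypotheses: dict, models=("DEC", "DIVALIKE"), *,
                       seed: int = 0, n_starts: int = 3) -> pd.DataFrame:
    """Fit every (model, hypothesis) pair and tabulate LnL/AIC/dAIC.

    ``hypotheses`` maps a name to a :class:`DECConfig`.  The returned frame
    has one row per pair with columns Model, Hypothesis, LnL, n_params, d,
    e, x, AIC, dAIC (dAIC relative to the best row), best row flagged.
    """
    rows = []
    for model in models:
        for name, config in hypotheses.items():
            params, info = fit_dec(tree, tip_ranges, space, config, model,
                                   seed=seed, n_starts=n_starts)
            rows.append({
                "Model": model, "Hypothesis": name, "LnL": info["loglik"],
                "n_params": info["n_params"], "d": params.d, "e": params.e,
                "x": params.x if config.use_distance else np.nan,
                "AIC": info["aic"],
            })
    df = pd.DataFrame(rows)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["best"] = df["dAIC"] == 0.0
    return df


# --------------------------------------------------------------------- #
# default Neotropical configuration
# --------------------------------------------------------------------- #
NEOTROPICAL_AREAS = (
    "CentralAmerica", "Caribbean", "Choco", "WesternAndes",
    "EasternAndes", "Amazon", "Guianas", "AtlanticForest",
)

#: adjacency over the 8 areas: a chain along the Andes flank plus the
#: lowland connections (Amazon touching Guianas and Atlantic Forest,
#: Caribbean reachable from Central America and the Choco lowlands)
NEOTROPICAL_ADJACENCY = np.array([
    # CA  Car  Cho  WAn  EAn  Ama  Gui  AtF
    [0,   1,   1,   0,   0,   0,   0,   0],   # CentralAmerica
    [1,   0,   1,   0,   0,   0,   1,   0],   # Caribbean
    [1,   1,   0,   1,   0,   0,   0,   0],   # Choco
    [0,   0,   1,   0,   1,   0,   0,   0],   # WesternAndes
    [0,   0,   0,   1,   0,   1,   0,   0],   # EasternAndes
    [0,   0,   0,   0,   1,   0,   1,   1],   # Amazon
    [0,   1,   0,   0,   0,   1,   0,   0],   # Guianas
    [0,   0,   0,   0,   0,   1,   0,   0],   # AtlanticForest
], dtype=bool)

#: area-centroid great-circle distances, thousands of km (synthetic but
#: rank-realistic; replaceable via config)
NEOTROPICAL_DISTANCES = np.array([
    [0.0, 1.5, 1.8, 2.2, 2.6, 3.5, 3.0, 5.5],
    [1.5, 0.0, 1.0, 1.4, 1.8, 2.8, 2.0, 5.0],
    [1.8, 1.0, 0.0, 0.5, 1.0, 2.2, 2.0, 4.5],
    [2.2, 1.4, 0.5, 0.0, 0.5, 1.8, 1.8, 4.0],
    [2.6, 1.8, 1.0, 0.5, 0.0, 1.4, 1.5, 3.5],
    [3.5, 2.8, 2.2, 1.8, 1.4, 0.0, 1.2, 2.0],
    [3.0, 2.0, 2.0, 1.8, 1.5, 1.2, 0.0, 2.8],
    [5.5, 5.0, 4.5, 4.0, 3.5, 2.0, 2.8, 0.0],
])

#: four time slices bounding the staged isthmus emergence and late uplift
DEFAULT_SLICES = [32.0, 23.0, 10.0, 7.0, 0.0]

#: dispersal factor across a closed barrier, and the staged factors for
#: the Central-South America connection in the four slices (oldest first)
BARRIER_FACTOR = 0.1
PANAMA_FACTORS = (0.1, 0.25, 0.5, 1.0)

_ANDES_WEST = ("CentralAmerica", "Caribbean", "Choco", "WesternAndes")
_PANAMA_NORTH = ("CentralAmerica",)


def neotropical_state_space(max_size: int = 6) -> RangeStateSpace:
    return build_state_space(NEOTROPICAL_AREAS, NEOTROPICAL_ADJACENCY, max_size)


def _pair_matrix(areas, group_a, group_b, factor):
    """Multiplier matrix penalizing movement between two area groups."""
    k = len(areas)
    m = np.ones((k, k))
    ia = [areas.index(a) for a in group_a]
    ib = [areas.index(a) for a in group_b]
    for i in ia:
        for j in ib:
            m[i, j] = m[j, i] = factor
    return m


def build_hypotheses(areas=NEOTROPICAL_AREAS, *, slices=None, distances=None,
                     barrier_factor=BARRIER_FACTOR,
                     panama_factors=PANAMA_FACTORS) -> dict:
    """The eight dispersal-restriction hypotheses as DECConfig objects.

    Ho1 null (no restriction); Ho2 distance penalty only; Ho3 staged
    trans-isthmus factors per slice; Ho4 Andes barrier from slice 3 (10 Ma)
    on, full barrier in the final slice; Ho5 distance+Andes; Ho6
    distance+Panama; Ho7 Panama+Andes; Ho8 all three.  The multiplier
    values are package defaults standing in for unpublished per-epoch
    matrices and are replaceable via configuration.
    """
    areas = tuple(areas)
    slices = list(DEFAULT_SLICES if slices is None else slices)
    n_slices = len(slices) - 1
    if distances is None:
        distances = NEOTROPICAL_DISTANCES if areas == NEOTROPICAL_AREAS else None
    west = [a for a in _ANDES_WEST if a in areas]
    east = [a for a in areas if a not in west]
    north = [a for a in _PANAMA_NORTH if a in areas]
    south = [a for a in areas if a not in north]

    def panama_stack():
        return [_pair_matrix(areas, north, south, f) for f in panama_factors[:n_slices]]

    def andes_stack():
        # barrier strengthens with uplift: open in the two oldest slices,
        # intermediate in the third, full barrier in the most recent
        factors = [1.0] * n_slices
        if n_slices >= 2:
            factors[-2] = math.sqrt(barrier_factor)
        factors[-1] = barrier_factor
        return [_pair_matrix(areas, west, east, f) for f in factors]

    def combine(stacks):
        if not stacks:
            return None
        out = []
        for s in range(n_slices):
            m = np.ones((len(areas), len(areas)))
            for st in stacks:
                m = m * st[s]
            out.append(m)
        return out

    specs = {
        "Ho1": (False, []),
        "Ho2": (True, []),
        "Ho3": (False, ["panama"]),
        "Ho4": (False, ["andes"]),
        "Ho5": (True, ["andes"]),
        "Ho6": (True, ["panama"]),
        "Ho7": (False, ["panama", "andes"]),
        "Ho8": (True, ["panama", "andes"]),
    }
    stacks = {"panama": panama_stack(), "andes": andes_stack()}
    out = {}
    for name, (use_dist, parts) in specs.items():
        mult = combine([stacks[p] for p in parts])
        out[name] = DECConfig(slice_boundaries=list(slices), multipliers=mult,
                              distances=distances, use_distance=use_dist)
    return out


def read_range_table(path, space: RangeStateSpace | None = None) -> dict:
    """Read a tab-delimited presence/absence table into {species: bitmask}."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = {}
    for sp, row in df.iterrows():
        mask = 0
        for i, v in enumerate(row.values):
            if int(v):
                mask |= 1 << i
        out[sp] = mask
    return out
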