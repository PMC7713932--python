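"""Rooted ultrametric tree container and basic chronogram summaries.

Every downstream analysis (trait models, diversification likelihoods,
biogeography) consumes the :class:`Phylo` container defined here.  Trees are
time-calibrated: branch lengths are in millions of years (Ma) and node ages
are measured *before present*, so the present is age 0 and the crown node
carries the largest age.

Newick parsing and writing are delegated to :mod:`dendropy`; this module only
adds validation (binary topology, unique tip labels, ultrametricity) and the
array-based representation the numerical code wants.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylo",
    "BranchingTimes",
    "LTTCurve",
    "read_newick",
    "write_newick",
    "validate_ultrametric",
    "branching_times",
    "ltt",
]


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages of an ultrametric tree, Ma before present.

    ``ages`` is sorted descending, so ``ages[0]`` is the crown age and the
    list has ``n_tips - 1`` entries for a binary tree.
    """

    ages: np.ndarray
    n_tips: int

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])


@dataclass(frozen=True)
class LTTCurve:
    """Lineage-through-time step curve.

    ``times`` are Ma before present in descending order (crown age first);
    ``counts[k]`` is the number of reconstructed lineages from ``times[k]``
    until the next (younger) time.  Counts start at 2 and end at ``n_tips``.
    """

    times: np.ndarray
    counts: np.ndarray


class Phylo:
    """Rooted binary tree with named tips and Ma branch lengths.

    Node ids are integers ``0 .. 2n-2``: tips are ``0 .. n-1`` (in the order
    of :attr:`tip_names`), internal nodes ``n .. 2n-2`` in postorder, so the
    root is always the last id and any internal child has a smaller id than
    its parent.  ``edge_length[v]`` is the length of the edge above node
    ``v`` (0 for the root unless the input carried a root edge).
    """

    def __init__(self, tip_names, parent, edge_length):
        self.tip_names: list[str] = list(tip_names)
        self.parent: np.ndarray = np.asarray(parent, dtype=int)
        self.edge_length: np.ndarray = np.asarray(edge_length, dtype=float)
        n = len(self.tip_names)
        self.n_tips = n
        self.n_nodes = 2 * n - 1
        if self.parent.shape != (self.n_nodes,) or self.edge_length.shape != (self.n_nodes,):
            raise ValueError("parent/edge_length arrays must have 2n-1 entries")
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self._validate()
        self._depths = None

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        if len(set(self.tip_names)) != self.n_tips:
            raise NewickError("duplicate tip labels")
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        for v in range(self.n_nodes):
            nc = len(self.children[v])
            if v < self.n_tips and nc != 0:
                raise ValueError("tip node with children")
            if v >= self.n_tips and nc != 2:
                raise ValueError("internal node is not bifurcating")
        if np.count_nonzero(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")

    # ------------------------------------------------------------------ #
    @property
    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (Ma since the crown split)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            # root is the largest id; parents precede children in reverse order
            for v in range(self.n_nodes - 2, -1, -1):
                d[v] = d[self.parent[v]] + self.edge_length[v]
            # tips (ids < n_tips) have parents with larger ids, handled above
            for v in range(self.n_tips):
                d[v] = d[self.parent[v]] + self.edge_length[v]
            self._depths = d
        return self._depths

    @property
    def crown_age(self) -> float:
        return float(self.node_depths[: self.n_tips].max())

    def node_ages(self) -> np.ndarray:
        """Age before present of every node (tips ~0 for ultrametric trees)."""
        return self.crown_age - self.node_depths

    @property
    def total_branch_length(self) -> float:
        s = self.edge_length.sum() - self.edge_length[self.root]
        return float(s)

    def tip_index(self, name: str) -> int:
        return self.tip_names.index(name)

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids descending from ``node`` (the node itself if a tip)."""
        if node < self.n_tips:
            return [node]
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def mrca(self, names) -> int:
        """Most recent common ancestor of a set of tip names."""
        ids = {self.tip_index(n) for n in names}
        if not ids:
            raise ValueError("empty tip set")
        # walk up from an arbitrary member until the clade covers all ids
        v = next(iter(ids))
        while not ids <= set(self.clade_tips(v)):
            v = int(self.parent[v])
        return v

    # ------------------------------------------------------------------ #
    def to_newick(self, precision: int = 17) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                body = self.tip_names[v]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            return f"{body}:{self.edge_length[v]:.{precision}g}"

        return rec(self.root) + ";"

    def prune_tips(self, drop_names) -> "Phylo":
        """Return a new tree with the named tips removed (outgroup pruning)."""
        drop = set(drop_names)
        unknown = drop - set(self.tip_names)
        if unknown:
            raise ValueError(f"unknown tips: {sorted(unknown)}")
        keep = [nm for nm in self.tip_names if nm not in drop]
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than 2 tips")
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick")
        taxa = [t for t in dt.taxon_namespace if t.label in set(keep)]
        dt.retain_taxa(taxa)
        return read_newick(dt.as_string(schema="newick"))


# ---------------------------------------------------------------------- #
def read_newick(text: str, resolve_polytomies: bool = False, seed: int | None = None) -> Phylo:
    """Parse a Newick string into a :class:`Phylo`.

    Branch lengths are mandatory for every non-root edge.  Polytomies are
    rejected by default; with ``resolve_polytomies=True`` they are resolved
    randomly with zero-length edges (seeded for reproducibility).
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick: {exc}") from exc

    if resolve_polytomies:
        rng = np.random.default_rng(seed)
        dt.resolve_polytomies(rng=_DendropyRng(rng))

    leaves = list(dt.leaf_node_iter())
    if len(leaves) < 2:
        raise NewickError("tree must have at least 2 tips")
    labels = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise NewickError("unlabeled tip")
        labels.append(lf.taxon.label)
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate tip labels")

    n = len(labels)
    order = {id(lf): i for i, lf in enumerate(leaves)}
    next_internal = n
    parent = np.full(2 * n - 1, -1, dtype=int)
    length = np.zeros(2 * n - 1)
    ids: dict[int, int] = {}
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            v = order[id(nd)]
        else:
            if len(nd.child_nodes()) != 2:
                raise NewickError("polytomy encountered (set resolve_polytomies=True)")
            v = next_internal
            next_internal += 1
        ids[id(nd)] = v
        el = nd.edge.length
        if el is None:
            if nd.parent_node is None:
                el = 0.0
            else:
                raise NewickError("missing branch length")
        length[v] = float(el)
    if next_internal != 2 * n - 1:
        raise NewickError("unexpected node count (unrooted or multifurcating tree?)")
    for nd in dt.postorder_node_iter():
        if nd.parent_node is not None:
            parent[ids[id(nd)]] = ids[id(nd.parent_node)]
    return Phylo(labels, parent, length)


class _DendropyRng:
    """Adapter exposing the ``random.Random`` surface dendropy expects."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def sample(self, seq, k):
        idx = self._rng.choice(len(seq), size=k, replace=False)
        return [seq[i] for i in idx]

    def shuffle(self, seq):
        self._rng.shuffle(seq)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def random(self):
        return float(self._rng.random())

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]


def write_newick(tree: Phylo, path=None, precision: int = 17) -> str:
    s = tree.to_newick(precision=precision)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def validate_ultrametric(tree: Phylo, tol: float | None = None) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol`` Ma.

    Default tolerance is ``1e-6 x crown age``.
    """
    depths = tree.node_depths[: tree.n_tips]
    if tol is None:
        tol = 1e-6 * float(depths.max())
    return float(depths.max() - depths.min()) <= tol


def branching_times(tree: Phylo, tol: float | None = None) -> BranchingTimes:
    """Internal node ages (Ma before present), sorted descending."""
    if not validate_ultrametric(tree, tol):
        raise ValueError("tree is not ultrametric")
    ages = tree.node_ages()[tree.n_tips:]
    return BranchingTimes(ages=np.sort(ages)[::-1].copy(), n_tips=tree.n_tips)


def ltt(tree: Phylo) -> LTTCurve:
    """Lineage-through-time curve: counts 2..n at descending node ages."""
    bt = branching_times(tree)
    counts = np.arange(2, tree.n_tips + 1)
    return LTTCurve(times=bt.ages.copy(), counts=counts)


def export_node_ages(tree: Phylo, path) -> None:
    """Tab-delimited (node_id, age_Ma) export for all nodes."""
    ages = tree.node_ages()
    with open(path, "w") as fh:
        fh.write("node_id\tage_Ma\n")
        for v in range(tree.n_nodes):
            fh.write(f"{v}\t{ages[v]:.9g}\n")
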