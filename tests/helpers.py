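"""Shared independent oracles for the test suite.

These deliberately use scalar enumeration and direct formulas rather than
the package's vectorized code paths, so they can serve as independent
references."""

import numpy as np
from scipy.linalg import expm

from wingdiv import biogeography as bg


def dec_oracle_loglik(tree, tips, space, params, model):
    """Exhaustive enumeration over cladogenetic events and branch-end
    states; O(states^2) per branch per recursion, feasible for tiny trees."""
    Q = bg.build_Q(space, params.d, params.e, x=params.x)
    ages = tree.node_ages()
    Ps = {v: expm(Q * (ages[tree.parent[v]] - max(ages[v], 0)))
          for v in range(tree.n_nodes) if v != tree.root}
    wt = bg.cladogenesis_weights(space, model)

    def L(v, R):
        if v < tree.n_tips:
            return 1.0 if R == tips[tree.tip_names[v]] else 0.0
        if R == 0:
            return 0.0
        ca, cb = tree.children[v]
        tot = 0.0
        for (l, r, w) in wt[R]:
            for (dl, dr) in ((l, r), (r, l)):
                sub_a = sum(Ps[ca][space.index[dl], j] * L(ca, space.ranges[j])
                            for j in range(space.n_states))
                sub_b = sum(Ps[cb][space.index[dr], j] * L(cb, space.ranges[j])
                            for j in range(space.n_states))
                tot += 0.5 * w * sub_a * sub_b
        return tot

    lik = sum(L(tree.root, R) for R in space.ranges[1:]) / (space.n_states - 1)
    return float(np.log(lik))
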