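import numpy as np
import pytest
from scipy.linalg import expm

from wingdiv import biogeography as bg
from wingdiv import synthetic_data as sd


def oracle_loglik(tree, tips, space, params, model):
    """Scalar enumeration over cladogenetic events and end states —
    independent of the vectorized pruning implementation."""
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


class TestStateSpace:
    def test_chain_enumeration(self, chain3_space):
        labels = {chain3_space.label(m) for m in chain3_space.ranges}
        assert labels == {"-", "A", "B", "C", "A+B", "B+C", "A+B+C"}
        assert "A+C" not in labels

    def test_complete_adjacency_all_subsets(self):
        k = 4
        adj = ~np.eye(k, dtype=bool)
        space = bg.build_state_space(tuple("WXYZ"), adj, k)
        assert space.n_states == 2 ** k

    def test_max_size_one(self):
        adj = ~np.eye(5, dtype=bool)
        space = bg.build_state_space(tuple("ABCDE"), adj, 1)
        assert space.n_states == 6

    def test_empty_area_list_rejected(self):
        with pytest.raises(ValueError):
            bg.build_state_space((), np.zeros((0, 0), bool), 1)

    def test_deterministic_ordering(self, chain3_space):
        sizes = [bin(m).count("1") for m in chain3_space.ranges]
        assert sizes == sorted(sizes)
        assert chain3_space.ranges[0] == 0


class TestRateMatrix:
    def test_rows_sum_to_zero(self, chain8_space):
        Q = bg.build_Q(chain8_space, 0.13, 0.07)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()

    def test_textbook_two_area_rates(self):
        adj = np.array([[0, 1], [1, 0]], bool)
        space = bg.build_state_space(("A", "B"), adj, 2)
        Q = bg.build_Q(space, d=0.3, e=0.11)
        iA, iAB = space.index[0b01], space.index[0b11]
        assert Q[iA, iAB] == pytest.approx(0.3)
        assert Q[iAB, iA] == pytest.approx(0.11)
        # empty reachable from singletons only, absorbing
        assert Q[iA, 0] == pytest.approx(0.11)
        assert np.all(Q[0] == 0.0)

    def test_zero_dispersal_leaves_only_contractions(self, chain3_space):
        Q = bg.build_Q(chain3_space, 0.0, 0.2)
        sizes = np.array([bin(m).count("1") for m in chain3_space.ranges])
        for i in range(chain3_space.n_states):
            for j in range(chain3_space.n_states):
                if i != j and Q[i, j] > 0:
                    assert sizes[j] < sizes[i]

    def test_barrier_multiplier_zeroes_one_route(self, chain3_space):
        k = 3
        m = np.ones((k, k))
        m[0, 1] = m[1, 0] = 0.0  # A-B closed
        Q = bg.build_Q(chain3_space, 0.5, 0.0, multipliers=m)
        sp = chain3_space
        assert Q[sp.index[0b001], sp.index[0b011]] == 0.0   # A -> AB blocked
        assert Q[sp.index[0b010], sp.index[0b110]] == pytest.approx(0.5)  # B -> BC


class TestCladogenesis:
    def test_singleton_identity(self, chain3_space):
        wt = bg.cladogenesis_weights(chain3_space, "DEC")
        assert wt[0b001] == [(0b001, 0b001, 1.0)]

    def test_dec_two_area_event_set(self, chain3_space):
        wt = bg.cladogenesis_weights(chain3_space, "DEC")
        events = {(l, r): w for l, r, w in wt[0b011]}
        assert events == {(0b011, 0b001): 0.25, (0b011, 0b010): 0.25,
                          (0b001, 0b010): 0.25, (0b010, 0b001): 0.25}

    def test_divalike_chain_vicariance_only(self, chain3_space):
        wt = bg.cladogenesis_weights(chain3_space, "DIVALIKE")
        splits = {frozenset((l, r)) for l, r, _ in wt[0b111]}
        # A+C is disconnected, so only A|BC and AB|C appear
        assert splits == {frozenset((0b001, 0b110)), frozenset((0b011, 0b100))}

    def test_weights_sum_to_one(self, chain8_space):
        for model in ("DEC", "DIVALIKE"):
            wt = bg.cladogenesis_weights(chain8_space, model)
            for R, evs in wt.items():
                assert sum(w for _, _, w in evs) == pytest.approx(1.0)

    def test_unknown_model_rejected(self, chain3_space):
        with pytest.raises(ValueError):
            bg.cladogenesis_weights(chain3_space, "DEC+J")


class TestLikelihood:
    def test_single_area_space(self, yule31):
        # one area: the only possible history, so the survival-conditioned
        # likelihood is exactly 1; the classic unconditioned likelihood
        # pays exp(-e * total branch length) for extirpation risk
        space = bg.build_state_space(("X",), np.zeros((1, 1), bool), 1)
        cfg = bg.DECConfig()
        tips = {nm: 1 for nm in yule31.tip_names}
        p = bg.DECParams(0.4, 0.2)
        ll_cond = bg.dec_loglik(yule31, tips, space, cfg, p,
                                condition_survival=True)
        assert ll_cond == pytest.approx(0.0, abs=1e-10)
        ll = bg.dec_loglik(yule31, tips, space, cfg, p)
        assert ll == pytest.approx(-0.2 * yule31.total_branch_length, abs=1e-8)

    def test_matches_enumeration_oracle(self, chain3_space):
        rng = np.random.default_rng(1)
        cfg = bg.DECConfig()
        for _ in range(12):
            tree = sd.simulate_yule_tree(n_tips=int(rng.integers(3, 5)),
                                         lambda0=0.5, rng=rng)
            p = bg.DECParams(d=float(rng.uniform(0.01, 0.5)),
                             e=float(rng.uniform(0.01, 0.5)))
            for model in ("DEC", "DIVALIKE"):
                tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.3, 0.1,
                                                  model=model, rng=rng)
                assert bg.dec_loglik(tree, tips, chain3_space, cfg, p, model) \
                    == pytest.approx(oracle_loglik(tree, tips, chain3_space, p,
                                                   model), abs=1e-8)

    def test_stratification_noop(self, chain3_space):
        tree = sd.simulate_yule_tree(n_tips=6, lambda0=0.4, seed=7)
        tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.2, 0.05, seed=3)
        p = bg.DECParams(0.2, 0.05)
        flat = bg.DECConfig()
        strat = bg.DECConfig(slice_boundaries=[np.inf, 3.0, 1.0, 0.0],
                             multipliers=[np.ones((3, 3))] * 3)
        assert bg.dec_loglik(tree, tips, chain3_space, flat, p) == pytest.approx(
            bg.dec_loglik(tree, tips, chain3_space, strat, p), abs=1e-10)

    def test_area_relabeling_equivariance(self, chain3_space):
        # reversing the chain A-B-C -> C-B-A maps each range to its mirror
        tree = sd.simulate_yule_tree(n_tips=6, lambda0=0.4, seed=9)
        tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.25, 0.05, seed=2)
        p = bg.DECParams(0.25, 0.05)

        def mirror(mask):
            return ((mask & 1) << 2) | (mask & 2) | ((mask >> 2) & 1)

        mirrored = {k: mirror(v) for k, v in tips.items()}
        cfg = bg.DECConfig()
        assert bg.dec_loglik(tree, tips, chain3_space, cfg, p) == pytest.approx(
            bg.dec_loglik(tree, mirrored, chain3_space, cfg, p), abs=1e-10)

    def test_disallowed_tip_range_rejected(self, chain3_space, yule31):
        tips = {nm: 0b101 for nm in yule31.tip_names}  # disconnected A+C
        with pytest.raises(ValueError, match="disallowed"):
            bg.dec_loglik(yule31, tips, chain3_space, bg.DECConfig(),
                          bg.DECParams(0.1, 0.1))


class TestAncestralRanges:
    def test_frozen_history_certain(self, chain3_space):
        tree = sd.simulate_yule_tree(n_tips=8, lambda0=0.4, seed=4)
        tips = {nm: 0b001 for nm in tree.tip_names}
        anc = bg.ancestral_ranges(tree, tips, chain3_space, bg.DECConfig(),
                                  bg.DECParams(1e-9, 1e-9))
        iA = chain3_space.index[0b001]
        for vec in anc.values():
            assert vec[iA] == pytest.approx(1.0, abs=1e-6)

    def test_matches_clamped_enumeration(self, chain3_space):
        # marginal at a node == enumeration likelihood with that node
        # clamped, normalized over clamp states
        tree = sd.simulate_yule_tree(n_tips=3, lambda0=0.5, seed=6)
        tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.3, 0.1, seed=8)
        p = bg.DECParams(0.2, 0.07)
        anc = bg.ancestral_ranges(tree, tips, chain3_space, bg.DECConfig(), p)
        for node in anc:
            liks = []
            for R in chain3_space.ranges:
                liks.append(0.0 if R == 0 else
                            _clamped_lik(tree, tips, chain3_space, p, node, R))
            liks = np.array(liks)
            np.testing.assert_allclose(anc[node], liks / liks.sum(), atol=1e-8)

    def test_probabilities_normalized(self, chain3_space):
        tree = sd.simulate_yule_tree(n_tips=10, lambda0=0.3, seed=5)
        tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.2, 0.05, seed=6)
        anc = bg.ancestral_ranges(tree, tips, chain3_space, bg.DECConfig(),
                                  bg.DECParams(0.2, 0.05))
        for vec in anc.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-8)
            assert vec[0] == 0.0


def _clamped_lik(tree, tips, space, params, node, clamp_R):
    Q = bg.build_Q(space, params.d, params.e, x=params.x)
    ages = tree.node_ages()
    Ps = {v: expm(Q * (ages[tree.parent[v]] - max(ages[v], 0)))
          for v in range(tree.n_nodes) if v != tree.root}
    wt = bg.cladogenesis_weights(space, "DEC")

    def L(v, R):
        if v < tree.n_tips:
            return 1.0 if R == tips[tree.tip_names[v]] else 0.0
        if R == 0 or (v == node and R != clamp_R):
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

    return sum(L(tree.root, R) for R in space.ranges[1:]) / (space.n_states - 1)


class TestFitAndHypotheses:
    def test_frozen_data_hits_lower_boundary(self, chain3_space):
        tree = sd.simulate_yule_tree(n_tips=10, lambda0=0.3, seed=2)
        tips = {nm: 0b010 for nm in tree.tip_names}
        params, info = bg.fit_dec(tree, tips, chain3_space, bg.DECConfig(),
                                  n_starts=1, seed=0)
        assert params.d < 1e-4 and params.e < 1e-4
        assert info["converged"]

    def test_identical_hypotheses_tie(self, chain3_space):
        tree = sd.simulate_yule_tree(n_tips=8, lambda0=0.3, seed=3)
        tips, _ = sd.simulate_dec_history(tree, chain3_space, 0.2, 0.05, seed=4)
        cfgs = {"H1": bg.DECConfig(), "H2": bg.DECConfig()}
        df = bg.compare_hypotheses(tree, tips, chain3_space, cfgs,
                                   models=("DEC",), seed=0, n_starts=1)
        assert df["LnL"].iloc[0] == pytest.approx(df["LnL"].iloc[1], abs=1e-10)
        assert df["dAIC"].max() == pytest.approx(0.0, abs=1e-10)

    def test_default_hypothesis_parameter_counts(self):
        hyp = bg.build_hypotheses()
        assert set(hyp) == {f"Ho{i}" for i in range(1, 9)}
        assert not hyp["Ho1"].use_distance and hyp["Ho1"].multipliers is None
        assert hyp["Ho2"].use_distance
        assert hyp["Ho7"].multipliers is not None

    def test_range_table_roundtrip(self, tmp_path, chain3_space):
        path = tmp_path / "ranges.tsv"
        sd.write_range_table({"T1": 0b011, "T2": 0b100}, ("A", "B", "C"), path)
        back = bg.read_range_table(path)
        assert back == {"T1": 0b011, "T2": 0b100}
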