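import itertools

import numpy as np
import pytest

from bristlephylo import synthdata
from bristlephylo.mk import QMatrix, transition_probability
from bristlephylo.simmap import (
    CharacterMap, _NodeSampler, density_map, density_map_newick,
    run_simmap, sample_branch_history, sample_branch_history_rejection,
    sample_node_states, summarize_maps,
)
from bristlephylo.treeio import parse_tree


def enumerate_node_marginals(tree, states, Q, pi=None):
    """Brute-force marginal node-state probabilities by summing the joint
    probability over every assignment of states to internal nodes."""
    qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, float)
    k = qm.shape[0]
    arr = tree.arrays()
    pi = np.full(k, 1 / k) if pi is None else np.asarray(pi)
    internal = [i for i in range(arr.n_nodes) if arr.children[i]]
    tips = {i: states[lab] for lab, i in arr.tip_index.items()}
    P = {i: transition_probability(qm, arr.edge_length[i])
         for i in range(arr.n_nodes) if arr.parent[i] >= 0}
    marg = np.zeros((arr.n_nodes, k))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        node_state = dict(zip(internal, assign))
        node_state.update(tips)
        prob = pi[node_state[arr.root]]
        for i in range(arr.n_nodes):
            p = arr.parent[i]
            if p >= 0:
                prob *= P[i][node_state[p], node_state[i]]
        total += prob
        for i in range(arr.n_nodes):
            marg[i, node_state[i]] += prob
    return marg / total


class TestNodeStateSampling:
    def test_zero_rate_propagates_root_state(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        q = QMatrix.from_params("ER", 2, [1e-9])
        ns = sample_node_states(tree, {"A": 0, "B": 0, "C": 0}, q, seed=0)
        assert set(ns.values()) == {0}

    def test_symmetric_two_tip_root_is_fair_coin(self, cherry, er_q):
        rng = np.random.default_rng(0)
        sampler = _NodeSampler(cherry, {"A": 0, "B": 1}, er_q)
        root = cherry.arrays().root
        draws = np.array([sampler.draw(rng)[root] for _ in range(10_000)])
        assert abs((draws == 0).mean() - 0.5) < 0.015

    def test_matches_enumeration_on_asymmetric_three_tip(self, er_q):
        tree = parse_tree("((A:0.3,B:1.1):0.9,C:2.0);")
        states = {"A": 0, "B": 1, "C": 1}
        exact = enumerate_node_marginals(tree, states, er_q)
        rng = np.random.default_rng(1)
        sampler = _NodeSampler(tree, states, er_q)
        n = 10_000
        counts = np.zeros_like(exact)
        for _ in range(n):
            s = sampler.draw(rng)
            counts[np.arange(len(s)), s] += 1
        freq = counts / n
        arr = tree.arrays()
        for i in range(arr.n_nodes):
            if arr.children[i]:
                sigma = np.sqrt(exact[i, 1] * (1 - exact[i, 1]) / n)
                assert abs(freq[i, 1] - exact[i, 1]) < 3 * max(sigma, 1e-4)


class TestBranchHistory:
    def test_no_rate_single_segment(self):
        q0 = QMatrix.from_params("ER", 2, [0.0])
        assert sample_branch_history(0, 0, 2.5, q0, seed=0) == [(0, 2.5)]

    def test_impossible_endpoints_rejected(self):
        q0 = QMatrix.from_params("ER", 2, [0.0])
        with pytest.raises(ValueError):
            sample_branch_history(0, 1, 1.0, q0, seed=0)

    def test_differing_endpoints_odd_change_count(self, er_q):
        rng = np.random.default_rng(2)
        for _ in range(300):
            segs = sample_branch_history(0, 1, 0.8, er_q, seed=rng)
            assert (len(segs) - 1) % 2 == 1
            assert segs[0][0] == 0 and segs[-1][0] == 1
            assert abs(sum(d for _, d in segs) - 0.8) < 1e-9

    def test_uniformization_agrees_with_rejection_oracle(self):
        q = QMatrix.from_params("ER", 2, [1.0])
        rng_u = np.random.default_rng(3)
        rng_r = np.random.default_rng(4)
        n = 20_000
        nu = np.array([len(sample_branch_history(0, 0, 1.0, q, seed=rng_u)) - 1
                       for _ in range(n)], dtype=float)
        nr = np.array([len(sample_branch_history_rejection(0, 0, 1.0, q, seed=rng_r)) - 1
                       for _ in range(n)], dtype=float)
        se = np.sqrt(nu.var() / n + nr.var() / n)
        assert abs(nu.mean() - nr.mean()) < 3 * se

    def test_asymmetric_rates_three_states(self):
        q = QMatrix.from_params("ARD", 3, [0.5, 0.1, 0.3, 0.2, 0.6, 0.4])
        rng = np.random.default_rng(5)
        for a, b in [(0, 2), (1, 1), (2, 0)]:
            segs = sample_branch_history(a, b, 1.5, q, seed=rng)
            assert segs[0][0] == a and segs[-1][0] == b
            assert abs(sum(d for _, d in segs) - 1.5) < 1e-9


class TestRunSimmap:
    def test_single_map_obeys_invariants(self, three_tip, er_q):
        maps = run_simmap(three_tip, {"A": 0, "B": 1, "C": 0}, nsim=1, seed=0,
                          Q=er_q)
        assert len(maps) == 1
        maps[0].validate()

    def test_identical_tips_small_rate_no_changes(self):
        tree = synthdata.simulate_tree(20, seed=6, root_age_myr=1.0)
        labels = tree.tip_labels
        states = {lab: 0 for lab in labels}
        states[labels[0]] = 1  # one discordant tip keeps rates identifiable
        q = QMatrix.from_params("ER", 2, [1e-4])
        maps = run_simmap(tree, states, nsim=50, seed=1, Q=q)
        s = summarize_maps(maps)
        assert s.mean_changes <= 2.0

    def test_seed_reproducibility(self, three_tip, er_q):
        a = run_simmap(three_tip, {"A": 0, "B": 1, "C": 0}, nsim=20, seed=7,
                       Q=er_q)
        b = run_simmap(three_tip, {"A": 0, "B": 1, "C": 0}, nsim=20, seed=7,
                       Q=er_q)
        assert all((x.node_state == y.node_state).all() and
                   x.segments == y.segments for x, y in zip(a, b))

    def test_inferred_changes_near_generating_expectation(self):
        tree = synthdata.simulate_tree(150, seed=8, root_age_myr=1.0)
        q = QMatrix.from_params("ER", 2, [0.8])
        # expectation of the generating process: rate x total tree length
        truth_counts = [synthdata.simulate_binary_trait(tree, q, seed=s)[1].n_changes()
                        for s in range(200)]
        states, _ = synthdata.simulate_binary_trait(tree, q, seed=999)
        maps = run_simmap(tree, states, nsim=200, seed=9, Q=q)
        s = summarize_maps(maps)
        expected = np.mean(truth_counts)
        sd = np.std(truth_counts)
        assert abs(s.mean_changes - expected) < 3 * sd


class TestSummaries:
    def _map_by_hand(self):
        tree = parse_tree("(A:2,B:8);")
        arr = tree.arrays()
        node_state = np.zeros(arr.n_nodes, dtype=int)
        segments = [[] for _ in range(arr.n_nodes)]
        ia, ib = arr.tip_index["A"], arr.tip_index["B"]
        node_state[ia] = 1
        segments[ia] = [(0, 1.5), (1, 0.5)]
        segments[ib] = [(0, 8.0)]
        return CharacterMap(tree=tree, node_state=node_state,
                            segments=segments)

    def test_time_fraction_arithmetic(self):
        s = summarize_maps([self._map_by_hand()])
        assert s.time_fraction[0] == pytest.approx(0.95)
        assert s.mean_changes == 1 and s.mean_gains == 1 and s.mean_losses == 0

    def test_gains_plus_losses_partition(self, three_tip, er_q):
        maps = run_simmap(three_tip, {"A": 0, "B": 1, "C": 1}, nsim=100,
                          seed=3, Q=er_q)
        for m in maps:
            d = m.changes_by_direction()
            assert d.sum() == m.n_changes()
        s = summarize_maps(maps)
        assert s.mean_gains + s.mean_losses == pytest.approx(s.mean_changes)

    def test_unanimous_root_confidence(self):
        m = self._map_by_hand()
        s = summarize_maps([m, m, m])
        assert s.root_confidence == 1.0 and s.root_state_label == "absent"

    def test_mismatched_trees_rejected(self, three_tip, four_tip, er_q):
        m1 = run_simmap(three_tip, {"A": 0, "B": 1, "C": 0}, nsim=1, seed=0,
                        Q=er_q)
        m2 = run_simmap(four_tip, {"A": 0, "B": 1, "C": 0, "D": 1}, nsim=1,
                        seed=0, Q=er_q)
        with pytest.raises(ValueError):
            summarize_maps(m1 + m2)


class TestDensityMap:
    def test_identical_maps_give_binary_bins(self):
        m = TestSummaries()._map_by_hand()
        dm = density_map([m, m], bins_per_edge=8)
        assert set(dm["prob"]).issubset({0.0, 1.0})

    def test_probabilities_bounded(self, three_tip, er_q):
        maps = run_simmap(three_tip, {"A": 0, "B": 1, "C": 1}, nsim=50,
                          seed=4, Q=er_q)
        dm = density_map(maps, bins_per_edge=20)
        assert dm["prob"].between(0, 1).all()

    def test_bin_average_consistent_with_dwell_fraction(self, three_tip, er_q):
        maps = run_simmap(three_tip, {"A": 0, "B": 1, "C": 1}, nsim=400,
                          seed=5, Q=er_q)
        dm = density_map(maps, bins_per_edge=200)
        arr = three_tip.arrays()
        for i, p, length in arr.edges():
            dwell = np.mean([sum(d for s, d in m.segments[i] if s == 1) / length
                             for m in maps])
            bin_avg = dm[dm["node"] == i]["prob"].mean()
            assert abs(bin_avg - dwell) < 0.02

    def test_annotated_newick_contains_tags(self, three_tip, er_q):
        maps = run_simmap(three_tip, {"A": 0, "B": 1, "C": 1}, nsim=10,
                          seed=6, Q=er_q)
        nwk = density_map_newick(maps)
        assert "state_prob=" in nwk
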