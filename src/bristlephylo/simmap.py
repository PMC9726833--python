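"""Stochastic character mapping.

Samples complete character histories (the state at every point along every
branch) conditional on observed tip states and a rate matrix, and summarises
a sample of such maps: counts of changes split by direction (gain = absent
to present, loss = present to absent), time spent in each state, per-node
posterior state probabilities and the confidence in the reconstructed root
state.  Endpoint-conditioned branch histories are drawn exactly by
uniformization; a naive rejection sampler is kept as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mk import QMatrix, MkFit, _edge_P, _pruning_partials, _resolve_pi, \
    _state_vectors, fit_mk, transition_probability
from .treeio import Phylogeny

__all__ = [
    "CharacterMap",
    "MapSummary",
    "sample_node_states",
    "sample_branch_history",
    "sample_branch_history_rejection",
    "run_simmap",
    "summarize_maps",
    "density_map",
    "density_map_newick",
]


@dataclass
class CharacterMap:
    """One sampled full character history on a tree.

    ``segments[i]`` is the ordered list of ``(state, dwell_time)`` pairs
    along the edge above node ``i`` (parent end first); dwell times sum to
    the edge length and consecutive segments differ in state.  ``node_state``
    holds the sampled state at every node.
    """

    tree: Phylogeny
    node_state: np.ndarray
    segments: list
    seed: int | None = None

    def n_changes(self) -> int:
        return sum(len(s) - 1 for s in self.segments if s)

    def changes_by_direction(self, k: int = 2) -> np.ndarray:
        """counts[a, b] = number of a -> b transitions over the whole tree."""
        counts = np.zeros((k, k), dtype=int)
        for segs in self.segments:
            for (a, _), (b, _) in zip(segs, segs[1:]):
                counts[a, b] += 1
        return counts

    def time_in_state(self, k: int = 2) -> np.ndarray:
        tot = np.zeros(k)
        for segs in self.segments:
            for s, dt in segs:
                tot[s] += dt
        return tot

    def validate(self, atol: float = 1e-9) -> None:
        arr = self.tree.arrays()
        for i, p, length in arr.edges():
            segs = self.segments[i]
            if abs(sum(dt for _, dt in segs) - length) > max(atol, atol * length):
                raise AssertionError(f"segment dwell times != edge length at node {i}")
            if any(dt <= 0 for _, dt in segs if length > 0):
                raise AssertionError("non-positive dwell time")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise AssertionError("consecutive segments share a state")
            if segs[0][0] != self.node_state[p]:
                raise AssertionError("first segment state != parent node state")
            if segs[-1][0] != self.node_state[i]:
                raise AssertionError("last segment state != child node state")


# ----------------------------------------------------------------------
# node-state sampling

class _NodeSampler:
    """Reusable conditional node-state sampler for one (tree, data, Q)."""

    def __init__(self, tree: Phylogeny, states: dict, Q: QMatrix | np.ndarray,
                 pi="equal"):
        qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, float)
        self.k = qm.shape[0]
        self.tree = tree
        self.arr = tree.arrays()
        self.Q = qm
        self.L = _state_vectors(self.arr, states, self.k)
        self.P = _edge_P(self.arr, qm)
        self.part, log_scale = _pruning_partials(self.arr, self.L, self.P)
        if not np.isfinite(log_scale):
            raise ValueError("data have zero likelihood under Q")
        self.pi = _resolve_pi(pi, self.k)
        self.preorder = self.arr.postorder[::-1]

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        arr = self.arr
        state = np.empty(arr.n_nodes, dtype=int)
        w = self.pi * self.part[arr.root]
        w = w / w.sum()
        state[arr.root] = rng.choice(self.k, p=w)
        for i in self.preorder:
            for c in arr.children[i]:
                w = self.P[c][state[i]] * self.part[c]
                tot = w.sum()
                if tot <= 0:
                    raise ValueError("zero-probability node state encountered")
                state[c] = rng.choice(self.k, p=w / tot)
        return state


def sample_node_states(tree: Phylogeny, states: dict, Q, pi="equal",
                       seed: int | np.random.Generator = 0) -> dict:
    """Draw one joint sample of node states conditional on the tip data.

    The root is sampled proportionally to prior times partial likelihood,
    then each child is sampled from transition probability times its own
    partial likelihood, top-down.  Returns node index -> state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = _NodeSampler(tree, states, Q, pi)
    s = sampler.draw(rng)
    return {int(i): int(s[i]) for i in range(len(s))}


# ----------------------------------------------------------------------
# endpoint-conditioned branch histories (uniformization)

_MAX_JUMPS = 100_000


def sample_branch_history(a: int, b: int, t: float, Q, seed=0) -> list:
    """Exact endpoint-conditioned history of a CTMC on one branch.

    Uses uniformization: with dominating rate mu = max(-q_ii) the jump count
    N given endpoints (a, b) follows a Poisson mixture weighted by powers of
    R = I + Q/mu; the jump chain is then sampled as a bridge through powers
    of R, jump times are uniform order statistics, and virtual (self) jumps
    are discarded.  Returns ``[(state, dwell), ...]`` summing to ``t``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, float)
    k = qm.shape[0]
    mu = float(np.max(-np.diag(qm)))
    if t < 0:
        raise ValueError("negative branch length")
    if mu == 0.0 or t == 0.0:
        if a != b:
            raise ValueError("endpoints differ but no change is possible")
        return [(int(a), float(t))]
    p_ab = transition_probability(qm, t)[a, b]
    if p_ab <= 0:
        raise ValueError(f"transition {a}->{b} has probability 0 on this branch")
    R = np.eye(k) + qm / mu

    # sample number of uniformized jumps
    u = rng.random() * p_ab
    log_pois = -mu * t  # log Poisson(0)
    Rn_row = np.zeros(k)
    Rn_row[a] = 1.0  # row a of R^0
    acc = np.exp(log_pois) * Rn_row[b]
    n = 0
    rows = [Rn_row]
    while acc < u:
        n += 1
        if n > _MAX_JUMPS:
            raise RuntimeError("uniformization jump count overflow")
        Rn_row = rows[-1] @ R
        rows.append(Rn_row)
        log_pois += np.log(mu * t) - np.log(n)
        acc += np.exp(log_pois) * Rn_row[b]
    if n == 0:
        return [(int(a), float(t))]

    # backward powers R^m for the bridge
    Rpow = [np.eye(k)]
    for _ in range(n):
        Rpow.append(Rpow[-1] @ R)

    # jump chain bridge
    chain = [a]
    for j in range(1, n):
        w = R[chain[-1]] * Rpow[n - j][:, b]
        chain.append(int(rng.choice(k, p=w / w.sum())))
    chain.append(b)

    times = np.sort(rng.random(n)) * t
    segs: list[tuple[int, float]] = []
    cur_state = a
    cur_start = 0.0
    for s_next, tm in zip(chain[1:], times):
        if s_next != cur_state:
            segs.append((int(cur_state), float(tm - cur_start)))
            cur_state = s_next
            cur_start = float(tm)
    segs.append((int(cur_state), float(t - cur_start)))
    return segs


def sample_branch_history_rejection(a: int, b: int, t: float, Q, seed=0,
                                    max_tries: int = 100_000) -> list:
    """Forward-simulation rejection sampler (slow; cross-check oracle)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, float)
    k = qm.shape[0]
    for _ in range(max_tries):
        segs = []
        s, tau = int(a), 0.0
        while True:
            rate = -qm[s, s]
            dt = rng.exponential(1 / rate) if rate > 0 else np.inf
            if tau + dt >= t:
                segs.append((s, t - tau))
                break
            segs.append((s, dt))
            w = np.clip(qm[s], 0, None)
            w[s] = 0
            s = int(rng.choice(k, p=w / w.sum()))
            tau += dt
        if segs[-1][0] == b:
            merged = [list(segs[0])]
            for st, dt in segs[1:]:
                if st == merged[-1][0]:
                    merged[-1][1] += dt
                else:
                    merged.append([st, dt])
            return [(int(st), float(dt)) for st, dt in merged]
    raise RuntimeError("rejection sampler failed to hit the endpoint")


# ----------------------------------------------------------------------
# full maps

def run_simmap(tree: Phylogeny, states: dict, model: str = "ER",
               nsim: int = 10_000, seed: int = 0, pi="equal",
               Q: QMatrix | None = None, fit: MkFit | None = None) -> list:
    """Draw ``nsim`` stochastic character maps.

    The rate matrix is fixed at its ML estimate under ``model`` (empirical
    approach) unless ``Q`` or a prior ``fit`` is supplied.  Reproducible
    given ``seed``.
    """
    if Q is None:
        if fit is None:
            fit = fit_mk(tree, states, model=model, pi=pi, seed=seed)
        Q = fit.Q
    rng = np.random.default_rng(seed)
    sampler = _NodeSampler(tree, states, Q, pi)
    arr = tree.arrays()
    maps: list[CharacterMap] = []
    for _ in range(nsim):
        ns = sampler.draw(rng)
        segments: list[list] = [[] for _ in range(arr.n_nodes)]
        for i, p, length in arr.edges():
            segs = sample_branch_history(int(ns[p]), int(ns[i]), length,
                                         Q, seed=rng)
            # store parent-end first
            segments[i] = segs
        maps.append(CharacterMap(tree=tree, node_state=ns, segments=segments,
                                 seed=seed))
    return maps


@dataclass
class MapSummary:
    """Means over a sample of character maps (2-state presence character)."""

    n_maps: int
    mean_changes: float
    mean_gains: float
    mean_losses: float
    time_fraction: dict            # state -> mean fraction of total tree time
    node_posterior: np.ndarray     # (n_nodes, k) frequencies
    root_state: int
    root_confidence: float
    state_labels: tuple = ("absent", "present")

    @property
    def root_state_label(self) -> str:
        return self.state_labels[self.root_state]

    def as_dict(self) -> dict:
        return {
            "n_maps": self.n_maps,
            "mean_changes": self.mean_changes,
            "mean_gains": self.mean_gains,
            "mean_losses": self.mean_losses,
            "time_fraction": {self.state_labels[s]: v
                              for s, v in self.time_fraction.items()},
            "root_state": self.root_state_label,
            "root_confidence": self.root_confidence,
        }


def summarize_maps(maps: list, k: int = 2) -> MapSummary:
    """Summarize maps: change counts, dwell fractions, node posteriors.

    Gains are 0 -> 1 transitions on the presence coding; the root confidence
    is the fraction of maps reconstructing the modal root state.
    """
    if not maps:
        raise ValueError("no maps to summarize")
    tree0 = maps[0].tree
    arr = tree0.arrays()
    if any(m.tree.arrays() is not arr and m.tree.tip_labels != tree0.tip_labels
           for m in maps):
        raise ValueError("maps were drawn on different trees")
    n = len(maps)
    changes = np.zeros(n)
    gains = np.zeros(n)
    losses = np.zeros(n)
    timefrac = np.zeros((n, k))
    node_counts = np.zeros((arr.n_nodes, k))
    root = arr.root
    root_counts = np.zeros(k)
    for j, m in enumerate(maps):
        d = m.changes_by_direction(k)
        changes[j] = d.sum()
        gains[j] = d[0, 1] if k >= 2 else 0
        losses[j] = d[1, 0] if k >= 2 else 0
        tis = m.time_in_state(k)
        timefrac[j] = tis / tis.sum()
        node_counts[np.arange(arr.n_nodes), m.node_state] += 1
        root_counts[m.node_state[root]] += 1
    root_state = int(np.argmax(root_counts))
    return MapSummary(
        n_maps=n,
        mean_changes=float(changes.mean()),
        mean_gains=float(gains.mean()),
        mean_losses=float(losses.mean()),
        time_fraction={s: float(timefrac[:, s].mean()) for s in range(k)},
        node_posterior=node_counts / n,
        root_state=root_state,
        root_confidence=float(root_counts[root_state] / n),
    )


# ----------------------------------------------------------------------
# density map

def density_map(maps: list, bins_per_edge: int = 100, state: int = 1) -> pd.DataFrame:
    """Time-resolved posterior probability of ``state`` along every edge.

    Each edge is split into equal bins; the value at a bin midpoint is the
    fraction of maps occupying ``state`` there.  Returns a long table with
    columns (node, bin, midpoint_time, prob).
    """
    if not maps:
        raise ValueError("no maps")
    arr = maps[0].tree.arrays()
    rows = []
    n = len(maps)
    for i, p, length in arr.edges():
        mids = (np.arange(bins_per_edge) + 0.5) / bins_per_edge * length
        hits = np.zeros(bins_per_edge)
        for m in maps:
            segs = m.segments[i]
            bounds = np.cumsum([dt for _, dt in segs])
            sts = np.array([s for s, _ in segs])
            idx = np.searchsorted(bounds, mids, side="left")
            idx = np.clip(idx, 0, len(sts) - 1)
            hits += (sts[idx] == state)
        prob = hits / n
        for bnum, (mid, pr) in enumerate(zip(mids, prob)):
            rows.append({"node": i, "bin": bnum, "midpoint_time": float(mid),
                         "prob": float(pr)})
    return pd.DataFrame(rows)


def density_map_newick(maps: list, state: int = 1) -> str:
    """Newick with per-edge mean occupancy of ``state`` as a comment tag."""
    if not maps:
        raise ValueError("no maps")
    tree = maps[0].tree
    arr = tree.arrays()
    n = len(maps)
    mean_occ = np.zeros(arr.n_nodes)
    for i, p, length in arr.edges():
        if length <= 0:
            continue
        tot = 0.0
        for m in maps:
            tot += sum(dt for s, dt in m.segments[i] if s == state)
        mean_occ[i] = tot / (n * length)

    t = tree.as_dendropy().clone(depth=1)
    nodes = list(t.postorder_node_iter())
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            nd.edge.annotations.add_new("state_prob", f"{mean_occ[i]:.6f}")
    return t.as_string(schema="newick", suppress_rooting=True,
                       suppress_annotations=False).strip()
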