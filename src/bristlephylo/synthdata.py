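"""Synthetic data with recorded ground truth.

Everything the pipeline consumes can be generated here with known truth:
time-calibrated ultrametric trees (Yule or birth-death, scaled to a 108-Myr
root age like a typical crown-bird phylogeny), pseudo-posterior tree sets
(topology moves plus branch-length jitter), binary traits evolved forward
under a 2-state Markov process with optional lambda attenuation, and
specimen-level ecological datasets from a phylogenetic animal model
(categorical fixed effects, phylogenetic and individual random effects,
liability-threshold presence and near-always-positive lengths).
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .mk import QMatrix
from .simmap import CharacterMap
from .treeio import Phylogeny, TreeSet, force_ultrametric, phylo_correlation, \
    root_age

__all__ = [
    "SimulationTruth",
    "simulate_tree",
    "simulate_tree_posterior",
    "simulate_binary_trait",
    "simulate_ecological_dataset",
    "DEFAULT_ROOT_AGE",
]

#: default crown age (Myr) of simulated trees — the scale of the crown-bird
#: phylogeny the pipeline targets
DEFAULT_ROOT_AGE = 108.0


@dataclass
class SimulationTruth:
    """Ground truth attached to a synthetic dataset."""

    seed: int
    q_true: list | None = None
    lambda_true: float | None = None
    root_state: int | None = None
    n_true_changes: int | None = None
    beta: dict | None = None
    var_phylo: float | None = None
    var_individual: float | None = None
    var_residual: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        return cls(**json.loads(text))


def simulate_tree(n_tips: int, model: str = "yule", seed: int = 0,
                  birth_rate: float = 1.0, death_rate: float = 0.5,
                  root_age_myr: float = DEFAULT_ROOT_AGE) -> Phylogeny:
    """Simulate an ultrametric tree and rescale it to ``root_age_myr``.

    ``model="yule"`` is a pure-birth process; ``"birth-death"`` uses the
    given birth and death rates (conditioned on ``n_tips`` extant tips,
    extinct lineages pruned).
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if model == "yule":
        b, d = birth_rate, 0.0
    elif model in ("birth-death", "birth_death", "bd"):
        b, d = birth_rate, death_rate
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = _pyrandom.Random(int(seed))
    t = treesim.birth_death_tree(
        birth_rate=b, death_rate=d, num_extant_tips=n_tips, rng=rng,
        is_retain_extinct_tips=False)
    for i, leaf in enumerate(t.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
    t.seed_node.edge.length = None
    ph = Phylogeny(t)
    if not ph.is_ultrametric(rtol=1e-6):
        ph = force_ultrametric(ph)
    age = root_age(ph)
    if age > 0:
        scale = root_age_myr / age
        t = ph.as_dendropy()
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
        ph = Phylogeny(t)
    return ph


def _nni_once(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange around a random internal edge."""
    internal = [e for e in tree.preorder_edge_iter()
                if e.head_node is not None and not e.head_node.is_leaf()
                and e.tail_node is not None and e.tail_node.parent_node is not None
                or (e.tail_node is tree.seed_node and e.head_node is not None
                    and not e.head_node.is_leaf())]
    internal = [e for e in internal if e.tail_node is not None]
    if not internal:
        return
    edge = internal[rng.integers(len(internal))]
    child, parent = edge.head_node, edge.tail_node
    siblings = [c for c in parent.child_nodes() if c is not child]
    grandkids = child.child_nodes()
    if not siblings or len(grandkids) < 2:
        return
    s = siblings[rng.integers(len(siblings))]
    g = grandkids[rng.integers(len(grandkids))]
    sl, gl = s.edge.length, g.edge.length
    parent.remove_child(s)
    child.remove_child(g)
    parent.add_child(g)
    child.add_child(s)
    s.edge.length, g.edge.length = sl, gl


def simulate_tree_posterior(tree: Phylogeny, n: int = 100,
                            topology_moves: float = 2.0,
                            length_jitter_sd: float = 0.05,
                            seed: int = 0) -> TreeSet:
    """A pseudo-posterior: NNI-perturbed, length-jittered, re-ultrametrized
    replicates of ``tree`` (Poisson(topology_moves) interchanges each,
    log-normal multiplicative edge jitter)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = tree.as_dendropy().clone(depth=1)
        for _ in range(rng.poisson(topology_moves)):
            _nni_once(t, rng)
        if length_jitter_sd > 0:
            for e in t.preorder_edge_iter():
                if e.length is not None and e.length > 0:
                    e.length *= float(np.exp(rng.normal(0, length_jitter_sd)))
        ph = Phylogeny(t)
        if topology_moves > 0 or length_jitter_sd > 0:
            ph = force_ultrametric(ph)
        out.append(ph)
    return TreeSet(out, provenance="synthetic")


def simulate_binary_trait(tree: Phylogeny, Q: QMatrix | np.ndarray,
                          lam: float = 1.0, root_state: int = 0,
                          seed: int = 0):
    """Forward-simulate a binary trait; returns (tip states, true history).

    The character evolves on the lambda-transformed tree; the recorded true
    history is expressed on the original edges (dwell times rescaled to the
    untransformed edge lengths, so bookkeeping sums still close).
    """
    from .mk import lambda_transform
    qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, float)
    k = qm.shape[0]
    rng = np.random.default_rng(seed)
    sim_tree = lambda_transform(tree, lam) if lam != 1.0 else tree
    arr_sim = sim_tree.arrays()
    arr_orig = tree.arrays()
    # postorder node numbering of a clone matches the original's traversal
    node_state = np.empty(arr_sim.n_nodes, dtype=int)
    node_state[arr_sim.root] = root_state
    segments: list[list] = [[] for _ in range(arr_sim.n_nodes)]
    for i in arr_sim.postorder[::-1]:
        p = arr_sim.parent[i]
        if p < 0:
            continue
        t_edge = float(arr_sim.edge_length[i])
        s, tau = int(node_state[p]), 0.0
        segs = []
        while True:
            rate = -qm[s, s]
            dt = rng.exponential(1 / rate) if rate > 0 else np.inf
            if tau + dt >= t_edge:
                segs.append([s, t_edge - tau])
                break
            segs.append([s, dt])
            w = np.clip(qm[s], 0, None)
            w[s] = 0
            s = int(rng.choice(k, p=w / w.sum()))
            tau += dt
        node_state[i] = segs[-1][0]
        # express dwell times on the original (untransformed) edge
        orig_len = float(arr_orig.edge_length[i])
        scale = orig_len / t_edge if t_edge > 0 else 0.0
        segments[i] = [(int(st), float(dt * scale)) for st, dt in segs]
    states = {lab: int(node_state[j]) for lab, j in arr_sim.tip_index.items()}
    truth = CharacterMap(tree=tree, node_state=node_state, segments=segments,
                         seed=seed)
    return states, truth


def simulate_ecological_dataset(
        tree: Phylogeny,
        effects: dict | None = None,
        var_phylo: float = 1.0,
        var_individual: float = 0.25,
        var_residual: float = 0.5,
        intercept_liability: float = -0.4,
        intercept_length: float = 12.0,
        specimens_per_species: int = 2,
        n_families: int = 20,
        family_fraction_range: tuple = (0.1, 1.0),
        seed: int = 0):
    """Specimen table from a phylogenetic animal model, with truth record.

    ``effects`` maps factor name -> {level: effect size}; the level mapped
    to 0 (or the vocabulary's reference) is the baseline.  Each species gets
    iid categorical ecology, a phylogenetic effect drawn from
    N(0, var_phylo * C) with C the tree correlation, and each specimen an
    individual effect and residual.  Presence is liability > 0; length is
    the Gaussian response shifted by ``intercept_length`` and floored at 0
    (the floor almost never binds at the default scale).  Families are
    assigned in contiguous blocks with heterogeneous nominal sampling
    fractions for the sensitivity analyses.
    """
    from .traitdata import load_vocab
    rng = np.random.default_rng(seed)
    vocab = load_vocab()
    if effects is None:
        effects = {
            "activity_period": {"Obligate nocturnal": 1.5},
            "habitat_type": {"Closed": 0.5},
            "foraging_height": {},
            "foraging_method": {},
            "diet": {},
        }
    labels = tree.tip_labels
    m = len(labels)
    C = phylo_correlation(tree).loc[labels, labels].to_numpy()
    a = np.linalg.cholesky(C + 1e-10 * np.eye(m)) @ rng.standard_normal(m)
    a *= np.sqrt(var_phylo)

    # categorical ecology, reference level most common
    refs = vocab["reference_levels"]
    factor_levels = {
        "activity_period": vocab["activity_period"],
        "habitat_type": vocab["habitat_type"],
        "foraging_method": vocab["foraging_method"],
        "foraging_height": vocab["foraging_height"],
        "diet": vocab["diet"],
    }
    species_cats: dict[str, dict] = {}
    for f, levels in factor_levels.items():
        probs = np.full(len(levels), 0.5 / max(len(levels) - 1, 1))
        probs[levels.index(refs[f])] = 0.5
        draws = rng.choice(len(levels), size=m, p=probs / probs.sum())
        for sp, d in zip(labels, draws):
            species_cats.setdefault(sp, {})[f] = levels[int(d)]

    # family blocks with heterogeneous nominal sampling fractions
    fam_names = [f"fam{j:03d}" for j in range(n_families)]
    fam_of = {sp: fam_names[int(j * n_families / m)]
              for j, sp in enumerate(labels)}
    lo, hi = family_fraction_range
    fam_fraction = {f: float(rng.uniform(lo, hi)) for f in fam_names}
    sampled = pd.Series(fam_of).value_counts().to_dict()
    fam_known = {f: max(int(round(sampled.get(f, 1) / fam_fraction[f])), sampled.get(f, 1))
                 for f in fam_names}

    rows = []
    ind = 0
    for si, sp in enumerate(labels):
        fixed = 0.0
        for f, eff in effects.items():
            fixed += eff.get(species_cats[sp][f], 0.0)
        for _ in range(specimens_per_species):
            u = rng.normal(0, np.sqrt(var_individual))
            e = rng.normal(0, np.sqrt(var_residual))
            liab = intercept_liability + fixed + a[si] + u + e
            length = max(intercept_length + fixed + a[si] + u + e, 0.0)
            rows.append({
                "species": sp, "individual": f"ind{ind:05d}",
                "family": fam_of[sp],
                "liability": liab,
                "presence": int(liab > 0),
                "length": length,
                **species_cats[sp],
            })
            ind += 1
    data = pd.DataFrame(rows)
    beta = {f"{f}:{lvl}": v for f, eff in effects.items()
            for lvl, v in eff.items()}
    truth = SimulationTruth(
        seed=seed, beta=beta, var_phylo=var_phylo,
        var_individual=var_individual, var_residual=var_residual,
        extras={
            "intercept_liability": intercept_liability,
            "intercept_length": intercept_length,
            "family_fraction": fam_fraction,
            "family_known": fam_known,
        })
    return data, truth
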