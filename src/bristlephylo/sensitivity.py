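"""Robustness of the ancestral-state reconstruction.

Two procedures: (1) family-weighted taxonomic downsampling — species are
removed preferentially from families whose sampling fraction (species in the
dataset / species known in the family) is high, the tree is pruned, and the
stochastic-mapping summary is recomputed at 90/80/70% of the species; and
(2) tree-topology uncertainty — the mapping is repeated over trees drawn
from a posterior (or pseudo-posterior) set, pooling all maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mk import MkFit, fit_mk
from .simmap import run_simmap, summarize_maps, MapSummary
from .treeio import Phylogeny, TreeSet, prune_to_taxa

__all__ = [
    "FamilySamplingTable",
    "SensitivityReport",
    "family_fractions",
    "weighted_downsample",
    "downsample_analysis",
    "tree_uncertainty_analysis",
    "reports_to_frame",
]


@dataclass
class FamilySamplingTable:
    """Per-family sampling fractions (sampled / known to exist)."""

    table: pd.DataFrame  # columns: family, sampled, known, fraction

    def fraction_for_species(self, species_family: pd.Series) -> pd.Series:
        frac = self.table.set_index("family")["fraction"]
        return species_family.map(frac)


def family_fractions(dataset: pd.DataFrame, richness: dict) -> FamilySamplingTable:
    """Sampling fraction per family from a species table with a 'family'
    column and a family -> known-species-count mapping."""
    if "family" not in dataset.columns or "species" not in dataset.columns:
        raise ValueError("dataset needs 'species' and 'family' columns")
    per_species = dataset.drop_duplicates("species")
    counts = per_species.groupby("family")["species"].nunique()
    missing = sorted(set(counts.index) - set(richness))
    if missing:
        raise ValueError(f"no richness entry for families: {missing}")
    rows = []
    for fam, sampled in counts.items():
        known = richness[fam]
        if known <= 0:
            raise ValueError(f"family {fam!r} has known richness {known}; "
                             "fraction undefined")
        rows.append({"family": fam, "sampled": int(sampled),
                     "known": int(known),
                     "fraction": float(sampled) / float(known)})
    return FamilySamplingTable(pd.DataFrame(rows))


def weighted_downsample(dataset: pd.DataFrame, fractions: FamilySamplingTable,
                        target: float, seed: int = 0) -> list:
    """Retain round(target * N) species, removing species sequentially
    without replacement with probability proportional to their family's
    sampling fraction (overrepresented families are thinned first)."""
    species = dataset.drop_duplicates("species")[["species", "family"]]
    n = len(species)
    n_keep = int(round(target * n))
    if n_keep < 2:
        raise ValueError("target subset would have fewer than two species")
    if n_keep >= n:
        return sorted(species["species"])
    rng = np.random.default_rng(seed)
    weight = fractions.fraction_for_species(
        species.set_index("species")["family"]).to_numpy(dtype=float)
    if np.any(~np.isfinite(weight)):
        bad = species["species"][~np.isfinite(weight)].tolist()
        raise ValueError(f"species with unknown family fraction: {bad}")
    names = species["species"].to_numpy()
    alive = np.ones(n, dtype=bool)
    for _ in range(n - n_keep):
        w = np.where(alive, weight, 0.0)
        w = w / w.sum()
        drop = rng.choice(n, p=w)
        alive[drop] = False
    return sorted(names[alive].tolist())


@dataclass
class SensitivityReport:
    """One Table-shaped row of the sensitivity analysis."""

    label: str
    mean_changes: float
    mean_gains: float
    mean_losses: float
    time_absent: float
    ancestral_state: str
    root_confidence: float
    n_maps: int = 0
    root_confidence_sd: float | None = None

    def as_row(self) -> dict:
        return {
            "analysis": self.label,
            "average_changes": self.mean_changes,
            "gains": self.mean_gains,
            "losses": self.mean_losses,
            "time_absent": self.time_absent,
            "ancestral_state": self.ancestral_state,
            "confidence": self.root_confidence,
        }


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def _summary_to_report(label: str, s: MapSummary) -> SensitivityReport:
    return SensitivityReport(
        label=label,
        mean_changes=s.mean_changes,
        mean_gains=s.mean_gains,
        mean_losses=s.mean_losses,
        time_absent=s.time_fraction.get(0, 0.0),
        ancestral_state=s.root_state_label,
        root_confidence=s.root_confidence,
        n_maps=s.n_maps,
    )


def downsample_analysis(tree: Phylogeny, states: dict, dataset: pd.DataFrame,
                        fractions: FamilySamplingTable,
                        targets=(0.9, 0.8, 0.7), model: str = "ER",
                        reps: int = 10_000, maps_per_rep: int = 1,
                        seed: int = 0, pi="equal",
                        refit_q: bool = True) -> list:
    """Repeat {downsample -> prune -> map -> summarize} per target.

    Each replicate draws a fresh weighted subsample, prunes the tree, and
    draws ``maps_per_rep`` stochastic maps; summaries are aggregated over
    all replicates.  ``refit_q=False`` reuses the full-data ML rates (fast
    mode).  With ``target == 1.0`` this reduces to the full-data analysis.
    """
    rng = np.random.default_rng(seed)
    base_fit = fit_mk(tree, states, model=model, pi=pi, seed=seed)
    out = []
    for target in targets:
        if target >= 1.0:
            maps = run_simmap(tree, states, model=model, pi=pi,
                              nsim=reps * maps_per_rep,
                              seed=int(rng.integers(2**31)), fit=base_fit)
            out.append(_summary_to_report("full dataset", summarize_maps(maps)))
            continue
        changes, gains, losses, t_absent = [], [], [], []
        root_present = []
        for _ in range(reps):
            sub_seed = int(rng.integers(2**31))
            keep = weighted_downsample(dataset, fractions, target, seed=sub_seed)
            sub_tree = prune_to_taxa(tree, keep)
            sub_states = {sp: states[sp] for sp in keep}
            if len(set(sub_states.values())) < 2:
                continue
            fit = None if refit_q else base_fit
            maps = run_simmap(sub_tree, sub_states, model=model, pi=pi,
                              nsim=maps_per_rep, seed=sub_seed, fit=fit)
            s = summarize_maps(maps)
            changes.append(s.mean_changes)
            gains.append(s.mean_gains)
            losses.append(s.mean_losses)
            t_absent.append(s.time_fraction.get(0, 0.0))
            root_present.append(s.node_posterior[sub_tree.arrays().root, 1])
        rp = float(np.mean(root_present))
        state = "present" if rp >= 0.5 else "absent"
        conf = rp if state == "present" else 1.0 - rp
        out.append(SensitivityReport(
            label=f"subset {int(round(target * 100))}%",
            mean_changes=float(np.mean(changes)),
            mean_gains=float(np.mean(gains)),
            mean_losses=float(np.mean(losses)),
            time_absent=float(np.mean(t_absent)),
            ancestral_state=state,
            root_confidence=float(conf),
            n_maps=len(changes) * maps_per_rep,
        ))
    return out


def tree_uncertainty_analysis(trees: TreeSet, states: dict,
                              model: str = "ER", n_trees: int = 100,
                              maps_per_tree: int = 100, seed: int = 0,
                              pi="equal") -> SensitivityReport:
    """Map the character over trees sampled from a posterior set.

    The rate matrix is refit per sampled tree, ``maps_per_tree`` maps are
    drawn on each, and the summary pools everything.
    """
    if len(trees) < n_trees:
        raise ValueError(f"tree set holds {len(trees)} < n_trees={n_trees}")
    tipset = set(trees.tip_labels)
    if set(states) != tipset:
        raise ValueError("tip set of trees does not match the trait data")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(trees), size=n_trees, replace=False)
    changes, gains, losses, t_absent, root_present = [], [], [], [], []
    per_tree_conf = []
    for idx in pick:
        tr = trees[int(idx)]
        maps = run_simmap(tr, states, model=model, pi=pi,
                          nsim=maps_per_tree, seed=int(rng.integers(2**31)))
        s = summarize_maps(maps)
        changes.append(s.mean_changes)
        gains.append(s.mean_gains)
        losses.append(s.mean_losses)
        t_absent.append(s.time_fraction.get(0, 0.0))
        rp = s.node_posterior[tr.arrays().root, 1]
        root_present.append(rp)
        per_tree_conf.append(rp)
    rp = float(np.mean(root_present))
    state = "present" if rp >= 0.5 else "absent"
    conf = rp if state == "present" else 1.0 - rp
    return SensitivityReport(
        label="random trees",
        mean_changes=float(np.mean(changes)),
        mean_gains=float(np.mean(gains)),
        mean_losses=float(np.mean(losses)),
        time_absent=float(np.mean(t_absent)),
        ancestral_state=state,
        root_confidence=float(conf),
        n_maps=n_trees * maps_per_tree,
        root_confidence_sd=float(np.std(per_tree_conf, ddof=1))
        if n_trees > 1 else None,
    )
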