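"""Phylogeny input, repair and interrogation.

Trees are time-calibrated (branch lengths in Myr) rooted phylogenies.  The
class :class:`Phylogeny` wraps a :class:`dendropy.Tree` and adds the
operations the comparative pipeline needs: pruning to the study's taxa,
flooring spurious negative branch lengths, least-squares ultrametric
coercion, root-age extraction and the tip-pair phylogenetic correlation
matrix used by the mixed models.

All operations are non-destructive: they return a new :class:`Phylogeny`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TreeSet",
    "TreeArrays",
    "parse_trees",
    "parse_tree",
    "prune_to_taxa",
    "fix_negative_edges",
    "force_ultrametric",
    "root_age",
    "phylo_correlation",
]

#: relative tolerance within which root-to-tip depths must agree for a tree
#: to count as ultrametric
ULTRAMETRIC_RTOL = 1e-8


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def _canonical_label(label: str) -> str:
    """Normalize a tip label: strip quotes/whitespace, spaces -> underscores."""
    return label.strip().strip("'\"").replace(" ", "_")


@dataclass(frozen=True)
class TreeArrays:
    """Indexed array view of a tree for likelihood and simulation code.

    Nodes are numbered 0..n_nodes-1 in a postorder traversal (tips first
    within their clades, root last).  ``parent[i]`` is -1 for the root.
    """

    parent: np.ndarray          # (n_nodes,) int
    edge_length: np.ndarray     # (n_nodes,) float; 0.0 for the root
    children: tuple             # tuple of tuples of child indices
    postorder: np.ndarray       # node indices, root last
    tip_index: dict             # tip label -> node index
    n_tips: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def edges(self):
        """Iterate (child_index, parent_index, length) over all true edges."""
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                yield i, int(p), float(self.edge_length[i])

    def node_depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.edge_length[i]
        return depth


class Phylogeny:
    """A rooted phylogeny with branch lengths, backed by dendropy."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._arrays: TreeArrays | None = None
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_tree(text, schema="newick")

    def _validate(self) -> None:
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()
                  if lf.taxon is not None]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for lf in self._tree.leaf_node_iter():
            if lf.taxon is None:
                raise TreeError("unlabelled tip in tree")

    # -- accessors ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def as_dendropy(self) -> dendropy.Tree:
        return self._tree

    def arrays(self) -> TreeArrays:
        """Indexed postorder view (cached)."""
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays

    def _build_arrays(self) -> TreeArrays:
        nodes = list(self._tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        elen = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        tip_index: dict[str, int] = {}
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                elen[i] = float(n.edge.length or 0.0)
            if n.is_leaf():
                tip_index[n.taxon.label] = i
        return TreeArrays(
            parent=parent,
            edge_length=elen,
            children=tuple(tuple(c) for c in children),
            postorder=np.arange(len(nodes)),
            tip_index=tip_index,
            n_tips=len(tip_index),
        )

    # -- depths / ultrametry ------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        arr = self.arrays()
        depth = arr.node_depths()
        return {lab: float(depth[i]) for lab, i in arr.tip_index.items()}

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.tip_depths().values()))
        dmax = d.max()
        if dmax == 0:
            return True
        return bool((d.max() - d.min()) <= rtol * dmax)

    def total_edge_length(self) -> float:
        arr = self.arrays()
        return float(arr.edge_length.sum())

    def pairwise_tip_distances(self) -> pd.DataFrame:
        """Patristic distance matrix between all tips."""
        labels = self.tip_labels
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace
                if t.label in set(labels)}
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                out.loc[a, b] = out.loc[b, a] = d
        return out

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


@dataclass
class TreeSet:
    """An ordered collection of phylogenies over one tip set."""

    trees: list
    provenance: str = "posterior sample"

    def __post_init__(self):
        if not self.trees:
            raise TreeError("empty tree set")
        tip0 = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != tip0:
                raise TreeError(f"tree {k} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


# ----------------------------------------------------------------------
# parsing

def _normalize_taxa(tree: dendropy.Tree) -> None:
    for taxon in tree.taxon_namespace:
        taxon.label = _canonical_label(taxon.label)


def parse_trees(text: str, schema: str | None = None,
                provenance: str = "posterior sample") -> TreeSet:
    """Parse one or more trees from Newick or Nexus text.

    ``schema`` may be ``"newick"``, ``"nexus"`` or ``None`` (auto-detect:
    text beginning with ``#NEXUS`` is Nexus).  Quoted and underscore tip
    names are both accepted and normalized to underscores.
    """
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=text, schema=schema,
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"could not parse {schema} input: {exc}") from exc
    if not tl:
        raise TreeError("no trees found in input")
    trees = []
    for t in tl:
        t = t.clone(depth=1)
        t.migrate_taxon_namespace(dendropy.TaxonNamespace())
        _normalize_taxa(t)
        trees.append(Phylogeny(t))
    return TreeSet(trees, provenance=provenance)


def parse_tree(text: str, schema: str | None = None) -> Phylogeny:
    """Parse a single tree; errors if the input holds more than one."""
    ts = parse_trees(text, schema=schema)
    if len(ts) != 1:
        raise TreeError(f"expected one tree, found {len(ts)}")
    return ts[0]


# ----------------------------------------------------------------------
# repair and transforms

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune the tree to ``keep`` tips, conserving root-to-tip path lengths.

    Unary internal nodes left behind by pruning are suppressed with their
    incident edge lengths summed, so pairwise tip distances are unchanged.
    """
    keep = {_canonical_label(k) for k in keep}
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise TreeError("need at least two taxa to keep")
    t = tree.as_dendropy().clone(depth=1)
    # dendropy sums edge lengths while suppressing the unary nodes pruning
    # leaves behind, so pairwise tip path lengths are conserved; when the new
    # root is the MRCA of a proper subset, the stem is kept as the root edge.
    t.retain_taxa_with_labels(sorted(keep))
    return Phylogeny(t)


def fix_negative_edges(tree: Phylogeny, floor: float = 1e-6) -> Phylogeny:
    """Set strictly negative edge lengths to ``floor``; leave others alone.

    Negative edges arise in time-calibrated consensus trees summarised over
    a posterior; a small positive floor keeps likelihood code valid.
    """
    t = tree.as_dendropy().clone(depth=1)
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = floor
    return Phylogeny(t)


def force_ultrametric(tree: Phylogeny, method: str = "nnls") -> Phylogeny:
    """Coerce a tree to be ultrametric.

    ``method="nnls"`` (default) finds edge lengths minimizing the sum of
    squared deviations from the input lengths subject to all tips lying at
    an equal depth and non-negativity.  The problem is solved in node-height
    coordinates (tips at height 0), where equal tip depth is automatic; a
    constrained refinement runs only if the unconstrained least-squares
    solution implies a negative edge.

    ``method="extend"`` simply lengthens each tip edge to the maximum tip
    depth (fast, but distorts tip edges more).
    """
    arr = tree.arrays()
    if np.any(arr.edge_length < 0):
        raise TreeError("negative edge lengths; run fix_negative_edges first")
    t = tree.as_dendropy().clone(depth=1)

    if method == "extend":
        ph = Phylogeny(t)
        depths = ph.tip_depths()
        dmax = max(depths.values())
        for lf in t.leaf_node_iter():
            lf.edge.length = (lf.edge.length or 0.0) + (dmax - depths[lf.taxon.label])
        return Phylogeny(t)
    if method != "nnls":
        raise ValueError(f"unknown method {method!r}")

    nodes = list(t.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf()]
    col = {i: c for c, i in enumerate(internal)}
    n_var = len(internal)

    rows, b = [], []
    for n in nodes:
        if n.parent_node is None:
            continue
        r = np.zeros(n_var)
        r[col[idx[id(n.parent_node)]]] = 1.0
        if not n.is_leaf():
            r[col[idx[id(n)]]] = -1.0
        rows.append(r)
        b.append(float(n.edge.length or 0.0))
    A = np.asarray(rows)
    b = np.asarray(b)

    h, *_ = np.linalg.lstsq(A, b, rcond=None)
    edge_hat = A @ h
    if np.any(edge_hat < -1e-10) or np.any(h < -1e-10):
        # refine with explicit monotonicity constraints h_parent >= h_child,
        # solved on a unit scale for conditioning
        from scipy.optimize import LinearConstraint, minimize

        scale = float(np.abs(b).max()) or 1.0
        bs = b / scale

        def obj(x):
            r = A @ x - bs
            return 0.5 * r @ r

        def grad(x):
            return A.T @ (A @ x - bs)

        H = A.T @ A

        res = minimize(obj, np.maximum(h / scale, 0.0), jac=grad,
                       hess=lambda x: H, method="trust-constr",
                       constraints=[LinearConstraint(A, 0.0, np.inf)],
                       options={"maxiter": 500, "gtol": 1e-10,
                                "xtol": 1e-12})
        edge_hat = np.maximum(A @ res.x, 0.0) * scale
        if np.abs(A @ res.x * scale - b).max() > max(1e-6 * scale,
                                                     2.0 * np.abs(b).max()):
            raise TreeError(
                f"ultrametric least squares failed: {res.message}; "
                f"residual {np.abs(A @ res.x * scale - b).max():.3g}")

    k = 0
    for n in nodes:
        if n.parent_node is None:
            continue
        n.edge.length = max(float(edge_hat[k]), 0.0)
        k += 1
    out = Phylogeny(t)
    if not out.is_ultrametric(rtol=1e-6):
        raise TreeError("ultrametric coercion failed to equalize tip depths")
    return out


def root_age(tree: Phylogeny) -> float:
    """Crown age: the common root-to-tip path length of an ultrametric tree."""
    if not tree.is_ultrametric():
        raise TreeError("tree is not ultrametric; cannot define a root age")
    return float(np.mean(list(tree.tip_depths().values())))


def phylo_correlation(tree: Phylogeny) -> pd.DataFrame:
    """Tip-pair phylogenetic correlation matrix.

    Entry (i, j) is the shared root-to-MRCA path length divided by the root
    age; the diagonal is 1.  This is the correlation implied by Brownian
    evolution on the tree, used for the phylogenetic random effect.
    """
    age = root_age(tree)
    arr = tree.arrays()
    depth = arr.node_depths()
    labels = sorted(arr.tip_index)
    pos = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # postorder: at each internal node, tips in different child subtrees
    # have that node as their MRCA
    tip_of_node = {j: pos[lab] for lab, j in arr.tip_index.items()}
    below: list[np.ndarray] = [np.empty(0, dtype=int)] * arr.n_nodes
    for i in arr.postorder:
        ch = arr.children[i]
        if not ch:
            below[i] = np.array([tip_of_node[i]])
            continue
        for a_i, a in enumerate(ch):
            for b in ch[a_i + 1:]:
                C[np.ix_(below[a], below[b])] = depth[i]
                C[np.ix_(below[b], below[a])] = depth[i]
        below[i] = np.concatenate([below[c] for c in ch])
    np.fill_diagonal(C, age)
    if age > 0:
        C = C / age
    return pd.DataFrame(C, index=labels, columns=labels)
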