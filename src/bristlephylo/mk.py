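"""Mk models of discrete character evolution and phylogenetic signal.

Implements the continuous-time Markov (Mk) likelihood on a phylogeny via
Felsenstein's pruning algorithm, maximum-likelihood fitting under the three
standard rate constraints (ER: one rate; SYM: symmetric rates; ARD: all
rates different), AIC-based model comparison with Akaike weights, and a
discrete-trait version of Pagel's lambda obtained by profiling the Mk
likelihood over the lambda branch-length transform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .treeio import Phylogeny, TreeArrays

__all__ = [
    "QMatrix",
    "MkFit",
    "ModelComparison",
    "LambdaFit",
    "tip_likelihood",
    "fit_mk",
    "compare_models",
    "akaike_weights",
    "lambda_transform",
    "fit_lambda",
    "transition_probability",
]

MODELS = ("ER", "SYM", "ARD")


def _n_free_rates(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass(frozen=True)
class QMatrix:
    """Instantaneous rate matrix under a named constraint model."""

    matrix: np.ndarray
    model: str
    params: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.matrix, dtype=float)
        k = q.shape[0]
        if q.shape != (k, k):
            raise ValueError("Q must be square")
        off = q[~np.eye(k, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.abs(q.sum(axis=1)).max() > 1e-8:
            raise ValueError("rows of Q must sum to zero")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_free(self) -> int:
        return _n_free_rates(self.model, self.k)

    @classmethod
    def from_params(cls, model: str, k: int, params) -> "QMatrix":
        """Build Q from the free-rate vector of the given constraint model.

        ER: one rate for every transition.  SYM: one rate per unordered
        state pair, in upper-triangle row-major order.  ARD: one rate per
        ordered pair, row-major over off-diagonal cells.
        """
        params = np.atleast_1d(np.asarray(params, dtype=float))
        n = _n_free_rates(model, k)
        if params.size != n:
            raise ValueError(f"{model} with k={k} needs {n} rates, got {params.size}")
        q = np.zeros((k, k))
        if model == "ER":
            q[~np.eye(k, dtype=bool)] = params[0]
        elif model == "SYM":
            for p, (i, j) in zip(params, itertools.combinations(range(k), 2)):
                q[i, j] = q[j, i] = p
        else:  # ARD
            it = iter(params)
            for i in range(k):
                for j in range(k):
                    if i != j:
                        q[i, j] = next(it)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(matrix=q, model=model, params=params)


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Q t); closed form for two states, expm otherwise."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape == (2, 2):
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        if s == 0:
            return np.eye(2)
        e = np.exp(-s * t)
        return np.array([
            [(b + a * e) / s, (a - a * e) / s],
            [(b - b * e) / s, (a + b * e) / s],
        ])
    return expm(Q * t)


# ----------------------------------------------------------------------
# likelihood

def _state_vectors(arr: TreeArrays, states: dict, k: int) -> np.ndarray:
    """Tip partial-likelihood rows; accepts state ints or uncertainty vectors."""
    missing = sorted(set(arr.tip_index) - set(states))
    orphans = sorted(set(states) - set(arr.tip_index))
    if orphans:
        raise ValueError(f"states given for taxa not in tree: {orphans}")
    if missing:
        raise ValueError(f"tips without a state: {missing}")
    L = np.zeros((arr.n_nodes, k))
    for lab, i in arr.tip_index.items():
        s = states[lab]
        if np.isscalar(s):
            s = int(s)
            if not 0 <= s < k:
                raise ValueError(f"state {s} out of range for k={k}")
            L[i, s] = 1.0
        else:
            v = np.asarray(s, dtype=float)
            if v.shape != (k,) or v.min() < 0 or v.max() <= 0:
                raise ValueError(f"bad uncertainty vector for {lab}")
            L[i] = v
    return L


def _pruning_partials(arr: TreeArrays, L: np.ndarray, P: np.ndarray):
    """Postorder conditional likelihoods with per-node log scaling.

    ``P[i]`` is the transition matrix along the edge above node ``i``.
    Returns (partials, log_scale_total).
    """
    part = L.copy()
    log_scale = 0.0
    for i in arr.postorder:
        ch = arr.children[i]
        if not ch:
            continue
        v = np.ones(part.shape[1])
        for c in ch:
            v = v * (P[c] @ part[c])
        m = v.max()
        if m <= 0:
            return part, -np.inf
        part[i] = v / m
        log_scale += np.log(m)
    return part, log_scale


def _edge_P(arr: TreeArrays, Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if k == 2:
        # vectorized two-state closed form over all edges at once
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        t = arr.edge_length
        e = np.exp(-s * t) if s > 0 else np.ones_like(t)
        P = np.empty((arr.n_nodes, 2, 2))
        if s > 0:
            P[:, 0, 0] = (b + a * e) / s
            P[:, 0, 1] = (a - a * e) / s
            P[:, 1, 0] = (b - b * e) / s
            P[:, 1, 1] = (a + b * e) / s
        else:
            P[:] = np.eye(2)
        P[arr.parent < 0] = np.eye(2)
        return P
    P = np.empty((arr.n_nodes, k, k))
    for i in range(arr.n_nodes):
        if arr.parent[i] >= 0:
            P[i] = transition_probability(Q, arr.edge_length[i])
        else:
            P[i] = np.eye(k)
    return P


def _resolve_pi(pi, k: int) -> np.ndarray:
    if pi is None or (isinstance(pi, str) and pi == "equal"):
        return np.full(k, 1.0 / k)
    v = np.asarray(pi, dtype=float)
    if v.shape != (k,) or v.min() < 0 or not np.isclose(v.sum(), 1.0):
        raise ValueError("root prior must be a probability vector of length k")
    return v


def tip_likelihood(tree: Phylogeny, states: dict, Q: QMatrix | np.ndarray,
                   pi="equal") -> float:
    """Log-likelihood of tip states under the Mk model (pruning algorithm)."""
    qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, dtype=float)
    k = qm.shape[0]
    arr = tree.arrays()
    L = _state_vectors(arr, states, k)
    P = _edge_P(arr, qm)
    part, log_scale = _pruning_partials(arr, L, P)
    root = arr.root
    lik = float(_resolve_pi(pi, k) @ part[root])
    if lik <= 0 or not np.isfinite(log_scale):
        return -np.inf
    return np.log(lik) + log_scale


# ----------------------------------------------------------------------
# ML fitting

@dataclass
class MkFit:
    """A maximum-likelihood Mk fit with its AIC."""

    Q: QMatrix
    loglik: float
    aic: float
    pi: np.ndarray
    n_restarts: int
    gradient_norm: float
    data_fingerprint: tuple = ()

    @property
    def model(self) -> str:
        return self.Q.model


def _observed_states(states: dict):
    obs = set()
    for s in states.values():
        if np.isscalar(s):
            obs.add(int(s))
        else:
            obs.update(np.nonzero(np.asarray(s))[0].tolist())
    return obs


def fit_mk(tree: Phylogeny, states: dict, model: str = "ER", pi="equal",
           k: int | None = None, n_restarts: int = 5, seed: int = 0) -> MkFit:
    """Fit Q by maximum likelihood under the given constraint model.

    Optimizes log-rates with L-BFGS-B from a tree-scale heuristic start plus
    ``n_restarts - 1`` seeded random restarts; deterministic given ``seed``.
    """
    obs = _observed_states(states)
    if len(obs) < 2:
        raise ValueError("trait invariant across tips; rates unidentifiable")
    if k is None:
        k = max(obs) + 1
    n_par = _n_free_rates(model, k)
    arr = tree.arrays()
    L = _state_vectors(arr, states, k)
    piv = _resolve_pi(pi, k)
    depth = float(arr.node_depths().max())
    rng = np.random.default_rng(seed)

    def negll(logp):
        Q = QMatrix.from_params(model, k, np.exp(logp))
        P = _edge_P(arr, Q.matrix)
        part, log_scale = _pruning_partials(arr, L, P)
        lik = float(piv @ part[arr.root])
        if lik <= 0 or not np.isfinite(log_scale):
            return 1e12
        return -(np.log(lik) + log_scale)

    base = np.log(max(1.0 / depth, 1e-8))
    if n_par == 1:
        # single-rate models: bounded scalar search, no restarts needed
        res = minimize_scalar(lambda x: negll(np.array([x])),
                              bounds=(-16.0, 8.0), method="bounded",
                              options={"xatol": 1e-7})
        best_x = np.array([res.x])
        best_fun = float(res.fun)
        n_starts = 1
        gnorm = np.nan
    else:
        starts = [np.full(n_par, base)]
        for _ in range(max(n_restarts - 1, 0)):
            starts.append(base + rng.normal(0, 1.5, size=n_par))
        best = None
        bounds = [(-16.0, 8.0)] * n_par
        for x0 in starts:
            res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        best_x, best_fun = best.x, float(best.fun)
        n_starts = len(starts)
        gnorm = (float(np.linalg.norm(np.atleast_1d(best.jac)))
                 if best.jac is not None else np.nan)
    loglik = -best_fun
    Q = QMatrix.from_params(model, k, np.exp(best_x))
    fp = (tree.n_tips, tuple(sorted((lab, tuple(np.atleast_1d(states[lab]).tolist()))
                                    for lab in states)))
    return MkFit(Q=Q, loglik=loglik, aic=-2 * loglik + 2 * n_par, pi=piv,
                 n_restarts=n_starts, gradient_norm=gnorm,
                 data_fingerprint=fp)


# ----------------------------------------------------------------------
# model comparison

@dataclass
class ModelComparison:
    """Per-model AIC, Akaike weights, and the selected (minimum-AIC) model."""

    aic: dict
    weights: dict
    selected: str

    def as_table(self):
        import pandas as pd
        rows = [{"model": m, "AIC": self.aic[m], "AIC.w": self.weights[m],
                 "selected": m == self.selected} for m in self.aic]
        return pd.DataFrame(rows)


def akaike_weights(aics: dict) -> dict:
    """Akaike weights: exp(-dAIC/2) normalized over the candidate set."""
    vals = np.array([aics[m] for m in aics], dtype=float)
    d = vals - vals.min()
    w = np.exp(-d / 2)
    w = w / w.sum()
    return {m: float(wi) for m, wi in zip(aics, w)}


def compare_models(fits: dict) -> ModelComparison:
    """Compare Mk fits on the same data by AIC and Akaike weight."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {f.data_fingerprint for f in fits.values() if f.data_fingerprint}
    if len(fps) > 1:
        raise ValueError("fits were computed on different data")
    aic = {m: float(f.aic) for m, f in fits.items()}
    w = akaike_weights(aic)
    selected = min(aic, key=aic.get)
    return ModelComparison(aic=aic, weights=w, selected=selected)


# ----------------------------------------------------------------------
# Pagel's lambda for a discrete trait

def lambda_transform(tree: Phylogeny, lam: float) -> Phylogeny:
    """Pagel's lambda branch-length transform.

    Internal edges are multiplied by lambda; each tip edge is lengthened so
    every root-to-tip depth equals the original root age.  lambda = 1 is the
    identity; lambda = 0 erases shared history while keeping tip depths.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    from .treeio import root_age as _root_age
    age = _root_age(tree)
    t = tree.as_dendropy().clone(depth=1)
    # depth of each node's parent in the original tree
    depth = {}
    for n in t.preorder_node_iter():
        if n.parent_node is None:
            depth[id(n)] = 0.0
        else:
            depth[id(n)] = depth[id(n.parent_node)] + float(n.edge.length or 0.0)
    for n in t.preorder_node_iter():
        if n.parent_node is None:
            continue
        if n.is_leaf():
            pdep = depth[id(n.parent_node)]
            n.edge.length = age - lam * pdep
        else:
            n.edge.length = lam * float(n.edge.length or 0.0)
    return Phylogeny(t)


@dataclass
class LambdaFit:
    """Profile-ML estimate of lambda for a binary trait."""

    lam: float
    Q: QMatrix
    loglik: float
    loglik_lambda0: float
    p_value: float
    boundary_mixture: bool = False


def fit_lambda(tree: Phylogeny, states: dict, model: str = "ER", pi="equal",
               seed: int = 0, boundary_mixture: bool = False) -> LambdaFit:
    """Phylogenetic signal of a binary trait via the lambda transform.

    Jointly maximizes the Mk likelihood over lambda in [0, 1] (profile: the
    rates are re-fit on each lambda-transformed tree) and tests lambda-hat
    against lambda = 0 with a likelihood-ratio test on chi-square(1).  With
    ``boundary_mixture=True`` the reference is the 50:50 mixture of a point
    mass at 0 and chi-square(1), appropriate at the boundary null.
    """
    obs = _observed_states(states)
    if len(obs) < 2:
        raise ValueError("trait invariant across tips; lambda unidentifiable")

    cache: dict[float, float] = {}

    def profile(lam: float) -> float:
        lam = float(np.clip(lam, 0.0, 1.0))
        key = round(lam, 12)
        if key not in cache:
            tt = lambda_transform(tree, lam)
            cache[key] = fit_mk(tt, states, model=model, pi=pi, seed=seed,
                                n_restarts=3).loglik
        return cache[key]

    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    gl = [profile(g) for g in grid]
    j = int(np.argmax(gl))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    if lo < hi:
        res = minimize_scalar(lambda x: -profile(x), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-4})
        cand = float(res.x)
    else:
        cand = grid[j]
    best_lam = max(set(grid) | {cand}, key=profile)
    ll_hat = profile(best_lam)
    ll0 = profile(0.0)
    lrt = max(2.0 * (ll_hat - ll0), 0.0)
    p = float(chi2.sf(lrt, df=1))
    if boundary_mixture:
        p = 0.5 * p if lrt > 0 else 1.0
    tt = lambda_transform(tree, best_lam)
    fit = fit_mk(tt, states, model=model, pi=pi, seed=seed, n_restarts=3)
    return LambdaFit(lam=float(best_lam), Q=fit.Q, loglik=ll_hat,
                     loglik_lambda0=ll0, p_value=p,
                     boundary_mixture=boundary_mixture)
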