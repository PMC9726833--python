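"""Phylogenetically controlled Bayesian mixed models via Gibbs sampling.

Two response families are supported, mirroring the comparative analysis of
bristle presence and length:

* ``gaussian`` — an animal model: response = X beta + phylogenetic effect
  + individual effect + residual, where the phylogenetic effects of the m
  species are jointly N(0, sigma2_phylo * C) with C the tip correlation
  matrix of the unit-depth tree.
* ``threshold`` — a probit/liability model for binary presence: a latent
  Gaussian liability with the same linear predictor determines the observed
  state by its sign; the residual variance is fixed at 1 for identification.

Priors follow the weakly-informative inverse-Gamma convention for variance
components (shape nu/2, scale nu*V/2 with V = 1, nu = 0.002) and a diffuse
zero-mean normal for fixed effects.  All full conditionals are conjugate
(the threshold model adds truncated-normal liability updates), so the
sampler is a plain Gibbs scheme, bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .treeio import Phylogeny, phylo_correlation

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "Design",
    "PosteriorSummary",
    "build_design",
    "run_chain",
    "run_model",
    "gelman_rubin",
    "effective_sample_size",
    "pmcmc",
    "liability_scale",
    "summarize_model",
    "backward_eliminate",
    "DESK_PLAN",
    "STUDY_PLAN",
]

#: desk-scale iteration plan (total, burn-in, thinning)
DESK_PLAN = (20_000, 4_000, 8)
#: the full-scale plan used for the published analysis sizes
STUDY_PLAN = (800_000, 80_000, 40)


@dataclass
class ModelSpec:
    """What to fit: response family, fixed factors, references, plan."""

    response: str                     # "gaussian" | "threshold"
    response_column: str
    factors: tuple = ("activity_period", "habitat_type", "foraging_method",
                      "foraging_height", "diet")
    references: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)   # optional declared levels
    total: int = DESK_PLAN[0]
    burnin: int = DESK_PLAN[1]
    thin: int = DESK_PLAN[2]
    n_chains: int = 3

    def __post_init__(self):
        if self.response not in ("gaussian", "threshold"):
            raise ValueError("response must be 'gaussian' or 'threshold'")
        if self.total <= self.burnin:
            raise ValueError("total iterations must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.total - self.burnin) // self.thin


@dataclass
class PriorSpec:
    """Variance-component and fixed-effect priors."""

    V: float = 1.0
    nu: float = 0.002
    fixed_effect_var: float = 1e10

    def __post_init__(self):
        if self.V <= 0 or self.nu <= 0:
            raise ValueError("V and nu must be positive")


@dataclass
class Design:
    """Design matrices plus the phylogenetic correlation."""

    y: np.ndarray
    X: np.ndarray
    columns: list
    col_factor: list            # factor name per column ("(intercept)" first)
    Z: np.ndarray               # specimen x species incidence
    W: np.ndarray               # specimen x individual incidence
    C: np.ndarray               # species correlation (order = species list)
    species: list
    response: str


def _default_references(factors) -> dict:
    from .traitdata import load_vocab
    refs = load_vocab()["reference_levels"]
    return {f: refs[f] for f in factors if f in refs}


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 tree: Phylogeny) -> Design:
    """Treatment-coded design against the declared reference levels.

    Errors on factor levels outside the declared vocabulary and on species
    missing from the tree.
    """
    refs = {**_default_references(spec.factors), **spec.references}
    tree_tips = set(tree.tip_labels)
    absent = sorted(set(data["species"]) - tree_tips)
    if absent:
        raise ValueError(f"species not in tree: {absent}")

    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(intercept)"]
    col_factor = ["(intercept)"]
    for f in spec.factors:
        observed = list(pd.unique(data[f].astype(str)))
        declared = spec.levels.get(f)
        if declared is not None:
            unseen = sorted(set(observed) - set(declared))
            if unseen:
                raise ValueError(f"factor {f!r} has undeclared levels: {unseen}")
            levels = [l for l in declared if l in observed]
        else:
            levels = sorted(observed)
        ref = refs.get(f, levels[0])
        if ref not in levels:
            # reference absent from the data: fall back to the first level
            ref = levels[0]
        for lvl in levels:
            if lvl == ref:
                continue
            cols.append((data[f].astype(str) == lvl).to_numpy(float))
            names.append(f"{f}:{lvl}")
            col_factor.append(f)
    X = np.column_stack(cols)

    species = sorted(set(data["species"]))
    sp_pos = {s: i for i, s in enumerate(species)}
    Z = np.zeros((n, len(species)))
    Z[np.arange(n), [sp_pos[s] for s in data["species"]]] = 1.0

    if "individual" in data.columns:
        inds = list(pd.unique(data["individual"]))
    else:
        inds = [f"row{i}" for i in range(n)]
    ind_pos = {s: i for i, s in enumerate(inds)}
    W = np.zeros((n, len(inds)))
    key = data["individual"] if "individual" in data.columns else pd.Series(inds)
    W[np.arange(n), [ind_pos[s] for s in key]] = 1.0

    C = phylo_correlation(tree).loc[species, species].to_numpy()
    y = data[spec.response_column].to_numpy(dtype=float)
    if spec.response == "threshold" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("threshold response must be binary 0/1")
    return Design(y=y, X=X, columns=names, col_factor=col_factor, Z=Z, W=W,
                  C=C, species=species, response=spec.response)


def _inv_gamma(rng, shape: float, scale: float) -> float:
    return float(scale / rng.gamma(shape))


def _truncated_liability(rng, eta: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Truncated-normal liabilities respecting each observation's sign."""
    u = rng.random(eta.size)
    p_neg = ndtr(-eta)                      # P(liability < 0)
    p = np.where(y01 > 0.5, p_neg + u * (1.0 - p_neg), u * p_neg)
    p = np.clip(p, 1e-13, 1.0 - 1e-13)
    return eta + ndtri(p)


def run_chain(design: Design, prior: PriorSpec, plan=DESK_PLAN,
              seed: int = 0) -> dict:
    """One Gibbs chain; returns retained samples and a DIC estimate.

    For the Gaussian family all updates are conjugate; the threshold family
    fixes the residual variance at 1 and resamples latent liabilities each
    sweep.  Retained samples number (total - burnin) / thin.
    """
    total, burnin, thin = plan
    rng = np.random.default_rng(seed)
    y, X, Z, W, C = design.y, design.X, design.Z, design.W, design.C
    n, p = X.shape
    m = Z.shape[1]
    r = W.shape[1]
    threshold = design.response == "threshold"

    jitter = 1e-8
    evals, U = np.linalg.eigh(C + jitter * np.eye(m))
    if evals.min() <= 0:
        raise ValueError("phylogenetic correlation not positive definite; "
                         "try a larger jitter")
    Cinv = (U / evals) @ U.T

    XtX = X.T @ X
    ZtZ_d = np.einsum("ij,ij->j", Z, Z)
    uniform_counts = bool(np.all(ZtZ_d == ZtZ_d[0]))
    WtW_d = np.einsum("ij,ij->j", W, W)
    B0 = np.eye(p) / prior.fixed_effect_var

    beta = np.zeros(p)
    a = np.zeros(m)
    u = np.zeros(r)
    s2a = s2u = 1.0
    s2e = 1.0
    liab = np.where(y > 0.5, 0.5, -0.5) if threshold else y.copy()

    keep = (total - burnin) // thin
    bsamp = np.empty((keep, p))
    vsamp = np.empty((keep, 3))
    dev = np.empty(keep)
    eta_sum = np.zeros(n)
    s2e_sum = 0.0
    ki = 0

    sp_of = Z.argmax(axis=1)
    ind_of = W.argmax(axis=1)

    for it in range(total):
        target = liab if threshold else y

        # fixed effects
        resid = target - a[sp_of] - u[ind_of]
        prec = XtX / s2e + B0
        Lb = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ resid / s2e)
        beta = mean + np.linalg.solve(Lb.T, rng.standard_normal(p))

        # phylogenetic effects; with equal per-species record counts the
        # posterior precision diagonalizes in the eigenbasis of C
        resid = target - X @ beta - u[ind_of]
        rhs = np.bincount(sp_of, weights=resid, minlength=m) / s2e
        if uniform_counts:
            dA = ZtZ_d[0] / s2e + 1.0 / (s2a * evals)
            a_rot = (U.T @ rhs) / dA + rng.standard_normal(m) / np.sqrt(dA)
            a = U @ a_rot
        else:
            precA = np.diag(ZtZ_d / s2e) + Cinv / s2a
            La = np.linalg.cholesky(precA)
            mean = np.linalg.solve(precA, rhs)
            a = mean + np.linalg.solve(La.T, rng.standard_normal(m))

        # individual effects (diagonal update)
        resid = target - X @ beta - a[sp_of]
        d = WtW_d / s2e + 1.0 / s2u
        mean = (np.bincount(ind_of, weights=resid, minlength=r) / s2e) / d
        u = mean + rng.standard_normal(r) / np.sqrt(d)

        # variance components
        s2a = _inv_gamma(rng, (prior.nu + m) / 2,
                         (prior.nu * prior.V + a @ Cinv @ a) / 2)
        s2u = _inv_gamma(rng, (prior.nu + r) / 2,
                         (prior.nu * prior.V + u @ u) / 2)
        eta = X @ beta + a[sp_of] + u[ind_of]
        if threshold:
            s2e = 1.0
            liab = _truncated_liability(rng, eta, y)
        else:
            res = y - eta
            s2e = _inv_gamma(rng, (prior.nu + n) / 2,
                             (prior.nu * prior.V + res @ res) / 2)

        if it >= burnin and (it - burnin) % thin == 0:
            bsamp[ki] = beta
            vsamp[ki] = (s2a, s2u, s2e)
            dev[ki] = _deviance(y, eta, s2e, threshold)
            eta_sum += eta
            s2e_sum += s2e
            ki += 1

    eta_bar = eta_sum / keep
    d_hat = _deviance(y, eta_bar, s2e_sum / keep, threshold)
    d_bar = float(dev.mean())
    dic = d_bar + (d_bar - d_hat)

    samples = pd.DataFrame(bsamp, columns=design.columns)
    samples["var_phylo"] = vsamp[:, 0]
    samples["var_individual"] = vsamp[:, 1]
    samples["var_residual"] = vsamp[:, 2]
    return {"samples": samples, "deviance": dev, "dic": float(dic),
            "seed": seed, "plan": tuple(plan)}


def _deviance(y, eta, s2e, threshold: bool) -> float:
    if threshold:
        p1 = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
        return float(-2.0 * np.sum(y * np.log(p1) + (1 - y) * np.log1p(-p1)))
    res = y - eta
    return float(len(y) * np.log(2 * np.pi * s2e) + res @ res / s2e)


def run_model(data: pd.DataFrame, tree: Phylogeny, spec: ModelSpec,
              prior: PriorSpec | None = None, seed: int = 0) -> dict:
    """Fit the model with ``spec.n_chains`` independent chains."""
    prior = prior or PriorSpec()
    design = build_design(data, spec, tree)
    plan = (spec.total, spec.burnin, spec.thin)
    chains = [run_chain(design, prior, plan, seed=seed + 1000 * c)
              for c in range(spec.n_chains)]
    return {"design": design, "spec": spec, "chains": chains}


# ----------------------------------------------------------------------
# diagnostics and summaries

def gelman_rubin(chains: list) -> pd.Series:
    """Classic potential scale reduction factor per parameter.

    ``chains`` is a list (>= 2) of equal-length sample DataFrames (or the
    dicts returned by run_chain).
    """
    frames = [c["samples"] if isinstance(c, dict) else c for c in chains]
    if len(frames) < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    lengths = {len(f) for f in frames}
    if len(lengths) != 1 or min(lengths) < 10:
        raise ValueError("chains must share one length >= 10")
    n = len(frames[0])
    out = {}
    for col in frames[0].columns:
        draws = np.array([f[col].to_numpy() for f in frames])
        means = draws.mean(axis=1)
        W = draws.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        if W <= 0:
            out[col] = 1.0 if B == 0 else np.inf
            continue
        var_hat = (n - 1) / n * W + B / n
        out[col] = float(np.sqrt(var_hat / W))
    return pd.Series(out)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of one chain (arviz bulk estimator)."""
    import arviz as az
    return float(az.ess(np.asarray(x)[None, :]))


def pmcmc(samples) -> float:
    """MCMC two-sided p: 2 * min(#draws > 0, #draws < 0) / N, floored at 2/N."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two posterior draws")
    n_pos = int(np.sum(x > 0))
    n_neg = int(np.sum(x < 0))
    p = 2.0 * min(n_pos, n_neg) / x.size
    return max(p, 2.0 / x.size)


def liability_scale(samples: pd.DataFrame) -> pd.DataFrame:
    """Rescale fixed-effect draws to the unit-total-variance liability scale.

    In the threshold model the data identify effects only relative to the
    total latent standard deviation, so each draw's location effects are
    divided by sqrt(var_phylo + var_individual + var_residual).  Comparisons
    across fits (or against a generating truth) should be made on this
    canonical scale.
    """
    tot = (samples["var_phylo"] + samples["var_individual"]
           + samples["var_residual"]).to_numpy()
    scale = np.sqrt(tot)
    out = samples.copy()
    for col in samples.columns:
        if not col.startswith("var_"):
            out[col] = samples[col].to_numpy() / scale
    return out


@dataclass
class PosteriorSummary:
    """Posterior means, 95% CIs, pMCMC and diagnostics per parameter."""

    table: pd.DataFrame
    dic: float
    psrf: pd.Series | None
    converged: bool | None

    def fixed_effects(self) -> pd.DataFrame:
        return self.table[~self.table.index.str.startswith("var_")]


def summarize_model(fit_or_chains, psrf_limit: float = 1.1) -> PosteriorSummary:
    """Summarize one or more chains into a caterpillar-plot-ready table.

    Per parameter: posterior mean, equal-tailed 95% credible interval,
    pMCMC, ESS (pooled), lag-1 autocorrelation and, when >= 2 chains, the
    PSRF.  A CI excluding zero flags the effect significant.  The summary
    carries a non-convergence flag if any PSRF >= ``psrf_limit``.
    """
    if isinstance(fit_or_chains, dict) and "chains" in fit_or_chains:
        chains = fit_or_chains["chains"]
    elif isinstance(fit_or_chains, dict):
        chains = [fit_or_chains]
    else:
        chains = list(fit_or_chains)
    frames = [c["samples"] for c in chains]
    pooled = pd.concat(frames, ignore_index=True)
    psrf = gelman_rubin(chains) if len(chains) >= 2 else None
    converged = bool((psrf < psrf_limit).all()) if psrf is not None else None

    import arviz as az
    rows = []
    for col in pooled.columns:
        stacked = np.array([f[col].to_numpy() for f in frames])
        x = pooled[col].to_numpy()
        lo, hi = np.quantile(x, [0.025, 0.975])
        x0 = x - x.mean()
        denom = float(x0 @ x0)
        lag1 = float(x0[:-1] @ x0[1:] / denom) if denom > 0 else 0.0
        ess = float(az.ess(stacked)) if x.std() > 0 else float(x.size)
        rows.append({
            "parameter": col,
            "mean": float(x.mean()),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "pMCMC": pmcmc(x),
            "significant": bool(lo > 0 or hi < 0),
            "ess": ess,
            "lag1_autocorr": lag1,
            "psrf": float(psrf[col]) if psrf is not None else np.nan,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    dic = float(np.mean([c["dic"] for c in chains]))
    return PosteriorSummary(table=table, dic=dic, psrf=psrf,
                            converged=converged)


def backward_eliminate(data: pd.DataFrame, tree: Phylogeny, spec: ModelSpec,
                       prior: PriorSpec | None = None, seed: int = 0,
                       threshold: float = 0.10):
    """Drop non-significant fixed factors when doing so improves the fit.

    Iteratively, the factor whose most-significant level still has
    pMCMC > ``threshold`` is removed and the reduction is kept only if the
    DIC decreases.  The intercept is never a candidate.  Returns the reduced
    spec, its fit, and a decision trail.
    """
    prior = prior or PriorSpec()
    trail = []
    current = spec
    fit = run_model(data, tree, current, prior, seed=seed)
    summ = summarize_model(fit)

    while True:
        design = fit["design"]
        factor_p = {}
        for f in current.factors:
            cols = [c for c, cf in zip(design.columns, design.col_factor)
                    if cf == f]
            if cols:
                factor_p[f] = min(summ.table.loc[c, "pMCMC"] for c in cols)
        droppable = {f: p for f, p in factor_p.items() if p > threshold}
        if not droppable:
            break
        worst = max(droppable, key=droppable.get)
        reduced = replace(current,
                          factors=tuple(f for f in current.factors
                                        if f != worst))
        red_fit = run_model(data, tree, reduced, prior, seed=seed)
        red_summ = summarize_model(red_fit)
        improved = red_summ.dic < summ.dic
        trail.append({"dropped": worst, "pMCMC": float(droppable[worst]),
                      "dic_before": summ.dic, "dic_after": red_summ.dic,
                      "kept": improved})
        if improved:
            current, fit, summ = reduced, red_fit, red_summ
        else:
            break
    return current, fit, trail
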