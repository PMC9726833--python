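# Methods note

This note records the statistical models, default parameters, numerical
choices and known limitations of `bristlephylo`. It makes no empirical
claims; every number quoted here is either a package default or computed by
the test suite / acceptance script on synthetic data.

## Trees

Input trees (Newick or NEXUS, parsed with dendropy) are normalized so tip
labels use underscores instead of spaces; duplicate labels are an error.
Pruning to a taxon subset preserves all pairwise path lengths between the
retained tips.

Strictly negative branch lengths (a common artifact of consensus trees) are
floored at `1e-6`; zero branches are left alone. Ultrametric coercion
solves a least-squares problem in node-height coordinates: with tips pinned
at height zero, equal tip depth is automatic and the objective is the
squared deviation of implied edge lengths from the input. The unconstrained
solution (`numpy.linalg.lstsq`) is used when it is feasible; if it implies
negative edges, the problem is re-solved with explicit monotonicity
constraints (`scipy trust-constr` with the exact constant Hessian, on a
unit-rescaled system for conditioning). Trees are considered ultrametric at
relative tip-depth tolerance `1e-8` (looser checks use `1e-6`).

The phylogenetic correlation matrix is MRCA depth divided by root age — the
tip correlation implied by Brownian motion on the tree — computed
vectorized over the postorder tip sets.

## Mk likelihood, model selection, and Pagel's λ

The pruning algorithm uses per-node scaling to avoid underflow; for two
states the edge transition probabilities use the closed form
P(t) = π ± e^{−(q₀₁+q₁₀)t} terms rather than `expm`, vectorized across
edges. Root states receive an equal prior by default.

Fitting maximizes the log-likelihood over log-rates: a bounded scalar
search (`minimize_scalar`, log-rate in (−16, 8)) for one-parameter models,
multi-start L-BFGS-B otherwise (seeded, deterministic). Monomorphic tip
data are rejected as unidentifiable. Models are compared by AIC; Akaike
weights are exp(−ΔAIC/2) normalized over the candidate set.

Pagel's λ for a discrete trait multiplies internal branches by λ and
extends tip branches to preserve tip depths. λ̂ is found by a coarse grid
{0, .25, .5, .75, 1} followed by bounded refinement, refitting the Mk rate
at each λ. The reported p-value is a likelihood-ratio test of λ̂ against
λ = 0 on χ²(1); because λ = 1 is a boundary, a 50:50 boundary-mixture
option is available.

## Stochastic character mapping

Node states are drawn from their exact joint conditional distribution
(root ∝ prior × partial likelihood, then descending with
P[s_parent, ·] × partial). Branch histories conditioned on both endpoints
are sampled by uniformization: with μ = max |q_ii| and R = I + Q/μ, the
number of (possibly virtual) jumps is drawn from its Poisson-mixture
posterior, the jump chain is a bridge through powers of R, jump times are
uniform order statistics, and virtual jumps are discarded. A simple
rejection sampler is retained solely as an independent oracle; the
acceptance suite checks the two agree within Monte-Carlo error, and against
a fine-grid conditioned-simulation oracle. Impossible endpoint pairs (zero
transition probability) are an error rather than silently retried.

Summaries report mean changes split into gains (0→1) and losses, expected
dwell-time fractions, per-node posterior state probabilities, the modal
root state with its posterior probability, and binned per-branch density
maps (also exportable as an annotated Newick with `&state_prob` comments).

## Sensitivity analyses

Family sampling fractions are sampled/known species per family. Weighted
downsampling retains exactly `round(target·N)` species by removing species
sequentially with probability proportional to their family's fraction, so
overrepresented families are thinned first. The downsampling analysis
repeats subsample → prune → map → summarize per target (90/80/70% by
default) and averages; `target = 1.0` is the full-data row. Tree
uncertainty repeats the mapping over trees sampled from a posterior set,
refitting Q per tree, and reports the across-tree dispersion of the root
posterior.

## Phylogenetic mixed models

Both families decompose a specimen-level response as
`y = Xβ + Za + Wu + e` with `a ~ N(0, σ²ₐC)`, `u ~ N(0, σ²ᵤI)` and
`e ~ N(0, σ²ₑI)`. Fixed factors are treatment-coded against declared
reference levels (defaults come from the packaged ecology vocabulary).
Priors: inverse-Gamma(ν/2, νV/2) with V = 1, ν = 0.002 on each variance
component and N(0, 10¹⁰) on fixed effects. All full conditionals are
conjugate, so the sampler is plain Gibbs and bit-reproducible given a seed.
When every species has the same number of records the phylogenetic-effect
update diagonalizes in the eigenbasis of C (one `eigh` up front), which is
the fast path; otherwise a dense Cholesky solve is used.

The threshold (probit) family fixes σ²ₑ = 1 and resamples latent
liabilities from sign-constrained truncated normals (`ndtr`/`ndtri`,
clipped at 1e-13). Because binary data identify effects only up to the
latent scale, `liability_scale()` divides each draw's location effects by
√(σ²ₐ + σ²ᵤ + σ²ₑ); comparisons across fits or against a generating truth
should be made on this canonical scale, and the calibration tests do so.

Diagnostics: classic Gelman–Rubin PSRF (identical chains give exactly
√((n−1)/n)); convergence gate PSRF < 1.1; ESS via arviz; pMCMC is twice the
smaller tail proportion, floored at 2/N. DIC is D̄ + p_D with
p_D = D̄ − D(ȳ-parameters). Backward elimination repeatedly drops the
factor whose most-significant level still has pMCMC > 0.10 and keeps the
reduction only if DIC decreases; the intercept is never a candidate.

Iteration plans: the desk plan (20,000 total / 4,000 burn-in / thin 8,
3 chains) is the default and what the tests use (often shortened further);
the study plan (800,000 / 80,000 / 40) matches the scale of a full
published analysis and is provided as a constant, not exercised in tests.

## Synthetic data generators

Generators are the package's own study conditions, fixed before any test
outcomes were inspected:

- Trees: Yule (default) or birth–death conditioned on the number of extant
  tips, rescaled to a 108-Myr crown age (the scale of a crown-bird
  phylogeny); pseudo-posterior sets apply Poisson(2) NNI moves and 5%
  log-normal branch jitter, then re-ultrametrize.
- Binary traits evolve forward under Q on the λ-transformed tree; the true
  history is recorded as a `CharacterMap` with dwell times re-expressed on
  the original branches so bookkeeping closes.
- Ecological datasets: per-species categorical ecology drawn from the
  packaged vocabulary (reference level given probability 0.5), phylogenetic
  effects N(0, σ²ₐ = 1 · C), individual effects (σ²ᵤ = 0.25) and residuals
  (σ²ₑ = 0.5); liability intercept −0.4 (presence is liability > 0) and
  length intercept 12.0, two specimens per species, with contiguous family
  blocks and heterogeneous nominal sampling fractions for the sensitivity
  analyses. Default fixed effects: nocturnal activity +1.5 and closed
  habitat +0.5 on both responses.

## Limitations

- Mk fitting supports equal or estimated-free stationary root priors but
  not per-model root-prior selection criteria (e.g. FitzJohn weights).
- The λ profile assumes a binary character; multistate λ is untested.
- The Gibbs sampler updates variance components one at a time; mixing of
  σ²ₐ can be slow when phylogenetic and individual effects are confounded
  (few records per species). PSRF gating will flag this.
- DIC for the threshold family uses the conditional (liability-integrated
  point) deviance; it is comparable across nested fits here but is not a
  marginal-likelihood substitute.
- The pseudo-posterior tree generator mimics topological and branch-length
  uncertainty but is not a sample from any real posterior.
- `force_ultrametric` minimizes squared edge-length changes; it is a
  repair, not a dating method.
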