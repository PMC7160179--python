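# Methods

`oushift` detects shifts in evolutionary allometry on a phylogeny: clades in
which the scaling relationship between a log-transformed trait (here the
dominant frequency of anuran advertisement calls, in log Hz) and log body
size (snout–vent length, log mm) has moved to a new optimum and/or slope.
This note documents the model, the priors and sampler, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the problem sizes the test suite uses.

## The model

The response vector `y` (log dominant frequency across `n` species at the
tips of a rooted, time-calibrated tree) follows an Ornstein–Uhlenbeck
process with a single global selection strength `α` (per unit time) and
diffusion variance `σ²` (log-Hz² per unit time).  The optimum is piecewise
over the tree: `K` shift points, each on a distinct branch at a continuous
position along it, partition every root-to-tip lineage into segments
belonging to `K+1` regimes (regime 0 is the ancestral/root regime; regimes
inherit tipward until overridden).  The optimum of regime `k` is a linear
function of log body size,

    optimum_k(x) = θ_k + β_k · x ,

so both intercepts and allometric slopes can shift.  With the root state
fixed at the root-regime optimum, the expectation at tip `i` is the
Hansen-weighted mixture

    E[y_i] = Σ_k W_ik (θ_k + β_k x_i) + d_i' β_site + (x_i d_i)' β_inter ,

where a lineage segment of regime `k` spanning times `[t0, t1]` contributes
`e^{−α(T_i − t1)} − e^{−α(T_i − t0)}` to `W_ik`, the residual weight
`e^{−α T_i}` goes to the root regime, and `d_i` is the dummy row for calling
site (aquatic / arboreal; terrestrial is the reference, the most common
site).  Site and size×site coefficients are global (non-shifting): the
regime summaries the method reports are per-regime `θ` and `β_size` only,
so letting covariate effects shift would be unidentifiable from those
outputs.  Three model forms are supported: (a) size only, (b) size + site,
(c) size + site + size×site.

The covariance between tips `i, j` with MRCA depth `s_ij` is

    V_ij = σ²/(2α) · e^{−α(T_i + T_j − 2 s_ij)} (1 − e^{−2α s_ij}) ,

with each species' measurement-error variance added to the diagonal.  Below
`α = 1e-8` the analytic Brownian-motion limit `σ² s_ij` (and all Hansen
weight on the root regime) is used, which avoids 0/0 and makes the BM limit
exact rather than approximate.  Fixing the root state at the root optimum
(rather than drawing it from the OU stationary distribution) is what makes
this limit proper.

The likelihood is the dense multivariate-normal density evaluated through a
lower-triangular Cholesky factor.  A covariance that fails factorization
raises an error naming the smallest eigenvalue rather than silently
regularizing.

## Priors and the reversible-jump sampler

Priors follow the design this pipeline reproduces: slopes `N(0, 0.2)`;
regime optima `N(mean log response, 1.5 × sd log response)` resolved from
the data at hand; number of shifts `K` uniform on `{0, …, K_max}` with
`K_max = 200` by default (a truncated-Poisson alternative is configurable);
shift locations with probability proportional to branch length and position
uniform along the branch, at most one shift per branch; `α` half-normal
(scale 2 per unit tree depth) and `σ²` log-uniform on `[1e-3, 10]` by
default, both replaceable by point masses for conditional analyses.

One consequence deserves emphasis.  With at most one shift per branch, the
joint prior over a shift *set* of size `K` is
`p(K) · K! · Π_b (ℓ_b / L)` on distinct-branch sets, and the implied
marginal over `K` is `p(K) · K! · e_K(ℓ/L)` where `e_K` is the K-th
elementary symmetric polynomial of the normalized branch lengths.  This is
*not* the bare `p(K)`: branch exclusivity thins large `K` (on a 150-tip
unit-depth tree the uniform-to-200 prior has an effective mean near 10, not
100).  `priors.k_marginal_exact` computes this marginal exactly by dynamic
programming, and the data-free sampler run is validated against it — the
no-data prior check is therefore sharp rather than approximate.

Moves: birth (unoccupied branch chosen ∝ length, position uniform, new
`θ, β` drawn from their priors so proposal and prior densities cancel),
death (the exact reverse, shift chosen uniformly), relocate (shift moved to
any available branch, keeping its parameters; symmetric proposal), and
random-walk updates of `θ`, `β`, site and interaction coefficients, with
log-scale multiplier proposals (Jacobian included) for `α` and `σ²`.  Birth
at `K = K_max` and death at `K = 0` are auto-rejections, not errors.
Random-walk step sizes adapt every 100 proposals toward a 0.2–0.5
acceptance rate during burn-in only and are frozen afterwards, so the
retained portion of the chain is a fixed-kernel Markov chain in detailed
balance.  The cached log-likelihood is re-derived from the reference
painting-and-weights path every 10,000 generations and the run aborts on
disagreement.

Caching makes the sampler practical in pure Python/NumPy: the triangular
inverse of the Cholesky factor is recomputed only when `α` or `σ²` move, so
mean-only moves (shifts, `θ`, `β`, site) cost one matrix–vector product.
Chains are bit-reproducible given their seed; multi-chain analyses derive
per-chain seeds from one master seed.

Default chain settings (500,000 generations, thinning 100, 25% burn-in,
4 chains) are desk-scale choices; the multi-million-generation settings of
a full-scale analysis are configuration, not defaults.

## Convergence, summarization, filters

Convergence is assessed with the classic Gelman–Rubin potential scale
reduction factor on per-branch shift-indicator traces across chains
(verdict "converged" iff all R < 1.1, configurable), plus effective sample
sizes (via arviz) for `K`, `α`, `σ²` and the log-likelihood.  Branches
whose indicator never varies in any chain report R = 1 with a note.

Post-burn-in samples of converged chains are pooled.  A branch's posterior
shift probability is the fraction of pooled samples containing a shift on
it; the identity Σ_b pp(b) = posterior mean of K holds exactly under the
one-shift-per-branch restriction and is asserted in tests.  The supported
set applies two filters: pp ≥ 0.7 (sets at 0.5 and 0.9 are also reported)
and clade size ≥ 4 species, i.e. shifts covering three or fewer species are
set aside as unreliable.  Regime parameter summaries are marginal
posteriors: the root regime over all pooled samples, and each supported
shift over the samples whose configuration contains that branch (not only
the modal configuration, which would discard most of the posterior).  A
regime's "mean age" is the mean age (tree depth minus node depth) of the
internal nodes of the subtree subtended by the shift branch — one of
several defensible conventions, stated here because the choice is not
forced.

## Phylogenetic ANCOVA corroboration

Each candidate clade is re-tested in a null-hypothesis framework
deliberately simpler than the OU machinery: generalized least squares under
Brownian motion (covariance = shared path lengths).  The full model gives
the clade its own intercept and slope (4 parameters); the reduced model
shares one intercept and one slope (2 parameters).  Fits go through
statsmodels GLS; residual sums of squares live in the whitened space and
any factor `C = L L'` yields identical RSS.  Models are compared by

    F = [(RSS_r − RSS_f)/(p_f − p_r)] / [RSS_f/(n − p_f)] ,

with `(p_f − p_r, n − p_f)` degrees of freedom; the denominator convention
`n − p_full` is validated against the published mean-square column, which
equals RSS/(n−p) row by row.  The pANCOVA uses size as the only predictor
(the published table is consistent with this); candidate clades come from
the supported-shift set or are user-specified, and must be monophyletic.

## Synthetic data

The generator emulates the structure of the empirical inputs: a Yule tree
(default birth rate 1) rescaled to unit depth — the simulator's termination
at the n-th speciation is corrected by extending all pendant edges by the
waiting time to the next event, so no zero-length tip branches occur; a
Brownian log body-size predictor (root 3.9 log mm ≈ 50 mm); calling site as
a symmetric 3-state Markov chain (rate 0.7 per unit depth, transition
probabilities in closed form); and the response drawn from the *exact*
joint normal implied by the model — no Euler stepping, so likelihood tests
are sharp — plus independent per-species measurement-error noise with
variances from Gamma(shape 2, mean 0.005 log-Hz²).

True parameters default to the ancestral-regime scale of the empirical
system: `θ_root = 9.3` log Hz, `β_root = −0.45`, `α = 1.5`, `σ² = 0.5` per
unit depth (stationary sd ≈ 0.41 log Hz).  The predictor BM rate is 1.0,
chosen so the cross-species OLS R² of log frequency on log size matches the
~51% observed empirically; this also governs how well the slope is
identified at small n.  Planted-shift datasets state the effect size in
units of the intercept-prior sd (which is a function of the data being
analyzed), found by a short fixed-point iteration.

What the generator does **not** emulate: real taxonomic imbalance and
diversified sampling of the frog tree, empirical body-size distributions
beyond scale, covariation between calling site and clade, heteroskedastic
or biased literature-derived measurement error, and tree uncertainty.
Passing tests therefore demonstrate correctness of the machinery and
desk-scale operating characteristics under the stated generative model, not
field performance on real comparative datasets.

## Problem sizes used by the tests

The suite runs at sizes chosen to exercise every code path in minutes:
likelihood oracles on all-random trees of ≤ 8 tips against dense
independent evaluations (rel. tol 1e-8); an exact 4-tip posterior
enumeration (Gaussian integration of `θ, β`, quadrature over shift
position) matched within 0.03 absolute probability; data-free prior
recovery on a 150-tip tree with 800,000 generations (K mean within 3 MC
standard errors of the exact marginal, KS distances < 0.05); planted-shift
recovery on 150-tip trees (one ~40-species shift of 3 prior sds, 100,000
generations, ≥ 8/10 seeds for detection and for root θ/β credible-interval
coverage); pANCOVA type-I error from 1,000 null replicates on a fixed
100-tip tree (0.05 ± 0.02); and a conjugate normal–normal toy whose
stepping-stone estimate must land within 3 Monte-Carlo standard errors of
the closed form (SEs use effective, not nominal, sample sizes).

## Known limitations

- Single global `α` and `σ²`; no regime-specific variance or multivariate
  response.
- At most one shift per branch (matches the granularity of branch-level
  posterior probabilities; relevant mainly for very long branches).
- Dense O(n³) likelihood: comfortable to a few thousand tips, not tens of
  thousands.  A pruning-based O(n) path would have to reproduce the dense
  path to 1e-8 before replacing it.
- Estimates of `α` and OU optima from comparative data are known to be
  fragile at moderate tree sizes; the desk-scale defaults here inherit that
  fragility (visible as occasional non-detections in the recovery study).
- The stepping-stone SE treats thinned samples as exchangeable within
  rungs after an ESS correction; very sticky rungs can still understate it.
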