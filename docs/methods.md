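# Methods

## The state-dependent diversification model

All likelihoods follow the binary-state speciation–extinction framework. Each
lineage carries a state i from an expanded state set (2 states for BiSSE,
4 for HiSSE/CID2, 8 for CID4) with speciation rate λᵢ, extinction rate μᵢ and
directed transition rates q_{i→j}. Along a branch, two coupled quantities are
integrated backwards in time:

- E_i(t): the probability that a lineage in state i at time t leaves no
  sampled descendants;
- D_i(t): the partial likelihood of the observed subtree given state i,

with

    dE_i/dt = μ_i − (λ_i + μ_i + Σ_j q_ij) E_i + λ_i E_i² + Σ_j q_ij E_j
    dD_i/dt = −(λ_i + μ_i + Σ_j q_ij) D_i + Σ_j q_ij D_j + 2 λ_i E_i D_i

and the node join D_i = λ_i D_i^left D_i^right. Incomplete sampling enters at
the tips (skeleton-tree correction): D_i(0) = f_{obs(i)} for expanded states
compatible with the observed tip state and 0 otherwise, and E_i(0) = 1 −
f_{obs(i)}, where f₀ and f₁ are the fractions of extant state-0 and state-1
species present in the tree (defaults 0.83 and 0.79).

At the root the state distribution uses likelihood-proportional (FitzJohn)
weights by default; `equal` and `fixed(state)` are available. The likelihood
is conditioned on survival of both root lineages (division by
Σ πᵢ λᵢ (1 − Eᵢ)²), toggleable — this matches common practice in Bayesian SSE
software, and none of the model comparisons here are sensitive to the toggle
because it applies identically across models.

### Hidden-state structures

Hidden states never change simultaneously with the observed state. H1 and
CID2 share four transition rates (q₀₁, q₁₀ across hidden contexts; q_AB, q_BA
across observed contexts). CID4 has 8 diversification rates tied into 4
hidden classes, one observed-flip pair (q₀₁, q₁₀) per hidden class, and a
hidden chain A↔B↔C↔D with 6 rates shared across observed states — 14
transition rates in all. This chain topology was one of several structures
consistent with a 14-rate count; it was chosen as the sparsest ordered one.

### Numerics

Each branch is integrated with an adaptive Cash–Karp Runge–Kutta (4,5) pair,
rtol 1e-8 / atol 1e-10, written as a numba kernel (SciPy's per-call solver
overhead is prohibitive inside MCMC at ~200 branches per likelihood). D is
renormalised at every node with the log-scaler accumulated, so 100-tip trees
do not underflow. E is clamped to [0, 1] against roundoff. A failed step
(non-finite error estimate, or step size collapsing below 1e-14 of the branch
length) aborts the branch and the likelihood returns −inf with the branch id
recorded. Tests verify agreement to 1e-6 with an independently coded
fixed-step RK4 oracle at step 1e-5, to 1e-8 with the pure-birth closed form,
and to 1e-8 with the BiSSE limit of the HiSSE model (hidden rates tied,
hidden transitions zero).

Trees must be ultrametric within 1e-6 relative depth spread for fitting
(metrics accept any tree); branch lengths are treated as relative time with
the root height as the time unit. The synthetic-data generator normalises
root height to 1 and rescales the generating rates accordingly, so recorded
truth parameters are in height-1 units. Where the source analyses constrain
"total tree length" the package standardises on root height instead; this
changes only the absolute scale of rates, not model comparisons or
equilibrium proportions.

## Bayesian machinery

**Priors.** Independent exponentials: mean 10 on λ and μ (height-1 units —
a pure-birth point estimate for ~100 tips over one time unit is ln 100 ≈ 4.6,
so mean 10 is weakly informative), mean 1 on q. All configurable.

**MCMC.** Single-site Metropolis–Hastings with lognormal multiplier proposals
(Hastings correction log m). Step sizes are tuned per parameter toward 20–40%
acceptance during burn-in (default 25% of the chain) and frozen afterwards,
preserving detailed balance post burn-in; a seeded generator makes chains
bit-reproducible. Stored draws are thinned to at most 10,000. Validation:
prior recovery with the likelihood switched off, and chain quantiles against
the exact conjugate posterior of a two-parameter Poisson–Gamma toy, both
within 3 Monte-Carlo standard errors.

**Marginal likelihoods.** Stepping-stone sampling over power posteriors with
powers β_k = (k/K)^(1/0.3) (stones concentrated near the prior), default
K = 30 stones, 2,000 recorded + 500 adaptation iterations per stone, each
stone's ratio averaged with log-sum-exp stabilisation. A model with zero free
parameters returns its fixed log-likelihood exactly. The estimator is
generic over (loglik, logprior, prior-sampler) targets; the conjugate-toy
test exercises the same code path as the SSE wrapper and agrees with the
closed-form evidence to 0.05 nats at default settings.

**Bayes factors.** Bf = 2 (ln Z_focal − ln Z_competing); a model is called
preferred when Bf > 1.16 (competing when < −1.16). The comparison table is
antisymmetric with a zero diagonal by construction.

**Ancestral states.** Marginal node probabilities by the conditional
re-rooting recursion: a down-pass stores each branch's D at both ends plus
its linear propagator M (integrated jointly with E by fixed-step RK4, 40
steps per branch), and an up-pass propagates the complement likelihood S via
S_bottom = Mᵀ S_top. Node marginals ∝ S · D, averaged over posterior draws.
Summary states are argmax of the observed-trait projection; an origin is an
edge whose parent summary is 0 and child summary is 1. Observed-state
probabilities within 1e-6 of 0.5 are flagged as ties, not silently resolved.
Per-edge origin probabilities are reported as the product of parent-state-0
and child-state-1 marginals — an independence approximation, adequate for the
coarse origin counting used here (stochastic mapping is out of scope).

**Origin-counting convention.** Parsimony origins (the tips-per-origin
metric) use minimum-change parsimony with the root held in state 0: the
derived state is, by definition, derived, and an unconstrained root would
let an all-derived clade count zero origins. Among root-0 reconstructions
with minimal total changes, the minimum 0→1 count is reported. An
irreversible variant (1→0 forbidden) is exposed as an option. The count is a
lower bound on the true number of gains whenever the crown ancestor truly is
state 0; when the truth has a state-1 crown ancestor (stem transition) the
root-0 convention can exceed the true event count by one or more, which the
simulator makes checkable by recording the true MRCA state.

## Simulation

Trees are grown forward from a single stem lineage: exponential waiting times
on the total event rate; event type and lineage chosen proportionally to
their rates; growth stops when the target extant count is reached, extended
by a uniform fraction of the waiting time to the next event so terminal
branches are strictly positive (without this, the final twin cherry has
zero-length terminals and any polymorphic assignment of those twins has
likelihood exactly zero under an Mk model). Extinct lineages are pruned and
unifurcations suppressed; the returned tree is the extant crown clade, which
is ultrametric and bifurcating by construction. Whole-clade extinction
restarts the simulation on the same random stream (up to 1,000 retries), so
accepted trees are conditioned on survival. The full transition history is
kept: per-type event counts over all lineages and over surviving lineages,
plus the true state of the extant MRCA.

Characters on fixed trees (the FiSSE null) evolve by exponential waiting
times along each branch under a two-state Markov model.

## The tip-rate test

Each tip's equal-splits measure is ES = Σ_j l_j (1/2)^(j−1) over the edges
walking rootward; 1/ES proxies the tip speciation rate, and Λ_k is the mean
over state-k tips. The null refits a symmetric one-rate Mk model to the
observed states by maximum likelihood (bounded scalar optimisation of the
pruning likelihood, stationary 0.5/0.5 root) and simulates characters on the
fixed tree, root state drawn from the stationary distribution; monomorphic
replicates are redrawn up to 100 times each. The p-value is twice the smaller
tail proportion of the observed Λ₀ − Λ₁ with the (m+1)/(n+1) correction,
capped at 1. Calibration: on 500 state-independent 64-tip datasets the
rejection rate at nominal 0.05 falls within [0.02, 0.08] (test-suite check).

## Adequacy

Posterior-predictive replication: for each replicate one posterior draw
(resampled with replacement — the source analyses do not specify a pairing),
one simulated tree at the empirical tip count with root state 0 (the
reconstructed ancestral state; configurable), and the four metrics. Replicates
with no derived tips are kept, with tips-per-origin and tip-age-rank-sum
reported missing rather than zero, and both counts (all replicates,
non-monomorphic replicates) are reported. Empirical values are located by
midrank percentile; the 95% interval is the 2.5/97.5 empirical percentile
pair; metrics with fewer than 100 valid replicates are flagged unusable.
Self-consistency: when the "empirical" dataset is itself a draw from the same
process, intervals built from 200 replicate trees cover each metric in ≈95%
of 200 meta-replicates.

## Equilibrium dynamics

Expected lineage counts n₀, n₁ obey dn₀/dt = r₀n₀ − q₀₁n₀ + q₁₀n₁ and
dn₁/dt = r₁n₁ + q₀₁n₀ − q₁₀n₁ (r = λ − μ), so the expected state-1 proportion
follows the scalar flow dp/dt = (r₁ − r₀)p(1 − p) + q₀₁(1 − p) − q₁₀p.
The equilibrium p₁\* is the root of the quadratic in [0, 1] with negative
flow derivative (the stable fixed point; equivalently the dominant-eigenvector
proportion of the 2×2 rate matrix); the degenerate case r₀ = r₁ with both q
zero is an error. Integration uses LSODA at rtol 1e-10 with event detection
for the time to reach a stated fraction (default 90%) of p₁\* from p₁(0) = 0
(all-state-0 root; configurable). Posterior propagation maps draws through
both quantities, dropping and counting degenerate draws. The quadratic root
agrees with the long-time ODE limit to 1e-6 over random parameter draws, and
with the terminal state frequencies of forward simulations run to 1,000 tips
within Monte-Carlo error.

## Synthetic study-like data

`generate_crownlike` draws from the B1-like scenario — λ₀ = 6, λ₁ = 3,
μ₀ = μ₁ = 1, q₀₁ = 0.5, q₁₀ = 0.05 in height-1 units; synthetic study
conditions, not empirical estimates — and rejection-samples on summary
targets: 104 tips, 15–25 state-1 tips, 12–20 parsimony origins, no origin
larger than 2 tips (enforced exactly via the largest monophyletic state-1
block). Rejection keeps accepted datasets exactly model-distributed
conditional on acceptance; the acceptance rate is ≈0.25%, well inside the
10,000-try cap. Accepted trees are rescaled to unit height with rates
rescaled to match, and a truth manifest records the generating parameters,
seed, retry count and true transition counts.

What the generator emulates: the tip count, rarity (~18% derived), tippiness
(tips per origin ≈ 1.2) and relative-time scaling of the motivating dataset.
What it does not: gene-tree discordance and its terminal-branch inflation
(only the branch-length consequence is probed, via cropping), despecialised
intermediate phenotypes, diversification rate variation unrelated to the
trait, and non-random taxon sampling. One empirical signature it actively
contradicts: because λ₁ < λ₀, simulated state-1 tips sit on terminal branches
*longer* than average (tip-age rank sums above the random expectation in ~92%
of simulations) — tippiness here is a property of origin sizes, not of
terminal branch lengths. Passing tests therefore demonstrate correctness of
the machinery under the stated generating process, not robustness to the
artifacts real data carry.

## Cropping

The slice depth s is found by bisection on [0, height] (truncated length is
monotone in s; up to 200 iterations, converging to machine precision), so the
retained length equals (1 − reduction) × total within 1e-9 relative. Lineages
whose crown age is more recent than s collapse to a single tip named after
their first member and carrying the shared member state; a mixed-state
collapse is an error by design, since it has no faithful character
assignment.

## Problem sizes in the test suite

The suite uses the study-scale settings where they are cheap (104-tip trees,
10,000-iteration chains, 500 FiSSE replicates, 200 posterior-predictive
meta-replicates of 200 trees) and small trees (≤10 tips) where an oracle must
be integrated at step 1e-5. Stepping-stone defaults (30 stones × 2,000
iterations) are used in the conjugate-toy validation; SSE marginal
likelihoods in the end-to-end tests use 12 stones × 600 iterations, which is
ample for Bayes factors of magnitude ≈10. The acceptance script's 10,000
equilibrium draws match the stated study condition.
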