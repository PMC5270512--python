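# Methods

## Model and score

A discrete Bayesian network over variables X₁,…,Xₙ (arities r₁,…,rₙ)
factorizes the joint as ∏ᵢ P(Xᵢ | Pa_G(Xᵢ)). We place independent
Dirichlet priors on the multinomial parameters and integrate them out,
giving the closed-form BDeu marginal likelihood per family (child i with
qᵢ joint parent configurations):

log P(D|G) = Σᵢ Σⱼ [ ln Γ(αᵢⱼ) − ln Γ(αᵢⱼ + Nᵢⱼ) + Σₖ ( ln Γ(αᵢⱼₖ + Nᵢⱼₖ) − ln Γ(αᵢⱼₖ) ) ]

with BDeu hyperparameters αᵢⱼₖ = ESS / (rᵢ qᵢ) and αᵢⱼ = ESS / qᵢ. All
computation is in log space via `scipy.special.gammaln`; no
probability-space products are ever formed. The default equivalent sample
size is **ESS = 1**, the common uninformative choice for this score
family. BDeu is score-equivalent: Markov-equivalent DAGs receive equal
scores on observational data (the test suite checks this by enumerating
equivalence classes at n = 3).

**Structure prior.** Uniform over DAGs (within the fan-in cap), so the
acceptance ratio reduces to likelihood ratio × Hastings ratio. A hook
(`ScoreSettings.log_structure_prior`) accepts any callable
`DagStructure -> float`; none is shipped.

**Interventions.** A value set by perturbation is excluded from its own
family's counts but still conditions its children (masking). This is the
standard treatment for hard interventions on discrete networks; it is what
breaks score equivalence and orients edges. The mask is per-cell, so a row
may mix observed and clamped values.

**Caching.** Family scores are memoized on (child, parent set); graph and
delta scores are sums of cached lookups, so an MH step costs at most two
fresh family evaluations (one for addition/deletion, two for reversal).
The cache is unbounded by default with a configurable entry limit.

## Proposal distribution

A transition of length t is a walk of t single-edge modifications
(addition, deletion, reversal), each drawn uniformly from the neighborhood
of the current intermediate structure; t itself is drawn from the mixture
vector [p₁,…,p_max]. The neighborhood 𝒩(G) contains exactly the moves
whose result is acyclic and respects the fan-in cap, and q(G) = |𝒩(G)|.

The probability of proposing endpoint k from i sums over all length-t
routes, Q^t(k|i) = (1/q(i)) Σ_r ∏ⱼ 1/q(rⱼ). Routes reverse one-to-one with
identical interior factors, so

Q^t(i|k) / Q^t(k|i) = q(i) / q(k)

for every t, and therefore for every mixture. The sampler consequently
needs only two neighborhood sizes per step: q(start), a byproduct of the
first sub-step draw, and q(end), one extra enumeration. The test suite
verifies the telescoping against exhaustive route enumeration on the
25-DAG 3-node space and against 10⁶ brute-force simulated proposals.

**Ergodicity.** `reachability_walk` realizes the irreducibility argument
constructively: tear the source DAG down to the empty graph with
deletions, spending leftover steps of a partial transition reversing a
final single edge; then build the target edge by edge, absorbing slack in
the building transition with a parity-correcting first edge plus
reversals. Every intermediate structure is acyclic, every returned
transition has exactly t moves, and the tests replay every move with full
validation over all ordered DAG pairs at n = 3, t ∈ {1,2,3}. Aperiodicity
follows from self-returning routes of both s and s+1 transitions through
the empty graph (add / reverse^(t−2) / delete filler). Positivity of
P(D|G), which irreducibility assumes, holds because all Dirichlet
hyperparameters are positive.

**Design choices.**
- A walk may end at its start or at a nearer neighbor; such proposals are
  kept (endpoint = start is accepted with probability 1). Rejecting or
  resampling them would change the proposal law the telescoping relies on;
  they are rare in large neighborhoods.
- Fan-in semantics: a move is admissible iff the child *gaining* a parent
  ends at ≤ max_fanin parents; deletions are always admissible. This keeps
  the neighborhood relation symmetric, which the Hastings ratio requires.
- Mixture length is capped at 5 by default (a warning beyond that):
  very long jumps amount to uniform resampling of the structure space.
- Random stream order is fixed — length draw, then one draw per sub-step —
  so a chain is replayable from its seed.
- Adaptive tuning of [p₁,…,p_max] during burn-in is deliberately not
  implemented; the mixture is static configuration.

## Sampler

Standard Metropolis-Hastings: acceptance min{1, exp(Δ log P(D|G) +
Δ log P(G) + log q(G)/q(G′))}; a rejected proposal re-counts the current
state. Protocol (burn-in, sample size, thinning, seed, initial DAG) is
explicit per chain; ensembles use independent seeds derived from one
master seed via `SeedSequence`. Random initial DAGs draw a uniform
topological order and include each order-compatible edge with probability
0.5 subject to the fan-in cap. Identical structures are interned through a
bounded neighborhood cache keyed on the adjacency bytes, which makes the
heavy revisiting typical of MH output cheap in both time and memory.

A `hastings=False` switch replaces the proposal-asymmetry correction with
1. This is a deliberately broken negative control: its stationary law is
provably tilted to P(G|D)·q(G), and the acceptance tests require it to
*fail* the oracle comparison that the correct chain passes.

## Exact oracle

For n ≤ 6 all DAGs are enumerated by assigning each unordered node pair
one of three states (none, u→v, v→u) depth-first with incremental cycle
and fan-in pruning — each DAG is produced exactly once, no deduplication.
Counts for n = 1..4 (1, 3, 25, 543) are cross-checked at test time by
filtering all 2^(n(n−1)) digraphs. The exact posterior normalizes scores
by log-sum-exp; exact edge posteriors are probability-weighted adjacency
sums. Every stationarity claim about the sampler is adjudicated against
this module. The n ≤ 6 guard is hard (the n = 6 count is 3,781,503 and
enumeration time grows accordingly; validation uses n ≤ 5).

## Diagnostics

Edge posteriors are means of edge indicators over retained states (pooling
chains = concatenation). Between-chain agreement is summarized by the sum
of squared differences (SSD) of edge-posterior matrices over all ordered
pairs; `best_converged_pair` and `mean_pairwise_ssd` reduce an ensemble to
the argmin pair and the mean over unordered pairs. The consensus graph
thresholds posteriors with strict `>` (default 0.85) and does *not*
enforce acyclicity — thresholded marginals can be cyclic — but flags
whether the result is a DAG. `neighborhood_acceptance_map` evaluates the
acceptance probability of every one-step neighbor, the tool for
visualizing the local-maximum traps that motivate multi-step proposals.
MAP is the argmax over retained scores, first occurrence winning ties;
unique-DAG counts use retained (post-thinning) states.

## Synthetic data

`random_bn` draws a structure (uniform topological order, independent edge
inclusion at density 0.3 by default) and CPTs from symmetric
Dirichlet(0.5) — peaky enough that edges are identifiable, strictly
positive so every structure has positive likelihood. Default arity is 3,
mirroring a typical low/medium/high discretization of signaling
measurements. Interventional sampling clamps exactly one uniformly chosen
node per intervened row to a uniformly chosen value (target list and fixed
value configurable) and samples descendants conditional on the clamp.
`combined_dataset` pools forward samples from two different networks into
one table with no provenance column: no single DAG generates such data,
the posterior becomes multimodal, and this is the stress scenario for
proposal comparisons.

What the generator does **not** emulate: continuous measurement noise and
the discretization step real assay data passes through, latent confounders
with specific structure, feedback dynamics (the two-network pool only
mimics the marginal effect of model misspecification), and realistic
intervention biology (off-target effects, partial efficacy). Passing
tests therefore demonstrate correctness of the inference machinery and
the direction of the convergence effect under controlled misspecification
— not recovery guarantees for any particular real assay.

## Validation problem sizes

The validation studies (`dagmcmc.validation`, exercised by both the test
suite and `scripts/acceptance.py`) use sizes chosen so the whole battery
runs in a few minutes on one CPU while keeping Monte-Carlo error well
below the tolerances tested:

- Oracle comparison: 3-node binary network, 200 rows, chains of 200,000
  retained states (burn-in 20,000) per mixture (1.0), (0.5, 0.5),
  (0.0, 1.0); tolerance 0.02 in total variation and max edge-posterior
  error, with the broken-Hastings control required to exceed it.
- Hastings ratio: 10⁶ simulated proposals per direction for a fixed DAG
  pair with q = 6 vs q = 5; agreement within 3 Monte-Carlo SE.
- Neighborhood counts: 500 random DAGs, n ≤ 6, alternating no cap / cap 3.
- Convergence comparison: 10 nodes, 3000 + 3000 pooled rows, 3 chains of
  burn-in 40,000 + 20,000 retained states, fan-in 5, 6 replicates, specs
  (1.0) vs (0.8, 0.2). Shorter chains were uninformative here — at a few
  thousand steps neither proposal's chains have left their initial
  basins, so their ensembles are equally inconsistent; 40,000 steps is
  where the mixture's chains begin to agree while one-step chains remain
  trapped, which is precisely the effect under study. The absolute SSD
  values at this scale are far larger than those from full-length chains;
  only the direction of the difference is the reproducible claim.

## Known limitations

- Scoring is restricted to complete discrete data; no missing values,
  no Gaussian/BGe branch.
- The sampler explores DAG space, not equivalence-class (CPDAG) space;
  observational data therefore spreads posterior mass across orientations
  within a class, by design.
- `neighborhood_size` enumerates rather than counts analytically; at the
  target scales (n ≲ 40) enumeration is not the bottleneck (scoring is).
- Exact validation is only possible for n ≤ 6; for larger n correctness
  rests on the small-n oracle plus the structural properties (neighborhood
  symmetry, telescoping, ergodicity) tested independently of n.
- Chains run sequentially; ensembles parallelize trivially at the process
  level but no in-package parallelism is provided.
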