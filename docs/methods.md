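# Methods

## Model

The generative model is the multispecies coalescent with a constant,
shared population size: time runs backward from 0 (the present), the
species tree on `n` taxa has divergence times `s_1 > … > s_{n−1} > 0` in
coalescent units, and within every population each pair of gene lineages
coalesces independently at rate 1. One gene copy is sampled per species,
so no coalescence is possible below `s_{n−1}` and exactly `n` lineages
enter the most recent interval. Lineages from different species may meet
only in populations ancestral to both. Migration, per-branch population
sizes, and multiple samples per species are out of scope.

A *ranked* topology carries the temporal order of its internal nodes
(rank 1 = root = most ancient) but no continuous times. Ranked gene tree
probabilities depend on the species tree only through its ranked topology
and the internal interval lengths `d_i = s_{i−1} − s_i`, `i = 2..n−1`;
they are invariant to time translation and to `s_{n−1}` itself. This
invariance is exploited throughout and asserted in tests.

## Core computation

The probability `P[G|T]` is a dynamic program over states
`(interval i, lineage count ℓ)`. The key structural fact is that a
ranking pins down which coalescences have happened once `ℓ` is known, so
the lineage-to-population assignment ("ancestral configuration") is
unique per state and the DP is polynomial, `O(n^5)` overall.

Implementation notes:

* **Embedding profile.** For each gene node the species-side least common
  ancestor rank is found by walking down the species tree; `g_i`, the
  minimum lineage count at `s_i`, comes from the longest suffix of gene
  ranks whose lca's all lie more recently than `s_i`. A brute-force
  enumeration over feasible interval assignments serves as the test
  oracle.
* **Rate tables.** For each interval row the total coalescence rate is
  precomputed as a function of the lineage count alone (cutting the gene
  tree at `c` lineages and counting per population). This makes the
  per-interval rate schedule an `O(1)` lookup and the whole DP cheap to
  re-evaluate for new interval lengths — the workhorse of likelihood
  optimization. The explicit per-transition `k_{i,j,z}` table construction
  (bottom counts from the lineage cut, then one decrement per event) is
  kept as the public, verifiable form; the identity between the cut-based
  bottom counts and the daughter-sum recursion over the beaded tree is a
  regression test. Each leaf population contributes exactly one exiting
  lineage at `s_{n−1}` (one sample per species).
* **Strictly increasing rates.** Each forward-time coalescence adds a
  lineage to a population already holding at least one, so rates increase
  strictly along an interval's schedule. This is asserted at runtime, not
  assumed; a violation is an internal error rather than a case to handle
  (repeated rates would require a different hypoexponential form that
  cannot arise here).

## Numerical evaluation of the interval probability

The transition probability is an alternating exponential mixture over the
integer rates `λ_0 < … < λ_m` — equivalently `(−1)^m` times the divided
difference of `exp(−λΔ)` over the rate grid. Direct evaluation cancels
catastrophically as `Δ → 0` (the value is `Θ(Δ^m)` while the terms are
`Θ(1)`), and small-`Δ` accuracy matters because likelihood optimizers
probe short intervals. Three evaluation paths are used:

1. **Direct partial fractions** in 80-bit extended precision with exact
   integer denominators, accepted only if a running bound on the rounding
   error stays below `1e−11` of the result.
2. **Taylor form** for `Δ·(λ_m − λ_0) ≤ 2`: after shifting out `λ_0`,
   the divided difference is an alternating series in the complete
   homogeneous symmetric polynomials of the scaled rates (Newton's
   identities on power sums), evaluated with its own error monitor and
   assembled in log space to dodge underflow.
3. **Uniformization fallback.** The event is "a pure-death chain with
   exit rates `λ_m, …, λ_0` sits in its final state at time `Δ`";
   uniformizing at the largest rate expresses this as a Poisson mixture of
   discrete-chain powers — all terms positive, no cancellation, just
   slower. Division by `Π_{j≥1} λ_j` converts the total-rate chain into
   the probability of the *specific* coalescence sequence.

Against a 60-digit reference evaluation the composite stays within
`1e−9` relative error (measured worst case ≈ `1e−11`) for rate sets up to
`C(12,2)` and `Δ ∈ [1e−6, 50]`. `Δ = ∞` is admitted only through its
documented limit (`1/Π_{j≥1} λ_j` when `λ_0 = 0`, else 0); `Δ = 0`
(coincident divergence times) is rejected upstream as a model violation.
Probabilities are stored linearly — `n` is small and the DP entries are
probabilities of compound events, rarely below `1e−300` in practice —
with a log accessor that reports `−inf` on underflow.

## Tunable parameters

* `cap` in `unranked_probability` / `enumerate_rankings` (default `10^6`
  rankings): balanced shapes have super-polynomially many rankings; the
  cap refuses explicitly rather than truncating a probability sum.
* `rtol = 1e−6` for ultrametricity checks: relative to tree height;
  tied node ages are a hard error because the continuous-time model puts
  zero mass on ties and silent tie-breaking would corrupt rankings.
* `fit_times`: `n_starts = 3` seeded Nelder-Mead starts on log-gaps,
  tolerance `1e−8`. Log-parametrization keeps gaps positive and removes
  the flat directions (translation, `s_{n−1}`) from the search space;
  anchoring `s_{n−1} = 1` is an arbitrary but harmless convention.
  Identifiability of the gaps is not asserted; flat likelihoods simply
  surface as `converged=False` with the best value found.
* `ml_species_tree` enumerates all `n!(n−1)!/2^{n−1}` ranked species
  topologies and is guarded at `n ≤ 6`.

## Simulator

The simulator draws the waiting time to the next coalescence from the
total pair-count rate (competing exponentials across the populations of
the current interval row), picks the population proportionally to its
pair count and the pair uniformly — exact, and convenient because every
event is recorded with its interval, population and pair, so traces
replay into the `ℓ_i`/`k_{i,j,z}` bookkeeping of the core algorithm.
Random species trees use a Yule process: uniform backward pair merges for
the ranked topology and `Exp(i·b)` interval lengths (`Exp(n·b)` for the
most recent divergence time), defaulting to birth rate `b = 1`, which
keeps interval lengths of order 1 coalescent unit — the regime where
ranked discordance is common and the computations are exercised
non-trivially.

What the simulator does *not* emulate: gene tree estimation error (real
ranked gene trees come from sequences via clock-constrained inference and
carry uncertainty — the fractional-count machinery accepts
posterior-weighted observations, but no sequence-level noise is
generated), recombination, migration, or population-size variation.
Passing tests therefore validate the probability calculus and the
estimator under the model, not robustness to misspecification.

## Problem sizes used in validation

Monte-Carlo cross-checks run at `2×10^5` replicates for 3–5 taxa with a
4-standard-error acceptance band per topology. Parameter recovery uses
`N = 2000` loci (gap tolerance ±0.15, consistent with the curvature of
the multinomial likelihood at that sample size) and 50 seeded replicates
for the exhaustive topology search with a single optimizer start per
candidate; the polynomial-scaling check runs one 50-taxon probability.
These sizes were chosen so the full validation completes in a few minutes
while keeping the statistical bands meaningful.

## Known limitations

* Unranked probabilities are exact but only for shapes whose ranking
  count fits under the cap; no ancestral-configuration (STELLS-style)
  algorithm is provided for balanced shapes.
* MDC is implemented in its standard maximal-subtree form purely as a
  comparison baseline for MAC.
* Exhaustive ML search beyond 6 taxa, heuristic tree search, and model
  selection are out of scope.
* Whether some tree classes have polynomially many rankings but
  exponentially many ancestral configurations (or vice versa) is an open
  question; the package takes no position on it.
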