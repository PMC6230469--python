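# Methods

## Model

Let `Y` be the `n_g × T` matrix of log-expression values after grand-mean
centering (one scalar, the mean over all genes and cells, subtracted from
every entry — the GP below is zero-mean). An ordering of the `T` cells is a
permutation `o`; given `o`, each gene's reordered profile `y_g(o)` is
modelled as an independent draw from a zero-mean Gaussian process evaluated
at pseudotimes `τ(o)`, with the squared exponential kernel

    Σ(τ)_ij = σ_w² exp(−(τ_j − τ_i)²/(2l²)) + δ_ij σ_ε².

All genes share one covariance, so the marginal log-likelihood of `Y` given
`o` needs a single Cholesky factorization per evaluation. The posterior
over orderings is proportional to this likelihood (uniform order prior).

**Pseudotime mappings.** Geodesic (default): cumulative Euclidean distances
between consecutive cells, rescaled to [0, 1]; this approximates geodesic
distance along the trajectory (as in Isomap) and lets pseudotime density
adapt to the local speed of expression change. Rank time: the fixed grid
`(i − 0.5)/T`. Both depend only on pseudotime *differences*, which full
reversal of an ordering preserves — hence the exact posterior symmetry
`p(o) = p(reverse(o))` that the test suite checks to 1e-8 and that
post-processing removes (below).

**Variance split and priors.** Total variability is signal plus noise, so
only `σ_w²` is sampled and `σ_ε² = V − σ_w²`, where `V` is the sample
variance of the whole centred matrix. Priors: `log σ_w² ~ N(log(0.9 V),
0.1²)` and `log l ~ N(log(1/2), 0.1²)`. The signal-variance prior encodes
comparatively low measurement noise (≈10% of `V`); the length-scale prior
is deliberately strong because with a vague prior the posterior length
scale collapses and the GP chases noise. Both means/sds are configurable
(`PriorSpec`), including the alternative parametrization that places
`log σ_w` (not `log σ_w²`) at `log(0.9 V)` — note that variant leaves no
support below `V` once `V > 1.23` and is not the default.

## Sampling

Each iteration makes one Metropolis step on the ordering and (when
hyperparameters are sampled) one on `(log σ_w², log l)`, a valid
Metropolis-within-Gibbs scheme.

**Order moves.** Five symmetric kernels, mixed with probabilities
`p_1..p_5`:

1. *Iterated neighbour swaps* — `r_1 ~ U{1..n_0}` adjacent transpositions
   at uniform positions (default `n_0 = ⌊T/4⌋`).
2. *Distance-weighted swap* — an unordered position pair is chosen with
   probability ∝ `exp(−d(c_i, c_j)²/γ)^α`, `d` the L1 distance of the cells
   currently at those positions; the cells are exchanged.
3. *Distance-weighted segment reversal* — same pair law; the segment
   between (and including) the pair is reversed. This is the long-range
   workhorse: it is a 2-opt move that keeps the trajectory smooth exactly
   when the endpoints are similar.
4. *Short random permutations* — `r_2 ~ U{1..n_3}` segments of length
   `U{3..max(n_3a, 3)}` at uniform starts, each scrambled uniformly
   (defaults `n_3 = ⌊T/20⌋`, `n_3a = ⌊T/12⌋`).
5. *Full reversal* (default probability 0.002).

All five kernels are exactly symmetric, so acceptance uses the likelihood
ratio alone. For moves 2/3 this hinges on two facts: the weight normalizer
sums over all unordered *cell* pairs and is therefore order-invariant, and
the selected pair's weight is unchanged by the move. The tests verify
symmetry by exhaustive enumeration of every kernel at T = 4–5 rather than
assuming it. Because the weights are indexed by cell identity, sampling a
position pair under the current order is implemented as sampling a cell
pair once from a fixed categorical table and looking up positions — O(T)
per proposal after O(T²) setup.

`γ` defaults to the median of the squared pairwise L1 distances, making the
pair weights scale-free; a pilot sweep over `γ` (med × 1/32 … ×4 and the
uniform limit) on the two-capture-time simulation design showed the default
at or near the best convergence, with markedly *worse* mode-trapping for
small `γ` (overly local proposals). `α ∈ (0, 1]` tempers the move-2/3 pair
law to lower their acceptance if required; default 1.

**Hyperparameter step.** Joint Gaussian random-walk proposal on
`(log σ_w², log l)` accepted as a block (one likelihood evaluation per
iteration); proposals with `σ_w² ≥ V` lie outside the prior support and are
rejected outright. During burn-in (default: first half of the iterations)
the proposal sds are adapted every 100 proposals — ×1.1 if the windowed
acceptance exceeds 0.5, ×0.9 below 0.45 — targeting acceptance in
[0.45, 0.5]. At the end of burn-in the sds are frozen at the geometric mean
of the adapted values over the second half of burn-in: the window estimates
carry binomial noise of about ±0.05, so the *last* raw sd can sit a step or
two off target, and averaging removes that jitter (in ten seeded runs of
the three-capture-time design this put every post-burn-in acceptance rate
in [0.47, 0.50], versus 7/10 above 0.45 with a raw freeze). No adaptation
happens after burn-in, so the post-burn-in chain is time-homogeneous.

**Initialization.** Starting orders are uniformly random permutations
*within* capture-time blocks (blocks concatenated in capture-time order);
hyperparameters start at prior draws. The restriction speeds convergence
without biasing the sampler and can be disabled.

**Fast path.** With rank-time pseudotimes and fixed hyperparameters
(the simulation-study setting) the covariance does not depend on the
ordering, so its inverse is precomputed once — per gene when gene-specific
generating values are fixed — and each proposal costs one gather plus a
quadratic form. This is what makes 100,000-iteration, 90-cell chains run in
tens of seconds.

## Convergence assessment

Multiple chains (five in the simulation protocol, thinning 10) are compared
with the corrected potential scale reduction factor
`R = sqrt(((d+3)/(d+1)) · V̂/W)`, where `W` is the mean within-chain
variance, `V̂ = (n−1)/n · W + (1 + 1/m) B/n` the pooled variance estimate,
and `d = 2V̂²/var(V̂)` the estimated degrees of freedom of `V̂` (the
sampling-variability correction). The implementation was verified to 1e-15
against the reference R implementation on fixed traces, and an independent
in-test transcription of the formula guards it at 1e-10. Two scalar
summaries are monitored: the log-likelihood and the L1 distance of the
sampled cell positions to a reference permutation (the true order when
known, else the identity), each evaluated at logarithmically spaced sample
counts with the first half discarded; the convergence threshold is the
strict `R̂ < 1.1`. Chains whose traces are constant yield a flagged
undefined `R̂` rather than 1, to avoid declaring a frozen chain converged.

When an anchor (capture times or a marker gene) is available, the reversal
symmetry is folded out *before* computing position distances: any draw
whose positions correlate negatively (Spearman; positions are already
ranks, so only the covariance sign matters) with the anchor is replaced by
its reversal. Without this, the two orientations form two exact mirror
modes of the L1 statistic that no sampler is expected to balance when the
full-reversal move is rare. The log-likelihood statistic is
orientation-invariant and is never affected by the folding.

## Posterior summaries

Pooled post-burn-in, reversal-resolved draws give, per cell: the mean and
sd of its geodesic pseudotime across draws, its rank-frequency distribution
(a row-stochastic cell × rank matrix), and a modal ordering defined by
sorting mean pseudotimes (the exact mode over T! orders being unavailable).
Position vectors of draws can be embedded in 2-D by classical MDS
(double-centred squared-distance eigendecomposition), which exposes
multi-modal posterior structure. A gene-set score (per-cell mean expression
of a chosen set, e.g. a response signature) plotted over mean pseudotime
provides a biological sanity check of the inferred ordering.

## Mini-cluster approximation

For large datasets, cells are first collapsed to k-means centroids computed
separately within each capture time — by default
`max(5, round(n_t/8))` clusters per capture time, squared-Euclidean
k-means with 10 seeded restarts — and the sampler runs on the centroid
matrix (total variance recomputed on centroids, since the likelihood sees
only them). Every cell then inherits its centroid's posterior summary. With
one cell per cluster the centroid matrix equals the data and the pipeline
is bit-identical to the exact method; on a 300-cell synthetic dataset the
approximate per-cell mean pseudotimes correlate with the exact ones at
r ≈ 0.98 while shrinking the sample space from 300! to ~36! orderings.

## Synthetic data

The generator reproduces the three simulation designs used throughout the
tests: `T = 90` cells with latent times uniform on [0, 1], `n_g = 50` genes
whose hyperparameters are drawn per gene as `log σ_w ~ N(0, 0.1²)`,
`log l ~ N(log 0.4, 0.1²)` and `log σ_ε ~ N(log 0.5, 0.1²)` (design 3 uses
`log σ_ε ~ N(0, 0.1²)`, i.e. four times the noise variance); trajectories
are draws from the noise-free kernel plus iid `N(0, σ_ε²)` noise, which is
equivalent to one draw from the full noisy kernel. Capture-time labels are
assigned in blocks along the true time order — three blocks of 30, or 30/60
in the two-capture-time design — and cells are returned shuffled together
with the generating permutation. The printed form of these laws is
ambiguous about whether 0.1 is an sd or a variance; the sd reading is used
because it reproduces the documented convergence behaviour of the
segment-reversal-only protocol, whereas the variance reading (sd ≈ 0.32)
yields occasional deep 2-opt local optima that contradict it.

What the generator deliberately does *not* emulate: count noise and
dropout, library-size effects, branching trajectories, or genes correlated
beyond the shared latent time. Tests passing on these data therefore
establish correctness of the sampler and diagnostics under the model's own
assumptions, not robustness to real scRNA-seq artefacts.

## Numerical choices and degenerate inputs

- Cholesky failures retry with diagonal jitter `1e-10 · trace/T`,
  escalating tenfold to `1e-6 · trace/T`, then raise naming the offending
  hyperparameters.
- Duplicate cells (zero consecutive distance) are legal: `σ_ε² > 0` keeps
  the covariance positive definite. A dataset whose consecutive cells are
  *all* identical has no geodesic mapping and raises a degenerate-data
  error (rank time still works).
- Prior draws reject `σ_w² ≥ V` with a bounded retry budget; exhausting it
  signals a prior inconsistent with the data variance.
- A constant reversal anchor is an error (orientation undefined) with a
  pointer to use a marker gene instead.
- Tie-breaks are deterministic: modal orderings and gene filters break ties
  by index; stable sorts throughout.
- On disk, positions and indices are 1-based; in memory they are 0-based
  numpy indices.

## Protocol sizes used in the checks

The simulation-study checks run at the published design sizes (90 cells,
50 genes, five chains of 100,000 iterations, thinning 10) on three
datasets; the order-recovery and mini-cluster checks use reduced instances
(30 cells/20 genes, and 300 cells/20 genes with two 40,000-iteration
chains) chosen so the whole suite completes in minutes on one CPU while
still exercising every code path at realistic scale.

## Known limitations

- The likelihood is Gaussian on log-transformed data; counts are not
  modelled directly (a negative-binomial likelihood would require latent
  mean sampling).
- Linear trajectories only; no branching.
- Single-move samplers can in principle lodge in deep local modes on
  adversarial data (segment reversal is 2-opt); the recommended default is
  the full move mixture, and multi-chain R̂ is designed to expose exactly
  this failure when it happens.
- The mini-cluster approximation inherits k-means' assumption that small
  clusters are locally homogeneous; with very aggressive reduction the
  within-cluster ordering information is lost by construction.
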