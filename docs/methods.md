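# Methods

## Model and assumptions

`mxlink` treats a multiplex network as `N` shared nodes carrying `M`
undirected, unweighted simple layers with a known one-to-one node mapping
across layers. Input weights and directions are discarded (any nonzero
weight becomes an edge); multi-edges and self-loops are dropped. Nodes
inactive in a layer remain in that layer's `N × N` adjacency as zero
rows/columns — the multiplex node count, not the per-layer active count,
sets every matrix dimension, so eigenvector spaces are directly comparable
across layers.

**Layer similarity.** The q statistic is the mean absolute cosine
similarity of greedily matched eigenvector pairs. The greedy matcher
(largest remaining entry, delete row and column, repeat) is the specified
algorithm, deliberately *not* an optimal assignment: on adversarial inputs
it can fall below the Hungarian optimum, and the test suite pins the greedy
behaviour rather than the bound. All `N` eigenvectors enter q; eigenvector
truncation applies only to prediction.

**Significance testing.** Null models replace one or both layers with
Bernoulli `ER(N, m/(N(N−1)/2))` draws at the real layer's density (not
fixed-edge-count graphs). The null q is assumed normal; its mean and sd are
fitted from `n_samples` draws (default 50) and the p-value is the one-sided
upper tail. Because a parametric tail at z ≈ 30 is an extreme
extrapolation, an add-one empirical estimate `(#{q_null ≥ q}+1)/(n+1)` is
reported alongside; with 50 samples its floor is 1/51 ≈ 0.02, so the two
disagree exactly when the normal tail claims more resolution than 50
samples can support. The three null modes are distinct random variables
(real–random, random–real, random–random) and are mapped as such; the
source formulas for two of the tail probabilities are typographically
identical, and the implementation follows the random-variable definitions
rather than the duplicated print.

**Reconstruction and prediction.** The reconstruction coefficients
`μ_k = x_kᵀ A x_k` are the exact global minimizer of the quadratic
objective (`∂²Z/∂μ_k² = 2`), so no iterative solver is involved. The SPM
self term removes a fraction `p_h` of training links, decomposes the
remainder, corrects the eigenvalues by `x_kᵀ ΔA x_k` while keeping
eigenvectors fixed, and averages the reconstruction over `iterations`
independent perturbation sets. LRM adds one closed-form reconstruction per
auxiliary layer; the perturbed variants reconstruct random
`subsample_fraction` subsamples of the training links and average; the GOR
variant weights each auxiliary term by
`2·|E_α ∩ E_β| / (|E_α| + |E_β|)`. Scores are raw and possibly negative —
every metric downstream is rank-based, so no normalization is applied.

## Parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `n_samples` (null models) | 50 | null draws per mode; the sd of the fitted mean is ≈ sd/√50, small against the effects of interest |
| `p_h` | 0.1 | perturbation fraction of the SPM self term; mirrors the 90%/10% split of the perturbed variants. Not separately prescribed for the self term, hence configurable |
| `iterations` | 10 | perturbation/subsample averages; variance of the averaged score falls ~1/iterations |
| `subsample_fraction` | 0.9 | training links shown per perturbed-LRM iteration |
| `k` | all | leading eigenvectors used in prediction. Sparse, structured layers often do best with small k (1 for hub-dominated transport layers, 10–30 for denser biological layers); `k = all` is the safe default and is required for the exact-recovery guarantee |
| `repeats` | 30 | independent train/probe splits per evaluation point; sd across repeats gives the error bars |
| fraction grid | 0.1 … 0.9 | probe fractions swept by the harness |
| significance level | 0.05 | conventional |

Probe sizes round half-up (`round(f·m)`), so a 10% split of 180 links is
exactly 18. Splits never produce an empty side; configurations that would
are rejected rather than silently clamped.

## Seeding

One master seed drives everything. Child streams derive as
`SeedSequence([master mod 2³¹, crc32(stage), index])`, so the SPM
perturbations, the subsample loop, the auxiliary randomization, the splits
and the null draws are independent streams that reproduce bit-identically,
and per-repeat streams do not shift when an unrelated stage adds draws.

## Synthetic generators

The generators exist so every claim is testable without data downloads:

* `erdos_renyi` / `erdos_renyi_gnm` — Bernoulli and fixed-edge-count ER
  layers; the latter matches printed node/link counts exactly (e.g. a
  69-node/180-link layer), which is what makes the null-model means
  reproducible from published summary statistics alone.
* `backup_duplex` — target plus an untouched identical auxiliary; the
  clean-room setting where all-eigenvector LRM is provably perfect while
  the training set keeps at least `N` links.
* `correlated_duplex` — the second layer rewires a fraction of the first's
  edges at constant edge count, interpolating between identical
  (`rewire_fraction = 0`, q = 1) and independent-like
  (`rewire_fraction = 1`, q statistically at the random–random null).

What they do **not** emulate: degree heterogeneity, clustering, community
structure and the partial node-activity overlap of real multiplexes. ER
layers are the *null* of this framework, so tests built on them demonstrate
the machinery (closed forms, protocols, null calibration) and the
directional value of an informative auxiliary — they do not certify
performance numbers on real heavy-tailed networks.

## Numerical choices

* Eigendecomposition: `scipy.linalg.eigh` (full, dense), eigenpairs sorted
  by descending algebraic eigenvalue with a stable sort; degenerate
  eigenvalues keep the solver's basis; eigenvector signs are arbitrary and
  every consumer is sign-invariant (absolute dot products, outer products).
* Eigen-similarity entries are clipped to [0, 1] to absorb ~1e-16 overshoot
  on unit vectors; this is what makes self-similarity exactly 1.
* Greedy-matching ties break toward the smallest row, then column index
  (numpy's row-major argmax), making the matcher deterministic and q
  transpose-symmetric up to floating-point noise.
* Exact AUC is computed through midranks (Mann–Whitney form), which is
  algebraically the all-pairs average with ties credited 0.5; the
  brute-force enumeration lives in the tests as an independent oracle.
* Ranking ties in precision / average precision break by node-pair
  lexicographic order (stable sort), documented because tie handling
  changes top-L membership.
* An all-zero auxiliary adjacency contributes zero to LRM scores by an
  explicit guard: its eigenbasis is arbitrary, and `x_kᵀ A x_k` in an
  arbitrary basis would make the contribution solver-dependent.
* A perturbation draw of zero links (possible when `p_h·m` rounds to 0) is
  allowed and degenerates to the unperturbed reconstruction.
* Training-graph connectivity is *not* enforced; high removal fractions
  necessarily disconnect layers and the spectrum handles that fine.

## Design choices

* The LRM self term is the SPM average, not the plain self-reconstruction:
  a full-rank reconstruction of the training adjacency in its own basis
  returns the training matrix exactly and carries no information about
  missing links. The plain variant stays available (`self_term="plain"`)
  for completeness.
* The perturbed-LRM auxiliary terms reconstruct the *subsampled* training
  adjacency in the auxiliary basis (the auxiliary eigenvectors reconstruct
  the perturbed layer), with subsamples drawn uniformly without replacement.
* The statsmodels-style surface (`LayerSimilarity.fit()`,
  `MultiplexLinkPredictor.fit()` returning results objects with
  `summary()`) wraps a plain functional layer; both are public, and the CLI
  is a thin shell over the same functions.
* Problem sizes in the tests and the acceptance script are desk-scale by
  design: null reproduction uses the published node/link counts directly
  (61–280 nodes), prediction benchmarks use 20–100 nodes, and the
  random-score AUC average uses 100–400 repetitions, enough to separate
  every asserted effect from Monte-Carlo noise by ≥3σ.

## Known limitations

* Dense `O(N³)` eigendecompositions bound practical layer sizes to a few
  thousand nodes; no sparse/truncated path is provided, and prediction with
  `k < N` still decomposes fully before truncating.
* The normal-tail p-values are extrapolations far beyond the 50-sample fit;
  use the empirical p-value when the distinction matters.
* Interlayer (cross-layer) edges, directed/weighted layers and temporal
  layers are out of scope; unknown node mappings would need a prior network
  alignment step.
* The greedy matcher is quadratic-per-step (`O(N³)` total) and can be
  arbitrarily far from the optimal assignment on crafted inputs; it is kept
  because q is defined by it.
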