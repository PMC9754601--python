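# Methods

## Model and assumptions

The method treats clustering as a normalized-cut partition of a weighted
bipartite graph between the N cells and p ≪ N anchor landmarks. Its core
assumptions are (i) the cell population's geometry is well summarized by
k-means centroids of a uniform subsample — true when clusters are
reasonably compact in the representation given to the algorithm (usually
PC scores), and (ii) cluster structure in the cell-cell similarity graph
survives the rank-p bipartite factorization `W ≈ B D_X⁻¹ Bᵀ`. Under those
assumptions the transfer-cut reduction is not an approximation at all:
the p×p generalized eigenproblem on the anchor side reproduces the full
(N+p)-node spectrum *exactly* (verified against a dense generalized
eigensolver in the test suite), so all the approximation error lives in
the anchor selection and the sparse k-nearest-anchor graph.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `n_anchors` (p) | 1000 | landmarks; the graph is N×p |
| subsample (p′) | 10·p, capped at N | cells seen by anchor k-means |
| `n_neighbors` (k) | 7 | nonzeros per affinity row |
| k′ | 10·k, capped at p−1 | anchor-to-anchor neighbor table width |
| o | round(√p) | anchor-clusters used for query routing |
| `metric` | euclidean | or cosine; used for routing and kernel |
| `k_method` | anchor_graph | or eigengap |
| `resolution` | 1.0 | Louvain resolution (anchor-graph estimator) |
| `alpha` | 4 | gap-threshold rank (eigengap estimator) |

p = 1000 and k = 7 are the defaults that performed best in the
benchmarking that motivated this design; o = √p balances the two
dominant terms of the query cost (routing to o centers vs searching the
average cluster of p/o anchors), giving the O(N√p·d) construction bound.
Datasets with fewer cells than the subsample skip subsampling entirely.

Anchor-selection k-means uses k-means++ with a single restart (one
restart keeps the stated complexity budget; the consensus layer is the
intended remedy for initialization variance). Empty-cluster repair is the
standard relocate-to-farthest-point rule, so exactly p anchors always
come back. Requesting p ≥ N is an error at the operation level; the
estimator clamps p to ⌊N/2⌋ with a warning instead so that default
parameters work on toy inputs (an anchor should summarize ≥ 2 cells).

### Neighbor search details

The candidate set for a cell is `{p⁽ⁱ⁾} ∪ knn(p⁽ⁱ⁾)` — the seed anchor is
included because it is by construction a strong candidate. Distance ties
break toward the lower anchor index (stable argsort), which makes runs
bit-reproducible. Cosine distance is `1 − cos`; zero-norm vectors are
defined to be at distance 1 from everything rather than erroring. When
k′ = p−1 the candidate set is exhaustive and the search is provably
exact; at the default k′ = 10k the measured mean recall on the
well-separated mixture fixtures is ≈ 1.0 (the test suite asserts the
≥ 0.90 contract).

### Affinity kernel

`b_ij = exp(−d_ij² / (2σ_i²))` with σ_i the mean of the k neighbor
distances. The denominator constant is exposed as a single named
parameter (`BANDWIDTH_SCALE = 2.0`); the Gaussian-kernel convention is
adopted so a neighbor at exactly the mean distance always receives
exp(−1/2). A cell coincident with all its anchors (σ_i = 0) gets k unit
weights — the coincident-point limit — never a division by zero. For the
cosine metric the same form applies to the squared cosine distance.

### Eigen-solve

The reduced problem is solved through the symmetric normalized operator
`D_p^{-1/2} W_p D_p^{-1/2}`: its largest-eigenvalue pairs give the
smallest λ = 1 − μ. A dense `eigh` is used unconditionally for p ≤ 200
(robustness over speed at toy scale) and as a fallback (p ≤ 2000) if
ARPACK fails to converge; the ARPACK path uses a fixed constant starting
vector so results are deterministic. λ spuriously ≥ 1 is clipped to
1 − 1e−12 with a warning; tiny negative λ is clipped to 0.
γ = 1 − √(1−λ) picks the root of γ(2−γ) = λ in [0, 1). The first
eigenvector (γ = 0, constant on the anchors) is kept in the embedding;
rows are L2-normalized before the final k-means (k-means++, 10 restarts,
seeded). All-zero embedding rows — a numerical degeneracy never observed
in practice — inherit the majority label of the cells attached to their
nearest anchor. Anchors with an all-zero affinity column are dropped with
a warning before any spectral work.

## Estimating the number of clusters

**Anchor graph (default).** Louvain modularity optimization on `W_p`
(diagonal zeroed) at resolution 1.0, seeded. The anchor graph is the
similarity the method already owns — no new graph construction is needed
— and working on p nodes keeps the estimate stable at any N. A known
limitation, inherited from modularity's resolution limit: a *single*
homogeneous cluster that carries all of the graph's weight is split into
a handful of communities (3–6 measured across fixture sizes), whereas
several well-separated clusters are each kept whole. The estimator is
therefore reliable for multi-cluster data and mildly upward-biased for
degenerate one-cluster data; the eigengap estimator returns 1 in that
case.

**Eigengap.** The min(p, 50) smallest reduced eigenvalues are rescaled
to [0, 1] (making the rule invariant to scaling the spectrum), binned
into 100 equal-width bins, and the gap between each pair of consecutive
non-empty bins is computed as (left edge of the next) − (right edge of
the current) — consecutive *non-empty* bins, because adjacent equal-width
bins touch and their literal edge difference is identically zero. The
threshold Δ_α is the α-th greatest gap (α = 4; the greatest when fewer
gaps exist), ties inclusive. The estimate is the number of eigenvalues at
or before the **first** bin whose following gap meets the threshold: the
near-zero group of the spectrum, matching the connected-components
rationale (a Laplacian has exactly as many zero eigenvalues as the graph
has components). The alternative reading — count everything before the
*last* qualifying gap — is available as `EigengapConfig(select="last")`
but systematically overcounts when only the bottom of the spectrum is
computed: the 50-eigenvalue window samples the bulk so sparsely that it
is full of spurious qualifying gaps (measured K ≈ 36–43 on a 3-cluster
fixture whose correct answer is 3).

## Consensus

Base runs vary three things: the master seed spawns per-run sub-seeds
(`numpy.random.SeedSequence`, so parallel execution with pre-assigned
seeds is bitwise identical to sequential), the metric alternates
euclidean/cosine, and the K-estimator settings cycle through anchor-graph
resolutions 0.5/1.0/1.5 and the eigengap method. M = 5 by default (5–10
is the range that performs well; more runs buy stability, linearly more
time). The N×K_C incidence matrix of the pooled base clusters (empty
clusters dropped; every row sums to M) is partitioned by the identical
transfer-cut code path — the incidence matrix simply stands where the
affinity matrix stood. Consensus K defaults to the median of the base-run
cluster counts, rounded half up; permuting labels inside any base run
only permutes incidence columns and provably cannot change the result.

## Synthetic data

`gaussian_mixture` places G unit-variance isotropic Gaussians on a scaled
regular simplex, so every pairwise centroid distance equals the requested
separation exactly (requires d ≥ G−1); group sizes are near-equal and
rows are shuffled. It emulates what clusterable PC-score data looks like
— compact, convex, isotropic groups — and deliberately not what raw
counts look like. `nb_counts` emulates raw data instead: lognormal
baseline gene means, disjoint per-group DE blocks with a fold-change, and
negative-binomial sampling with variance μ + φμ² (φ = 0.5 default, a
typical droplet-data overdispersion). Consequences for interpretation:
passing tests demonstrate correctness of the algorithmic contracts and
recovery of well-separated structure; they do not demonstrate robustness
to batch effects, doublets, imbalanced rare populations or non-convex
manifolds, none of which the generators produce.

Test and acceptance problem sizes (N up to 5000 for oracle comparisons,
one 100k-cell structural run, p ≤ 1000) are chosen so the full suite
re-runs in well under a minute of compute while still exercising the
sparse code paths at a scale where a dense N×N approach would already be
prohibitive.

## Numerical conventions

- Eigenvector comparisons in tests are made per *simple* eigenpair via
  |cosine| ≥ 1 − 1e−6; eigenvectors inside a degenerate eigenvalue block
  are not individually identifiable and are skipped.
- ARI uses exact integer pair counts (int64, safe far beyond single-cell
  sizes); its degenerate 0/0 case (both partitions trivial) returns 1.
  NMI uses natural logs (the base cancels) with arithmetic-mean
  normalization; a single-cluster partition gives denominator 0 and
  returns 0.
- All randomness flows from one seed through `SeedSequence`-derived
  sub-seeds (< 2³¹), covering subsampling, both k-means stages, igraph's
  Louvain RNG and the final k-means; identical input + seed ⇒ identical
  labels, which the suite asserts bitwise.

## Known limitations

- Anchors from a single k-means restart can under-represent very rare
  populations; raise `subsample_size` or p, or use the consensus variant.
- The anchor-graph K estimator inherits Louvain's resolution limit (see
  above) and its resolution parameter is data-scale sensitive.
- The eigengap estimator needs a visible spectral gap; overlapping
  clusters blur it and the estimate degrades toward 1.
- H5AD input reads only the main matrix and identifiers; layers, obsm
  and raw slots are ignored by design.
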