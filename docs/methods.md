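# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `sparsekm`. Everything empirical stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

The input is a cells-by-genes matrix of nonnegative counts in canonical
compressed-sparse-row form: per row, strictly increasing column indices,
no explicit zeros, duplicates summed (`sparsekm.validate` enforces this;
Matrix Market and binary CSR readers canonicalize on load; Matrix
Market's 1-based indices are converted at the I/O boundary only). Counts
are kept as provided — integer or real — and all divergence arithmetic
promotes to float64.

Gene preselection uses the per-gene population variance of the raw
counts, computed sparsely as `E[X²] − E[X]²` with ties broken toward the
lower column index. This is a deliberately simple, deterministic,
oracle-checkable dispersion score; variance-to-mean or fitted dispersion
scores used by single-cell toolkits would slot in behind the same
interface, and the choice is exposed so they can be added.

## Divergences and the lazy prior

Five measures operate on rows `X, Y` over `d` genes:

| measure | definition | representation |
|---|---|---|
| SQE | `Σ (X_i − Y_i)²` | raw counts |
| KLD | `Σ X̂_i ln(X̂_i/Ŷ_i)` | probability |
| JSD | `½[KLD(X̂, M) + KLD(Ŷ, M)]`, `M = (X̂+Ŷ)/2` | probability |
| BATMET | `sqrt(1 − Σ sqrt(X̂_i Ŷ_i))` | probability |
| COS | `1 − X·Y / (‖X‖‖Y‖)` | raw counts |

with `X̂_i = (X_i + β)/(S + dβ)` under a Gamma(β, β) pseudo-count prior
(β > 0; β = 1 is the Dirichlet/add-one case). Logarithms are natural, so
`0 ≤ JSD ≤ ln 2`. Without a prior, probability measures require strictly
positive row sums and raise `DegenerateInputError` otherwise — an
infinite or undefined divergence is never produced silently.

A prior-adjusted row is a constant baseline `β/(S + dβ)` plus sparse
corrections on its support. A pairwise distance therefore needs only the
union of the two supports; the shared-zero genes contribute one
closed-form term, e.g. `(d − |union|) · b_X ln(b_X/b_Y)` for KLD. This
is the package's central performance contract, checked two ways: lazy
evaluation agrees with full densified-formula evaluation to 1e-10
relative across measures, β ∈ {0.01, 1} and d ∈ {10, 10³, 10⁵}
(in practice the worst observed error is ~1e-13), and an instrumented
entry-touch counter stays below 100·nnz at d = 10⁵, nnz = 10.

Design notes:

* **COS and SQE ignore the prior.** The prior exists to repair zeros for
  probability measures; cosine and squared Euclidean are well defined on
  raw counts. A zero row has cosine distance 1 to everything.
* **BATMET** is the metric form `sqrt(1 − BC)` of the Bhattacharyya
  coefficient `BC = Σ sqrt(X̂ Ŷ)`, clamped at 0 against floating
  negatives. It satisfies the triangle inequality (spot-checked on random
  triples), as does `sqrt(JSD)`. Near-identical rows push `BC → 1`, where
  the square root amplifies summation roundoff; comparisons of BATMET
  values near 0 should use absolute tolerances around 1e-8.
* **JSD forms the mixture from the prior-adjusted vectors** `M = (X̂+Ŷ)/2`
  (rather than adjusting after mixing); the two orders differ at O(β).
* **Row-to-center distances.** Centers are dense vectors in the measure's
  working representation. SQE, COS, KLD and BATMET need one aggregate per
  center (`‖c‖²`, `Σ ln c_i`, `Σ sqrt(c_i)`), after which a sparse matvec
  prices all rows in O(nnz + d) total. JSD's off-support terms couple a
  row's baseline with every center entry, so no per-center closed form
  exists; row-to-center JSD is evaluated exactly on memory-bounded
  densified row blocks (~32 MB per block). The pairwise O(nnz) path is
  unaffected.

## Weighted sampling kernel

Sampling `m` of `n` items without replacement, proportional to weights,
is done by assigning keys `−ln(u_i)/w_i` (`u ~ U(0,1)`; the stable form
rather than the equivalent `u^{1/w}`) and keeping the `m` smallest via a
bounded max-heap: a candidate enters only if it beats the heap ceiling,
so updates become rare as the scan proceeds. Zero weights map to `+inf`
keys rather than being filtered, preserving index alignment — cost arrays
legitimately contain zeros for points that coincide with centers. An
all-zero weight vector raises `NoMassError`.

Randomness comes from counter-based Philox generators with named streams
(`stream_rng(seed, stream)`); partial samples built per index range with
range-keyed streams merge into a result that is identical however the
ranges are scheduled across workers. Exactness is verified against
probabilities enumerated over all ordered sequential draws (chi-square,
α = 0.01, 2·10⁵ draws per weight vector). Statistical tests at fixed
seeds carry a single retry on an independent stream, so a contract
failure requires two consecutive rejections (~10⁻⁴ false-positive rate
under the null) rather than the GOF test's native 1%.

## Seeding and refinement

**k-means++**: first center uniform among rows; each subsequent center
sampled with probability proportional to the current cost (distance to
the nearest chosen center); per-row costs are elementwise minima across
steps, hence monotone. The greedy variant draws `1 + floor(log2 k)`
candidates per step (configurable) and keeps the one minimizing the
would-be total cost. If fewer distinct rows than `k` exist, remaining
centers are duplicated with a warning rather than failing. The expected
`O(log k)` guarantee is exercised on a 40-point one-dimensional instance
whose 3-means optimum is computed exactly — optimal SQE clusters of
sorted 1-D data are contiguous, so enumerating all C(39,2) contiguous
partitions is exhaustive; mean seeding cost over 500 seeds sits well
inside the `8(ln k + 2)` bound and far below uniform seeding.

**localsearch++**: each round samples one candidate row `z ∝ cost`
through the sampling kernel, evaluates replacing each center with `z`,
and applies the best swap only on strict improvement (ties rejected),
guaranteeing a nonincreasing objective and termination. One candidate
per round keeps each round's work at one rows-to-center pass plus
O(nk). The implementation keeps the full (n, k) row-by-center distance
matrix — the same O(nk) memory class as the best/second-best pair that
would suffice, but exact and simple after swaps; swap evaluation uses
`min(second-best where assigned to the removed center, else best, d_z)`.
Each accepted swap is audited in tests against exhaustive single-swap
enumeration on 20-point instances, for every measure.

## Lloyd and mini-batch k-means

Assignment always uses the active measure, ties to the lowest center
index. Center updates are arithmetic means in the working
representation: for Bregman divergences (SQE, KLD) the mean is the exact
right-centroid minimizer, so the cost trace is nonincreasing (asserted
per iteration in tests); for JSD and BATMET the mean is the standard
practical surrogate and the trace is recorded but not asserted monotone;
for COS, averaged unit vectors are re-normalized. Probability-space
means are computed sparsely: row `i`'s probability vector is baseline
`β/N_i` plus sparse `X_ij/N_i`, so a group mean is a mean baseline plus
a sparse row mean. Empty clusters are reseeded deterministically to the
rows with the largest current cost. Lloyd stops when the relative cost
change drops below `tol` (default 1e-4) or at `max_iter` (default 100);
the final step is always an assignment, so results are a fixed point of
reassignment.

Mini-batch k-means draws uniform batches without replacement within the
batch (default size 10,000, clamped to n with a warning) and updates each
touched center with the streaming rate `1/N_c`, `N_c` the cumulative
count of batch points ever assigned to `c`; a whole-dataset batch
therefore reproduces one Lloyd update exactly (asserted to 1e-10). The
full-data objective is evaluated at each epoch end (default 10 epochs);
empty centers are reseeded there. Uniform (not importance-weighted)
batch sampling is used; COS centers are kept un-normalized during
streaming — assignment is scale-invariant — and normalized on output.

## Evaluation

The Adjusted Rand Index is computed from the contingency table in the
Hubert–Arabie form `(Index − Expected)/(Max − Expected)`. The degenerate
case `Max = Expected` (e.g. both labelings a single cluster) returns 0
by convention so trivial clusterings are not rewarded; note scikit-learn
returns 1 there. Verified against brute-force pair counting on
enumerated small labelings, and chance correction verified as mean ARI
within ±0.02 of 0 for independent random labelings (n = 1000, 5
clusters, 200 replicates).

## Synthetic fixtures

The generator plants `k` cluster gene-profiles `p_c ~ Dirichlet(α·1_d)`
and draws each cell `Multinomial(total, p_c)`. Defaults (100 cells per
cluster, d = 200, k = 5, α = 0.1, total = 500) give sparse matrices with
realistic per-cell library sizes at test scale. `α` is the separation
knob (recovery difficulty is monotone in it — asserted in tests);
`disjoint=True` plants clusters on disjoint gene blocks, the
infinite-separation limit where every measure must recover labels
exactly; `total_sigma` draws lognormal library sizes; `overdispersion`
re-draws each cell's probabilities from a Dirichlet around its cluster
profile (extra-multinomial noise). The multinomial default matches the
probability-vector view the divergences assume. What the generator does
*not* emulate: doublets, ambient RNA, batch effects, gene-gene
correlation within a cluster, or zero inflation beyond the multinomial —
so passing tests demonstrate algorithmic correctness and recovery on
well-specified mixtures, not performance on real tissue atlases.

## Scales used in the checks

The reference pipeline settings (k = 25, batch 10,000, 25 localsearch++
rounds, prior 0.01, 500 variable genes) are the package defaults.
Correctness checks run on planted mixtures sized for exhaustive or dense
oracles: pairwise-divergence audits up to d = 10⁵; mini-batch-vs-Lloyd
fidelity on 2000×200 with k = 5, batch 256 (within 5% of Lloyd's cost
and ARI ≥ 0.9 in the median over 20 seeds); full-pipeline recovery on
600×600 mixtures (ARI ≥ 0.95 well-separated; exactly 1 on disjoint
supports). `scripts/acceptance.py` re-runs these end to end from a
single seed.

## Known limitations

* Itakura–Saito divergence is not implemented (a natural extension of
  the Bregman family used here).
* No memory-mapped backing; matrices are held in RAM (scipy CSR).
* Execution is single-process; the named-stream contract makes results
  independent of worker count, and the `--threads` flag is accepted for
  interface stability but does not change behavior or results.
* Lloyd monotonicity is guaranteed (and asserted) only for Bregman
  measures; JSD/BATMET traces can in principle tick upward.
* `k` greater than the number of distinct rows yields duplicated centers
  with a warning, not an error.
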