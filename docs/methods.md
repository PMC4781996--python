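# Methods

This note documents the statistical model behind `scnet`, the choices made
where conventions genuinely diverge, and what the synthetic cohorts do and
do not establish about real data.

## The analysis in one paragraph

Structural covariance networks treat brain regions as nodes and the
across-subject correlation of a regional morphometric feature (cortical
thickness, sulcal depth, ...) as the basis for edges. For each group
separately, `scnet` regresses every region on nuisance covariates, shrinks
the residual covariance, converts it to partial correlations, thresholds to
a binary graph at each sparsity in a sweep, and summarizes each graph by
clustering coefficient, characteristic path length, small-world indices
against degree-preserving random nulls, and betweenness-based hub scores.
Group differences are assessed by permuting the group labels and re-running
all of the above, because the networks are group-level objects with no
subject-level replicates.

## Covariate residualization

Each region's values within a group are replaced by OLS residuals of
`y ~ 1 + age + gender + total_feature`, where `gender` is a 0/1 dummy and
`total_feature` is the subject's whole-cortex value of the measure (row sum
by default; mean optional — the field is not consistent about which
"total" to use, and the choice only rescales the covariate). Choices:

* **Intercept always included.** Without it residuals are not centered and
  every downstream correlation is distorted.
* **Per-group fits by default.** Fitting each group separately prevents
  between-group mean differences from leaking into the within-group
  covariance; `pooled=True` provides the alternative reading, since
  published descriptions frequently leave this ambiguous.
* **Rank deficiency.** A covariate constant within the fitted rows (e.g. a
  single-gender permuted subgroup) is dropped with a warning rather than
  silently producing an unstable fit.

## Ledoit-Wolf shrinkage

With n = 36 subjects and p = 148 regions the sample covariance S is
singular, so the estimate used is the convex combination

    Sigma = (1 - a) S + a mu I,    mu = trace(S) / p,

with `a` the Ledoit-Wolf optimal intensity (the ratio b²/d² of estimated
dispersion terms under the normalized Frobenius inner product), clipped to
[0, 1]. S uses the 1/n convention, matching the original estimator. The
scaled identity is the standard target; when the true covariance happens to
equal the target the optimal intensity approaches 1, which is correct
behavior, not a failure mode. Any a > 0 makes Sigma positive definite for
non-degenerate input, which is what the partial-correlation step needs.
The implementation is cross-checked in the test suite against
scikit-learn's independent implementation to 1e-10.

## Partial correlation and thresholding

With precision Omega = Sigma^-1, the partial correlation is
`-Omega_ij / sqrt(Omega_ii Omega_jj)`, diagonal set to 1. Binarization at
sparsity s keeps the top `floor(s * p(p-1)/2)` region pairs ranked by
absolute partial correlation — absolute by default because structural
covariance edges are conventionally retained by magnitude; a positive-only
mode is available. Rounding uses floor; ties at the cutoff resolve to the
lexicographically smaller region pair, so the graph is a deterministic
function of the association matrix (reproducibility is worth more than
statistical purity at a measure-zero event). Because ranking is fixed
across the sweep, the 31 default graphs (5% to 35%, step 0.01) are nested
by construction. Sparsities below the point where the edge budget reaches
zero are rejected rather than returning an empty graph.

## Graph metrics

* Degree: row sums.
* Clustering: `C_i = 2 e_i / (k_i (k_i - 1))`, with `C_i := 0` when
  `k_i < 2` (the formula is 0/0 there); the network value C averages over
  all N nodes, including isolated ones.
* Path length: BFS distances; `L_i` averages over the nodes reachable from
  i, and L averages `L_i` over nodes with at least one reachable partner.
  Unreachable pairs are excluded, never imputed, and their count is
  reported so the policy is visible. A printed-formula variant that
  divides each node's distance sum by N instead of the number of terms is
  available as `divide_by_n=True`; it understates L by (N-1)/N on
  connected graphs and exists for comparability only.
* Betweenness: fractional (Brandes) counting over unordered pairs with
  endpoints excluded — the ratio-of-geodesics definition. Computed via
  networkx; an exhaustive simple-path enumeration oracle in the tests
  verifies it (together with the other metrics) on every connected graph
  with up to 7 nodes. Normalized betweenness is `bc_i = BC_i / mean(BC)`;
  hubs are `bc_i > 2`, strictly. When every BC is 0 (complete graphs), bc
  is undefined and no node is a hub.

## Null models and small-worldness

Surrogates are Maslov-Sneppen double-edge swaps: pick two edges, swap
endpoints, reject self-loops and duplicates. This preserves the exact
degree sequence — the stricter reading of "same degree distribution" — and
10 successful swaps per edge (configurable) is the conventional mixing
budget. Surrogates are not forced connected; their path length uses the
same unreachable-pair exclusion as the real graph. Ensemble seeds are
spawned from one seed sequence, so results are reproducible and
independent of evaluation order. gamma = C/C_rand, lambda = L/L_rand,
sigma = gamma/lambda, with sigma > 1 flagged small-world. Degenerate
ensembles with zero mean clustering yield gamma = +inf with an explicit
flag instead of an exception. The default ensemble size is 1000; tests and
the acceptance script use 100, where the Monte-Carlo error on sigma is
already at the percent level for 100-node graphs.

## Permutation testing

Labels are permuted with group sizes fixed; for every permutation the
entire pipeline is re-run — including the per-group covariate fits, since
relabeling changes them. Observed and null statistics go through literally
the same function (asserted in the tests), so no processing asymmetry can
bias the test. Critical values are the 5th and 95th percentiles (linear
interpolation) of the null differences: two one-tailed 5% tests, reported
separately, matching the convention of reporting increases and decreases
without multiplicity correction — with N nodes per tail, about 0.05*N
null-true flags are expected, and the nodal difference map keeps that
visible. `n_perm` below 20 is refused because the 95th percentile of fewer
draws is noise. A `fast_permute` mode shuffles precomputed residual rows
instead of re-fitting covariates per permutation; it is cheaper and
usually close, but its null ignores the label-dependence of the covariate
fits, so the full recomputation is the default. The demographic tests are
classic pooled-variance two-sample t-tests with dummy-coded two-level
categoricals.

## Synthetic cohorts

The generator draws subject feature vectors from a multivariate normal
with a block-community covariance (equicorrelated within blocks), plus
linear age and gender effects and i.i.d. residual noise, then adds an
optional group-B mean shift and/or within-block correlation change.
Defaults mirror the study design the package targets: 36 subjects per
group, 148 regions, ages uniform on [55, 80] years, gender Bernoulli(0.5),
within-block correlation 0.3 against an 0.05 background — a covariance
strength typical of regional morphometry once global effects are removed.
`total_feature` is computed from the generated regions (sum by default).

What the synthetic model deliberately omits: spatial autocorrelation on
the cortical sheet, heavy-tailed or skewed feature distributions,
site/scanner effects, hemispheric asymmetries, and any realistic anatomy
behind the block structure. Passing tests therefore establish that the
pipeline's statistics behave correctly for Gaussian data with known
second-moment structure — calibrated type-I error, power against a
covariance effect, exact metric values — not that any particular clinical
contrast is detectable in real MRI cohorts.

## Numerical choices

* Sparsity grids are built with a rounded arange so accumulated float
  error cannot change the number of sweep points, and the edge budget adds
  a 1e-9 epsilon before flooring so an exactly-integral s*E is not
  truncated by binary representation error.
* Covariance inversion uses LAPACK through `numpy.linalg.inv`; singular
  input raises with a pointer to the shrinkage intensity rather than
  returning NaNs.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; ensembles use `SeedSequence.spawn` so per-surrogate streams
  are independent and reproducible.

## Problem sizes in the shipped checks

The test suite and acceptance script run the pipeline at study scale
(36 + 36 subjects, 148 regions) for single-network quantities, and at a
reduced scale (40 regions, 100-200 Monte-Carlo repetitions, 100-200
permutations) for the calibration studies, chosen so the full suite
completes in minutes while keeping the binomial error on rejection rates
near one percentage point. The permutation machinery is identical at every
scale; only the loop counts differ.

## Known limitations

* Only the scaled-identity shrinkage target is implemented; graphical
  lasso or other sparse precision estimators are out of scope.
* Graphs are binary and undirected; weighted analyses are not supported.
* No multiple-testing correction beyond the reported expectation, by
  design fidelity to the reference procedure.
* The permutation test's full recomputation is O(n_perm) pipeline runs;
  at 148 regions with n_perm = 1000 and the whole 31-point sweep this is
  minutes of CPU, and `fast_permute` trades exactness for speed.
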