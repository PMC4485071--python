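# Methods

This note documents the models, conventions and numerical choices behind
`netconnkit`, in the spirit of a statistical software methods appendix.

## Preprocessing

Time series are T x P matrices (time by units) with a sampling interval
`dt` in seconds. Steps are pure functions composed in caller-chosen order;
the pipeline default is remove -> detrend -> band-pass -> regress, the
order used in typical resting-state analyses.

- **Volume removal** supports both "delete the first n" and "retain the
  last n" modes (the latter matters for pooling acquisitions of different
  lengths); they coincide when n_retain = T − n_delete.
- **Detrending** removes a least-squares polynomial of configurable order
  per column (order 0 = demean, order 1 = linear drift, default 1). The fit
  uses a normalized-time Vandermonde basis purely for conditioning; the
  residual is orthogonal to every monomial up to the requested order.
- **Ideal band-pass** zeroes FFT amplitude outside the closed band
  [f_low, f_high]. A bin is kept iff its exact frequency lies in the band —
  no snapping — and the DC bin is kept only when f_low = 0. The filter is a
  projection (idempotent) and exactly linear; tones on pass-band bins are
  untouched, stop-band tones are annihilated to rounding error.
- **Nuisance regression** computes OLS residuals against [1 | regressors]
  per column. Constant regressor columns would duplicate the intercept and
  are dropped before fitting, so a constant covariate behaves exactly like
  no covariate; any remaining rank deficiency is an error. The
  24-parameter motion expansion is [m, m², m_lag, m_lag²] with a one-step
  backward shift zero-padded at the first row (the common backward-
  difference convention for motion derivatives).

## Connectivity

Pearson correlation with the diagonal forced to zero; columns with (up to
rounding) zero variance are reported by index rather than silently
producing NaN. Sliding windows start at 0, S, 2S, ... giving
floor((T − W)/S) + 1 windows. Group averaging goes through Fisher's
r-to-z (atanh) with |r| clipped to 1 − 1e−7, the arithmetic mean in z, and
tanh back.

Voxel-wise degree maps classify every pair (i, j), i ≠ j, by distance
(short: d ≤ d0; long: d > d0; full: all — Euclidean mm between voxel
centers), by sign (positive: c > r0; negative: c < −r0; absolute:
|c| > r0; all strict), and by type (binary counts peers, weighted sums
|c|), giving 18 maps; the 6 connectivity-strength maps are the full-range
slice. Default thresholds: r0 = 0.2 (a conventional low-correlation
cutoff) and d0 = 75 mm. The correlation matrix is traversed in row blocks
so P ~ 1e4–1e5 voxels never require the full P x P matrix in memory; block
rows are computed as per-voxel vector products rather than a blocked
matrix product, which keeps the output bit-identical for any block size
(BLAS matrix kernels may re-associate sums).

## Graph construction

Members first, thresholds second: the positive member keeps positive
correlations, the negative member keeps |negative| correlations, the full
member takes |c|; thresholding then operates on a nonnegative matrix.
Strength thresholding is strict (w = |c| if |c| > r_thr). Sparsity
thresholding keeps the E* = round(s·N(N−1)/2) strongest edges
(round-half-away-from-zero for platform-stable counts) with a
deterministic tie-break at the cutoff: descending |c|, then ascending
(i, j). Zero entries are never edges, so very sparse matrices may yield
fewer than E* edges.

## Metrics

Edge lengths are 1 (binary) or 1/w (weighted) — connectivity must be a
similarity for the reciprocal to make sense. All-pairs shortest paths use
Floyd–Warshall above 10% density and Johnson's algorithm below, matching
the classic dense/sparse trade-off; the two agree to rounding and the
switch is tested explicitly.

- **Clustering**: Watts–Strogatz for binary graphs; Onnela's
  geometric-mean triangle intensity for weighted graphs with weights
  rescaled by the graph maximum (keeps C_i in [0, 1]). Nodes with degree
  < 2 contribute C_i = 0 — included, not excluded, so the denominator
  stays N across thresholds.
- **Lp** is the harmonic-mean characteristic path length
  N(N−1)/Σ 1/d_ij with 1/∞ = 0, finite under disconnection; **Eg** is its
  reciprocal by construction (Lp·Eg = 1 whenever both are finite), and
  **Eloc_i** is Eg of the neighbor-induced subgraph with inherited
  weights, 0 for degree < 2.
- **Modularity** reports Newman's Q for the partition found by
  deterministic greedy agglomeration (CNM): start from singletons, always
  merge the connected pair with the largest ΔQ (ties: smallest community
  index pair), run to a single community and return the best partition
  passed. The Q formula is exact for any partition; the optimizer is a
  heuristic and is validated against exhaustive partition search on small
  graphs as a bound, not as an optimality guarantee.
- **Assortativity** is the Pearson correlation of endpoint degrees over
  all edges counted in both orientations; weighted graphs use strengths
  with each edge term weighted by its connection weight (Leung–Chau).
  When every edge joins the same unordered degree pair (stars, regular
  graphs, regular bipartite graphs) the two-point distribution makes the
  correlation vacuous and the metric signals undefined instead of
  reporting the degenerate ±1.
- **Hierarchy** is minus the least-squares slope of log C_i on log k_i
  (natural logs; the base cancels) over nodes with binary degree ≥ 2 and
  C_i > 0; weighted graphs pair the weighted C_i with the binary degree.
  Fewer than two eligible nodes, or all-equal degrees, signal undefined.
- **Synchronizability** is lambda_2/lambda_max of L = D − A (strength
  diagonal for weighted graphs); disconnected graphs (lambda_2 = 0)
  signal undefined.
- **Betweenness** uses Brandes' accumulation (BFS for unit lengths,
  Dijkstra with reciprocal-weight lengths otherwise) and is reported
  unnormalized; normalization by (N−1)(N−2)/2 is an option.
- **AUC** is the trapezoid rule over the threshold grid; intervals
  touching an undefined (NaN/inf) value are skipped with a warning count
  rather than interpolated.

Undefined metrics raise a dedicated signal at the function level and
become NaN in tables, never fabricated numbers.

## Null models

Degree-preserving randomization is the Maslov–Sneppen double-edge swap:
pick edges (i1,j1), (i2,j2), rewire to (i1,j2), (i2,j1) when this creates
no self-loop or multi-edge. "2 x the number of edges" is interpreted as 2E
*successful* swaps — this guarantees the stated amount of mixing — with an
attempt cap of 100E and a warning when the cap is hit (e.g. complete
graphs admit no legal swap and are returned unchanged). Weighted graphs
carry each weight with its moved edge: the degree sequence and the weight
multiset are preserved exactly, the strength sequence is not. Ensemble
member k uses seed master + k, so ensembles regenerate bit-identically.

Phase randomization keeps each column's FFT amplitude spectrum (hence its
periodogram and circular autocorrelation) and randomizes phases:
independent uniform draws per column (destroys cross-column correlation;
the default surrogate for connectivity null testing) or one shared
rotation per bin (preserves relative phases and thus zero-lag
cross-correlation).

Small-world ratios: gamma = Cp/⟨Cp_null⟩, lambda = Lp/⟨Lp_null⟩,
sigma = gamma/lambda. Metrics undefined on some nulls are averaged over
the nulls where they are defined.

## Statistics

All tests are two-sided. Covariates of no interest are residualized out
against [1 | covariates] before group tests; the one-sample test with
covariates instead tests the OLS intercept (residualizing would zero the
tested mean identically). The repeated-measures ANOVA is the two-level
additive condition + subject model with F on the condition effect; richer
within-subject designs are out of scope.

NBS: edges with |t| above the primary threshold form a graph; connected
components are measured by extent (edge count — the default) or by
intensity (Σ over component edges of |t| − threshold). Significance comes
from permuting group labels (or flipping signs for one-sample designs)
and rebuilding the maximal component statistic, with
p = (1 + #{null max ≥ observed}) / (1 + n_perm) — never zero. Because the
extent statistic is a small integer, its permutation distribution has
heavy ties and the resulting familywise error rate is strictly
conservative (measured ≈ 0.025–0.035 at a nominal 0.05 in the calibration
simulations); the continuous intensity statistic removes the ties and is
near-exact (measured 0.044 over 2000 independent null replicates, 0.046
on iid Gaussian edge data). The calibration harness therefore exercises
the intensity statistic; extent remains the default for analysis use, as
in the original method.

## Synthetic data

The generator draws T x N Gaussian blocks with a block (modular) target
correlation — within-module rho_in = 0.6, between-module rho_out = 0.1
over four equal modules by default — via the Cholesky factor, then colors
all columns with the same AR(1) filter (phi = 0.3; identical filtering
preserves zero-lag cross-correlation, and the output is rescaled to unit
stationary variance), then adds white measurement noise (SD 0.1) and
optionally a linear drift spanning ±amplitude. Defaults mirror a typical
resting-state block: 200 time points at dt = 2 s, 20 regions. The spatial
structure is applied before the temporal coloring; the order matters for
spectra and is fixed deliberately.

Two-group datasets raise group 2's target correlations by delta_rho on a
chosen edge set (positive-definiteness checked) and push every subject
through an independent spawned random stream — subject streams are
independent across subjects *and* across nearby master seeds, which the
error-rate simulations rely on — followed by the ordinary Pearson
estimator, so planted effects pass through the same estimation noise as
real data.

What the generator does *not* emulate: hemodynamics, motion artifacts,
physiological noise spectra, spatial autocorrelation of voxels, or
heavy-tailed BOLD noise. Passing tests demonstrate correctness of the
algorithms under the stated statistical model, not robustness to every
property of real recordings.

The default fixture seed is 20150630; fixture graphs (complete, path,
star, ring lattice, bridged cliques, Watts–Strogatz, Erdős–Rényi)
regenerate bit-identically and carry their analytic metric values.

## Problem sizes and determinism

The shipped test suite and the acceptance script run at deliberately small
sizes chosen to estimate each quantity well: metric/oracle equivalence on
all non-isomorphic graphs with N ≤ 5 plus 500 random graphs with N ≤ 7;
null-model harness on Watts–Strogatz (N = 100, K = 6, p = 0.1) with 100
nulls and 20 replicates; type-I calibration with 1000 t-test replicates
and 500 NBS replicates of 1000 permutations each (10 regions, 10–15
subjects per group). Every random quantity derives from an explicit seed;
pipeline runs embed the config hash and seed in a sidecar file, reruns are
byte-identical, and parallel per-subject execution reduces results in
subject order so it matches serial output exactly.

## Known limitations

- The CNM modularity optimizer can land in local optima on degenerate
  modularity landscapes; Q values are exact for the returned partition.
- Weighted hierarchy and synchronizability have no universally agreed
  definition; the conventions above (weighted C with binary k; strength
  Laplacian) are explicit choices.
- The Dijkstra tie tolerance for equal-length weighted paths is 1e−14;
  adversarially constructed near-ties in betweenness could differ from
  exact rational arithmetic.
- `.mat` input is restricted to files containing exactly one plain numeric
  2-D array.
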