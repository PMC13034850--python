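# Methods

## The model

Let `x_1..x_n ∈ R^D` be the original data, assumed to lie near a
d-dimensional manifold, and `y_1..y_n ∈ R^d` an embedding produced by an
arbitrary method that is treated as a black box. An ideal embedding would
be an isometry of the manifold; real embeddings warp it. The object we
estimate at every point is the dual `H_i` of the embedding's pushforward
Riemannian metric: a symmetric PSD d × d matrix whose eigenvectors `v_j`
are the principal directions of distortion and whose eigenvalues `λ_j`
are squared linear stretches (a map that dilates one axis by s gives
λ = s² along it; isometry gives `H_i = I`). The inverse `G_i = H_i⁻¹` is
the pushforward metric itself: `G_i (y' − y_i)` restores original-space
directions and lengths of short segments at `y_i`.

## Estimator

1. **Neighborhood graph.** Exact Euclidean radius graph on the original
   data (block-wise search; ties at equal distance resolved toward the
   lower index so output is deterministic and order-independent). k-NN
   graphs are supported, but metric estimation defaults to radius graphs,
   which keep the kernel truncation unbiased. The default radius is
   r = 3 × the mean neighbor distance of a k-NN graph (k = 10 unless
   stated), and r is expected to sit in the [3ε, 10ε] band of the kernel
   width ε — outside it a warning is logged.
2. **Kernel.** `K_ij = exp(−‖x_i − x_j‖²/ε²)` on stored edges, 0
   elsewhere, `K_ii = 1`. Default ε = r/3. `select_epsilon(points, k)`
   instead picks ε so that the mean row sum of K over a radius graph with
   r = 3ε equals k (bisection on log ε between the smallest nonzero
   nearest-neighbor distance and the data diameter; row sums are monotone
   in ε; default tolerance 0.05·k).
3. **Geometric Laplacian.** Density renormalization `W = D⁻¹ K D⁻¹` with
   `D = diag(rowsums K)`, row normalization to a Markov matrix P, and
   `L = (4/ε²)(P − I)`. This is the α = 1 renormalized construction whose
   limit is the Laplace–Beltrami operator regardless of sampling density;
   the 4/ε² constant matches the `exp(−d²/ε²)` kernel convention (so
   `L f → Δf`, verified against a finite-difference oracle in the tests).
4. **Local metric.** The centered second-moment (carré du champ) form
   `H_i = ½ Σ_j L_ij (y_j − y_i)(y_j − y_i)ᵀ`, algebraically equal to
   applying L to coordinate products but numerically stabler. Spectra are
   sorted descending with near-ties (relative gap < 1e-9) ordered by
   eigenvector angle and canonical signs, which stabilizes eigenvector
   tracking across hyperparameter grids. `G` uses a pseudo-inverse with
   eigenvalue floor 1e-10.

Two bandwidths coexist: the kernel width and the `4/ε²` rescaling. They
default to the same value, which makes the estimator consistent — on a
900-point flat grid with the identity embedding the interior mean
`‖H − I‖_F` is ≈ 1e-3, and a diag(2,1) stretch is recovered with eigenvalue
ratio 4.000 — but the rescaling is exposed separately because published
analyses also use it as a free output scaling.

**Post-processing.** `truncate_singular_values` clips λ at a cap (default
workflows use 5) and reports how many samples were affected;
`normalize_metrics` divides every H by `s = (1/4n) Σ_i Σ_kl H_i[k,l]`.
The sum runs over all d² signed entries exactly as the convention is
stated; s ≤ 0 is reported as a diagnostic error rather than silently
flipped (conceivable when large negative off-diagonals dominate the
trace). Cost is one kernel evaluation per edge and ~d² work per edge for
H, so the whole pass is linear in the edge count; the batched
eigendecompositions are d³ per point.

## Fragmentation screening

The screen works on D = {(‖x_i − x_j‖, ‖y_i − y_j‖)} over neighbor edges,
deduplicated to unordered pairs so symmetric duplicates do not
double-weight stratum statistics (a directed mode exists for comparison
with tools that count both directions). Self-pairs are excluded
throughout — they can never be outliers, so they would only dilute
fractions.

* **Bin strategy.** L equal-width bins over original distance,
  `w = (d_max − d_min)/L`, last interval closed; within a bin a pair is
  outlying when its embedding distance leaves `median ± σ·IQR`. This
  interval is deliberately median-centered — distinct from Tukey's
  quartile-anchored whiskers, which the boxplot display uses; both are
  implemented in their own contexts and a regression test pins the
  difference. Bins with < 4 pairs are marked low-support (IQR computed
  anyway); a bin whose embedding distances are all equal has IQR 0 and
  flags anything off the median.
* **Window strategy.** Per pair, the window is its Δ nearest pairs by
  original distance (ties toward the lower record index, the pair itself
  included), same median ± σ·IQR rule. Smoother boundaries, O(PΔ) after
  one sort.
* **Centers.** A point is a fragmented-neighborhood center when at least
  a fraction κ of its neighbor pairs are outlying; the denominator counts
  stored neighbors (self excluded). κ = 0 flags every point that has
  neighbors. `kappa_sweep` recomputes counts over a κ grid (weakly
  decreasing by construction).

Quantiles use numpy's linear-interpolation convention everywhere,
including the brute-force oracles the tests compare against.

## Isometrization

`H* = Σ_j w_j H_j` with Gaussian weights `w_j ∝ exp(−‖y_j − m‖²/ε₂²)`
normalized to 1; the transform `ỹ = (H*)^p (y − m) + m` is blended as
`k_ε₁(y, m)·ỹ + (1 − k_ε₁(y, m))·y`. The exponent p is a parameter with
default −1/2: because λ carries *squared* stretch, (H*)^(−1/2) is the
distance-correcting choice, while (H*)⁻¹ (also implemented) applies the
full dual metric and overcorrects lengths; both conventions circulate and
neither is asserted as canonical. Default bandwidths ε₁ = ε₂ = 0.1 × the
embedding diameter (visually local; overridable). Degenerate cases: all
averaging weights underflowing falls back to the nearest point's H with a
warning; a singular H* is regularized before inversion with a warning.
When H* is exactly the identity the transform returns the input bitwise
(the blend of equal endpoints is short-circuited to avoid round-off).

Views can be frozen; export of corrected coordinates plus ellipse
geometry requires a frozen view, mirroring an interactive
freeze-then-export workflow. Link selection for focus-plus-context
queries is pure filtering: flagged centers within δ of the query, each
linked to its k nearest original-space neighbors.

## Sensitivity analysis

`expand_geoms` builds one geometry per cell of a full-factorial grid of
radius factors × rescaling values (the joint-vs-one-at-a-time question is
resolved as full factorial; one-at-a-time slices are extractable). Per
cell the kernel width follows the ε = radius/3 default, so the radius
axis probes truncation error while the ε axis probes output rescaling.
Because P − I depends only on the radius and the rescaling is a scalar,
each radius's Markov matrix is factored once and reused — per-cell
results are identical to independent reconstruction, and a test asserts
bit-identity of the factor-1 cell with the baseline path. Disconnected
cells are recorded as failed with a reason and excluded from summaries.
Stability is summarized by per-point relative ranges
(max − min)/|mean| of λ along each axis, plus a count of benign
eigenvector rank swaps (adjacent cells matched by maximal |cos| whose
crossed matching coincides with near-equal λ).

Comparing variability across the two axes is only meaningful on a
complete grid, so the study base radius is 3 × the mean neighbor
distance, grown when necessary to (minimal connecting radius)/smallest
factor so that even the smallest-radius cell stays connected
(`minimal_connecting_radius` returns the largest Euclidean MST edge — a
data statistic). On the noiseless Swiss roll with the default grid
(11 radius factors 2^−1..2, 10 ε in [3, 7]) the median relative range
across ε (≈1.8) is strictly below the range across radius (≈2.8–2.9
across seeds) — the rescaling axis is the tamer knob, and its effect is
an exact scalar; radius truncation changes the estimate itself.

## Synthetic generators

The generators define the package's controlled study conditions; their
defaults are fixed, not tuning knobs.

* **Gaussian mixture:** 500 points per component from N(μ_k, τ_k² I₂),
  μ_A = (0,0), μ_B = (30,0), τ_A = 10, τ_B = 1. The companion
  `cluster_scale` map shrinks cluster A tenfold about its centroid,
  emulating an embedder equalizing cluster spreads.
* **Variable-density Swiss roll:** n = 1500 latents z from
  0.25·Unif([0,2]×[0,1]) + 0.375·N([0,½], 0.2²) + 0.375·N([2,½], 0.2²),
  roll angle t = 1.5π(z₁/a + 1), noiseless surface point
  (t cos t, 10 z₂/b, t sin t), optional isotropic noise τ (0 by
  default). Gaussian latents are not clamped to the rectangle (a clamp
  option exists); isotropic 2-D latent covariance ν² I is assumed. The
  closed-form arc length ½(t√(1+t²) + asinh t) gives the isometric
  "unroll" chart used as a reference embedding, and `planted_break`
  translates all points with t > t₀ by 10 × the data diameter, planting
  fragmented neighborhoods with construction-known ground truth.

All randomness flows through `numpy.random.default_rng(seed)` with the
seed a required config field.

What these generators do *not* emulate: technical noise structure of real
sequencing data (counts, dropout, batch effects), high ambient dimension
with correlated features, or the optimizer-specific artifacts of any
particular embedding method. Passing tests therefore demonstrate that the
estimators recover known geometry and planted defects under clean
conditions, not that any particular real embedding is good or bad.

## Planted-break evaluation protocol

The break detector is scored on the noiseless Swiss roll with the unroll
chart broken at the mid-range angle t₀. The neighborhood graph is the
radius graph at r = 3 × mean 10-NN distance (the same convention the
estimation stage uses; radius graphs also keep neighborhood radii
bounded). Ground truth is defined by the construction at the tested κ:
the outlying pairs are exactly the cross-break pairs, so the true centers
are the points whose cross-break fraction of neighbor pairs reaches κ.
(Defining truth as "any cross neighbor" would be unattainable at
κ = 0.2 by arithmetic — a point with one cross pair among ten neighbors
is below threshold by definition of the center rule.) With
(L = 10, σ = 2, κ = 0.2) recovery is exact across seeds: every true
center flagged, no flags among points ≥ 5 neighborhood radii (per-point
largest stored neighbor distance) from the break that have no cross
pairs.

## Visualization geometry

Ellipse semi-axes default to √λ (linear stretch; raw λ available), so a
circle marks local isometry; the reported scalar "size" is λ₁λ₂, the
local volume change. Hairs run along the minor axis with length λ₁/λ₂
(capped at 1e6 when λ₂ underflows). SVG output is plain text with one
element per glyph/edge in input order — re-rendering identical inputs is
byte-identical, and element counts are verifiable by parsing. All
floating-point output (SVG and tables) uses 9 significant digits.

## Numerical choices, in one place

* Quantiles: linear interpolation (numpy default), shared with oracles.
* k-NN ties: lower index wins; union symmetrization (degrees ≥ k counting
  self; the 2k−1 upper bound holds on 1-D data but a hub point in higher
  dimensions can exceed it).
* Zero-distance edges between duplicate points are preserved explicitly.
* Eigen-sorting: descending; near-ties ordered by eigenvector angle to
  +x; canonical signs (largest-magnitude component positive).
* Pseudo-inverse floor 1e-10; isolated kernel rows are an error naming
  the node; empty neighborhoods get fraction 0 with a warning.
* Problem sizes in the test and acceptance workloads — a 900-point grid,
  1500-point rolls, ~100-point oracle fixtures, the full 110-cell
  sensitivity grid — are the study sizes stated above; the whole suite
  runs in well under a minute of pure computation apart from the
  sensitivity grid (~1 minute).

## Limitations

* Exact neighbor search only; for n ≫ 1e5 an approximate index should
  replace the block-wise search (the graph builders are the plug-in
  point).
* Metric glyphs are rendered for d = 2; H is computed for any d but not
  drawn beyond 2-D.
* Intrinsic-dimension estimation, geodesic-distance variants of the pair
  set, and in-browser interactivity are out of scope; "freeze" is a state
  flag standing in for interactive gestures.
* The bin screen's tail bins can be sparse on strongly inhomogeneous
  densities (marked low-support); the window strategy is the smoother
  alternative there.
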