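# Methods

## Data model

A trajectory is a matrix `P ∈ R^{K×M}` of contact distances: `K` saved
frames at spacing `dt` (ps), `M` contacts (nm). An ensemble is `N ≥ 2` such
matrices sharing one contact set and column order; frame counts may differ
per trajectory (only the Wasserstein and DTW measures tolerate that
downstream, and the aligned preprocessing steps refuse it). Units are fixed
package-wide — nm, ps, kJ/mol — with conversion confined to I/O adapters
(e.g. the optional MDAnalysis reader converts Å → nm).

Contacts are defined on raw coordinates: a residue whose Cα comes within
0.45 nm (inclusive boundary; configurable) of any ligand atom in **any**
frame of the ensemble qualifies, and the feature value is the minimum over
all ligand-heavy-atom × residue-heavy-atom pairs per frame. The union over
all frames and trajectories is used rather than a single reference
structure, so late-forming contacts are not missed; per-trajectory unions
would yield incompatible column sets across an ensemble and are not
offered. Periodic-boundary imaging is out of scope: coordinates are assumed
whole and unwrapped.

## Preprocessing

Order is fixed: smoothing → normalization → PCA. Each stage is optional.

* **Gaussian smoothing.** Per column, convolution with a normalized
  Gaussian kernel of standard deviation σ frames truncated at ±σ. The
  narrow truncation follows the defining summation window; a wider
  truncation (e.g. the common 4σ) is available via `smooth_truncate` for
  comparison. At the series edges the truncated kernel is renormalized over
  the frames actually present (implemented as the ratio of two "same"-mode
  convolutions), so constants are preserved exactly and no data is
  fabricated beyond the ends.
* **Time-resolved normalization** divides each entry by the ensemble mean
  `μ_{t,m}` at that frame and contact, counteracting the growing
  inter-trajectory spread from free diffusion in the unbound state. It
  requires aligned (equal-K) trajectories and guards against division by
  means below 1e-12 nm. It is *not* idempotent — the second application
  normalizes an already-normalized ensemble — but the defining property
  (ensemble mean exactly 1 at every (t, m)) holds after each application
  and is what the tests assert.
* **Global standardization** pools all frames of all trajectories and maps
  each contact column to zero mean, unit variance with the population
  (divisor `N·K`) convention.
* **Contact PCA** diagonalizes the pooled population covariance (same
  divisor; covariance, not correlation). Eigenvalues are clipped at zero
  and sorted descending; eigenvector signs are fixed by making the
  largest-magnitude loading positive. PCA consumes whatever the preceding
  stages produced — the chain is explicit rather than hard-wired to raw or
  standardized input. The default projection PC 1–4 reflects the common
  finding that the leading few components carry the path-discriminating
  signal; the full-rank projection is unitary and preserves all pairwise
  frame distances (asserted to 1e-10).

sklearn's PCA is deliberately not used for the fit: its `(n−1)` divisor
conflicts with the population convention above. It serves as a subspace
cross-check in the tests.

## Similarity measures

All four measures are symmetric, nonnegative and zero on identical inputs.

* **Mean Euclidean**: the per-frame feature-space distance averaged over
  frames, no `1/M` factor (the per-frame distance is taken literally as the
  vector norm). Requires equal-length, aligned trajectories.
* **Dependent DTW**: dynamic program over the `K × K′` grid with local cost
  the *squared* per-frame Euclidean distance, steps {(−1,−1),(−1,0),(0,−1)},
  boundary (1,1) → (K,K′). The returned value is the square root of the
  minimal cumulative cost — the convention of the standard DTW tooling —
  keeping units in nm; the raw summed cost is available via `squared=True`.
  No Sakoe–Chiba band is applied by default (none is part of the method
  definition); the DP is numba-compiled. DTW is not a metric (triangle
  inequality fails), which is fine for similarity-matrix construction.
* **Procrustes disparity**: both strided matrices are column-centered and
  scaled to unit Frobenius norm; the optimal orthogonal map (reflections
  allowed) comes from an SVD and the disparity is the residual sum of
  squares in [0, 2]. This standardized-disparity convention (scipy's) is a
  documented deviation from the plain minimized Frobenius norm: it is what
  the established pipeline this package follows actually computes. Default
  stride 5 because the underlying SVD cost grows steeply with K while
  striding barely changes the similarities; stride 1 is allowed.
* **Summed 1D Wasserstein**: per contact, the order-1 Wasserstein distance
  between the two empirical distributions with uniform weights `1/K`
  (scipy's implementation), summed over contacts. Time order is discarded
  entirely; lengths may differ; the triangle inequality holds per dimension
  and in the sum.

The similarity map `s_ij = 1 − d_ij/d_max` is affine, so pair ranking is
exactly reversed; `d_max` is the matrix maximum (the zero diagonal can
never attain it), the max-distance pair lands exactly at 0, and an all-zero
distance matrix ("no contrast between trajectories") is an error rather
than a division by zero.

## Clustering

The similarity matrix is treated as a complete weighted graph — no
sparsification, since the CPM objective `Φ = Σ_c [e_c − γ·C(n_c,2)]`
presupposes that every intra-cluster pair contributes and γ is a soft
bound, not a cutoff. Optimization uses leidenalg's CPM partition with 10
independently seeded restarts; the in-package objective evaluator (plain
pair sums) is authoritative — it ranks the restarts and is the quantity
verified against exhaustive partition enumeration on small instances
(Leiden attains the global CPM maximum on ≥ 95% of random N ≤ 8 matrices
and never exceeds it). Cluster ids are relabeled contiguously by descending
size for determinism.

γ candidates are quantiles of the off-diagonal upper-triangle similarities
(self-similarities are excluded — they are not pairwise values) with linear
interpolation between order statistics: Q2, Q3, and their average. Q2 is
the recommended starting point; for downstream free-energy work, raising γ
toward Q3 trades cluster size for purity.

Clusters with at most 5 members (configurable) can be merged into a
reserved `?` pseudo-cluster (id −1). For scoring, `?` members are kept as
one ordinary cluster by default — matching how a single reported "?" group
is treated — with an option to exclude them.

## Scoring

Entropy, mutual information and NMI are computed from the closed forms in
nats; NMI uses the arithmetic-mean normalization. Conventions at zero
entropy: both partitions trivial → 1, exactly one trivial → 0 (the behavior
of the standard scoring library, which the tests cross-check to 1e-10 on
random partition pairs). Labels may be any hashables; both scores are
invariant under relabeling.

## dcTMD

From constraint forces, `W(x)` is the cumulative trapezoid of `f_c` with
`W(x₀) = 0`. The free-energy estimator is the second-order cumulant
expansion `ΔG(x) = ⟨W(x)⟩ − var W(x) / 2k_BT`, exact for Gaussian work. The
variance uses the unbiased `N−1` divisor by default (appropriate for the
moderate per-cluster N this is applied to; the `N` divisor is a flag).
Temperature is a required input — it is simulation metadata, not a package
default. Work curves must share a pulling-coordinate grid; regridding is an
explicit helper (`resample_works`), never silent. The estimator is intended
for the constraint protocol, where x and t are rigidly linked; for
restraint data the alignment of W across trajectories is not well defined
and the package does not pretend otherwise.

Per-pathway application requires ≥ 100 trajectories per cluster by default
(configurable down for synthetic studies); smaller clusters and `?` are
skipped with a log message. Mixing routes with different friction violates
the Gaussian assumption and provably inflates the pooled variance — the
pooled `W_diss` exceeds the size-weighted within-cluster dissipation by the
between-cluster spread of mean work — which is the package's central
motivation for clustering first; the property is asserted on synthetic
two-population ensembles. Normality diagnostics (Shapiro–Wilk plus Q–Q
data at probe points, Hazen plotting positions) are reported, never
auto-enforced.

## Synthetic generator

The generator emulates the *kinematics* of biased pulling, not its physics
(no force field, solvent or membrane):

* **Constraint mode**: displacement along the pulling direction is exactly
  `x₀ + v·t` — the defining property of a distance constraint.
* **Restraint mode**: the displacement fluctuates around `x₀ + v·t` as an
  exact discrete-time Ornstein–Uhlenbeck process (stationary start,
  correlation time `ou_tau` frames) whose stationary variance is the
  equipartition value `k_BT/k_spring`. The exact discrete update keeps the
  statistics step-size independent. The default spring constant
  (1000 kJ mol⁻¹ nm⁻²) is a typical steered-MD stiffness, giving ~0.05 nm
  positional fluctuation at 300 K. Temperature is a scenario parameter
  because the OU amplitude is undefined without it.
* **Lateral motion**: a Gaussian random walk in the plane perpendicular to
  the pulling direction whose *end-point* standard deviation is
  `lateral_sigma` (per-step std `lateral_sigma/√(K−1)`), so the bundle
  width in nm is independent of the frame count.
* **Features**: distances from the ligand point to `M` pseudo-residue
  anchors, plus i.i.d. Gaussian noise (`noise_sigma`), floored at zero.
* **Anchors**: the default layout is deterministic and seed-independent.
  Half the anchors sit on a Fibonacci sphere with radii spread uniformly in
  volume over a 1–3 nm shell, guaranteeing quasi-uniform coverage of every
  pulling direction; the other half line each direction's exit corridor in
  a direction-specific radial band and perpendicular offset, emulating the
  distinct close-range residue arrangements of real exit channels. The
  banding is essential for the shape-based measure: a contact column
  depends on its anchor only through the axial projection and miss distance
  seen from the path, so two pathways whose anchor environments sample the
  same (projection, miss) distribution produce orthogonally equivalent
  matrices that Procrustes cannot distinguish — as happens for symmetric or
  regular layouts and for unlucky uniform-random draws. A seeded random
  shell (`anchor_seed`) and fully explicit anchor arrays remain available.
* **Kinematic scale**: defaults `v = 0.02 nm/ps`, `dt = 1 ps`, `K = 200`
  give 4 nm of travel — full unbinding, traversing and exiting the anchor
  shell — so contacts form, dip and break with pathway-specific timing.
* **Presets**: `A_like` (two directions 90° apart, well separated),
  `B_like` (60° apart, substantially overlapping bundles — higher median
  pairwise similarity than `A_like` at matched noise), `C_like` (all three
  merged).

Work ensembles realize the generative model under which the cumulant
estimator is exact: `W_i(x) = ΔG(x) + W_diss(x) + η_i(x)` with `η`
accumulating independent Gaussian increments of variance
`2k_BT·ΔW_diss` per grid step, so the pointwise variance is exactly
`2k_BT·W_diss(x)`. This forces `W_diss` nondecreasing with
`W_diss(x₀) = ΔG(x₀) = 0`, which the generator validates.

What passing on synthetic data does **not** show: robustness to force-field
level noise correlations (real contact distances fluctuate smoothly and
anisotropically, not i.i.d. per frame), to protein conformational change,
to contact-set instability between trajectories, or to pathways that split
or merge mid-course. The straight-ray bundles are an idealization of
well-defined exit channels.

## Numerical and reproducibility choices

* Every stochastic element (Leiden move order, synthetic ensembles, work
  noise) is driven by an explicit integer seed; pipeline reruns with the
  same config and seed are byte-identical, and each run writes its resolved
  config with a hash that is stamped on every artifact.
* Zero-mean guard for time-resolved normalization: 1e-12 nm. Objective
  reproducibility tolerance: 1e-10. Degenerate inputs (constant
  trajectories for Procrustes, zero-variance columns for standardization,
  all-zero distance matrices) raise errors naming the offender instead of
  propagating NaNs.
* Problem sizes in the test suite and acceptance script (80-trajectory
  ensembles with K = 200 and 20 contacts; 1000-curve work ensembles;
  exhaustive enumeration up to N = 8) are chosen so every oracle comparison
  is exact or statistically decisive while the whole suite runs in well
  under a minute of compute per module.

## Known limitations

* The Euclidean measure requires aligned equal-length trajectories by
  construction; the pipeline reports this as an error rather than silently
  resampling.
* dcTMD applies to constraint-protocol works; no friction estimation or
  pathway-probability reweighting is included.
* Leiden is a local optimizer: global CPM optimality is verified
  exhaustively only for small N; for large N the restart mechanism is a
  heuristic safeguard.
* No plotting: the block-ordered similarity matrix, partitions, profiles
  and Q–Q tables are exported as delimited text for external tools.
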