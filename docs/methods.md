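# Methods

## Imaging model

The phase-contrast optics are modeled by the kernel
`PSF = δ − airy`, where the obscured-Airy amplitude of an annular aperture
is

    A(r) = [ 2 J₁(a r)/(a r) − R² · 2 J₁(R a r)/(R a r) ] / (1 − R²)

with `a` the spatial-frequency scale of the unobscured aperture
(reciprocal pixels), `R ∈ [0,1)` the inner/outer annulus ratio and
`A(0) = 1` by the analytic limit. Defaults `a = 2.0`, `R = 0.5`,
`half_width = 5` (an 11×11 kernel) place the first Airy zero at ~2 px, a
resolvable halo scale for desk-sized frames; all three are config keys
(`psf.*`). The sampled Airy array is rescaled to unit sum so the kernel
sums to zero: the operator **P** annihilates constant images, which encodes
the model assumption that a uniform background restores to exactly zero.
Convolution uses symmetric (reflect) boundaries to avoid a dark frame at
the edges; with this boundary and the quadrant-symmetric kernel the
operator matrix is exactly symmetric (**Pᵀ = P**), which the test suite
verifies against a dense materialization.

## Restoration

The restored nonnegative image minimizes
`‖P f ∓ g‖₂² + w_smooth fᵀLf + w_sparse ‖D f‖₁` with `f ≥ 0`; the `−g`
sign recovers normal cells, `+g` enhances mitotic regions. Two distinct
diagonal matrices are involved: the degree matrix inside the Laplacian
`L = degree − W`, and the sparseness reweighting `D_kk = 1/(|f_k|+ε)`
refreshed in an outer loop (3 passes by default) — the iteratively
reweighted L1 scheme.

Numerical choices:

- **Preprocessing.** Frames are min-max normalized to [0,1] (so the default
  weights transfer across bit depths) and median-centered. Centering
  removes the background level and makes the sign-flip identity
  `restore(g, mitotic) = restore(−g, normal)` hold exactly; min-max
  normalization alone would break it by an additive constant **P** does not
  annihilate.
- **Inner solver.** Each fixed-weight subproblem
  `½ fᵀHf + bᵀf, f ≥ 0` with `H = 2PᵀP + 2 w_smooth L` is solved by the
  multiplicative update
  `f_k ← f_k (−b_k + √(b_k² + 4(H⁺f)_k(H⁻f)_k)) / (2(H⁺f)_k)`,
  which preserves nonnegativity and monotonically decreases the objective
  for any entrywise-nonnegative split `H = H⁺ − H⁻`. The split is formed at
  the kernel level — `P = P⁺ − P⁻` from the sign split of the PSF kernel
  and `L = degree − W` — so each iteration costs six small 2-D
  correlations plus one sparse neighbor product; no N×N matrix is formed.
- **Weights.** Defaults `w_smooth = 0.1`, `w_sparse = 0.02`,
  `ε = reweight_eps = 0.1` on [0,1]-scaled intensities. After reweighting
  the largest L1 weight is `1/ε = 10`, so the per-pixel sparsity pressure
  (~0.2) dominates noise-level background residuals (~10⁻⁴) but not
  cell-level fidelity terms (~10⁻¹). `ε` also floors σ₁ of the similarity
  graph so constant images are well defined.
- **Initialization.** `f⁰ = max(h − median h, 0)` scaled to [0,1] and
  floored at 10⁻⁶ (multiplicative updates preserve zeros, so a strictly
  positive start avoids dead pixels). Pixels whose iterate underflows to
  exact zero stay zero; their update factor is masked to avoid 0/0.
- **Objective trace.** The recorded trace is the tangent-majorizer (MM)
  form of the log-penalty surrogate
  `‖Pf∓g‖² + w_smooth fᵀLf + w_sparse Σ [log(f⁰_k+ε) + (f_k−f⁰_k)/(f⁰_k+ε)]`
  (anchor f⁰ = the iterate at the last reweight). Because the tangent
  majorizes the concave log penalty, this trace is provably nonincreasing
  across the entire run including reweight refreshes, whereas the plain
  reweighted-L1 value can jump upward at a refresh. The plain objective of
  the final pass is available through `restoration_objective`.
- **Termination and cleanup.** Inner loops stop at relative objective
  change < 10⁻⁶ or 500 iterations. Multiplicative iterates can never reach
  exact zero, so on return pixels at or below `zero_clip` (10⁻⁵) of the
  peak are snapped to 0 — the model's own background claim — which keeps
  connected-component extraction meaningful.

On ≤16×16 frames the final objective agrees with a long-run projected
gradient reference to better than 10⁻³ relative (tested); the solver's
practical accuracy, not machine precision, since multiplicative updates
converge linearly.

## Candidate extraction

The mitosis-enhanced restored image is binarized at
`threshold_frac × max` (default 0.1), 8-connected components smaller than
`min_area` (default 10 px) are dropped, and each survivor's bounding box —
expanded to a square and clamped to the frame — is cropped **from the
original frame** (the restored image localizes; the raw appearance is what
the classifier should see; a flag allows restored-image patches for
ablation) and resized bilinearly to 25×25. A small relative threshold is
needed because the nonnegative fit partially explains the inverted halos
of *normal* cells as weak rings; at a zero threshold those rings can bridge
to mitotic blobs and merge components. At the defaults the closed loop
reaches candidate recall 1.00 at precision ≈ 0.44, a deliberately
high-recall operating point.

Matching against ground truth is greedy centroid-in-box in (frame, row,
col) order, each annotation claimed at most once. Boxes are 0-based
half-open everywhere. Note the candidate *count* is not monotone in the
threshold — raising it can split a merged component into several — only
the retained pixel mass is; the tests check the monotone quantities.

## Sparse coding and dictionary learning

The coding problem is the nonnegative elastic net
`min_{w≥0} ‖x − Φw‖² + γ₁‖w‖₁ + γ₂‖w‖₂²` (the squared-L2 form: strict
convexity is what guarantees stable codes when atoms are nearly
collinear — with duplicated atoms and γ₂ > 0 the solver returns equal
coefficients to 10⁻⁶, tested). Inputs are unit-L2-normalized before coding
and learning, so the working range γ ∈ [10⁻⁴, 10⁻¹] is
dimension-independent; defaults γ₁ = γ₂ = 0.1, the strongest end of that
range. The solver is cyclic coordinate descent with the exact
per-coordinate nonnegative minimizer, sweeping atoms in ascending index
(deterministic), stopping when the KKT violation — max over active
coordinates of the absolute gradient and over inactive ones of the
negative gradient — falls below `tol` (10⁻⁸).

Dictionary learning is the online scheme: per iteration one uniformly
drawn sample is coded over the current dictionary, the statistics
`A += w wᵀ`, `B += x wᵀ` are accumulated, and one block coordinate-descent
pass updates each atom `u_j = φ_j + (b_j − Φa_j)/A_jj`,
`φ_j ← u_j / max(1, ‖u_j‖)` — the exact constrained minimizer of the
surrogate in that atom, with the `max(1,·)` projection implementing the
inequality constraint `‖φ_j‖² ≤ 1`. Atoms with `A_jj < 10⁻¹²` (never
activated) are left unchanged to keep learning deterministic. One pass per
iteration, not convergence: running the update to convergence at small t
destabilizes learning (observed empirically), while the single warm-started
pass matches the standard online analysis. `T_max` defaults to 10·N but is
independent of N. The dictionary is initialized with M distinct
unit-normalized training samples (seeded draw without replacement).

### Known limitation: exact atom recovery at weak penalties

In the planted-model experiment (8 random unit atoms in 25 dimensions, 400
nonnegative 2-sparse mixtures with coefficients in [0.5,1.5], noise
σ = 0.01, γ₁ = γ₂ = 0.01, T_max = 2000) the learner resolves six of the
eight atoms to cosine > 0.96 but typically mixes one pair, for a mean
best-match cosine around 0.79–0.97 depending on the random stream. The
cause is the penalty strength, not the online scheme: at γ₁ = 0.01 the
convex codes keep ~6 of 8 atoms active against the true 2-sparse supports,
and a batch alternating-minimization reference under identical conditions
does no better than ≈ 0.94. With γ₁ = 0.05–0.2 the same learner reaches
0.98–1.00. Applications that need exact recovery should use the stronger
end of the γ grid; the detection pipeline (γ = 0.1) is unaffected.

## Detection

Low-level features are pluggable by name; only `raw` (raster-order pixel
intensities, 625-dimensional for 25×25 patches) ships — shape/texture
descriptors can be mounted through the registry. The classifier is a
linear-kernel SVM (C = 1.0; the margin objective is what the method calls
for, and codes are low-dimensional and near-separable) with optional
`class_weight="balanced"` for imbalanced candidate sets (mitotic candidates
are typically a small minority). Metrics are the standard confusion-matrix
quartet; degenerate ratios (empty denominators) return 0 with a flag
rather than NaN so batch evaluation never crashes.

## Synthetic data

`simulate_frame` places non-overlapping disk cells (rejection sampling;
centers at least the sum of radii apart, fully inside the frame) with
cosine-tapered phase profiles `amp · ½(1 + cos(π r/radius))` — smooth
profiles render realistic halos through the δ−airy kernel — and forms

    observed = P f_normal − P f_mitotic + background + N(0, σ²).

Mitotic cells enter through a sign flip of the same forward operator,
exactly the mechanism the mitotic restoration inverts, so the closed loop
is a genuine test of the restoration mathematics. Defaults: 96×96 frames,
8 normal + 5 mitotic cells, radii 3–5 px, amplitudes 0.6–1.0, background
0.5, noise σ = 0.01. The radii keep cell structure resolvable through the
11×11 kernel: large smooth disks are strongly attenuated by the high-pass
δ−airy operator and would make restoration ill-posed at this scale. Note
the taper's outer rim carries negligible phase mass, so support-recovery
comparisons use the mass-bearing region (above 10% of the profile peak).

`simulate_patch_dataset` emulates the class-conditional sparse structure
the representation assumes: positives are nonnegative k-sparse (k = 2)
combinations of mitotic-tagged atoms, negatives of nonmitotic-tagged
atoms, plus noise, unit-normalized. The default class dictionary is 8 + 8
random unit atoms in 625 dimensions (the raw-feature dimension). What the
simulator does **not** model: cell motility and division dynamics across
frames, texture inside cells, photobleaching, uneven illumination, or
annotation noise. Passing tests therefore demonstrate the internal
consistency of the pipeline — restoration inverts its own forward model,
codes separate classes that genuinely have sparse class-conditional
structure — not performance on real C3H10 microscopy, whose candidate
patches are far less cleanly separable.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at desk
scale: ten 96×96 frames for the closed candidate loop, 400 + 400 patches
for detection, and the planted-recovery experiment above — sizes chosen so
a complete run takes on the order of a minute on one CPU while every stage
still operates in its intended regime.
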