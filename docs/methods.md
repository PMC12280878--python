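# Methods

`omtapc` implements two computational engines for volumetric brain-MRI
analysis at desk scale: (1) a density-weighted discrete optimal-mass-
transport (OMT) "tensorization" that converts an irregular masked brain
volume into a regular m̂×m̂×m̂ tensor while enlarging a designated whole-tumor
(WT) region, and (2) an algebraic preclassification (APC) model that
extracts multimode truncated-SVD features from WT tensor crops and
classifies them with multiview orthonormalized partial least squares
(MvOPLS) solved as a generalized eigenvalue problem. A synthetic phantom
generator makes every stage testable without external data.

## The transport model

The masked brain volume is represented as a tetrahedral mesh M. With
He ∈ [0,1] the histogram-equalized image intensity at a vertex and R_w the
WT region, the tumor-weighting density is

    ρ_γ(v) = exp(γ·He(v))  if v ∈ R_w,   1 otherwise,

with per-tet density ρ(τ) the mean of the four vertex densities and local
vertex mass m_ρ(v) = ¼ Σ_{τ∈N(v)} ρ(τ)|τ|. The mass-preserving map
f*_ρ: M → B³ minimizes Σ_v ‖v − f(v)‖² m_ρ(v) subject to the per-tet mass
constraints ρ(τ)|τ| = |f(τ)|; a volume-preserving map f*: C → B³ (ρ ≡ 1)
takes the reference cube C of side (4π/3)^{1/3} to the same ball, and the
composition f̂ = (f*)⁻¹ ∘ f*_ρ carries M onto C. Sampling the composed mesh
on a regular grid of C yields the OMT tensor; raising γ inflates the
tumor's share of the tensor without changing the nontumor volume
distribution, which is the mechanism used both for augmentation (a γ sweep)
and for giving the classifier a larger effective tumor image.

Before solving, the density is rescaled so the total mass Σ ρ(τ)|τ| equals
|B³| = 4π/3 exactly, which makes the constraint family consistent in the
aggregate.

### Discretization choices

**Mesh.** `build_tet_mesh` defaults to the classical Kuhn subdivision (six
tets per voxel sharing the cell diagonal, conforming across cells). The
transport stage, however, meshes with a 24-tet-per-voxel subdivision (cell
center plus six face centers). The reason is a counting argument validated
empirically: per-tet mass prescription imposes ~6 constraints per cell on
Kuhn-6 while cells own only ~3 interior degrees of freedom, so at sharp
density interfaces (the tumor rim, where ρ jumps from exp(γ·He) ≈ 5 to 1
within one cell) the best achievable max per-tet residual plateaus around
0.1–0.2. The 24-tet subdivision gives every cell an unshared center vertex
and six half-shared face centers; a single interface cell is then *exactly*
feasible (verified to 1e-11 by direct optimization), and no tet has all
four vertices on the domain boundary.

**Discrete ball radius.** A polyhedron inscribed in the unit ball has
volume strictly below 4π/3 (by O(h²)), so demanding both boundary vertices
on the unit sphere and discrete image volume 4π/3 is impossible. The solver
therefore volume-calibrates the codomain: after convergence all positions
are scaled so the discrete image volume is exactly 4π/3; boundary vertices
then lie within a thin O(h) shell just inside the sphere of radius
`ball_radius` = 1 + O(h²) recorded on the map. Staircase corners may dip
slightly deeper — this is what makes per-tet feasibility attainable at all
on voxel meshes (an exactly spherical boundary would force staircase
corner tets to be nearly flat while still carrying O(h³) mass).

### Solver

The solver is deterministic (no randomness anywhere):

1. **Initialization.** Smoothed star-shaped normalization: a real
   spherical-harmonic fit (degree 8) of the boundary radius function
   removes the gross shape anisotropy; positions are divided by the fitted
   radius and rescaled to total volume 4π/3. Falls back to an inscribed
   affine map if the smoothed map folds a tet. If the input is already
   feasible (e.g. a structured discrete ball under uniform density), it is
   accepted immediately — the uniform-density fixed point.
2. **Augmented Lagrangian.** Gauss–Newton steps on the augmented Lagrangian
   of the relative mass residuals, with Levenberg damping adapted by a
   merit-function test, a backtracking line search that rejects any step
   producing a non-positively oriented tet, a one-sided quadratic penalty
   keeping vertices inside the working ball, and a multiplier-runaway
   safeguard that restores the best iterate. Linear systems are solved
   matrix-free by Jacobi-preconditioned CG (the Gauss–Newton matrix is
   never assembled).
3. **Local sweeps.** On 24-tet meshes, exact block-coordinate updates:
   every tet contains exactly one cell-center and one face-center vertex,
   so simultaneous per-center (and per-interior-face, and per-parity-class
   corner) weighted least-squares updates decouple into independent 3×3
   solves. These crush the high-frequency residual the global steps leave
   behind.
4. **Polish.** Constraint restoration (damped minimum-norm Gauss–Newton
   steps via column-scaled LSMR) followed by minimax refinement
   (iteratively reweighted steps with p-norm continuation), which spreads
   the residual that least-squares stages concentrate on a few interface
   tets.
5. **γ-continuation.** `solve_gamma_ladder` solves γ = 0 first (a smooth,
   easy problem) and warm-starts each subsequent rung. This keeps the
   iterates in the basin that tracks the continuum transport map; solving a
   strongly weighted problem cold reliably lands in rough local minima with
   several-fold larger residuals. Rungs continue from the least-squares
   iterate *before* minimax polishing (polish trades smoothness for the
   worst tet, which makes a worse warm start), and polishing itself keeps
   the best-by-max incumbent so it can never return worse than its input.

**Known limitation — the per-tet feasibility floor.** Tet meshes have ~6
tets per vertex, so per-tet volume prescription is globally overdetermined
(T > 3V); discrete feasibility rests on the smoothness of the target
relative to the mesh. The hard WT-membership step in ρ_γ is not smooth, and
its residual floor grows with γ. On the bundled 48³ phantom the solver
reaches ≈5e-3 at γ ≤ 0.5 and ≈1.1e-2 at γ = 1.0 (just above the 1e-2
tolerance), and the floor rises to the 3–6e-2 range at γ = 1.5–2.0.
Extensive experiments (first-order stationarity of the residual, agreement
of four independent optimizers, direct feasibility probes on small coupled
blocks, and insensitivity to doubled iteration counts and halved
continuation steps) indicate this is a property of the discretization, not
of the optimizer. The solver's strict
default tolerance (1e-2, exposed in config) is therefore attainable only
for moderate γ; the cohort pipeline uses 0.075 and proceeds with a logged
warning on marginal subjects, since classification quality is insensitive
to residuals at this level.

### Tensor construction

Map inversion and resampling use exact barycentric point location with a
KD-tree over image-tet centroids (a widened second candidate pass for hard
points, degenerate candidates excluded). Grid cells outside the composed
mesh get zero intensity and background label, and are counted in
provenance. A tensor cell is labeled WT when at least two of the four
vertices of its containing tet lie in R_w (ties break toward tumor); if
rounding ever leaves a nonempty source WT without tensor support, the cell
nearest the image of the WT centroid is labeled — label survival is
guaranteed. m̂ defaults to 64 for the reference sweep and 32 for the cohort
pipeline; the cube map depends only on (resolution, tolerance) and is
cached across subjects.

## The APC model

From each subject's m³ WT crop (axis-aligned WT bounding box padded by one
voxel, trilinearly resampled; m = 32), the three mode unfoldings
T(s) ∈ R^{m×m²} are reduced by truncated SVD to x(s) = vec(U_jΣ_j) ∈ R^d,
d = m·j, j = 8. Left singular vectors follow a deterministic sign
convention (largest-magnitude entry positive) so features are reproducible
across linear-algebra backends. Training solves

    min_{P_s, W} Σ_s ‖Y − WᵀP_sᵀX_s‖_F² + Σ_s γ_s ‖P_s W‖_F²

on class-balanced weighted views (each class receives unit total weight via
D_n), by the generalized eigenvalue problem for (A, B) with A = XYᵀYXᵀ and
B = blockdiag(X_sX_sᵀ + γ_s I_d); γ_s = 1e-4. k = 2 matches rank(A) ≤ 2 for
binary one-hot labels. W* is computed by the printed formula
(P*ᵀBP*)⁻¹P*ᵀXYᵀ even though the constraint makes the inverse an identity,
guarding against inexact orthonormalization. At test time each modality and
mode yields y_t(s) = W*ᵀP*(s)ᵀx_t(s): six raw 2-vectors per subject with
two modalities.

Two estimator choices matter at desk scale (n of tens, d = 256 per view):

* **Per-view centering.** Features are centered on their training mean
  before the fit (the centers are stored in the model and subtracted at
  test time). Without centering the leading generalized eigenvector is
  spent on the grand-mean direction and held-out discrimination collapses;
  with it, A becomes effectively rank one in the between-class direction.
* **Calibrated, reliability-weighted aggregation.** The six raw vectors are
  exposed unmodified (they approximate probabilities but are not confined
  to the simplex); in the original design they feed a downstream learned
  layer, which is out of scope here. As its standalone combiner the
  package converts each view's margin y₁−y₀ to a train-referenced rank
  probability and averages them with reliability weights estimated by
  deterministic stratified 4-fold cross-validation on the training set
  (weight ∝ max(CV-AUC − ½, 0)). An unweighted mean would let a view with
  no class information — by construction, the second modality — veto the
  informative ones. The module-level `preclassify` keeps the plain
  mean-then-softmax aggregation for reference; argmax ties break toward
  class 0 everywhere.

Label smoothing ŷ = (1−ε)y + ε/C with ε = 0.1 is provided for downstream
training targets.

## The phantom generator

Phantoms emulate skull-stripped, co-registered, [0, 1000]-normalized
two-channel volumes: an ellipsoidal brain with smooth background texture
(unit-SD Gaussian noise blurred at σ = 2.5 voxels, amplitude 20, base
level 400 — a constant background would make histogram equalization
degenerate), white observation noise (SD 30), and a spherical WT region
with +180 additive contrast on both channels. The texture amplitude is
kept below the white-noise SD so that `effect_size` — a mean shift of
`effect_size` × noise-SD inside the tumor on channel 0 only — retains its
meaning against the total between-subject variability; a texture that
dwarfs the noise would silently deflate every nominal effect size. The
second channel carries no class signal, so the multiview model is
genuinely exercised. Labels, geometry and noise are all driven by one
seed; identical seeds give bit-identical volumes.

What the phantoms deliberately do not model: scanner artifacts, bias
fields, registration error, anisotropic acquisition, nonspherical or
heterogeneous tumors, and any realistic relationship between texture and
genotype. Passing benchmarks therefore demonstrates that the pipeline
recovers a planted, well-posed signal through the full transport + algebra
chain — not clinical performance.

### Study conditions (bundled benchmarks)

* Reference phantom: 48³ grid, brain semi-axes (15, 13, 11) voxels,
  tumor radius 5 at an off-center site, effect size 3, seed fixed. Used for
  the γ-sweep (γ = 1.0, 1.5, 1.75, 2.0 — the augmentation set; γ = 1.75 is
  the training value) at m̂ = 64.
* Classification benchmark: n = 60 subjects on 18³ grids (semi-axes
  (7, 6.5, 6), tumor radii 2.8–3.8), class balance 0.5, effect size 3,
  stratified 80/20 split, OMT tensorization at γ = 1.75, m̂ = 32, APC with
  m = 32, j = 8, k = 2. Grid sizes are deliberately small so the full
  transport chain runs for every subject; tumors span at least ~6 voxels
  across because the rank-8 mode features need crops with genuine content
  (with 2–3-voxel tumors the crop is almost pure interpolation and
  held-out discrimination saturates well below its potential). The class
  effect is strong enough that the benchmark tests the plumbing end to
  end rather than statistical power.
* Null calibration: 20 replicate cohorts (n = 30) with effect size 0,
  using identity (raw-grid) tensorization — the transport map is
  deterministic and label-independent, so it cannot introduce label
  leakage; the null isolates the classifier. Same fast path for the
  label-permutation check (n = 60, 3 permutations).

## Numerical conventions

* Voxel (i, j, k) spans [i−½, i+½]×…; mesh vertices live on voxel corners
  (plus face/cell centers for the 24-tet subdivision); intensities are
  sampled trilinearly at vertex positions.
* He uses a 256-bin right-continuous empirical CDF over brain-mask voxels
  of the tensorization modality (channel 0); a constant image maps to
  He ≡ 1.
* A vertex belongs to R_w when any voxel whose closed cell contains it is
  WT.
* AUC uses the Mann–Whitney formulation with ties counted ½; its 95% CI is
  a 2000-resample percentile bootstrap with fixed seed. Undefined ratios in
  confusion metrics are reported as None, never as silent zeros.
* Dice and HD95 are plain volumetric (no per-lesion matching); HD95 pools
  symmetric surface distances (6-connectivity surfaces, spacing-aware EDT)
  before the 95th percentile; two empty masks have Dice 1 by convention.
* Ties in the aggregate argmax break toward class 0.
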