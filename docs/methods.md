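# Methods

## Problem

The sella turcica (ST) — the saddle of the sphenoid bone, midway between
the anterior and posterior clinoid processes — anchors the standard
sella–nasion (S-N) cephalometric reference frame.  It is a hard-tissue
landmark and therefore invisible on surface captures such as 3D
stereophotographs, which are the radiation-free modality of choice for
following infants with craniosynostosis.  This package estimates the ST
coordinate from a cranial *surface* mesh alone, so that surface scans can
be realigned into the S-N frame: a statistical-shape-model (PCA) feature
extraction feeds a small regression network, and the conventional
Computed Cranial Focal Point (CCFP) plus per-subtype offset serves as the
baseline it is compared against.

## Pipeline

1. **Horizontal alignment.** Three annotated soft-tissue landmarks
   (nasion, left/right supra-aurale) define a canonical pose: supra-aural
   midpoint at the origin, left→right supra-aural axis along +x, nasion
   in the y>0 half-plane.  Axes follow the cephalometric convention
   (+x mediolateral right, +y anteroposterior, +z craniocaudal).  The
   transform is rigid; no scaling is ever applied (fixed-distance frames
   are unsuitable in growing subjects).

2. **Raycast standardization.** From the supra-aural midpoint, rays are
   cast along the 1016 fixed directions of a hemi-icosphere template; per
   ray the *farthest* intersection is kept, which discards any interior
   shell (residual soft-tissue structure) in favour of the outermost skin
   surface.  The result is a 1016-vertex surface in fixed correspondence
   across subjects.

   *Template construction.* 1016 is not a count any latitude cut of a
   symmetric icosphere can produce (ring cumulative counts jump
   1011→1015→1019 at subdivision 4).  The template therefore tilts the
   subdivision-4 icosphere by a fixed rotation (7° about x, 3° about y)
   to break the latitude degeneracy, then cuts at z ≥ sin(12.00918…°),
   which retains exactly 1016 directions with a comfortable (1.6·10⁻⁴)
   z-gap to the first discarded vertex.  Ordering is descending z then
   azimuth; the construction is frozen in `config.py` and bitwise
   deterministic.  The construction is count-matched, not claimed to be
   geometry-identical to any particular clinical implementation.

   Rays that miss (not possible for shells star-shaped around the
   origin) are filled by inverse-angular-distance interpolation over the
   3 nearest hit directions and flagged; >10 % misses aborts with a
   quality error.

3. **Shape model.** The 1016×3 vertex matrices are flattened and reduced
   by mean-centred PCA to 32 components; the first 10 scores (the
   variance-ordered components carry the highest individual variances)
   are z-scored by their training-set standard deviations.  Score
   standardization is needed because raw scores span orders of magnitude
   and batch-size-1 training is unstable otherwise.  Component signs
   follow a deterministic convention (largest-magnitude loading
   positive).  PCA, score scales and CCFP offsets are fitted per
   cross-validation fold on training data only, so no information leaks
   into test folds.

4. **Regression network.** dense(14→8) → ReLU → dropout 0.5 → three
   residual blocks x + ReLU(dense(8→8)(x)) → dropout 0.1 → dense(8→3).
   The input is the 10 standardized PC scores plus a 4-element one-hot
   subtype indicator (control, plagiocephaly, trigonocephaly,
   scaphocephaly); the output is the ST coordinate in the horizontally
   aligned frame (mm) — the only frame that exists before the ST is
   known.  Training: Adam, MSE loss, batch size 1, 400 epochs, learning
   rate 10⁻³ halved every 100 epochs.  The "identity mapping through 3
   consecutive 8-neuron layers" is realized as residual blocks in the
   ResNet sense; the exact activation/dropout placement inside those
   layers admits other readings, and this one is recorded as the
   package's choice.  The network has <500 parameters and is implemented
   directly in numpy with hand-derived backpropagation; all randomness
   (initialization, shuffling, dropout, fold splits) flows from one run
   seed, making runs bit-for-bit reproducible.  Early stopping and
   feature-jitter augmentation exist as optional flags but default OFF:
   the fixed 400-epoch schedule governs.

   *A note on dropout.* A 0.5 dropout rate on an 8-unit layer acts as
   heavy multiplicative regularization: even on a noiseless linear
   target the evaluation-mode fit plateaus at roughly 0.6× the target
   standard deviation (with dropout disabled the same optimizer drives
   the error to ~0.02 mm, confirming the optimization itself is sound).
   Predicted deviations from the class mean are correspondingly shrunk;
   this is a property of the prescribed architecture, not a defect of
   the fit, and it bounds the achievable accuracy well above the
   annotation-noise floor.

5. **CCFP baseline.** The focal point is the least-squares convergence
   point of the vertex normal lines, solved in closed form from the
   rank-3 normal equations (Σᵢ(I − nᵢnᵢᵀ))p = Σᵢ(I − nᵢnᵢᵀ)vᵢ, with
   normals estimated as outward-oriented area-weighted averages of
   incident template triangles.  The ST estimate adds a per-subtype
   constant offset (mean of true-ST − focal-point over training
   subjects).  Age/sex-dependent offsets are not modelled.  A constant
   offset cannot follow shape-dependent displacement of the ST — the
   known weakness, most pronounced for asymmetric deformation, that the
   comparison is designed to expose.

6. **Evaluation.** Per-subject Euclidean and signed per-axis deviations;
   for realignment, each subject's full mesh is expressed in the S-N
   frame built from each method's predicted ST (origin at ST, y toward
   the nasion as primary axis, supra-aural direction Gram-Schmidt
   orthogonalized as x, z = x×y) and compared with the true-ST alignment
   by a signed distance map: exact point-to-triangle closest distances,
   outward-positive relative to the reference, summarized by the 5th and
   95th percentile (linear interpolation) and mean.  Method comparisons
   use a paired t-test when the paired differences pass Shapiro–Wilk
   normality at α = 0.05 and a Wilcoxon signed-rank test otherwise;
   constant nonzero differences (normality undefined) route to the
   Wilcoxon branch, identical samples report "no-difference".  No
   multiple-testing correction is applied.

## Synthetic cohorts

No clinical data ship with the package; cohorts are generated.  Each
phantom is a closed superellipsoid head shell (semi-axes 80 × 95 × 70 mm,
exponent 2.2 — an infant-sized head) deformed per subtype:

* scaphocephaly: y scaled by 1 + 0.25 m, x by 1 − 0.2 m (long, narrow);
* trigonocephaly: anterior wedge, x compressed by up to 40 % · m
  growing with the anterior direction component;
* plagiocephaly: one posterior-left quadrant radially compressed by up
  to 30 % · m under a Gaussian angular window (σ = 0.6 rad);
* control: no field.

The magnitude m is drawn per affected subject from U(0.3, 0.8).
Individual variation adds per-subject log-radii jitter (sd 4 %) and six
low-order harmonic-polynomial radial bumps (coefficient sd 0.015);
surface noise is radial, N(0, 0.5² mm²) per vertex.  The ten latent
coefficients (3 jitters, m, 6 bump amplitudes) drive the true ST through
a fixed affine map around an anchor near the shell centroid with an
anterior-inferior offset (0, +8, −12) mm, plus isotropic N(0, 1 mm²)
annotation noise — so the ST carries shape information that a constant
per-class offset cannot capture, with a within-class spread of a few mm,
while remaining exactly learnable in principle.  Landmarks are placed by
casting rays along anatomical directions onto the generated mesh, so
they lie exactly on the surface; every subject is finally put in a
random rigid pose.  All draws derive from one root seed through
spawned per-subject seed sequences.

What the phantoms do *not* emulate: facial and ear geometry, age/sex
covariates, capture artifacts of real stereophotogrammetry, and the
CT-derived soft-tissue segmentation chain.  Passing tests on phantoms
therefore demonstrate correctness of the pipeline and the *relative*
behaviour of the two estimators under controlled shape variation — not
clinical accuracy on real scans.

## Study conditions and problem sizes

The standard cohort used by the validation suite and the acceptance
script is 50 subjects per class (200 total), 1 mm ST annotation noise,
5-fold subtype-stratified cross-validation, 400 epochs — at which the
network reaches ≈3.2 mm mean Euclidean error versus ≈5.7 mm for the
CCFP baseline, with distance-map percentiles correspondingly tighter.
Phantom meshes use a subdivision-3 icosphere (642 vertices, 1280 faces),
whose ~0.3 mm faceting error is below the surface noise.  The
irreducible floor of the mean Euclidean error at 1 mm isotropic noise is
E‖N(0, I₃)‖ ≈ 1.60 mm.

## Numerical choices

* Ray/triangle intersection: vectorized Möller–Trumbore over all
  (ray, face) pairs in chunks, boundary tolerance 10⁻⁹, farthest
  positive hit per ray.
* Closest points: exact, as the minimum over the interior plane
  projection (when barycentrically admissible) and the three clamped
  edge projections, evaluated for every (vertex, triangle) pair.
* CCFP normal-equation solve guards on condition number (>10⁸ raises);
  degenerate vertex neighbourhoods fall back to the radial direction.
* Duplicate vertices are merged at 10⁻⁶ mm on STL load; zero-area faces
  dropped.
* Percentiles use linear interpolation between order statistics.
* Orthogonalization order in the S-N frame (y primary, x secondary) is
  fixed and documented: supra-aural noise can roll the frame about the
  anteroposterior axis but never bend that axis.

## Known limitations

* The hemi-icosphere geometry is count-matched (1016) by a documented
  tilt-and-cut construction; other constructions with the same count
  would yield slightly different correspondences.
* Whether to take the first or farthest ray hit is a modelling choice;
  farthest implements the removal of interior structures.
* The CCFP is reimplemented from its published construction
  (least-squares normal convergence); no byte-level parity with any
  clinical implementation is claimed.
* Dropout shrinkage (above) caps network accuracy at a fixed fraction
  of the within-class target spread.
* Phantom realism limits are listed under Synthetic cohorts.
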