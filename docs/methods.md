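# Methods

This note records how each stage of `bladresp` is modelled, the defaults
that matter, and the design choices made where the procedure was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task and data model

A *case* is a temporal lesion pair: a pre-treatment CT volume, a
post-treatment CT volume, and a binary pathologic outcome — complete
response (stage T0, no residual tumor at cystectomy) versus non-complete
(> T0). Volumes are 3D arrays indexed `(z, y, x)` with per-axis spacing in
mm (`slice_thickness, row, col`); lesions live inside user-drawn (here:
phantom-derived) half-open voxel boxes. Scores are likelihoods of T0 in
[0, 1]; higher means more likely complete response, and at a threshold a
score ≥ threshold predicts complete response.

## Synthetic phantom

The phantom stands in for the patient cohort and defines the study
conditions for all end-to-end checks.

* **Geometry.** A roughly ellipsoidal bladder (semi-axis scale
  0.85/1.0/1.1 of `bladder_radius_mm`, default 28 mm) with a 3 mm wall
  (intensity 45), urine-filled lumen (10), and soft-tissue background (40)
  on a default grid of 28×96×96 voxels at 3.0×0.75×0.75 mm — in-plane
  spacing and slice thickness inside the clinical acquisition ranges this
  emulates (0.586–0.977 mm pixels, 0.625–7 mm slices).
* **Lesion.** A sphere whose radius is modulated by a seeded low-frequency
  radial perturbation (fractional amplitude 0.2), placed tangent to the
  outer bladder surface along a fixed direction so it overlaps the wall
  and protrudes into the lumen. The tangent-inside placement keeps the
  undisturbed blob entirely inside the bladder, so for zero perturbation
  the mask volume has a closed form (4πr³/3) used as an oracle.
* **Intensities.** The source study gives no intensity statistics for
  lesions versus lumen, so levels are free parameters; the defaults model
  an *enhancing* lesion: mean level `lumen + lesion_contrast` with
  contrast 70 (cohort range 60–90), distinguishable from both lumen (10)
  and wall (45), as in contrast-enhanced CT. Lesion texture is seeded
  Gaussian noise smoothed to `texture_corr_length_mm` (default 2 mm,
  amplitude 5–9), which gives run-length features real structure; white
  acquisition noise (SD 5) is added everywhere.
* **Response.** Partial response is radius shrinkage (post/pre ratio
  0.55–0.9) with contrast retention 0.75–1.0; complete response removes
  the lesion entirely, with an optional flag that deposits benign residual
  wall thickening at the site (the confounder that misleads human
  readers). Labels for a cohort come from one seeded Bernoulli draw at the
  configured complete-response rate (the clinical training cohort this
  emulates had 28/104 ≈ 27%; the synthetic experiments use 0.30 at n=60).
* **Reproducibility.** All randomness flows from one root seed through
  named per-case substreams (shape, pre/post texture, pre/post noise), so
  cohorts are bitwise reproducible and the label draw can be replayed
  independently.

What the phantom does **not** emulate: anatomy beyond a single bladder
(no bowel, no bone), contrast-agent kinetics, scanner physics (beam
hardening, streaks), inter-scan misregistration, and multi-lesion cases.
Passing the end-to-end checks shows the chain recovers a known signal
under these controlled conditions; it does not certify clinical accuracy.

## AI-CALS segmentation

Three deterministic stages inside the lesion box.

1. **Preprocessing.** Intensities are standardized over the box (zero
   mean, unit variance) so the nonlinear steps behave identically across
   CT intensity scales, then smoothed with a Gaussian at a *physical*
   scale of 1 mm per axis — voxel-based smoothing at 3–7 mm slice
   thickness would smear thin lesions into the lumen — followed by five
   iterations of gradient anisotropic (Perona–Malik-type) diffusion with
   conductance 1.0. Gradients are central differences in mm; the gradient
   magnitude is rank-transformed within the box to [0, 1] (ties averaged,
   constant regions map to 0). The rank transform makes the edge map
   contrast-invariant.
2. **Initial surface.** Voxels within 3 standard deviations of the
   average gray level form the object band. The average and SD are
   estimated robustly (median and MAD-derived σ) over the central 30% core
   of the box: the user box is drawn around the lesion, so its core is
   lesion tissue, and robust estimates keep lumen/wall contamination and
   partial-volume voxels from inflating the band until it swallows the
   box. A zero spread degenerates to labeling the whole box. The band is
   cleaned by dilation with a spherical element of radius 2 voxels, 3D
   flood fill, and a matching erosion (the element is voxel-based
   regardless of anisotropy, and the closing leaves an already-solid
   convex object unchanged); the largest 26-connected component is kept.
3. **Level-set refinement.** A geodesic active contour (SimpleITK's
   solver) evolves the initial surface, first in 3D then slice-by-slice in
   2D. The speed image is a sigmoid edge-stopping function of the
   gradient-magnitude rank (centre 0.8, width 0.05 — speed ≈ 1 on the flat
   ~80% of voxels, → 0 on the top-ranked edges), with propagation 0.4,
   curvature 0.6 and advection 2.0; defaults 60 3D and 30 2D iterations.
   A divergence guard stops refinement with a warning if the mask covers
   ≥ 50% of the box faces. With zero iterations the initialization is
   returned unchanged.

## ROI construction

From every slice with lesion pixels, 32-row × 16-column windows are
enumerated on a stride-8 lattice anchored at the slice's lesion bounding
box; a window is kept when ≥ 75% of its footprint lies inside the mask
(strict 100% coverage would eliminate most windows on irregular lesions).
If no window qualifies, a single patch centred at the lesion centroid is
used. Pre- and post-treatment patches of a lesion are combined as the
Cartesian product, capped by a seeded uniform subsample (pipeline default
24 pairs per lesion), each paired ROI being the 32×32 array `[pre | post]`
carrying the outcome label. The 32×16 orientation (rows × columns) is the
only one for which side-by-side pasting yields a 32×32 paired ROI.

## Radiomics banks

**SL bank (91 features).** Computed after trilinear resampling of the
lesion box to cubic voxels at the in-plane pixel size (nearest-neighbour
for the mask):

* morphology (18): 3D volume, marching-cubes surface area,
  surface-to-volume; on the central (maximum-area) slice: area, perimeter
  (Crofton), circularity 4πA/P², rectangularity A/bbox, and 10 normalized
  Fourier-descriptor magnitudes |F_k/F_1| (k = 2…11) plus their energy;
* gray level (12): mean, SD, skewness, excess kurtosis, min, max, median,
  P10, P90, 64-bin entropy and energy, and a Michelson-style contrast
  against a 3-voxel peripheral shell on the central slice,
  `(mean_in − mean_shell)/(|mean_in + mean_shell| + ε)` — the source names
  a contrast feature but does not define it, so this definition is a
  documented stand-in (sentinel 0 when the shell is empty);
* run length (55): the 11 classical statistics (SRE, LRE, GLN, RLN, RP,
  LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE), direction-averaged, in 3D over
  the 13 canonical directions at 8/16/32 gray levels and on the central
  slice over the 4 directions at 8/16 levels. Quantization is equal-width
  over the masked min–max range; a constant region collapses to one bin;
  runs break at mask boundaries;
* gradient field (6): mean, SD, skewness, kurtosis, max and range of the
  gradient magnitude over the surface voxels (mask minus its 6-connected
  erosion; a mask without interior is its own surface).

The exact 91-feature list of the reference system is not public; this bank
is a versioned manifest covering the same four families and is treated as
configuration by the classifiers, not as a constant. Zero-variance
skewness/kurtosis are defined 0 throughout.

For a lesion pair, RF-SL consumes the per-feature percent change
`100·(post − pre)/|pre|`, with a signed ±1000 sentinel when the
pre-treatment value is numerically zero. A complete responder with an
empty post-treatment segmentation contributes the all-zero SL vector, so
positive pre-treatment features register as −100%.

**ROI bank (38 features).** On a 32×32 paired ROI: 16 histogram statistics
(mean, SD, skewness, kurtosis, energy, entropy, min, max, range, median,
P5/P10/P25/P75/P90/P95) plus the 11 run-length statistics at 8 and 16
levels over the 4 2D directions. Per-lesion features are the elementwise
mean over the lesion's paired ROIs.

## Models

* **Random forests** (scikit-learn) with exactly the configured tree count
  and minimum leaf size; scores are mean per-tree class-T0 probabilities.
  Training rows are canonicalized (lexicographic sort) before fitting so
  row order cannot change the model. Reference configurations: 6 trees /
  min-leaf 13 (RF-SL) and 2 trees / min-leaf 29 (RF-ROI), selected on a
  104-pair clinical training set. Those leaf sizes are absolute counts
  tied to that cohort size — at 40 training lesions a min-leaf of 29
  forbids any split — so the experiment pipeline scales min-leaf by the
  reference leaf-to-train-size ratios (13/104 and 29/104) to the actual
  training-fold size, keeping the regularization pressure rather than the
  raw count. The module-level defaults keep the absolute values.
* **Feature selection** defaults to sequential forward selection
  maximizing the stratified cross-validated AUC of the configured forest
  (stop at no improvement or k_max: 5 features for RF-SL, 4 for RF-ROI,
  matching the counts the reference system reports selecting); a
  per-feature folded-AUC ranking (`max(AUC, 1−AUC)`, ties by index) is the
  alternative method and doubles as the importance ordering.
* **DL-CNN.** Input 32×32×1, then conv16@3×3 → ReLU → maxpool 2×2 → LRN →
  conv16@3×3 → ReLU → maxpool → LRN → two locally-connected 16@3×3 layers
  (independent kernels at every location; tying them to one kernel set
  reproduces the convolution exactly, which is tested) → fully-connected →
  2-way softmax. The published hyperparameters of the reference network
  are not available, so the optimizer settings are documented stand-ins:
  SGD with momentum 0.9, learning rate 0.001, batch 64, LRN n=5, α=1e-4,
  β=0.75, k=2, He initialization, float32 arithmetic (float64 available
  for gradient checking), inputs standardized by the training set's global
  mean/SD. Per-ROI probabilities are calibrated softmax outputs; the
  per-lesion score is their arithmetic mean (order-invariant). Training is
  deterministic given the seed.

## Evaluation

Empirical (trapezoid/Mann–Whitney, midrank ties) ROC and AUC with the
DeLong standard error. The reference analysis does not state its ROC
estimator; if it used a binormal fit there can be a small systematic
difference. Operating points are the largest threshold whose training
sensitivity reaches the target (default 0.65; exposed as a parameter since
the reference "certain sensitivity level" is unstated); percentages are
rounded half-up to one decimal. Agreement regions count each of the 2^m
per-case correctness patterns across m methods.

## Experiment protocol

`run_experiment` simulates a cohort (default 60 lesions, 30% responders),
segments both time points of every case with AI-CALS, extracts features,
and evaluates the three models with stratified 3-fold cross-validation
*split by lesion* (ROIs of one lesion never cross a split). Out-of-fold
per-lesion scores are pooled into a single ROC per model; at these cohort
sizes a single holdout split is too unstable to characterize either the
signal or the null. Fold models select features and scale leaf sizes on
their own training lesions only. Problem sizes (60 lesions, 24 ROI pairs
per lesion, 30 CNN epochs, 3 folds) are the package's defaults and keep
the full experiment in the minutes range on one CPU.

**Null experiment.** The no-signal control replaces the labels with an
independent seeded Bernoulli draw at the configured response rate, and the
reported null AUC averages two such draws. A fixed permutation was
deliberately not used: with cross-validation, a permutation's fixed class
counts couple the train-fold and test-fold label/phenotype correlations
negatively, and since the two phenotypes are well separated in image
space, a flexible model amplifies the chance training correlation into
strongly anti-correlated test predictions (pooled null AUCs far below
0.5). Independent relabeling breaks that coupling and centres the null at
0.5.

**Caching.** The expensive simulate+segment+extract stage is
content-addressed by a hash of the configuration that determines it;
re-running a completed stage with an unchanged configuration loads the
cached arrays (a no-op), which also lets the signal and null experiments
share one feature computation.

## Known limitations

* The level-set energy, the exact 91-feature enumeration, the selection
  algorithm and the CNN hyperparameters of the reference system are not
  public; each is implemented as a documented, configurable choice
  validated by phantom oracles rather than bit-exact reproduction.
* Morphology in voxel units (structuring elements, surface voxels) depends
  mildly on anisotropy before resampling; run-length values depend on the
  quantization level counts, which are part of the bank manifest.
* The phantom's class separation is stronger than clinical reality (the
  reference cohort's test AUCs were ~0.7); end-to-end checks here verify
  signal recovery and calibration of the machinery, not clinical
  performance.
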