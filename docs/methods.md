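# Methods

`gliomets` implements a computer-aided diagnosis pipeline that separates
high-grade gliomas from brain metastases (mets) on two conventional MRI
sequences (contrast-enhanced T1 and T2-FLAIR), exercised end-to-end on
synthetic 3D tumor phantoms.  This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Problem and pipeline

Gliomas typically present as one large, irregular lesion with three
compartments (enhancing tumor, necrotic core, peritumoral edema); mets
frequently present as several smaller enhancing lesions with edema but no
necrotic compartment in the segmentation scheme used here.  The pipeline:

1. **standardize** — resample both sequences to 1×1×1 mm voxels and
   Z-score the intensities over the brain area;
2. **extract** — compute 960 radiomics features per sequence from the
   whole tumor ROI (union of compartments), plus the lesion number;
3. **select** — Mann–Whitney prefilter (p < 0.05) then LASSO (or mutual
   information / RFE-RF), fitted on training rows only;
4. **classify** — a weighted soft-voting ensemble (RSV) of the two
   best-performing base classifiers with weight pair ω = (ω₁, ω₂);
5. **decide** — when masks come from automatic segmentation, the EDPK
   strategy adapts the ROI set and the vote weights to the lesion count;
6. **explain** — additive Shapley attributions of the ensemble output.

## Phantom simulator

The generator replaces both a hospital cohort and the deep segmentation
networks, so its defaults define the study conditions.

* **Geometry.** Each lesion is a union of randomly perturbed ellipsoids
  smoothed by a 1-voxel Gaussian; the `shape_irregularity` parameter in
  [0, 1] scales the number and offset of the perturbing bumps.  Gliomas:
  1 lesion (occasionally 2, with satellites at half the primary radius),
  radius 6–15 mm, irregularity 0.3–0.7.  Mets: 1–8 lesions, radius
  3–7 mm, irregularity 0.05–0.35.  Necrosis (gliomas only) is the deep
  interior of the enhancing lesion (distance transform above 0.4 of the
  mean radius); edema is a 2–5 mm shell.  These ranges are conventional
  rather than calibrated — no distributional statistics of a real cohort
  back them — and they deliberately build in the two class signals a
  radiologist uses: multiplicity and size/shape.
* **Intensities.** Compartment means (enhancing bright on T1-CE, edema
  bright on FLAIR, necrosis dark on T1-CE; background 80, noise sd 5 in
  arbitrary units) mimic contrast semantics, not MR physics.  No bias
  fields, no motion, no skull: the "brain area" for normalization is the
  nonzero support of the phantom.
* **Automatic-segmentation emulation.** `corrupt_mask` adds smooth
  zero-mean noise to the signed distance of the whole-ROI support and
  bisects the amplitude until the Dice coefficient against truth reaches
  the target (±0.05; bisection itself converges to ±0.01), then relabels
  surviving voxels by nearest truth label and injects 1–3 spurious
  components of ≤ 30 voxels — small enough that default post-processing
  removes them, configurable larger to stress the decision strategy.
* **Splits.** Stratified train/validation/test assignment per class by
  largest-remainder apportionment (default fractions 0.6/0.2/0.2).

Because the class signal is strong and the confounders of real data
(scanner effects, annotation noise, overlapping phenotypes) are absent,
passing the synthetic studies demonstrates *correctness of the machinery*
(feature definitions, selection hygiene, decision logic, reproducibility),
not clinical-grade discrimination.

## Image standardization

Resampling uses SimpleITK with cell-centered grid alignment; output
dimensions are `round(dim · spacing / target)` per axis, linear
interpolation for images and nearest-neighbor for label masks, with
nearest-neighbor extrapolation at the half-voxel boundary.  Z-scoring uses
the **population** standard deviation (ddof = 0) over the brain mask;
voxels outside the mask are set to 0, and a constant brain region is a
hard error.  The two sequences of a case must share a grid — registration
and bias-field correction are solved library problems outside this
package's scope.

## Radiomics engine

Per sequence: 14 shape features (mask only) + 18 first-order and 68
texture features on each of 11 image types — original, Laplacian of
Gaussian at σ = 3 and 5 mm, and the 8 subbands of a one-level 3D wavelet
decomposition — for 960 features; two sequences plus the lesion number
give a 1921-long case vector.

* **Filters.** The LoG is spacing-aware (σ in mm converted per axis) with
  a wide kernel truncation (8σ) so a constant image maps to numerical
  zero.  The wavelet bank applies the `coif1` decomposition filters (any
  PyWavelets family is accepted) as an undecimated separable convolution
  with zero padding, so all 8 subbands live on the original grid; the
  detail filter of a constant image vanishes identically away from the
  boundary.
* **Discretization.** Fixed bin width within the ROI,
  `bin = floor((x − min)/width) + 1`.  The library default width of 25
  follows the raw-intensity radiomics convention; the pipeline presets use
  0.25 because they operate on Z-scored images (a few tens of gray levels
  result).  An optional gray-level cap guards pathological ranges.
* **Shape.** Surface area and volume come from a marching-cubes mesh of
  the mask; the indicator is smoothed by a 0.8-voxel Gaussian before
  meshing because the staircase mesh of a raw binary ball otherwise reads
  ~8% too much area (a 10-mm digital ball then scores sphericity ≈ 0.99
  instead of 0.92).  Thin ROIs that vanish under smoothing fall back to
  the raw mask and finally to voxel-count approximations.  Maximum 2D/3D
  diameters use the voxel-center convention on surface voxels (convex-hull
  pruning keeps this fast); axis lengths are 4√λ of the PCA eigenvalues of
  voxel-center coordinates.
* **Texture.** GLCM (symmetric, distance 1, 13 unique 3D directions,
  features averaged over directions), GLRLM (same directions; run lengths
  by pointer doubling), GLSZM (26-connected zones), GLDM (dependence = 1 +
  equal-gray 26-neighbors).  Family sizes 22/16/16/14 satisfy the fixed
  68-per-image-type total: the GLCM list omits SumAverage (duplicates
  JointAverage for a symmetric matrix) and the maximal correlation
  coefficient; the first-order list omits StandardDeviation (redundant
  with Variance).  Since no matrix entry can cross a whole-ROI connected
  component, matrices are accumulated per component on tight per-lesion
  boxes, a large speed-up for multi-lesion masks that is exactly
  equivalent to the direct computation.  Degenerate single-gray-level
  limits are defined (correlation 1, IMC1 0, inverse variance 0) so every
  vector entry is finite.

No parity with any existing radiomics library's numeric output is claimed;
the registry counts and internal oracles are the contract.

## Selection and ensemble

Scaling and every selector see training rows only.  The Mann–Whitney gate
uses the asymptotic p-value with tie and continuity correction at raw
p < 0.05 (Benjamini–Hochberg available but off, matching the stated gate).
LASSO is L1-penalized logistic regression with the penalty chosen by CV
AUC; MI uses the k-nearest-neighbor estimator (k = 3); RFE-RF eliminates
10% of remaining features per iteration by random-forest Gini importance.

Hyperparameters are tuned by grid search under the **one-standard-
deviation rule** in stratified 10-fold CV: among candidates whose mean AUC
is within one sd (the best candidate's own fold-score sd) of the best
mean, the simplest wins.  "Simplest" needs an ordering the rule itself
does not supply; per kind it is: stronger regularization (smaller C),
lower polynomial degree, fewer/shallower trees, larger naive-Bayes
smoothing.  SVMs obtain probabilities through their internal
cross-validated calibration.

The RSV model ranks the candidate classifiers by out-of-fold CV AUC, keeps
the top two (ties prefer the random-forest + RBF-SVM pair), and picks the
vote weights from the grid {1:1, 2:1, 2:3, 4:3, 3:1} by out-of-fold AUC.
AUC uses the trapezoidal ROC with half-credit ties, which makes it exactly
U/(n₁n₂); the test suite checks this against brute-force pair counting.

## EDPK decision strategy

Given the two automatic masks: remove components below `min_voxels`
(default 50 ≈ 50 mm³ at 1 mm isotropic; the threshold for "small false
positive" is a package choice), count whole-ROI lesions under
26-connectivity, and set `Number = max(L_G, L_M)`.  If `Number` is below
the set number (3), the case looks glioma-like: the masks are merged into
one ROI and the vote weights are equal.  Otherwise both masks are kept,
each is classified separately with the high-multiplicity weights (default
2:1 favoring the better-ranked base model), and the two vote outputs are
averaged (fusion configurable).  The lesion-number feature fed to the
classifier at inference is the decision's `Number` — ground truth is not
available clinically.  Weights are fixed per regime, not tuned per case,
and the whole decision serializes to an auditable record.

## Shapley explanations

Explanations live in the model's class-1 probability space.  Exact mode
enumerates all 2^k coalitions (k ≤ 12), marginalizing absent features over
background rows; additivity holds to 1e-8 by construction.  Monte-Carlo
mode samples feature permutations and averages each walk over a background
subsample (default 10 rows per permutation; using more rows trades compute
for variance), reporting per-feature standard errors and the additivity
residual as a diagnostic.  The background is the post-selection training
table, subsampled to at most 100 rows.  Cohort importance is the mean
|attribution| per feature, with the per-sample matrix retained for
beeswarm-style export.

## Validation studies and problem sizes

The studies the suite and `scripts/acceptance.py` run, with sizes chosen
as the package's own desk-scale defaults:

* registry counts on one 96×96×64 glioma phantom;
* oracle equivalences: GLCM vs. explicit pair counting on a 4×4×1 grid,
  AUC vs. U/(n₁n₂) on 20 scores, Mann–Whitney vs. exhaustive enumeration
  at n ≤ 8 per group (±0.02), exact Shapley vs. the linear closed form
  (1e-8), Monte-Carlo Shapley vs. exact on 3 features at 2000 permutations
  (±0.02);
* decision-branch property over all lesion-count pairs in [0, 10]²;
* parameter recovery on an n = 200 cohort (64×64×48 grids): test AUC of
  the radiologist-ROI pipeline, and recovery of the planted class signal
  by LASSO and RFE-RF.  Three class differences are constructed into the
  phantoms — lesion multiplicity, lesion size/shape, and the
  necrotic-compartment contrast (necrosis exists only in gliomas and is
  dark on T1-CE) — and the recovery check accepts any of them; in
  practice the necrosis signature (low-gray-level and minimum statistics
  of T1-CE) dominates because it separates the classes perfectly, while
  multiplicity and volume are noisier (univariate validation AUC ≈ 0.9
  and ≈ 0.7).  Every selected feature must additionally be genuinely
  class-informative on held-out validation rows (univariate AUC ≥ 0.8),
  so a selector that kept noise would fail;
* bit-level reproducibility of two identically seeded end-to-end runs
  (n = 16 demo cohort);
* EDPK vs. fixed-weight RSV on three seeded n = 60 cohorts with masks
  degraded to Dice ≈ 0.85, compared in median accuracy — a qualitative
  direction, not a numeric claim.

## Known limitations

* The phantoms carry no scanner effects, no annotation disagreement, and
  a deliberately separable class signal; synthetic performance numbers do
  not transfer to clinical data.
* The mask-corruption operator perturbs boundaries and adds small false
  positives but does not emulate systematic network failure modes
  (missing the necrotic core, hallucinating distant lesions).
* Lesion counting convention (whole ROI vs. enhancing compartment) is a
  package choice — whole ROI — and matters when edema bridges lesions.
* The one-sd-rule complexity orderings and the EDPK high-regime weights
  are under-determined by the problem statement; both are explicit,
  configurable package decisions.
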