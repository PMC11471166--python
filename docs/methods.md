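# Methods

## Problem and pipeline

A voxelwise segmentation model for pulmonary emboli produces, per CTPA
examination, a 3D field of softmax probabilities. The clinical question
is binary per examination. `pevol` converts the field into a decision
in three steps: binarize at a softmax threshold *p*, measure the
predicted embolus volume in physical units, and compare against a
volume threshold *V*. All statistics treat the examination, not the
voxel or the embolus, as the unit of analysis.

## Geometry and volumetry

Volumes are NIfTI images; spacing is taken from the affine (column
norms of the 3×3 block) and the voxel volume is |det| of that block,
which reduces to the spacing product for axis-aligned images and
remains correct for oblique ones. DICOM conversion handles the plain
single-series axial case: slices sorted by the projection of
ImagePositionPatient onto the slice normal, rescale slope/intercept
applied, variable inter-slice spacing rejected rather than resampled
(how non-uniform acquisitions should be handled is a scanner-protocol
question the pipeline does not decide). Multi-frame DICOM and gantry
tilt are out of scope.

Binarization keeps voxels with probability **≥ p**, so *p* = 1.0 is
meaningful and masks nest monotonically in *p*. Connected components
default to 26-connectivity in 3D and 8-connectivity in 2D — the common
convention for blob-like radiological structures; both are
configurable. 2D components are counted per axial slice (the
annotation plane), and a "1D component" is a single voxel, so the
3D/2D/1D counts decompose a segmentation hierarchically. Component
order is deterministic (lexicographically smallest voxel index).
`volume_profile` computes a whole threshold grid from one sort of the
voxel values rather than one image pass per threshold.

Empty masks are valid input throughout and yield a report with null
volume statistics: PE-negative examinations are the common path.

## Decision rules

An atomic rule fires when the measured volume **strictly exceeds** *V*.
Strict comparison makes *V* = 0 mean "any predicted voxel", which is
the natural low end of the calibration grid. The baseline
"no post-processing" configuration is the raw argmax mask of a
two-class softmax — threshold 0.5 — with a volume threshold only.
Rules carry either total-volume or per-component scope and combine via
ANY/ALL, so richer rule sets can be expressed in configuration without
code changes. The shipped defaults (strategy 1: p = 0.85, V = 20 mm³;
strategy 2: p = 0.90, V = 50 mm³) place the probability threshold
mid-grid at the canonical volume cutoffs; they are starting points
meant to be replaced by calibration output on the cohort of interest.

## Calibration

The grid search evaluates all 5 × 21 = 105 (p, V) points. Volume
profiles are computed once per (case, p); the V sweep is then pure
array thresholding, so calibration is O(cases × |p-grid|) image passes.
Strategy 1 is the MCC argmax; strategy 2 the specificity argmax, with
an optional sensitivity floor because unconstrained specificity
maximization can select degenerate all-negative rules on some cohorts
(the default keeps it unconstrained). Ties are broken toward higher
sensitivity, then lower V, then lower p: prefer the clinically safer,
simpler operating point; the order is deterministic and tested. On a
separable cohort several grid points may tie at MCC 1.0 — the returned
point is then one member of the classification-equivalent set.

## Statistics

* **MCC** — computed from exact integer products before the single
  square root; defined as 0 when any marginal is empty (standard
  convention, avoids NaN propagation in the grid search).
* **Wilson score intervals** for sensitivity, specificity, accuracy,
  with the normal quantile computed exactly from the confidence level
  (statsmodels backend). Bounds are snapped to exactly 0/1 at k = 0 and
  k = n, where the Wilson formula is exact. The interval always
  contains the point estimate and satisfies the complement symmetry
  low(k, n) = 1 − high(n−k, n); both are verified exhaustively for
  n ≤ 1000.
* **MCC confidence interval** — seeded stratified parametric bootstrap
  (binomial resampling within each true class, 2000 replicates,
  percentile bounds). Published MCC intervals for such classifiers do
  not state their method; the bootstrap is declared, not claimed
  identical.
* **AUROC** — ROC points at every distinct case-level volume score with
  strict-> thresholding (matching the classifier boundary), endpoints
  appended, trapezoidal area. This equals the Mann–Whitney probability
  of ranking a random positive above a random negative with ties
  counted half; the equivalence is tested against an O(n²) pairwise
  oracle. DeLong variance and AUC-difference tests are not provided.
* Percentages are displayed rounded to one decimal; tests compare
  unrounded values at tolerance 5e-4.

### Pooled ("combined") evaluation

The combined reference evaluation pools all negative examinations
(551 internal + 2 FUMPE + 385 RSPECT = 938) but only the external
positives (32 + 385 = 417); the internal positive arm, which the model
was trained on in cross-validation, contributes only its false
positives/true negatives. The reference confusion-matrix module encodes
this pooling explicitly. Strategy-2 per-cohort counts are reconstructed
from published sensitivity/specificity percentages and the fixed class
sizes; each is the unique integer count consistent with the printed
one-decimal percentage.

## Cohort handling

The small-PE exclusion removes PE-positive examinations whose
ground-truth annotated volume is **strictly below 50 mm³** (about a
cylinder 4 mm in diameter and height) before evaluation — very small
emboli carry high inter-observer variability and debatable clinical
relevance. Ground-truth volumes go through the same volumetry code
path as predictions. A positive case whose annotation cannot be
resolved is excluded and flagged `unresolvable`, never silently kept.
Fold splitting is plain seeded permutation into near-equal folds
(149 cases → 30/30/30/30/29); no stratification is applied.

## Synthetic phantoms

The generator emulates exactly the two properties the post-processing
consumes, nothing more:

* **Emboli**: voxelized ellipsoids. Interior probability is
  `peak · (1 − 0.15·r⁴)` with r the normalized ellipsoidal radius — at
  the peak in the center, 85% of the peak at the surface. The quartic
  taper keeps most of the blob above thresholds near the peak while
  still making measured volume shrink as the softmax threshold rises,
  the mechanism threshold calibration exploits. Default peak 0.95.
* **Cohort defaults**: positive cases draw embolus volumes from a
  log-normal (median 150 mm³, σ = 0.8) clipped to 60–1000 mm³, with a
  30% chance of a second embolus; every case carries 0–3 distractor
  blobs of 2–10 mm³ at peak 0.8 (abstract stand-ins for flow
  artifacts, veins, and low-contrast vessels) and sparse background
  speckle below 0.5. Together distractors and emboli span the
  ~10–1000 mm³ range over which the decision thresholds operate.
* Reported ground-truth volumes are measured from the generated
  annotation mask through the standard volumetry path, so generator
  and pipeline can never disagree about what was planted. All
  randomness flows from one seed; cohorts are byte-identical across
  reruns.

Voxelization accuracy: a sphere of radius 3 mm at 1 mm spacing
voxelizes to within 15% of (4/3)π·27 ≈ 113.1 mm³; the 15% bound was
fixed empirically as a regression tolerance and holds for semi-axes
≥ 3 mm (smaller blobs discretize more coarsely, which is why
sub-voxel-scale distractor volumes are nominal rather than exact).

What the phantoms do **not** model: HU intensities, vessel anatomy,
scanner noise, motion or contrast artifacts, or the correlation
structure of real network errors. Passing synthetic tests therefore
demonstrates correctness of the post-processing machinery — volumetry,
rule evaluation, calibration, statistics — not clinical performance of
any segmentation model.

Test and calibration cohorts use 48³ phantom volumes at 1 mm isotropic
spacing and 20 + 20 cases; these sizes make the planted effects
unambiguous while keeping the full suite fast.

## Known limitations

* Lesion-level (per-embolus) detection metrics and anatomical PE
  localization (main/lobar/segmental) are out of scope.
* No morphological post-filtering of masks; the rules operate on raw
  thresholded volumes.
* Acute vs. chronic PE is not distinguished anywhere in the pipeline.
* The DICOM path covers plain single-series axial CT only.
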