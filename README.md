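# pevol

Patient-level pulmonary embolism (PE) classification from the voxelwise
probability output of a CT pulmonary angiography (CTPA) segmentation
model.

A volumetric segmentation network (e.g. an nnU-Net) emits, for every
voxel of a CTPA examination, a softmax probability of belonging to an
embolus. Radiologists, however, need a single answer per examination:
PE or no PE. `pevol` implements the post-processing that bridges the
two:

1. **Volumetry** — threshold the probability field at a softmax level
   *p*, label 3D connected components, and measure the total predicted
   embolus volume in mm³ (voxel count × voxel volume from the NIfTI
   affine).
2. **Decision rules** — call the examination positive when the
   predicted volume *v(p)* exceeds a volume threshold *V*:
   `positive ⇔ v(p) > V`. Rules can be combined (ANY/ALL, total or
   per-component volume).
3. **Calibration** — grid-search the operating point over softmax
   thresholds p ∈ {0.75, 0.80, 0.85, 0.90, 0.95} and volume thresholds
   V ∈ {0, 10, …, 200} mm³ (105 points). *Strategy 1* maximizes the
   Matthews correlation coefficient (best sensitivity/specificity
   trade-off); *strategy 2* maximizes specificity.
4. **Evaluation** — confusion-matrix statistics with the standard
   diagnostic battery:

   - MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
   - Wilson score intervals for sensitivity, specificity, accuracy
   - AUROC over the case-level volume score (trapezoid = tie-corrected
     Mann–Whitney)

A cohort layer applies the small-PE exclusion filter (positives with
ground-truth volume < 50 mm³ removed from evaluation) and
cross-validation fold splitting, and a synthetic module generates
phantom cohorts — ellipsoidal emboli with radially tapering probability
plus low-probability distractor blobs — so the entire pipeline is
testable without patient data or a trained network.

Intended users: researchers building segmentation-based CAD pipelines
for PE who need the classification, calibration, and statistics layers
downstream of model inference.

## Worked example

Evaluate an operating point directly from patient-level counts
(TP = 123, FP = 30, TN = 521, FN = 5 — a 128-positive / 551-negative
cohort):

```
$ echo '{"tp": 123, "fp": 30, "tn": 521, "fn": 5}' > counts.json
$ pevol evaluate --counts counts.json --out report.json
MCC 0.849  sensitivity 0.961  specificity 0.946
```

i.e. sensitivity 96.1% (Wilson 95% CI 91–98%), specificity 94.6%
(92–96%), MCC 84.9%. The same numbers are available in the library as
`metric_set(ConfusionMatrix(tp=123, fp=30, tn=521, fn=5))`.

Calibrate operating points on a synthetic separable cohort (20
positives with planted emboli ≥ 60 mm³ at peak probability 0.95, 20
negatives with distractors ≤ 10 mm³ at peak 0.8):

```python
from pevol import ThresholdCalibrator, make_cohort
from pevol.synthetic import CohortSpec

manifest, volumes, _ = make_cohort(CohortSpec(n_positive=20, n_negative=20, seed=7))
vols = [volumes[c] for c in manifest["case_id"]]
result = ThresholdCalibrator.from_volumes(vols, manifest["label"].tolist()).fit()
print(result.summary())
```

```
Threshold calibration (grid search)
===================================================
cases: 40 (20 PE positive, 20 negative)
grid: 5 softmax thresholds x 21 volume thresholds = 105 points

strategy         p   V mm^3     MCC    sens    spec
---------------------------------------------------
strategy1     0.80        0   1.000   1.000   1.000
strategy2     0.80        0   1.000   1.000   1.000
---------------------------------------------------
strategy1: MCC argmax; strategy2: specificity argmax
```

The planted separation is recovered: at softmax threshold 0.80 no
distractor survives binarization, so any predicted voxel (V = 0)
perfectly identifies the positives. The full shell pipeline —
`pevol simulate → calibrate → classify → evaluate` — runs the same
computation from NIfTI files on disk; `pevol convert` turns a
single-series axial DICOM stack into the NIfTI input format, and
`pevol components` prints the 3D/2D/1D connected-component report of a
segmentation.

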