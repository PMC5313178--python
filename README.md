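# keyfusion

Registration-free classification of volumetric brain MR images by
**two-stage local feature fusion**: SIFT keypoints for cross-subject
correspondence, fixed-scale HOG descriptors for anatomical representation,
RV-coefficient scoring of per-keypoint group differences, and a signed
score-sum decision rule.

## Who this is for

Morphometry studies that want to compare local anatomy between a patient
group and controls **without deformable registration**. Voxel-based methods
assume a nonlinear warp establishes one-to-one correspondence across
subjects; when that assumption is shaky, the warp itself can destroy or
fabricate the group difference. Here, affine-aligned volumes are enough:
correspondence is established per landmark by matching scale-space
keypoints against a common template.

## The method

For a template volume *T* and labelled training volumes, each sliced along
the three anatomical orientations:

1. **Correspondence.** Keypoints (maxima/minima of the scale-normalised
   Laplacian of Gaussian) with 128-long unit-norm SIFT descriptors are
   extracted from every 2D slice. A template keypoint
   *f_i = {d_i, l_i, x_i, o_i, a_i}* (slice orientation, slice order,
   location, dominant orientation, appearance) is matched within each
   subject among the candidate points on the *same* slice: the closest
   candidate in descriptor space wins iff
   d_closest / d_second < ε_match (= 0.8), where the second distance comes
   from a geometrically distinct candidate. Keypoints matched in fewer than
   ε_rate (= 0.5) of either group's subjects are discarded; the survivors
   are the *K* **effective keypoints**.
2. **Representation.** Around every matched point, on the
   original-resolution slice rotated to the point's dominant orientation, a
   16×16-pixel block yields a HOG descriptor (4×4 subregions × 8
   orientation channels, unit norm; gray values and GLCM are available as
   alternatives). Stacking subjects gives per-keypoint group matrices
   Q_{i,p} (patients) and Q_{i,c} (controls).
3. **Quantification.** Each keypoint is scored by the group difference

       f_i^score = 1 − RV(Q_{i,p}, Q_{i,c}),

   RV(A,B) = tr(AAᵀBBᵀ) / [tr((AAᵀ)²)^½ · tr((BBᵀ)²)^½] ∈ [0,1],

   and a SMOTE-balanced linear SVM is trained on its descriptor columns
   (+1 patient, −1 healthy). The top-*k* keypoints by score are kept.
4. **Classification.** A test subject is matched against the effective
   keypoints; each matched keypoint contributes ±f_i^score according to its
   SVM's vote, giving LS_sum = Σ_i LS(θ_i). The subject is labelled patient
   iff LS_sum > ε_c, with ε_c calibrated on the training subjects to
   minimise |FN − FP|. Evaluation is leave-one-out, reporting accuracy,
   sensitivity, specificity and equal-error-rate (EER) accuracy.

Since real clinical cohorts cannot ship with a package, a
first-class synthetic generator produces template + cohort volumes with
planted textured landmarks and a controllable patient-group texture effect;
every claim the test suite makes is validated on those cohorts.

## Worked example

```python
from keyfusion import (PipelineConfig, SyntheticCohortSpec,
                       TwoStageFusionModel, generate_cohort)

spec = SyntheticCohortSpec(seed=0)          # 10 patients, 10 controls, 64^3
template, subjects, landmarks = generate_cohort(spec)

model = TwoStageFusionModel(template, subjects, PipelineConfig(top_k=30))
results = model.fit()
print(results.summary())
```

```
Two-stage local feature fusion classifier
=============================================
feature kind:            HOG
block size:              16 x 16
ratio-test eps_match:    0.8
coverage eps_rate:       0.5
keypoints selected (K):  30 (top_k=30)
score type:              rv (1-RV)
keypoint score range:    [0.0928, 0.4340]
mean keypoint score:     0.1858
decision threshold e_c:  -0.9358
```

The 30 selected keypoints are the template landmarks whose local HOG
structure differs most between the groups (scores up to 0.43 where planted
patient texture diverges; background keypoints score near 0.1). The
negative threshold compensates for keypoints that vote "healthy" slightly
more often than "patient" on both groups.

```python
cv = model.cross_validate()                 # leave-one-out over 20 subjects
print(cv.accuracy, cv.sensitivity, cv.specificity, cv.eer_accuracy)
# 100.0 100.0 100.0 100.0
```

On this strong-effect cohort every held-out subject is classified
correctly; with `effect_magnitude=0` the same pipeline stays at chance.

A CLI mirrors the library: `keyfusion simulate | train | predict |
evaluate` (see `keyfusion --help`).

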