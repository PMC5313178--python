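# Methods

This note documents the models, algorithms and numerical choices behind
`keyfusion`, in the order the pipeline runs them, together with what the
synthetic validation cohorts do and do not establish.

## Problem setting and assumptions

The package classifies 3D single-channel brain volumes into a patient and
a control group using only *local* anatomical structure. It assumes:

* inputs are already affine-aligned to a designated template volume (no
  deformable registration is attempted, by design — avoiding warp-induced
  loss of the very differences being studied);
* the same anatomical landmark appears on the same slice (orientation and
  order) in every aligned subject, up to small local displacement;
* group differences manifest as local gradient-structure changes around
  landmarks, at a common spatial scale.

Volumes are reoriented to canonical axes on load (axis 0 sagittal, 1
coronal, 2 axial) and decomposed into all 2D slices of the three
orientations; every stage below operates on slices.

## Stage 1 — correspondence

**Detection.** Keypoints are maxima and minima of the scale-normalised
Laplacian of Gaussian, computed per slice (after min–max normalisation to
[0, 1]) over a log-spaced σ grid of 1.6–6.4 px (6 steps). Defaults:
contrast threshold 0.08 on the scale-normalised response, principal-
curvature (edge) ratio 10, border margin 6σ. The contrast threshold was
chosen against the noise floor: with voxel noise at a few percent of the
dynamic range, pure-noise LoG responses reach ≈0.04, while blob-like
structures of amplitude comparable to the signal respond at 0.2–0.5; 0.08
sits a factor two above the noise ceiling. Each detection receives
dominant orientations from a 36-bin Gaussian-weighted gradient histogram
(σ_w = 1.5·scale, circular smoothing, parabolic peak refinement); every
peak ≥ 0.8 of the maximum spawns its own keypoint. This multi-orientation
rule matters: locally symmetric texture (any grating) has a bimodal
orientation histogram whose winner is decided by noise, and committing to
a single arbitrary winner makes descriptors irreproducible across
subjects.

**Appearance.** The SIFT descriptor is a 4×4 spatial grid of 8-channel
orientation histograms computed from a 16×16 sample grid spanning a window
of width 12·scale, rotated to the keypoint orientation, Gaussian-weighted,
clipped at 0.2 and renormalised to unit length (128 values). Samples
clipped by the slice border contribute zero gradient mass.

**Matching.** For template keypoint *f_i*, candidates are the subject's
keypoints with the same slice orientation and order (exact equality — the
affine pre-alignment justifies no ±1-slice tolerance). The closest
candidate by plain (unsquared) Euclidean descriptor distance is accepted
iff d₁/d₂ < ε_match = 0.8, where d₂ is the distance of the nearest
candidate *more than 3 px away from the best one*. The 3 px exclusion
implements the intent of the ratio test — the denominator is the closest
*incorrect* match — in the presence of duplicate detections of the same
physical point (secondary orientation copies, adjacent scale-space
responses). Without it, a keypoint's own duplicate drives the ratio to ~1
and vetoes nearly every correct match on textured structure. A slice
offering no geometrically distinct second candidate never yields a match
(a lone candidate cannot be certified), and equal distances at distinct
locations (ratio exactly 1) are rejected as ambiguous. Matching is
template-anchored and per-subject; subjects are never matched to each
other, and the identical operation is reused at test time.

**Coverage filter.** A keypoint matched in fewer than ε_rate = 0.5 of the
subjects of either group (strict inequality) is unrepresentative and
discarded; the survivors are the K effective keypoints.

## Stage 2 — representation and scoring

**Local descriptors.** Around each matched point, on the original-
resolution slice (down-sampled detection coordinates are mapped back by
the block-mean centre rule `i·f + (f−1)/2`), a `block_size`² block (16×16
default; 4 and 8 supported with the 4×4 subregion grid retained) is
resampled on a grid rotated to the matched point's own dominant
orientation (bilinear interpolation; out-of-bounds blocks raise and the
match is dropped with a warning). Three descriptors are implemented:

* **HOG** — central-difference gradients of the rotated block accumulated
  into 4×4 subregions × 8 orientation channels (soft-assigned between
  adjacent bins, Gaussian-weighted over the block with σ = block/2),
  flattened to 128 values, L2-normalised. The Gaussian weighting
  suppresses the block corners, which in noisy data are dominated by
  noise gradients rather than landmark structure.
* **GV** — the raw gray values of the rotated block, flattened, unit norm.
* **GLCM** — the block quantised to 8 gray levels; symmetric, per-offset
  normalised co-occurrence matrices for the four unit offsets (0,1),
  (1,0), (1,1), (1,−1) averaged and flattened to 64 values, unit norm
  (computed with scikit-image).

Degenerate (zero-gradient / all-zero) blocks fall back to the uniform
unit-norm vector so the column-norm invariant always holds.

**RV scoring.** The group difference at keypoint *i* is
1 − RV(Q_{i,p}, Q_{i,c}) with

    RV(A, B) = tr(A Aᵀ B Bᵀ) / [ tr((A Aᵀ)²)^½ · tr((B Bᵀ)²)^½ ],

computed through the cross-Gram identity tr(AAᵀBBᵀ) = ‖AᵀB‖²_F (O(H·n²)
instead of O(H²·n)), clamped to [0, 1] with a warning beyond 1e-8
round-off. RV is undefined for a zero matrix (error). A `uniform` scoring
mode (every score 1) is available for comparison. An RV-threshold
parameter is *not* implemented: no operation consumes one.

**Per-keypoint SVMs.** Columns of Q_{i,p} (+1) and Q_{i,c} (−1) train a
linear soft-margin SVM (libSVM via scikit-learn, C = 1, no kernel, no
scaling beyond the descriptors' unit norm). The minority group is first
over-sampled to the majority size with SMOTE (k = 5 neighbours, synthetic
samples x + u·(x_nn − x), u ~ U[0,1]; a single-sample minority falls back
to jittered duplication with a warning). Keypoints are ranked by score and
the top k = 100 kept (ties broken by template index; 30 is used in the
desk-scale studies below, commensurate with their ~10× smaller landmark
count).

## Classification and evaluation

A test subject's statistic is LS_sum = Σ_i ±f_i^score over matched
effective keypoints (+ if the keypoint's SVM labels the local descriptor
patient, − otherwise; unmatched keypoints contribute 0). The decision is
patient iff LS_sum > ε_c strictly. ε_c is calibrated on the training
subjects, scored by resubstitution, to minimise |FN − FP| over candidate
thresholds (midpoints of sorted unique scores plus sentinels beyond both
ends); ties prefer the candidate closest to 0, then the smaller value.
Resubstitution calibration is a known optimism source and is retained
deliberately as the method's defined procedure. EER accuracy is computed
the same way but minimising |FPR − FNR| (exact equality is generally
unattainable with discrete scores).

Leave-one-out cross-validation refits everything with fitted state —
coverage filtering, RV scores, SVMs, top-k selection, threshold — on each
training remainder. Keypoint detection, descriptor extraction and
template matching are per-subject deterministic operations with no
cross-subject state, so they are computed once and shared across folds;
a structural test asserts the fitted model is invariant to held-out data.

All randomness (SMOTE, synthetic cohorts) derives from a single seed via
`numpy` `SeedSequence` spawning; repeated runs are bit-identical.

## Synthetic validation cohorts

The generator renders, analytically (so sub-voxel jitter is exact rather
than a resampling artefact), a template with 12 blob landmarks
(anisotropic Gaussians, σ = 3 px, on a smooth background) on a 3-valued
grid per axis arranged so every occupied slice of every orientation holds
at least two landmarks — a lone candidate could never pass the
single-candidate rejection rule. Each landmark carries an oriented
sinusoidal grating (wavelength 4 px, relative amplitude 0.5, envelope
σ = 2.5·blob scale so texture fills the 16×16 block).

Subjects are noisy copies: landmark centres jittered N(0, jitter²)
(default 1 px), texture angle jittered (sd 0.05·jitter), texture phase
jittered (sd 1.2·jitter rad) and voxel noise at 5% of blob amplitude.
Patients differ at 6 of the 12 landmarks: the grating is blended toward a
concentric spherical-shell pattern (blend 0.75·min(effect, 1)). Choices
worth spelling out, found the hard way:

* A *rotation* or pure *frequency* change of the grating is invisible to
  the pipeline's descriptors — rotation is normalised away by the
  dominant-orientation frame and frequency by L2 normalisation. The
  grating→rings change alters the orientation *distribution*, which no
  rotation can hide.
* The blend is capped at 0.75 so the residual grating still wins the
  orientation vote and both groups are described in a common rotational
  frame.
* Phase jitter is the lever separating the representations: it
  decorrelates raw gray values within groups while oriented-gradient
  histograms remain comparatively stable. At sd 1.2 rad the HOG pipeline
  retains high accuracy while the GV pipeline degrades, reproducing the
  expected HOG ≥ GV ordering; far larger phase jitter eventually breaks
  per-keypoint SIFT matching stability itself.

**What passing these cohorts shows — and does not.** The cohorts validate
the machinery: correspondence under jitter and noise, the coverage filter,
RV ranking, SVM voting, threshold calibration, and the end-to-end recovery
of a known planted effect (and chance-level behaviour when the effect is
absent). They do not establish clinical performance: real MR anatomy has
cortical folding, global shape variation, intensity inhomogeneity and far
richer texture than Gaussian blobs with gratings, and real group effects
are weaker and spatially diffuse; the synthetic strong-effect cohort is
deliberately easier than any clinical problem.

## Study sizes and runtime

Desk-scale study conditions, frozen in the test fixtures: 10 patients +
10 controls, 64³ voxels, 12 landmarks (6 carrying the effect), effect
magnitude 1.0, top_k = 30, no down-sampling (the down-sampling operation
exists and defaults to factor 1; the block-mean factor-2 path is exercised
separately in tests because at 64³ a halved grid leaves too few pixels per
slice for 16×16 blocks at detection positions). One cohort takes ≈1 min to
extract and match on a single CPU; a full leave-one-out evaluation adds
seconds thanks to the per-subject caching.

## Known limitations

* 2D slice-wise SIFT, not 3D: keypoints are matched only within identical
  slice positions; out-of-plane displacement beyond a slice is invisible.
* Resubstitution threshold calibration is optimistic; EER accuracy on
  held-out scores is reported alongside.
* RV is sensitive to column count; scores of keypoints with few matched
  subjects are noisy (the coverage filter bounds, but does not remove,
  this effect).
* The SVM vote is a hard sign; margins are discarded by design.
* GLCM blocks are bilinearly resampled before quantisation, which smooths
  extreme single-pixel patterns (visible only in adversarial inputs like
  pixel-perfect checkerboards at half-pixel offsets).
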