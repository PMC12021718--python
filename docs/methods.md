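# Methods

## The segmentation model

`interactiveseg` implements minimally interactive 3D lesion segmentation
from six clicks. A user (or the synthetic-interaction generator) places
one point just inside the object near each of its six extreme
boundaries — the minimum and maximum extent along each spatial axis
("interior margin points"). These six points drive three stages:

1. **Volume of interest (VOI).** The componentwise bounding box of the
   points is relaxed on each side along axis *a* by
   `max(relaxation_fraction · extent_a, relaxation_min_voxels)`
   (defaults 0.1 and 5) and clipped to the grid. Because the points sit
   *inside* the object, the un-relaxed box would truncate it; the
   relaxation exists to guarantee encapsulation, which the test suite
   verifies on generated ellipsoid phantoms.
2. **Exponentialized geodesic distance (EGD).** On the cropped,
   intensity-normalized image, the geodesic distance D(i) from every
   voxel to the nearest click is the shortest-path cost over the
   6-connected voxel graph with edge weight
   `w(u,v) = sqrt((1−λ)·d_mm(u,v)² + λ·(I(u)−I(v))²)`, and the map is
   `exp(−α·D)`. Seeds have value exactly 1; values lie in (0, 1]. High
   values mark voxels both close and similar in intensity to the
   clicks, so the map highlights the clicked object. Defaults λ = 1
   (pure intensity; spatial separation is implicit in path length) and
   α = 1, both exposed. Because the EGD is computed *after*
   normalization and cropping, α is scale-free across modalities.
   The primary implementation is multi-source Dijkstra
   (`scipy.sparse.csgraph.dijkstra`, `min_only`), which is exact; the
   tests hold it to bit-exact agreement with an independent
   priority-queue Dijkstra.
3. **Network.** The normalized image crop and the EGD map are stacked
   as two channels and fed to a 3D U-Net-style encoder-decoder with
   `depth` resolution levels, two 3×3×3 convolutions per level
   (instance norm + leaky ReLU), 2× average pooling, nearest-neighbor
   upsampling with skip concatenation, and a 1×1×1 classification head.
   The network is implemented directly on numpy arrays with
   hand-written backpropagation (verified against finite differences in
   the tests) and Adam. Training minimizes equally weighted soft Dice +
   cross-entropy; k-fold cross-validation produces an ensemble whose
   softmax maps are averaged at inference. Predictions are argmaxed,
   optionally reduced to the largest 26-connected component, and mapped
   back to the original grid through the recorded crop/resample/pad
   geometry (nearest-neighbor for labels; exact when no resampling was
   applied).

## Synthetic interactions

Given a reference mask, the generator finds, for each axis and side,
a foreground voxel achieving the extreme coordinate, then moves it
inward along that axis by 5 voxels in-plane. A grid is anisotropic when
`max(spacing)/min(spacing) > 3`; its max-spacing ("out-of-plane") axis
uses a 1-voxel shift instead, since a 5-voxel displacement along a
thick-slice axis could exit a small lesion entirely. If the nominal
shift lands on background the shift is reduced stepwise until the point
is foreground, so thin structures still receive valid interior points.
Tie-breaks among extreme-face voxels go to the voxel nearest the face
centroid, then smallest linear index — deterministic and stable.

User variability is emulated by jittering each coordinate with a
uniform integer offset in [−m, +m], re-drawing (then clamping to the
nearest foreground voxel) when a draw lands outside the object; fully
determined by the configured seed.

## Phantoms

The phantom generator emulates the regime this method targets: a single
blob-shaped lesion in a noisy, smoothly textured background, with
controllable contrast (in noise-SD units), lobulation (a smooth
low-order angular perturbation of the ellipsoid radius, giving the
irregular, lobulated margins that make real tumors hard), an optional
1-voxel partial-volume edge ramp, anisotropic spacing, and optional
same-intensity decoy blobs placed disjoint from the lesion (≥ 3 voxel
separation) to make blob-designation experiments well-posed.

What the phantoms deliberately do **not** model: anatomy, multi-organ
backgrounds, bias fields, or modality-specific artifacts. Passing the
battery therefore certifies the pipeline's mechanics (geometry,
guidance, learnability, statistics), not clinical performance on real
CT/MRI — which would require real cohorts and full-scale training.

## Desk-scale validation battery

All validation runs on one CPU in minutes; problem sizes are the
package's desk profile, chosen as the smallest scales at which each
property is meaningfully exercised:

- EGD oracle equivalence: 50 random 16³ crops, 6 random seeds each,
  λ ∈ {0, ½, 1}; exact equality demanded.
- Interaction-rule fidelity: 100 phantoms alternating isotropic with
  spacing-ratio-4 anisotropic grids; point/foreground, exact shift and
  VOI-containment checks.
- Metric identities: 1000 random mask pairs (DSC = 2·IOU/(1+IOU) to
  1e−12), brute-force diameter oracle, exhaustive Wilcoxon enumeration
  for n ≤ 10.
- Learnability: 16 training + 8 held-out phantoms (32³, contrast 4,
  lobulation 0.2), tiny profile (depth 3, base 8), 6 epochs, single
  fold; thresholds mean DSC ≥ 0.75 and every case > 0.5.
- EGD-guidance ablation: 14 training + 10 held-out two-blob phantoms
  (40³); a guided and an image-only network trained identically with
  the crop covering the whole grid so both blobs are always visible.
  The guided model must designate the clicked blob in ≥ 90% of cases;
  the image-only model's designation rate must be statistically
  compatible with chance (95% binomial CI covering 0.5).
- Volumetry: analytic ellipsoids with semi-axes ≥ 8 voxels; volume
  within 5% of (4/3)πabc, transverse diameter within 2 in-plane voxels
  of the in-plane major axis.
- Reproducibility: the full CLI chain run twice with one seed must
  produce byte-identical metrics.csv.

## Numerical and design choices

- **Axis convention**: arrays are (x, y, z) with z the through-slice
  axis; NIfTI input is reoriented to closest-canonical (RAS) at load.
  Boxes are half-open `[lower, upper)`, coordinates 0-based.
- **Resampling**: origin-anchored voxel-center sampling; output shape
  `round_half_up(shape·spacing/target)`; linear for images, nearest for
  labels (preserves binarity).
- **Largest component**: 26-connectivity for postprocessing (permissive
  lesion retention); the geodesic graph is 6-connected (conservative
  path costs). Equal-size ties keep the component with the smallest
  minimum linear index.
- **Normalization**: CT uses cohort foreground statistics (clip to
  [p0.5, p99.5], then standardize); MRI uses per-volume z-scores over
  the nonzero region; constant volumes map to zeros.
- **Wilcoxon signed-rank**: zeros dropped, mid-ranks for ties; exact
  two-sided p by dynamic programming over the signed-rank distribution
  for n ≤ 25 (equivalent to enumerating all 2ⁿ sign assignments),
  normal approximation with tie correction above.
- **Empty masks**: empty-vs-empty overlap is defined as perfect
  agreement (1.0), because interactive and automatic predictions can
  legitimately be empty; sensitivity against an empty reference is
  undefined and reported missing.
- **Volume** is voxel-count × voxel-volume (oracle-verifiable); mesh
  measures would differ by well under a percent at lesion scale.
  **Diameter** uses voxel centers, a ≤ 1-voxel systematic difference
  from mesh-vertex conventions.
- **Bland-Altman**: differences in absolute units or percent of the
  pairwise mean (both supported; cohort reports default to percent);
  SD with n−1; limits of agreement mean ± 1.96·SD.
- **Loss/optimizer**: soft Dice (smoothing 1e−5) + cross-entropy,
  equally weighted; Adam with lr 1e−2 works well for the tiny profile.
- **Seeding**: every stochastic stage (phantoms, perturbation, fold
  splits, shuffling, initialization) derives from a single seed via
  `numpy.random.SeedSequence`, making training and inference
  run-to-run identical on one CPU.

## Known limitations

- The network is numpy-based and single-threaded-CPU oriented; it is
  intended for method validation and desk-scale experiments, not
  GPU-scale training on clinical cohorts.
- Only single-label (binary) segmentation is supported; no DICOM series
  reading or registration.
- The image-only ablation arm shares all preprocessing including the
  points-derived VOI; it isolates the EGD channel specifically, not the
  interaction information as a whole.
- Exact EGD/oracle equality relies on unique shortest paths, which
  holds almost surely for continuous random intensities; degenerate
  images with exactly tied path costs could differ in the last ulp.
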