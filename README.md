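# interactiveseg

Minimally interactive 3D tumor segmentation from six clicks.

Manual delineation of soft-tissue tumors on CT/MRI takes a radiologist
tens of minutes per scan, while fully automatic methods struggle to even
*find* lesions that can appear anywhere in the body with poor contrast
and irregular, lobulated margins. This package implements the middle
ground: a user clicks six **interior margin points** — one just inside
the object near its minimum and maximum extent along each spatial
axis — and the method does the rest. It is aimed at researchers who
need accurate 3D masks (for volumetry, diameter measurement, or
radiomics) at a fraction of the manual annotation cost, and at method
developers who want a fully reproducible, CPU-scale testbed for
click-guided segmentation.

## Method

The six clicks drive three stages:

1. **Volume of interest.** The bounding box of the points, relaxed by
   `max(0.1 × extent, 5)` voxels per side, crops the image — since the
   clicks are *inside* the object, relaxation is what guarantees the
   whole lesion is captured.
2. **Exponentialized geodesic distance (EGD).** For every voxel, the
   geodesic distance D(i) to the nearest click is the shortest-path
   cost on the 6-connected voxel graph with edge weight
   w(u,v) = √((1−λ)·d_mm(u,v)² + λ·(I(u)−I(v))²),
   and the guidance map is exp(−α·D(i)) ∈ (0, 1]. It highlights voxels
   close and similar in intensity to the clicks — effectively a soft,
   learnable segmentation prior.
3. **Segmentation network.** The normalized crop and the EGD map are
   concatenated as two channels into a 3D U-Net-style encoder-decoder
   (numpy implementation with hand-written backprop, soft Dice +
   cross-entropy loss, Adam, k-fold ensembling). Predictions are
   restored to the original grid with largest-component postprocessing.

Synthetic interactions are generated from reference masks exactly as a
careful user would click: extreme voxels moved 5 voxels inward in-plane
and — on anisotropic grids (max/min spacing ratio > 3) — 1 voxel along
the out-of-plane axis, with clamping so points always land inside the
object. A phantom generator (lobulated lesions, controllable contrast
and noise, decoy blobs, anisotropic spacing) makes the entire pipeline
trainable and testable without any data downloads. The evaluation
module provides DSC/IOU/sensitivity, voxel volumetry, maximum
transverse diameter, Bland-Altman limits of agreement, Pearson
correlation, and an exact paired Wilcoxon signed-rank test.

## Worked example

```python
import numpy as np
from interactiveseg import (PhantomConfig, generate_phantom, simulate_points,
                            compute_voi, overlap_metrics, volume_mm3,
                            max_diameter_transverse)
from interactiveseg.pipeline import PipelineConfig, TrainingConfig, train, predict
from interactiveseg.experiments import make_cases

# a 32^3 phantom with a lobulated lesion, and its six synthetic clicks
cfg = PhantomConfig(shape=(32, 32, 32), lesion_semiaxes_range=(6.0, 10.0), seed=7)
image, mask = generate_phantom(cfg)
pts = simulate_points(mask)
print("clicks:", pts.points.tolist())
print("VOI:", compute_voi(pts, image.shape).lower, "to",
      compute_voi(pts, image.shape).upper)

# train the tiny profile on 12 phantoms, then segment the example
cases = make_cases(12, cfg, seed=1)
ens = train([(v, m, p) for v, m, p in cases],
            PipelineConfig(training=TrainingConfig(epochs=6, seed=1)))
pred = predict(image, pts, ens)
dsc, iou, sens = overlap_metrics(pred, mask)
print(f"DSC={dsc:.3f}  IOU={iou:.3f}  sensitivity={sens:.3f}")
print(f"volume: pred {volume_mm3(pred):.0f} mm^3 vs ref {volume_mm3(mask):.0f} mm^3")
```

Output (about two minutes on one CPU):

```
clicks: [[10, 15, 19], [18, 15, 17], [14, 13, 18], [13, 17, 18], [15, 15, 14], [13, 15, 22]]
VOI: (5, 8, 9) to (24, 23, 28)
DSC=0.930  IOU=0.869  sensitivity=0.886
volume: pred 2807 mm^3 vs ref 3102 mm^3
```

The six clicks sit 5 voxels inside the lesion's extreme boundaries; the
relaxed VOI encloses the whole lesion; and the trained model recovers
the mask with DSC 0.93 and a ~10% volume error on this unseen phantom.

The same workflow is available from the shell:

```bash
interactiveseg phantom --n 20 --out data/ --seed 1
interactiveseg train --data data/ --out run/ --seed 1
interactiveseg predict --image data/images/case_000.nii.gz \
    --points data/points/case_000.json --model run/ --out seg.nii.gz
interactiveseg evaluate --pred-dir preds/ --ref-dir data/masks/ --out metrics.csv
```

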