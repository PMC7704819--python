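# muscleseg

Automated segmentation of the four functional thigh muscle groups —
quadriceps femoris (ROI1), sartorius (ROI2), gracilis (ROI3) and hamstrings
(ROI4) — in fat–water decomposition (Dixon) MRI, with per-muscle fat-fraction
quantification and reproducibility statistics. It is aimed at quantitative
muscle imaging: tracking fatty infiltration of muscle in neuromuscular
disease requires per-muscle-group masks on every scan, and drawing them by
hand is slow and operator-dependent.

## What the pipeline does

Given co-registered 3D **water** and **fat** magnitude volumes (NIfTI):

1. **Split** the bilateral volume into left/right thigh volumes at the
   in-plane midline.
2. **Preprocess**: K-means clustering (k = 2) of the water intensities keeps
   the high-intensity cluster (subcutaneous fat is dark on water images), an
   order-statistic filter strips the thin skin rim, slice-wise hole filling
   and an in-plane dilation produce the muscle-region mask; both channels
   are masked.
3. **Segment**: a 2-channel slice-wise U-net (water + fat, each min-max
   normalized to [0, 1] per volume) scores every pixel for
   {background, ROI1..ROI4}; per-ROI maps are squashed to (0, 1),
   binarized at 0.5 and multi-label pixels resolved by the highest score.
   The network is implemented in pure NumPy (im2col/shifted-GEMM
   convolutions with hand-written backpropagation and Adam), so training
   and inference run on any CPU with no deep-learning framework.
4. **Postprocess**: per ROI, only the largest 3D connected component
   (26-connectivity by default) is kept.
5. **Quantify**: the fat-fraction map FF = F / (W + F) is computed from the
   *original* intensities, and each ROI's volume (mm³) and mean fat
   fraction (meanFF, %) are reported.
6. **Evaluate**: volumetric Dice 2|A∩B|/(|A|+|B|), percent volume
   differences, meanFF differences (percentage points), test–retest
   reproducibility via ICC(2,1) with 95% F-distribution confidence bounds,
   and one-tailed Welch two-sample t-tests for group comparisons. Repeated
   scans of a thigh are averaged before any cohort mean.

A synthetic **phantom** module generates bilateral thigh cross-sections
(skin ring, subcutaneous fat ring, four muscle-group sectors with known
per-ROI fat fraction, bone) in separate water/fat channels with additive
Gaussian noise, per-subject anatomy draws and repositioning between
repeated scans — so the whole pipeline can be developed and validated with
exact ground truth.

## Worked example

```python
from muscleseg import (PhantomSpec, generate_phantom, split_thighs, split_labels,
                       muscle_mask_from_water, fat_fraction_map, roi_stats)

spec = PhantomSpec(noise_sigma=0.0,
                   roi_fat_fraction={1: 0.30, 2: 0.10, 3: 0.20, 4: 0.05})
vol, labels = generate_phantom(spec)
left, _ = split_thighs(vol)
ffm = fat_fraction_map(vol)
for roi in (1, 2, 3, 4):
    s = roi_stats(ffm, labels, roi)
    print(roi, s.n_voxels, round(s.volume_mm3), round(s.mean_ff_percent, 2))
```

prints

```
1 9686 58116 30.0
2 3120 18720 10.0
3 3120 18720 20.0
4 7862 47172 5.0
```

i.e. on a noise-free phantom the recovered meanFF of every muscle group
equals the specified ground-truth fat fraction exactly (30%, 10%, 20%, 5%),
and ROI volumes follow from voxel count × voxel volume (1 × 1 × 6 mm³
here). The same functions applied to a segmented clinical scan give the
per-muscle volumes and fat fractions used for reporting.

The command-line entry point mirrors the stages:

```bash
muscleseg phantom --out out/phantom --seed 1
muscleseg preprocess --water w.nii.gz --fat f.nii.gz --out out/pre
muscleseg run --config config.yaml --out out/run   # full staged pipeline
muscleseg icc --table meanff_table.csv
```

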