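# Methods

This note documents the models, parameter choices and numerical decisions
behind `muscleseg`, and what the synthetic validation does and does not
demonstrate.

## Problem setting

Fat–water decomposition (Dixon) MRI reconstructs separate water and fat
magnitude images from multi-echo acquisitions. The per-voxel fat fraction
FF = F / (W + F) of a muscle is a biomarker of fatty infiltration, but it
is only useful per muscle group, which requires segmenting each group on
every scan. The pipeline automates that segmentation for the four
functional thigh groups (quadriceps femoris, sartorius, gracilis,
hamstrings) and the downstream quantification and reproducibility
statistics.

## Synthetic phantom

The phantom is a geometric stand-in for an axial bilateral mid-thigh
acquisition. Each thigh is a set of nested discs/annuli: skin ring
(default 2 mm), subcutaneous fat ring (5 mm), a muscle compartment holding
the four muscle-group ROIs as angular sectors separated by 4° septa, and a
central bone (5 mm radius). The default grid is 64 × 128 × 12 voxels at
1 × 1 × 6 mm (half the grid per thigh); the anisotropic 6 mm slice spacing
mirrors clinical axial protocols. A linear through-plane taper (10% radius
decrease across the stack) models the distal narrowing of the thigh and
makes slices within a volume non-identical.

Signal model: each tissue has a nominal total amplitude T and a fat
fraction FF; noise-free channels are W = T(1−FF), F = T·FF, so F/(W+F)
equals FF *exactly* at every voxel — the ground-truth meanFF of an ROI is
the specified value with no discretization error. Defaults: muscle and
subcutaneous fat T = 100 (subcutaneous FF 0.90, unlabelled muscle FF 0.10),
skin T = 30 (FF 0.20), bone/marrow T = 40 (FF 0.50). Additive i.i.d.
Gaussian noise (σ expressed as a fraction of the muscle amplitude, then
clipped at zero) emulates magnitude-image noise. No MR physics is
simulated: no echoes, T1/T2* weighting, phase errors, chemical-shift
artefacts, bias fields, or partial-volume mixing.

Cohorts draw per-subject parameters once (per-ROI FF uniform in a
configurable range; thigh radius 25–30 mm, subcutaneous thickness 4–7 mm,
bone radius 4–6 mm by default, so subjects differ anatomically as real
cohorts do) and re-render each repeated scan under a fresh small in-plane
rigid transform (|shift| ≤ 3 mm per axis, |rotation| ≤ 5°) with fresh
noise, emulating subject repositioning. Re-rendering the analytic geometry
(rather than resampling a rendered volume) keeps masks crisp and fat
fractions exact under repositioning. The right thigh is the exact voxel
mirror of the left.

Consequently, passing tests on phantoms demonstrate that the pipeline's
machinery is correct and self-consistent — they do not demonstrate
segmentation accuracy on clinical images, whose texture, contrast and
anatomical variability the phantom deliberately does not model.

## Preprocessing

Subcutaneous fat and skin are removed from the water image only:

1. K-means with k = 2 on the nonzero water intensities of the whole volume
   (one threshold per volume avoids slice-to-slice jitter); the cluster
   with the higher centroid is kept. Seeded with 10 restarts, best inertia,
   so the step is deterministic.
2. A slice-wise order-statistic filter on the binary mask (5 × 5 window,
   ascending rank 7 — a voxel survives only if ≥ 18 of its 25 neighbours
   are in the mask) strips a 1–2 voxel rim without rounding off convex
   muscle boundaries.
3. Slice-wise binary hole filling (restores the bone region and interior
   dropouts), then dilation with an in-plane disc of radius 2 voxels to
   recover muscle voxels eroded in step 2.

All window sizes, ranks and radii are config-exposed (`PreprocessConfig`);
the defaults above were chosen for the geometry of the phantom and of
512 × 512 thigh scans and are the package's own choices — the procedure
prescribes the steps, not their parameters. Bone is deliberately not
removed. Masking the channels zeroes everything outside the muscle region.

## U-net segmenter

Architecture: 2 input channels (water, fat), `depth` encoder levels of two
3 × 3 conv + ReLU blocks with channel doubling (16, 32, 64 at depth 3) and
2 × 2 max pooling, a bottleneck, and a decoder of nearest-neighbour 2×
upsampling, skip concatenation and two conv blocks per level; a final
1 × 1 convolution emits one score map per class. Input sizes must be
divisible by 2^depth.

The default head is a 5-class softmax trained with categorical
cross-entropy over {background, ROI1..ROI4}; a per-ROI sigmoid/BCE head is
selectable. Prediction squashes each ROI map to (0, 1) — the softmax class
probability under the softmax head, the elementwise sigmoid under the
sigmoid head — binarizes at 0.5 (strictly greater; exactly-at-threshold is
background, a deterministic measure-zero convention), resolves pixels
above threshold in several maps by the highest score, and restacks slices.
Binarizing raw-logit sigmoids under a softmax head is incorrect (background
pixels can carry positive ROI logits) and is intentionally not done.

Training: Adam, batch size 6, per-epoch validation with best-validation
parameters retained, optional per-epoch cosine learning-rate decay (to 5%
of the initial rate). The train/validation split is at volume level, with
optional grouping so the two thighs (and repeated scans) of one subject
never straddle the split — without this the validation loss leaks
subject-specific appearance and stops tracking generalization. Optional
group normalization after each convolution (batch-size independent, no
running statistics, so training and inference are identical and
deterministic) is available for harder regimes; the desk-scale default
trains without it. He initialization, float32 throughout; all randomness
(init, shuffling) flows from one seed and training is bit-deterministic
for a fixed BLAS.

**Chirality canonicalization.** Left and right thighs are mirror images,
so the anatomical layout of the muscle groups is reversed between sides.
A single network shown both chiralities must infer the side from image
content, which is impossible wherever fat-fraction contrast between
neighbouring groups vanishes — in practice the nearly mirror-symmetric
anterior quadriceps sector was learned well while posterior/medial groups
collapsed. The pipeline therefore mirrors right thighs in-plane to the
left-handed frame before the network (training and inference) and mirrors
predictions back. This is a lossless relabeling, not augmentation; it
also doubles the effective sample density per anatomical configuration,
exactly as pooling left and right thighs is meant to.

The implementation is pure NumPy: convolutions are evaluated as k²
shifted GEMMs (measured ~2–3× faster on CPU than materializing the im2col
patch matrix at these channel counts), with analytic backward passes
verified against finite differences. The desk-scale default (depth 3, 16
base filters, ≈ 0.49 M parameters, 64 × 64 slices, learning rate 10⁻³,
25 epochs) trains in minutes on one CPU core; depth/width/epochs scale up
by config for full-resolution use, where a small learning rate
(e.g. 10⁻⁶) with many epochs is the appropriate regime.

## Postprocessing

Stacked 2D predictions may contain spurious islands; for each ROI only the
largest 3D connected component is kept. Default connectivity is 26
(face + edge + corner): the most permissive choice, so thin oblique
muscles (sartorius) are not split across the anisotropic 6 mm slices.
Voxel topology ignores metric spacing. Size ties break to the component
whose first voxel comes earliest in C-order raster scan (deterministic).
The operation is idempotent and voxel-count non-increasing.

## Quantification

FF maps are computed on original intensities — per-channel min-max
normalization is for the network only and does not preserve F/(W+F).
Voxels with W + F = 0 carry no tissue signal and are marked undefined and
excluded from meanFF (their count is reported) rather than treated as
FF = 0, which would bias means toward zero. meanFF is reported in percent;
ROI volume is voxel count × voxel volume.

## Evaluation statistics

* **Dice** 2|A∩B|/(|A|+|B|) over 3D voxel sets per ROI. Both-empty pairs
  return 1.0 (vacuous agreement, logged); empty-vs-nonempty returns 0.
* **Percent volume difference** is signed, (auto − manual)/manual × 100;
  absolute values are taken only when averaging over a cohort.
* **Aggregation**: repeated scans of a thigh are averaged before cohort
  means, so thighs scanned three times do not carry triple weight.
* **ICC**: reproducibility of meanFF across repeated scans uses ICC(2,1) —
  two-way random effects, absolute agreement, single measure — because
  repositioned repeat scans are a random factor and reproducibility means
  absolute agreement, not mere consistency; ICC(3,1) is selectable. The
  estimate comes from the classical ANOVA mean squares and the 95% CI from
  the standard F-distribution bounds (McGraw & Wong); the implementation is
  cross-checked against `pingouin` in the test suite. A table with zero
  total variance is flagged degenerate (NaN); perfect repeatability with
  subject differences returns exactly 1.0.
* **Group comparison**: one-tailed two-sample Welch t-test (unequal
  variances, Welch–Satterthwaite df), e.g. abnormal > normal meanFF, with
  p < 0.05 as the conventional significance level.

## Desk-scale validation experiment

`run_experiment` (and `scripts/acceptance.py`) runs the whole study on a
synthetic cohort sized for a single CPU core: 20 training + 5 held-out
bilateral subjects (50 thigh volumes, 600 slices), per-ROI FF uniform in
[0.05, 0.4], 3% noise, subject-grouped 3 : 1 train/validation split, depth-3
U-net with 16 base filters trained 25 epochs at a cosine-decayed learning
rate starting from 10⁻³ with batch size 6, right thighs mirrored to the
canonical chirality, largest-component postprocessing, then
Dice/volume/meanFF
evaluation on the 10 held-out thighs. These sizes are the package's
desk-scale defaults; they trade statistical power for a run time of
minutes, and every one of them scales up by config.

## Known limitations

* The phantom's sector geometry makes muscle-group boundaries partly
  visible through FF contrast; real inter-muscle fascia is far subtler, so
  phantom Dice overstates clinical accuracy.
* No data augmentation (none is part of the procedure); the network relies
  on cohort variability.
* Multi-stack scans must be stitched upstream; inputs are assumed
  single-stack and co-registered.
* No confounder-corrected PDFF (T1 bias, T2*, multi-peak fat spectrum) —
  FF here is the plain magnitude ratio; correction belongs to the
  acquisition/reconstruction side.
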