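# Methods

`oppscreen` implements an opportunistic osteoporosis screening pipeline
for axial vertebral CT: vertebral-body segmentation by an
encoder–decoder convolutional network with channel-attention skip
fusion, quantitative-CT (QCT) bone-mineral-density (BMD) measurement and
three-class bone-mass labeling, and a residual-network classifier that
predicts the bone-mass class directly from the segmented vertebral
image(s). Because clinical CT cohorts of this kind are not publicly
distributable, the package ships a synthetic phantom generator that
reproduces the statistical structure of an adult health-check cohort;
all tests and benchmarks run on phantoms.

## Phantom model

A phantom slice is an ellipse (the vertebral body) on a noisy
soft-tissue background:

* **Geometry.** Semi-axes default to 0.26 and 0.20 of the image side,
  with ±5 % axis jitter and ±2 % centre jitter per slice. A cortical rim
  of fixed thickness (6 px at 512 px, scaled for smaller profiles) is
  drawn at constant high intensity (default 420). The ground-truth mask
  is the set of pixels strictly inside the inner rim edge — the region a
  radiologist outlines for QCT.
* **Trabecular texture.** Interior intensity is `slope·BMD + intercept`
  plus i.i.d. Gaussian noise (sd 25) plus a low-frequency blob field
  whose sd is 0.15 of the noise sd. The blob fraction was fixed by a
  100-seed Monte-Carlo so that the total ROI measurement error stays
  within the standard-error tolerance implied by the i.i.d. noise alone
  (max |error| 2.8 mg/cm³ at the default profile); larger blob fields
  add spatially correlated error that no pixel-count argument bounds.
* **Calibration.** Intensity maps linearly to BMD with slope 1 and
  intercept 0 by default, so intensity is numerically mg/cm³. Real QCT
  uses a vendor phantom calibration; a linear map with identity default
  removes an unidentifiable nuisance while keeping the labeling rule
  directly checkable.
* **Vessel.** With probability 0.5 a small dark disc (the basivertebral
  vein) is placed in the posterior third of the body.
* **Intensity scale.** The clinical source images are soft-tissue-window
  CT without a stated intensity convention, so the phantom scale is a
  free choice recorded in `PhantomSpec`.

### Cohort model

A cohort draws one subject-level BMD per subject from a per-class
truncated normal; defaults reproduce a 1048-subject screening cohort:
class counts 621/296/131 (normal/osteopenia/osteoporosis) and per-class
mean ± sd of 168.33 ± 23.12, 99.35 ± 10.91 and 60.32 ± 16.48 mg/cm³ on
supports [120.30, 295.10], [80, 120] and [5.70, 79.90]. Because those
published figures are moments **of the truncated data**, the generator
solves for the parent-normal parameters whose truncation matches them
(`scipy.optimize.fsolve`); sampling the printed values directly as
parent parameters would bias the osteoporosis class mean by ≈ −3.6
mg/cm³. L1 and L2 BMD are `m ± d` with `d ~ N(0, 4 mg/cm³)`, so their
mean is exactly the subject BMD (keeping the label consistent by
construction) while the two vertebrae differ realistically. Optional
demographics (sex ≈ 58 % male, age ≈ N(51, 14.4) clipped to 20–92) feed
only the statistics reports, never the models.

### Labeling rule

`bmd_individual` is the mean of the available vertebral measurements;
class cut-offs are > 120 (normal), 80–120 inclusive (osteopenia), < 80
mg/cm³ (osteoporosis). Both boundaries belong to osteopenia.

### ROI measurement

The operator-placed ROI is replaced by a deterministic surrogate: erode
the mask by 3 px (scaled with image size) to avoid cortical bone, keep
the 60 % of remaining pixels closest to the centroid, then drop pixels
more than 3 sd below the ROI median in one pass (vessel avoidance).
BMD = (mean intensity − intercept)/slope.

## Segmentation network

Configurable-depth encoder–decoder (default depth 7). Encoder layers
1…d−2 each apply a 1×1 convolution (channel mixing) followed by a 3×3
residual block; all but the first of these halve the resolution (the
residual shortcut is a strided 1×1 projection where needed). Layers
d−1 and d are 2×2 stride-2 convolutions. The decoder uses 2×2
transposed convolutions; the deepest skip is fused by channel
attention — concatenate, global-average-pool, two 1×1 convolutions,
sigmoid — with the weights multiplied onto the skip features and the
product added to the upsampled features; shallower skips use plain
concatenation + 3×3 convolution. A final 1×1 convolution yields the
foreground logit, whose bias is initialised to −1.9 (≈ the 13 %
foreground prior). Channel widths double from `base_channels` and are
capped (defaults 16→256); ReLU + batch normalisation follow every
convolution, and the second batch-norm of each residual block starts at
γ = 0 so blocks begin as identities. Input spatial size must be
divisible by 2^(depth−1). The reference architecture description leaves
the per-layer widths and the exact attention placement open; the
readings above are this package's.

**Loss** is soft-Dice (per-sample, ε = 1) plus pixel-mean binary
cross-entropy. **Training** uses SGD (the only supported optimizer)
with the standard learning rate 0.001; augmentation applies an
identical random flip/mirror/±15° rotation/90–100 % crop to image and
mask. Model selection keeps the checkpoint with the best tuning-set
mean Dice; the output threshold is 0.5. Training aborts on a non-finite
loss.

Two named profiles ship:

| profile | size | depth | base ch. | epochs | batch | momentum |
|---|---|---|---|---|---|---|
| clinical | 512 | 7 | 16 | 500 | 64 | 0.9 |
| desk | 96 | 5 | 8 | 15 | 2 | 0.99 |

The desk profile is the package's CPU-scale study condition. At the
fixed 0.001 learning rate a short epoch budget is compensated by many
small-batch SGD steps and heavy momentum (effective step ∝ 1/(1−m));
batch normalisation keeps this stable. The test suite exercises only
the desk profile; the clinical profile is provided but not
benchmarked here.

Two baselines support sanity checks: a classic U-Net builder
(`build_unet_baseline`, same channel scheme, no residual blocks or
attention) and, in the tests, a best-fixed-ellipse oracle (the mean of
the training masks, thresholded) that any trained model must beat on
noise-free phantoms.

## Classifier

Residual network: 7×7 stride-2 convolution stem (+BN+ReLU), 3×3
stride-2 max-pool, four residual stages with unit counts (3, 4, 6, 3) —
each unit is 3×3, 3×3, 1×1 convolutions with shortcut; the first unit
of stages 2–4 is a projection ("DBlock") unit whose shortcut carries a
strided 1×1 convolution — then global average pooling and a fully
connected layer to three logits. The reference description names
ResNet-101 yet spells out (3, 4, 6, 3) units; the spelled-out counts
are the default and a canonical (3, 4, 23, 3) switch exists rather
than silently "fixing" the discrepancy. Model 1 takes the
two-channel (L1, L2) fusion feature image; model 2 takes L1 alone —
the builders differ only in stem input channels.

Inputs are the original intensities multiplied by the segmentation mask
(background zeroed), resized to `input_size`, divided by 300. Training:
cross-entropy with inverse-frequency class weights (the cohort is ~6:3:1
imbalanced), SGD momentum 0.9 / lr 0.001 by default; the desk profile
raises momentum to 0.99 for the same short-budget reason as above.
Model selection keeps the best validation macro one-vs-rest AUC.

## Evaluation statistics

* **Splitting**: largest-remainder apportionment of the 5:1:4
  train:validation:test ratios, optionally stratified per label (each
  part's class count is then within one item of the global proportion).
  A published 1096/200/800 split of 2096 images is not an exact 5:1:4
  largest-remainder partition (which gives 1048/210/838); the splitter
  documents its rounding rule rather than targeting printed counts.
* **ROC/AUC**: Mann–Whitney form (ties ½) via midranks.
* **CI**: DeLong variance, normal approximation, clipped to [0, 1].
* **DeLong test**: paired structural-components estimator (midrank,
  O(n log n)); Z = ΔAUC/√var, two-sided normal P. Zero variance with
  unequal AUCs is flagged degenerate rather than silently 0 or ∞-safe.
* **Confusion metrics**: one-vs-rest Se/Sp/PPV/NPV/Ac at the arg-max
  prediction; zero-denominator ratios are NaN, never 0.
* **χ²**: Pearson, no continuity correction (the published 0.862 and
  22.91 reproduce only uncorrected).
* **t from summaries**: Welch or pooled — an explicit argument, because
  the published per-row tests mix both; t = (mean₂ − mean₁)/SE.
* **One-way ANOVA from summaries**: between/within mean squares from
  (n, mean, sd) triplets.

## Desk-scale benchmarks (the package's study conditions)

* Segmentation: 300 training / 25 tuning / 100 test phantom slices at
  96 px (cohort-distributed BMD), desk profile. Reference floor: mean
  test Dice 0.951 — the published real-CT value at 300 training images;
  phantoms are cleaner than real CT, so the trained network should
  exceed it.
* Classification: 500-subject cohort at 6:3:1 with the reference
  cohort's BMD distributions, stratified 5:1:4 split, model-2 (L1-only) desk
  training on ground-truth-masked inputs. Reference floor: osteoporosis
  one-vs-rest test AUC 0.978 (the published model-2 value).
* Calibration: DeLong type-I error over 2000 null replicates (two
  equally informative correlated score vectors, n = 200, α = 0.05)
  within 3.5–6.5 %; DeLong CI coverage at true AUC 0.8, n = 100, within
  93–97 %.

These scaled-down conditions are the package's own choices for
single-CPU reproducibility; sizes and seeds are fixed in
`oppscreen.benchmarks` and `scripts/acceptance.py`.

## What the phantoms do and do not show

Passing benchmarks on phantoms demonstrates that the architectures,
losses, training loops and statistics are implemented correctly and can
solve a structurally analogous task end to end. Phantoms lack real
trabecular microarchitecture, degenerative change, implants, partial
volume and scanner physics (beam hardening, dose, reconstruction
kernels), and the vertebra is a single convex ellipse — so phantom
Dice/AUC values say nothing quantitative about clinical performance,
and the published cohort-specific values are deliberately not treated
as reproduction targets, only as floors for the easier synthetic task.

## Numerical choices and degenerate inputs

* All network arithmetic is float32 on a numpy autodiff stack written
  for this package (`oppscreen.nn`): im2col convolutions, exact
  analytic backward passes (verified against numeric and naive-loop
  oracles in the test suite), SGD with momentum.
* Dice of two empty masks is 1.0; single-class label vectors, empty
  ROIs after erosion, missing classes in a training set, and non-finite
  BMD inputs all raise typed errors rather than returning silent
  defaults.
* Determinism: every stochastic component takes a seed;
  `SeedSequence` children fan a single pipeline seed out to stages, so
  stages can be recomputed in isolation. Reruns are bit-identical in
  single-threaded mode.

## Known limitations

2-D only; no DICOM; the clinical profile is untested at full
scale on CPU; the classifier benchmark uses ground-truth masks (the
pipeline variant chains the trained segmenter instead); momentum-heavy
small-batch SGD is tuned for the easy phantom task and would need
re-tuning on harder data.
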