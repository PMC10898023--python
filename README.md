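# oppscreen

Opportunistic osteoporosis screening from axial vertebral CT, exercised
end to end on synthetic phantoms.

Routine chest CT already images the upper lumbar spine, so the bone
mineral density (BMD) that quantitative CT (QCT) measures there can be
extracted "for free" and screened for osteoporosis without extra
scanning. This package implements that pipeline as testable software:

* **`oppscreen.phantom`** — synthetic axial vertebral slices (elliptical
  body, bright cortical rim, trabecular texture whose mean intensity
  encodes BMD, optional basivertebral vessel) and cohorts matching a
  1048-subject health-check population (class mix 621/296/131; per-class
  BMD 168.33 ± 23.12, 99.35 ± 10.91, 60.32 ± 16.48 mg/cm³).
* **`oppscreen.qct`** — ROI-based BMD measurement on a segmented slice
  and the three-class rule: BMD > 120 normal, 80 ≤ BMD ≤ 120 osteopenia,
  BMD < 80 mg/cm³ osteoporosis; the subject value is the L1/L2 mean.
* **`oppscreen.segnet`** — encoder–decoder segmentation network (1×1
  convolution + 3×3 residual block encoder layers, 2×2 stride-2 tail,
  transposed-convolution decoder with channel-attention skip fusion),
  Dice+BCE training, augmentation, Dice metrics, learning curves.
* **`oppscreen.classifier`** — residual three-class bone-mass classifier;
  model 1 takes the (L1, L2) two-channel fusion feature image, model 2
  takes L1 alone.
* **`oppscreen.evalstats`** — 5:1:4 largest-remainder splits, ROC/AUC
  (Mann–Whitney), DeLong confidence intervals and the paired DeLong
  test, Se/Sp/PPV/NPV/Ac, χ²/t/ANOVA from printed summary tables.
* **`oppscreen.pipeline` / the `oppscreen` CLI** — a reproducible
  simulate → split → train → segment → classify → evaluate → compare run
  with per-stage seeds, config hashes and resume.

The networks run on a compact numpy autodiff stack (`oppscreen.nn`)
written for this package, sized so the whole pipeline trains on one CPU.

## Worked example

```python
import numpy as np
from oppscreen import phantom, qct, segnet

spec = phantom.PhantomSpec.desk(96)             # 96-px desk profile
subject = phantom.generate_subject(spec, bmd_l1=168.33, bmd_l2=160.0, seed=7)

roi = qct.RoiSpec.for_image_size(96)
result = qct.measure_subject(subject.l1_slice, subject.l1_mask,
                             subject.l2_slice, subject.l2_mask, roi=roi)
print(f"L1 {result.bmd_l1:.1f}  L2 {result.bmd_l2:.1f}  "
      f"subject {result.bmd_individual:.1f} mg/cm3 -> {result.label}")
```

prints

```
L1 169.0  L2 160.9  subject 165.0 mg/cm3 -> normal
```

— the ROI measurement recovers each vertebra's true BMD (168.33 and
160.0) to within ~1 mg/cm³ of trabecular-noise error, and the subject
mean 165.0 > 120 labels the subject normal.

Narrative scripts in `examples/` cover each capability (phantom
cohorts, segmentation training, classification, the evaluation
statistics, the full pipeline), each printing the numbers it computes
and what they mean. The shell entry point mirrors them, e.g.

```bash
oppscreen run-all --profile desk --seed 7 --out runs/demo
oppscreen tablestats --ttest examples/data_age30_39.csv
```

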