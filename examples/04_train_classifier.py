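"""Train the L1-only (model 2) bone-mass classifier on a small cohort.

120 subjects at the reference class mix, ground-truth masks, 8 desk epochs
(~1-2 minutes); prints per-class one-vs-rest AUCs on the held-out part.
The full 500-subject condition lives in `oppscreen.benchmarks`.
"""

import numpy as np

from oppscreen import classifier as clf
from oppscreen import phantom
from oppscreen.evalstats import SplitSpec, roc_auc, split_indices
from oppscreen.qct import LABELS

spec = phantom.PhantomSpec.desk(96)
cohort = phantom.CohortSpec.scaled(120, seed=5)
subjects, meta = phantom.generate_cohort(cohort, spec)

parts = split_indices(meta.label.to_numpy(),
                      SplitSpec(ratios=(5, 1, 4), stratify=True, seed=5))


def inputs(idx):
    xs = [clf.prepare_input(subjects[i].l1_slice, subjects[i].l1_mask, 96)[None]
          for i in idx]
    ys = [subjects[i].true_label for i in idx]
    return xs, ys


tr, va, te = (inputs(p) for p in parts)
model, hist = clf.train_classifier(
    *tr, *va, clf.ClfModelConfig.desk(in_channels=1),
    clf.ClfTrainConfig.desk(epochs=8, seed=2))
print("validation macro AUC per epoch:",
      [round(v, 3) for v in hist["val_macro_auc"]])

probs = clf.predict_proba_batch(model, te[0])
y = np.array([LABELS.index(l) for l in te[1]])
for k, lab in enumerate(LABELS):
    if len(set(y == k)) == 2:
        print(f"test one-vs-rest AUC, {lab:<12}: "
              f"{roc_auc(probs[:, k], (y == k).astype(int)):.3f}")
# Each AUC is the probability that a random subject of that class gets a
# higher class score than a random subject of the other classes. The
# phantom encodes class in trabecular brightness, so the extreme classes
# approach AUC 1 even at this small cohort size; osteopenia, squeezed
# between both thresholds, is hardest and benefits most from more
# subjects (see the 500-subject benchmark).
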