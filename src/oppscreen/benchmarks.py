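"""Desk-scale reference benchmarks.

Self-contained experiments at the package's CPU-scale study conditions:

* ``segmentation_benchmark`` — train the encoder-decoder on 300 phantom
  slices (25 tuning) and report mean/SD Dice on 100 held-out phantoms.
* ``classification_benchmark`` — generate a 500-subject phantom cohort
  at the 6:3:1 class mix with the reference cohort's per-class BMD distributions,
  split 5:1:4 stratified, train the residual classifier, and report
  per-class one-vs-rest test AUCs.
* ``delong_type1_error`` / ``auc_ci_coverage`` — statistical calibration
  of the DeLong test and the DeLong confidence interval under simulation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import classifier as clf
from . import phantom, segnet
from .evalstats import SplitSpec, auc_ci, delong_test, roc_auc, split_indices
from .qct import LABELS

__all__ = ["segmentation_benchmark", "classification_benchmark",
           "delong_type1_error", "auc_ci_coverage"]


def _phantom_pool(n_slices: int, spec: phantom.PhantomSpec, seed: int):
    """Slices drawn from cohort-distributed subjects (two per subject)."""
    n_subjects = (n_slices + 1) // 2
    cohort = phantom.CohortSpec.scaled(n_subjects, seed=seed)
    subjects, _ = phantom.generate_cohort(cohort, spec)
    imgs, msks = [], []
    for s in subjects:
        imgs.extend([s.l1_slice, s.l2_slice])
        msks.extend([s.l1_mask, s.l2_mask])
    return imgs[:n_slices], msks[:n_slices]


def segmentation_benchmark(seed: int = 0, n_train: int = 300, n_tune: int = 25,
                           n_test: int = 100, image_size: int = 96,
                           epochs: int = 15) -> dict:
    """Held-out Dice of the desk-profile segmentation network trained on
    ``n_train`` phantom slices."""
    spec = phantom.PhantomSpec.desk(image_size)
    ss = np.random.SeedSequence((seed, 5))
    s_train, s_tune, s_test = [int(c.generate_state(1)[0] % 2 ** 31)
                               for c in ss.spawn(3)]
    tr_i, tr_m = _phantom_pool(n_train, spec, s_train)
    tu_i, tu_m = _phantom_pool(n_tune, spec, s_tune)
    te_i, te_m = _phantom_pool(n_test, spec, s_test)
    cfg = segnet.SegTrainConfig.desk(epochs=epochs, seed=s_train)
    model, hist = segnet.train_segmentation(tr_i, tr_m, tu_i, tu_m,
                                            segnet.SegModelConfig.desk(), cfg)
    m = segnet.evaluate_dsc(model, te_i, te_m)
    return dict(dsc_mean=m.dsc_mean, dsc_sd=m.dsc_sd, n_train=n_train,
                n_test=n_test, history=hist)


def classification_benchmark(seed: int = 0, n_subjects: int = 500,
                             variant: str = "model2", image_size: int = 96,
                             epochs: int = 15) -> dict:
    """Per-class one-vs-rest test AUCs of the desk-profile classifier on a
    6:3:1 phantom cohort (ground-truth masks, 5:1:4 stratified split)."""
    counts = (int(n_subjects * 0.6), int(n_subjects * 0.3),
              n_subjects - int(n_subjects * 0.6) - int(n_subjects * 0.3))
    ss = np.random.SeedSequence((seed, 6))
    s_cohort, s_split, s_train = [int(c.generate_state(1)[0] % 2 ** 31)
                                  for c in ss.spawn(3)]
    cohort = phantom.CohortSpec(n_subjects=n_subjects, class_counts=counts,
                                seed=s_cohort)
    spec = phantom.PhantomSpec.desk(image_size)
    subjects, meta = phantom.generate_cohort(cohort, spec)

    labels = meta.label.to_numpy()
    parts = split_indices(labels, SplitSpec(ratios=(5, 1, 4), stratify=True,
                                            seed=s_split))

    def build_inputs(idx):
        xs, ys = [], []
        for i in idx:
            s = subjects[i]
            l1 = clf.prepare_input(s.l1_slice, s.l1_mask, image_size)
            if variant == "model1":
                l2 = clf.prepare_input(s.l2_slice, s.l2_mask, image_size)
                xs.append(clf.fuse_features(l1, l2))
            else:
                xs.append(l1[None])
            ys.append(s.true_label)
        return xs, ys

    tr_x, tr_y = build_inputs(parts[0])
    va_x, va_y = build_inputs(parts[1])
    te_x, te_y = build_inputs(parts[2])
    mcfg = clf.ClfModelConfig.desk(
        in_channels=2 if variant == "model1" else 1, input_size=image_size)
    tcfg = clf.ClfTrainConfig.desk(epochs=epochs, seed=s_train)
    model, hist = clf.train_classifier(tr_x, tr_y, va_x, va_y, mcfg, tcfg)
    probs = clf.predict_proba_batch(model, te_x)
    y_idx = np.array([LABELS.index(l) for l in te_y])
    aucs = {lab: roc_auc(probs[:, k], (y_idx == k).astype(int))
            for k, lab in enumerate(LABELS)}
    return dict(auc=aucs, n_subjects=n_subjects, n_test=len(te_y),
                variant=variant, history=hist)


def delong_type1_error(seed: int = 0, n_replicates: int = 2000, n: int = 200,
                       alpha: float = 0.05) -> float:
    """Empirical type-I error of the paired DeLong test under the null:
    two equally informative, correlated score vectors."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    rejections = 0
    y = np.repeat([0, 1], n // 2)
    for _ in range(n_replicates):
        latent = rng.normal(size=n) + y          # common signal, AUC ~0.76
        s1 = latent + rng.normal(0, 0.8, n)
        s2 = latent + rng.normal(0, 0.8, n)      # same distribution as s1
        if delong_test(s1, s2, y).p < alpha:
            rejections += 1
    return rejections / n_replicates


def auc_ci_coverage(seed: int = 0, n_replicates: int = 2000, n: int = 100,
                    true_auc: float = 0.8, level: float = 0.95) -> float:
    """Empirical coverage of the DeLong CI in the binormal model whose
    population AUC is ``true_auc``."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 8)))
    mu = np.sqrt(2.0) * stats.norm.ppf(true_auc)
    y = np.repeat([0, 1], n // 2)
    hits = 0
    for _ in range(n_replicates):
        scores = rng.normal(size=n) + mu * y
        lo, hi = auc_ci(scores, y, level)
        if lo <= true_auc <= hi:
            hits += 1
    return hits / n_replicates
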