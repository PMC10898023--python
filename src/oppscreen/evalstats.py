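"""Evaluation statistics for the screening models.

ROC/AUC in the Mann-Whitney form with DeLong confidence intervals, the
paired DeLong test for correlated AUCs (midrank structural-components
estimator), one-vs-rest confusion metrics (Se, Sp, PPV, NPV, Ac),
largest-remainder 5:1:4 dataset splitting with optional stratification,
and the contingency-table / summary-statistics tests used for cohort
baseline tables (Pearson chi-square, two-sample t from summaries, one-way
ANOVA from summaries).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["SplitSpec", "SummaryGroup", "TestResult", "DelongResult",
           "ClassificationReport", "split_indices", "split_dataset",
           "roc_auc", "auc_ci", "delong_test", "confusion_metrics",
           "chi_square_homogeneity", "t_from_summary", "anova_f_from_summary",
           "evaluate_model"]


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train : tuning/validation : test ratios (default 5:1:4)."""

    ratios: tuple[float, ...] = (5, 1, 4)
    stratify: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) < 2 or any(r <= 0 for r in self.ratios):
            raise ValidationError("ratios must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratios"] = list(self.ratios)
        return d


def _apportion(n: int, ratios: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of n items by the given ratios."""
    r = np.asarray(ratios, dtype=float)
    quota = n * r / r.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    frac = quota - base
    order = np.argsort(-frac, kind="stable")
    base[order[:rem]] += 1
    return base


def split_indices(labels_or_n, spec: SplitSpec) -> tuple[np.ndarray, ...]:
    """Disjoint, exhaustive index arrays for each part.

    Pass an integer for an unstratified split, or the label sequence when
    ``spec.stratify``; stratification apportions within each label.
    """
    k = len(spec.ratios)
    rng = np.random.default_rng(spec.seed)
    if isinstance(labels_or_n, (int, np.integer)):
        labels = None
        n = int(labels_or_n)
    else:
        labels = np.asarray(labels_or_n)
        n = labels.size
    if n < k:
        raise ValidationError(f"cannot split {n} items into {k} parts")
    if not spec.stratify or labels is None:
        perm = rng.permutation(n)
        sizes = _apportion(n, spec.ratios)
        cuts = np.cumsum(sizes)[:-1]
        return tuple(np.sort(p) for p in np.split(perm, cuts))
    parts: list[list[np.ndarray]] = [[] for _ in range(k)]
    for lab in pd.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if idx.size < k:
            warnings.warn(
                f"class {lab!r} has {idx.size} item(s), fewer than {k} parts; "
                "some parts get none of this class", stacklevel=2)
        idx = rng.permutation(idx)
        sizes = _apportion(idx.size, spec.ratios)
        cuts = np.cumsum(sizes)[:-1]
        for p, chunk in enumerate(np.split(idx, cuts)):
            parts[p].append(chunk)
    return tuple(np.sort(np.concatenate(p)) if p else np.array([], dtype=int)
                 for p in parts)


def split_dataset(items, spec: SplitSpec, labels=None):
    """Split a sequence of items into disjoint parts by ``spec``."""
    if spec.stratify and labels is None:
        raise ValidationError("stratified split requires labels")
    idx_parts = split_indices(labels if spec.stratify else len(items), spec)
    return tuple([items[i] for i in part] for part in idx_parts)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components via midranks (O(n log n)).

    Returns (auc, v10, v01) where v10 are per-positive and v01
    per-negative components.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels) -> float:
    """AUC: probability a random positive outscores a random negative,
    ties counted one-half (Mann-Whitney form)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores/labels length mismatch")
    auc, _, _ = _structural_components(s, y)
    return auc


def auc_variance(scores, labels) -> float:
    """DeLong variance estimate of the AUC."""
    y = _check_binary(labels)
    auc, v10, v01 = _structural_components(np.asarray(scores, dtype=float), y)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation DeLong confidence interval, clipped to [0,1]."""
    auc = roc_auc(scores, labels)
    se = np.sqrt(auc_variance(scores, labels))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.clip(auc - z * se, 0.0, 1.0)),
            float(np.clip(auc + z * se, 0.0, 1.0)))


@dataclass(frozen=True)
class DelongResult:
    auc_1: float
    auc_2: float
    z: float
    p: float
    degenerate: bool = False


def delong_test(scores_model1, scores_model2, labels) -> DelongResult:
    """Paired DeLong test for two correlated AUCs on the same items."""
    y = _check_binary(labels)
    s1 = np.asarray(scores_model1, dtype=float)
    s2 = np.asarray(scores_model2, dtype=float)
    if s1.shape != y.shape or s2.shape != y.shape:
        raise ValidationError("both models must score the same items")
    a1, v10_1, v01_1 = _structural_components(s1, y)
    a2, v10_2, v01_2 = _structural_components(s2, y)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = a1 - a2
    if var <= 0:
        if diff == 0:
            return DelongResult(a1, a2, 0.0, 1.0, degenerate=False)
        return DelongResult(a1, a2, float(np.sign(diff) * np.inf), 0.0,
                            degenerate=True)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(a1, a2, float(z), float(p))


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def confusion_metrics(predicted, true, positive) -> dict[str, float]:
    """One-vs-rest Se, Sp, PPV, NPV, Ac; zero-denominator ratios are NaN."""
    pred = np.asarray(predicted)
    ref = np.asarray(true)
    if pred.size == 0 or pred.shape != ref.shape:
        raise ValidationError("predicted/true must be equal-length and non-empty")
    if positive not in ref:
        raise ValidationError(f"positive class {positive!r} absent from truth")
    pp = pred == positive
    tp_mask = ref == positive
    tp = int((pp & tp_mask).sum())
    fp = int((pp & ~tp_mask).sum())
    fn = int((~pp & tp_mask).sum())
    tn = int((~pp & ~tp_mask).sum())

    def ratio(a, b):
        return a / b if b else float("nan")

    return {"se": ratio(tp, tp + fn), "sp": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp), "npv": ratio(tn, tn + fn),
            "ac": (tp + tn) / pred.size}


# ---------------------------------------------------------------------------
# contingency and summary-statistics tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryGroup:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1 or self.sd < 0:
            raise ValidationError("need n >= 1 and sd >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    kind: str = ""


def chi_square_homogeneity(table) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValidationError("table must be a 2-D array of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("table has a zero row/column margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(chi2), df=int(df), p=float(p), kind="chi2")


def t_from_summary(g1: SummaryGroup, g2: SummaryGroup,
                   method: str = "welch") -> TestResult:
    """Two-sample t test from group summaries; t = (mean2 - mean1) / SE."""
    if g1.n < 2 or g2.n < 2:
        raise ValidationError("each group needs n >= 2")
    v1, v2 = g1.sd ** 2, g2.sd ** 2
    if method == "welch":
        se2 = v1 / g1.n + v2 / g2.n
        t = (g2.mean - g1.mean) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / g1.n) ** 2 / (g1.n - 1)
                         + (v2 / g2.n) ** 2 / (g2.n - 1))
    elif method == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        t = (g2.mean - g1.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    else:
        raise ValidationError(f"unknown method {method!r}; use 'welch' or 'pooled'")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), kind=f"t-{method}")


def anova_f_from_summary(groups: list[SummaryGroup]) -> TestResult:
    """One-way ANOVA F from per-group (n, mean, sd) summaries."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    k = len(groups)
    df_within = n_total - k
    if df_within < 1:
        raise ValidationError("no within-group degrees of freedom")
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds ** 2).sum()
    msb = ssb / (k - 1)
    msw = ssw / df_within
    if msw == 0:
        f = 0.0 if msb == 0 else float("inf")
    else:
        f = msb / msw
    p = float(stats.f.sf(f, k - 1, df_within)) if np.isfinite(f) else 0.0
    return TestResult(statistic=float(f), df=(k - 1, float(df_within)), p=p,
                      kind="anova")


# ---------------------------------------------------------------------------
# model evaluation report
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Per-class one-vs-rest metrics on one dataset."""

    dataset: str
    classes: tuple[str, ...]
    rows: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "class"
        df.insert(0, "dataset", self.dataset)
        return df.reset_index()


def evaluate_model(probs: np.ndarray, y_true, classes: tuple[str, ...],
                   dataset: str = "test", level: float = 0.95) -> ClassificationReport:
    """Assemble AUC (+CI) and Se/Sp/PPV/NPV/Ac per class from softmax
    probabilities; predictions are the arg-max class."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y_true)
    if probs.ndim != 2 or probs.shape[0] != y.size:
        raise ValidationError("probs must be (n_items, n_classes)")
    if probs.shape[1] != len(classes):
        raise ValidationError("probs columns must match classes")
    y_idx = y if np.issubdtype(y.dtype, np.integer) else \
        np.array([classes.index(v) for v in y])
    pred = probs.argmax(axis=1)
    report = ClassificationReport(dataset=dataset, classes=tuple(classes))
    for k, name in enumerate(classes):
        binary = (y_idx == k).astype(int)
        if binary.min() == binary.max():
            report.rows[name] = dict(auc=float("nan"), ci_low=float("nan"),
                                     ci_high=float("nan"), se=float("nan"),
                                     sp=float("nan"), ppv=float("nan"),
                                     npv=float("nan"), ac=float("nan"),
                                     flagged="class absent")
            continue
        auc = roc_auc(probs[:, k], binary)
        lo, hi = auc_ci(probs[:, k], binary, level)
        cm = confusion_metrics((pred == k).astype(int), binary, positive=1)
        report.rows[name] = dict(auc=auc, ci_low=lo, ci_high=hi, **cm, flagged="")
    return report
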