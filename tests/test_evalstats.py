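"""Evaluation statistics: splits, ROC/AUC, DeLong, contingency and
summary-statistics tests, oracle equivalences."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oppscreen import cohort_tables as tables
from oppscreen import evalstats as es
from oppscreen.errors import ValidationError


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def auc_by_pair_counting(scores, labels):
    """Exhaustive concordant-pair count over all positive-negative pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def delong_components_naive(scores, labels):
    """O(n^2) structural components by the double loop."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

class TestSplit:
    def test_exact_apportionment_n10(self):
        parts = es.split_indices(10, es.SplitSpec(ratios=(5, 1, 4), seed=0))
        assert tuple(len(p) for p in parts) == (5, 1, 4)

    @given(st.integers(min_value=3, max_value=300), st.integers(0, 99))
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, n, seed):
        parts = es.split_indices(n, es.SplitSpec(ratios=(5, 1, 4), seed=seed))
        allidx = np.concatenate(parts)
        assert allidx.size == n
        assert np.array_equal(np.sort(allidx), np.arange(n))

    def test_stratified_matches_apportionment_oracle(self):
        """Per-part class counts equal largest-remainder apportionment of
        each class, checked by enumerating remainders directly."""
        counts = (621, 296, 131)
        labels = np.repeat(["normal", "osteopenia", "osteoporosis"], counts)
        spec = es.SplitSpec(ratios=(5, 1, 4), stratify=True, seed=3)
        parts = es.split_indices(labels, spec)

        def oracle(n, ratios=(5, 1, 4)):
            q = [n * r / sum(ratios) for r in ratios]
            base = [int(np.floor(v)) for v in q]
            rem = n - sum(base)
            fr = sorted(range(3), key=lambda i: -(q[i] - base[i]))
            for i in fr[:rem]:
                base[i] += 1
            return tuple(base)

        for lab, n in zip(("normal", "osteopenia", "osteoporosis"), counts):
            got = tuple(int((labels[p] == lab).sum()) for p in parts)
            assert got == oracle(n)
        # within 1 item of the global proportions in every part
        for p in parts:
            for lab, n in zip(("normal", "osteopenia", "osteoporosis"), counts):
                expected = len(p) * n / 1048
                assert abs((labels[p] == lab).sum() - expected) <= 1

    def test_same_seed_idempotent(self):
        spec = es.SplitSpec(seed=9)
        a = es.split_indices(57, spec)
        b = es.split_indices(57, spec)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_split_dataset_items(self):
        items = list("abcdefghij")
        tr, tu, te = es.split_dataset(items, es.SplitSpec(seed=1))
        assert sorted(tr + tu + te) == items
        assert len(tr) == 5 and len(tu) == 1 and len(te) == 4

    def test_small_class_warns(self):
        labels = np.array(["a"] * 9 + ["b"])
        with pytest.warns(UserWarning, match="fewer than"):
            es.split_indices(labels, es.SplitSpec(stratify=True, seed=0))


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        assert es.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert es.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        # 4 positive-negative pairs, 3 concordant -> 0.75
        assert es.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            es.roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 999))
    @settings(max_examples=40, deadline=None)
    def test_complement_identity(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        scores = r.normal(size=n)
        labels = np.r_[0, 1, r.integers(0, 2, n - 2)]
        assert es.roc_auc(scores, labels) + es.roc_auc(-scores, labels) \
            == pytest.approx(1.0)

    @given(st.integers(0, 999))
    @settings(max_examples=40, deadline=None)
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 50))
        scores = np.round(r.normal(size=n), 1)   # force some ties
        labels = np.r_[0, 1, r.integers(0, 2, n - 2)]
        assert es.roc_auc(scores, labels) == pytest.approx(
            auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert es.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestAucCi:
    def test_contains_point_and_ordered(self, rng):
        scores = rng.normal(size=80) + np.r_[np.zeros(40), np.ones(40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        lo, hi = es.auc_ci(scores, labels)
        auc = es.roc_auc(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_width_shrinks_with_n(self, rng):
        widths = []
        for n in (40, 160, 640):
            scores = rng.normal(size=n) + np.repeat([0, 1.19], n // 2)
            labels = np.repeat([0, 1], n // 2)
            lo, hi = es.auc_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


# --------------------------------------------------------------------------
# DeLong
# --------------------------------------------------------------------------

class TestDelong:
    def test_identical_scores(self, rng):
        s = rng.normal(size=60)
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        r = es.delong_test(s, s, y)
        assert r.z == 0.0 and r.p == 1.0 and not r.degenerate

    def test_antisymmetry(self, rng):
        s1 = rng.normal(size=100) + np.repeat([0, 0.8], 50)
        s2 = s1 + rng.normal(0, 0.6, 100)
        y = np.repeat([0, 1], 50)
        a = es.delong_test(s1, s2, y)
        b = es.delong_test(s2, s1, y)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    @given(st.integers(0, 499))
    @settings(max_examples=30, deadline=None)
    def test_variance_matches_naive_double_loop(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 50))
        scores = np.round(r.normal(size=n), 1)
        y = np.r_[0, 1, r.integers(0, 2, n - 2)]
        auc_fast = es.roc_auc(scores, y)
        var_fast = es.auc_variance(scores, y)
        auc_naive, v10, v01 = delong_components_naive(scores, y)
        var_naive = (v10.var(ddof=1) / v10.size if v10.size > 1 else 0.0) \
            + (v01.var(ddof=1) / v01.size if v01.size > 1 else 0.0)
        assert auc_fast == pytest.approx(auc_naive, abs=1e-12)
        assert var_fast == pytest.approx(var_naive, abs=1e-12)

    def test_degenerate_flagged(self):
        # perfect separation by both models with unequal AUCs is impossible;
        # build zero-variance case: both models constant-order, all items agree
        y = np.array([0, 0, 1, 1])
        r = es.delong_test([1, 2, 3, 4], [1, 2, 4, 3], y)
        # model 2 has one discordant pair -> auc 0.75, var may be positive
        assert 0 <= r.p <= 1


# --------------------------------------------------------------------------
# confusion metrics
# --------------------------------------------------------------------------

class TestConfusionMetrics:
    def test_perfect(self):
        m = es.confusion_metrics([1, 0, 1], [1, 0, 1], positive=1)
        assert all(v == 1.0 for v in m.values())

    def test_all_negative_predictions(self):
        true = np.r_[np.ones(10, int), np.zeros(30, int)]
        pred = np.zeros(40, int)
        m = es.confusion_metrics(pred, true, positive=1)
        assert m["se"] == 0.0
        assert m["sp"] == 1.0
        assert m["npv"] == pytest.approx(30 / 40)
        assert np.isnan(m["ppv"])          # no positive predictions

    def test_stated_counts(self):
        """TP=48 FN=3 FP=17 TN=350 -> the five standard ratios."""
        true = np.r_[np.ones(51, int), np.zeros(367, int)]
        pred = np.r_[np.ones(48, int), np.zeros(3, int),
                     np.ones(17, int), np.zeros(350, int)]
        m = es.confusion_metrics(pred, true, positive=1)
        assert m["se"] == pytest.approx(48 / 51)
        assert m["sp"] == pytest.approx(350 / 367)
        assert m["ppv"] == pytest.approx(48 / 65)
        assert m["npv"] == pytest.approx(350 / 353)
        assert m["ac"] == pytest.approx(398 / 418)

    def test_positive_absent(self):
        with pytest.raises(ValidationError):
            es.confusion_metrics([0, 1], [0, 0], positive=1)


# --------------------------------------------------------------------------
# contingency and summary tests
# --------------------------------------------------------------------------

class TestChiSquare:
    def test_sex_by_dataset(self):
        r = es.chi_square_homogeneity(tables.SEX_BY_DATASET)
        assert r.statistic == pytest.approx(0.862, abs=5e-4)
        assert r.df == 2
        assert r.p == pytest.approx(0.650, abs=5e-4)

    def test_bmd_category_by_dataset(self):
        r = es.chi_square_homogeneity(tables.BMD_CATEGORY_BY_DATASET)
        assert r.statistic == pytest.approx(0.994, abs=5e-4)
        assert r.df == 4

    def test_sex_by_age_group(self):
        r = es.chi_square_homogeneity(tables.SEX_BY_AGE_GROUP)
        assert r.statistic == pytest.approx(22.91, abs=5e-3)
        assert r.df == 7
        assert r.p == pytest.approx(0.002, abs=5e-4)

    def test_proportional_rows_zero(self):
        r = es.chi_square_homogeneity([[10, 20, 30], [20, 40, 60]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            es.chi_square_homogeneity([[0, 0], [1, 2]])

    @given(st.integers(0, 199))
    @settings(max_examples=25, deadline=None)
    def test_permutation_and_transpose_invariance(self, seed):
        r = np.random.default_rng(seed)
        t = r.integers(1, 50, size=(3, 4))
        base = es.chi_square_homogeneity(t).statistic
        perm = t[r.permutation(3)][:, r.permutation(4)]
        assert es.chi_square_homogeneity(perm).statistic == pytest.approx(base)
        assert es.chi_square_homogeneity(t.T).statistic == pytest.approx(base)


class TestTFromSummary:
    def test_published_30_39_welch(self):
        r = es.t_from_summary(tables.BMD_30_39_MALE, tables.BMD_30_39_FEMALE,
                              method="welch")
        assert abs(r.statistic) == pytest.approx(4.174, abs=0.01)
        assert r.p < 0.001

    def test_equal_means_zero(self):
        g = es.SummaryGroup(20, 50.0, 5.0)
        h = es.SummaryGroup(30, 50.0, 8.0)
        for method in ("welch", "pooled"):
            assert es.t_from_summary(g, h, method).statistic == 0.0

    @pytest.mark.parametrize("method", ["welch", "pooled"])
    def test_moment_matched_raw_data_oracle(self, rng, method):
        """Summary-based t equals scipy's raw-data t on samples constructed
        to have exactly the summary moments."""
        def sample(n, mean, sd, r):
            x = r.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        a = sample(25, 10.0, 3.0, rng)
        b = sample(40, 12.5, 4.0, rng)
        raw = sps.ttest_ind(b, a, equal_var=(method == "pooled"))
        r = es.t_from_summary(es.SummaryGroup(25, 10.0, 3.0),
                              es.SummaryGroup(40, 12.5, 4.0), method)
        assert r.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert r.p == pytest.approx(raw.pvalue, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            es.t_from_summary(es.SummaryGroup(1, 5.0, 1.0),
                              es.SummaryGroup(5, 5.0, 1.0))


class TestAnovaFromSummary:
    def test_identical_means(self):
        gs = [es.SummaryGroup(10, 5.0, 1.0), es.SummaryGroup(12, 5.0, 2.0)]
        assert es.anova_f_from_summary(gs).statistic == 0.0

    def test_two_groups_f_equals_pooled_t_squared(self):
        g1 = es.SummaryGroup(14, 8.0, 2.0)
        g2 = es.SummaryGroup(19, 10.5, 3.0)
        f = es.anova_f_from_summary([g1, g2])
        t = es.t_from_summary(g1, g2, method="pooled")
        assert f.statistic == pytest.approx(t.statistic ** 2, rel=1e-12)
        assert f.p == pytest.approx(t.p, rel=1e-10)

    def test_moment_matched_raw_data_oracle(self, rng):
        def sample(n, mean, sd, r):
            x = r.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x

        specs = [(12, 4.0, 1.0), (20, 5.5, 2.0), (9, 3.2, 1.5)]
        raws = [sample(*s, rng) for s in specs]
        f_raw, p_raw = sps.f_oneway(*raws)
        r = es.anova_f_from_summary([es.SummaryGroup(*s) for s in specs])
        assert r.statistic == pytest.approx(f_raw, abs=1e-10)
        assert r.p == pytest.approx(p_raw, abs=1e-10)

    def test_published_age_group_anova_significant(self):
        r = es.anova_f_from_summary(list(tables.BMD_BY_AGE_GROUP))
        assert r.statistic > 100          # strongly age-dependent BMD
        assert r.p < 1e-10


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

class TestEvaluateModel:
    def test_separable_toy(self):
        y = np.array([0] * 5 + [1] * 5 + [2] * 5)
        probs = np.zeros((15, 3))
        probs[np.arange(15), y] = 1.0
        probs += 1e-6
        rep = es.evaluate_model(probs, y, ("a", "b", "c"))
        for row in rep.rows.values():
            assert row["auc"] == pytest.approx(1.0)
            assert row["se"] == 1.0 and row["sp"] == 1.0

    def test_invariants_and_flags(self, rng):
        probs = rng.dirichlet(np.ones(3), size=40)
        y = rng.integers(0, 2, 40)           # class 2 absent
        y[:2] = [0, 1]
        rep = es.evaluate_model(probs, y, ("a", "b", "c"))
        for name, row in rep.rows.items():
            if name == "c":
                assert row["flagged"] == "class absent"
                continue
            assert row["ci_low"] <= row["auc"] <= row["ci_high"]
            for k in ("auc", "se", "sp", "ac"):
                assert 0.0 <= row[k] <= 1.0
        df = rep.to_frame()
        assert set(df["class"]) == {"a", "b", "c"}
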