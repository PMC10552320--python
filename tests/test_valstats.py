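"""Logistic panel fits, LOOCV ROC, Youden, confusion CIs, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methpanel.valstats as vs
from methpanel.io import BetaMatrix, ValidationError


def auc_pair_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def youden_scan_bruteforce(scores, labels):
    best = (-np.inf, -np.inf, None)
    for t in np.concatenate([np.unique(scores), [np.inf]]):
        pred = scores >= t
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        j = sens + spec - 1
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, t)
    return best


class TestPanelLogit:
    def test_matches_statsmodels_irls(self, rng):
        """MLE coefficients agree with the reference IRLS fit to 1e-6."""
        import statsmodels.api as sm

        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = (rng.uniform(size=20) < 1 / (1 + np.exp(-(0.3 + X["a"] - 0.5 * X["b"])))).astype(float)
        if y.sum() < 3 or y.sum() > 17:
            y.iloc[:3] = [0, 1, 0]
        res = vs.PanelLogit(X, y).fit()
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert res.method == "mle"
        assert np.allclose(res.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)

    def test_separation_falls_back_to_firth(self):
        X = pd.DataFrame({"x": np.concatenate([np.zeros(8), np.ones(8)])})
        X["x"] += np.linspace(0, 0.01, 16)  # strictly separating
        y = np.concatenate([np.zeros(8), np.ones(8)])
        res = vs.PanelLogit(X, y).fit()
        assert res.method == "firth"
        # monotone score preserved
        scores = res.predict(X)
        assert (np.diff(scores) >= -1e-9).all()

    def test_null_coefficient_ci_coverage(self):
        """A null feature's 95% CI covers zero in >= 90% of replicates."""
        covered = 0
        for s in range(50):
            r = np.random.default_rng(s)
            X = pd.DataFrame({"x": r.normal(size=40)})
            y = (r.uniform(size=40) < 0.5).astype(float)
            if y.sum() < 3 or y.sum() > 37:
                continue
            res = vs.PanelLogit(X, y).fit()
            ci = res.conf_int().loc["x"]
            covered += ci["lower"] <= 0 <= ci["upper"]
        assert covered >= 45

    def test_collinear_features_named(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (x > 0).astype(float)
        with pytest.raises(ValidationError, match="collinear"):
            vs.PanelLogit(X, y)


class TestLoocv:
    def test_equals_kfold_with_k_equal_n(self, rng):
        from sklearn.model_selection import LeaveOneOut

        X = pd.DataFrame({"x": rng.normal(size=14)})
        y = np.array([0, 1] * 7, dtype=float)
        X["x"] += y
        scores = vs.loocv_scores(X, y)
        manual = np.empty(14)
        for tr, te in LeaveOneOut().split(X):
            res = vs.PanelLogit(X.iloc[tr], y[tr]).fit()
            manual[te[0]] = res.predict(X.iloc[te])[0]
        assert np.allclose(scores, manual)

    def test_constant_feature_no_discrimination(self):
        """An uninformative feature yields no real discrimination.

        Equal scores give AUC exactly 0.5; LOOCV scores of a
        (near-)constant feature are dominated by the leave-one-out
        class-prevalence shift, which anti-correlates scores with the
        left-out label, so the pooled LOOCV AUC is at or below chance.
        """
        assert vs.roc_auc(np.full(20, 0.5), np.array([0, 1] * 10)).auc == 0.5
        X = pd.DataFrame({"x": np.zeros(20) + 1e-9 * np.arange(20)})
        y = np.array([0, 1] * 10, dtype=float)
        scores = vs.loocv_scores(X, y)
        assert vs.roc_auc(scores, y).auc <= 0.5

    def test_no_optimism_inflation(self):
        """Pooled LOOCV AUC does not exceed the training AUC (20 seeds)."""
        worse_or_equal = 0
        for s in range(20):
            r = np.random.default_rng(s)
            y = np.array([0.0, 1.0] * 7)
            X = pd.DataFrame({"x": r.normal(size=14) + 1.5 * y})
            fit = vs.PanelLogit(X, y).fit()
            train_auc = vs.roc_auc(fit.predict(X), y).auc
            cv_auc = vs.roc_auc(vs.loocv_scores(X, y), y).auc
            worse_or_equal += cv_auc <= train_auc + 1e-12
        assert worse_or_equal >= 18


class TestRocAuc:
    def test_perfect_separation(self):
        roc = vs.roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_tied_scores_worked_example(self):
        scores = np.array([0.9, 0.8, 0.8, 0.1])
        labels = np.array([1, 1, 0, 0])
        roc = vs.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.875)
        assert roc.auc == pytest.approx(auc_pair_bruteforce(scores, labels))

    def test_matches_pair_counting_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.integers(0, 2, size=n).astype(float)
            if labels.sum() in (0, n):
                continue
            roc = vs.roc_auc(scores, labels)
            assert roc.auc == pytest.approx(auc_pair_bruteforce(scores, labels), abs=1e-12)

    def test_null_scores_auc_near_half(self):
        """Null AUC at n=200 concentrates near 0.5 (sd ~ 0.041, so the
        band [0.42, 0.58] has ~95% coverage; a finite seed sample is
        asserted at 90% with a mean check)."""
        aucs = []
        for s in range(40):
            r = np.random.default_rng(s)
            scores = r.uniform(size=200)
            labels = np.repeat([0.0, 1.0], 100)
            aucs.append(vs.roc_auc(scores, labels).auc)
        inside = np.mean([(0.42 <= a <= 0.58) for a in aucs])
        assert inside >= 0.9
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            vs.roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_delong_ci_contains_auc(self, rng):
        scores = rng.uniform(size=60)
        labels = np.repeat([0.0, 1.0], 30)
        roc = vs.roc_auc(scores + 0.3 * labels, labels)
        lo, hi = roc.auc_ci
        assert lo <= roc.auc <= hi


class TestYouden:
    def test_matches_bruteforce_scan(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.integers(0, 2, size=n).astype(float)
            if labels.sum() in (0, n):
                continue
            roc = vs.roc_auc(scores, labels)
            j, spec, t = youden_scan_bruteforce(scores, labels)
            assert roc.youden_j == pytest.approx(j, abs=1e-12)
            assert roc.specificity == pytest.approx(spec, abs=1e-12)

    def test_tie_goes_to_higher_specificity(self):
        # J = 0.5 at two thresholds; the higher-specificity one must win
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 1, 0, 1])
        roc = vs.roc_auc(scores, labels)
        assert roc.specificity == 1.0
        assert roc.youden_threshold == pytest.approx(0.9)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,npv,ppv",
        [
            (52, 14, 39, 0, 73.6, 100.0),  # 2-marker panel row
            (41, 25, 38, 1, 60.3, 97.6),  # 4-marker panel row
            (61, 5, 7, 32, 58.3, 65.6),  # 20-marker + sex row
            (10, 56, 39, 0, 41.1, 100.0),  # single-gene promoter row
        ],
    )
    def test_reconstructed_validation_rows(self, tp, fn, tn, fp, npv, ppv):
        pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        cm = vs.confusion_metrics(pred, true)
        d = cm.as_dict()
        assert round(d["npv"], 1) == npv
        assert round(d["ppv"], 1) == ppv

    def test_sensitivity_ci_first_row(self):
        cm = vs.confusion_metrics(
            np.array([1] * 52 + [0] * 14 + [0] * 39),
            np.array([1] * 66 + [0] * 39),
        )
        lo, hi = cm.sensitivity_ci
        assert (round(100 * lo), round(100 * hi)) == (67, 88)

    def test_clopper_pearson_39_of_39(self):
        lo, hi = vs.clopper_pearson(39, 39)
        assert (round(100 * lo), round(100 * hi)) == (91, 100)

    def test_all_correct(self):
        cm = vs.confusion_metrics(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0]))
        d = cm.as_dict()
        assert d["sensitivity"] == d["specificity"] == d["npv"] == d["ppv"] == 100.0
        assert d["sensitivity_ci"][1] == 100.0

    def test_empty_denominator_is_none(self):
        cm = vs.confusion_metrics(np.array([0, 0]), np.array([0, 0]))
        assert cm.sensitivity is None and cm.ppv is None
        assert cm.specificity == 1.0


class TestSubgroupDetection:
    def _cohort_frame(self):
        rows = []
        for i in range(23):  # distal AA, 20 detected
            rows.append({"finding": "AA", "location": "distal", "stage": "none"})
        for i in range(19):  # proximal AA, 13 detected
            rows.append({"finding": "AA", "location": "proximal", "stage": "none"})
        for i in range(24):
            rows.append({"finding": "CRC", "location": "distal", "stage": "II"})
        return pd.DataFrame(rows)

    def test_detection_rates_and_fisher(self):
        df = self._cohort_frame()
        pred = np.array([1] * 20 + [0] * 3 + [1] * 13 + [0] * 6 + [1] * 19 + [0] * 5)
        out = vs.subgroup_detection(pred, df)
        assert out["aa"]["all"]["rate"] == pytest.approx(100 * 33 / 42)
        assert round(out["aa"]["all"]["rate"], 1) == 78.6
        assert round(out["aa"]["distal"]["rate"]) == 87
        assert round(out["aa"]["proximal"]["rate"], 1) == 68.4
        assert round(out["crc"]["all"]["rate"], 1) == 79.2
        assert out["aa"]["fisher_distal_vs_proximal_p"] > 0.05

    def test_all_detected_fisher_p_one(self):
        df = self._cohort_frame()
        out = vs.subgroup_detection(np.ones(len(df), dtype=int), df)
        assert out["aa"]["fisher_distal_vs_proximal_p"] == pytest.approx(1.0)


class TestGroupTests:
    def test_exact_rank_sum_matches_enumeration(self):
        """p for {1,2,3} vs {4,5,6} equals the full permutation count."""
        values = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        p = vs.group_tests(values, groups)
        # enumerate all 20 assignments of 3-of-6 to group a
        obs = values[:3].sum()
        sums = [sum(c) for c in itertools.combinations(values, 3)]
        mean_sum = np.mean(sums)
        extreme = sum(abs(s - mean_sum) >= abs(obs - mean_sum) - 1e-12 for s in sums)
        assert p == pytest.approx(extreme / len(sums))
        assert p == pytest.approx(0.1)

    def test_paired_identical_vectors(self):
        with pytest.warns(UserWarning):
            assert vs.group_tests(np.arange(5.0), np.arange(5.0), paired=True) == 1.0

    def test_large_sample_uses_tie_corrected_normal(self):
        r = np.random.default_rng(0)
        a = np.round(r.normal(0, 1, 40), 1)
        b = np.round(r.normal(0.8, 1, 40), 1)
        p = vs.group_tests(np.concatenate([a, b]), np.array(["a"] * 40 + ["b"] * 40))
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestAverageProbeSet:
    def _beta(self):
        df = pd.DataFrame(
            [[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]],
            index=["pa", "pb", "pc"], columns=["s1", "s2"],
        )
        return BetaMatrix(df)

    def test_three_probe_mean(self):
        out = vs.average_probe_set(self._beta(), ["pa", "pb", "pc"])
        assert out["s1"] == pytest.approx(0.2)

    def test_missing_probe_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = vs.average_probe_set(self._beta(), ["pa", "pb", "ghost"])
        assert out["s1"] == pytest.approx(0.15)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            vs.average_probe_set(self._beta(), ["ghost"])
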