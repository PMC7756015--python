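import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaflow import (
    DiagnosticModel,
    classification_metrics,
    delong_compare,
    esc_classifier,
    fit_logistic_model,
    predict_coa_probability,
    roc_auc,
    spearman_matrix,
    youden_threshold,
)
from coaflow.diagnosis import InvalidLabelsError, delong_variance


class TestLogisticFit:
    def test_intercept_only_mle(self):
        # constant features: slope stays 0 and the intercept is the log-odds
        # of the base rate, ln(3/7) for 3 positives of 10
        X = np.zeros((10, 2))
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        model = fit_logistic_model(X, y)
        assert model.c == pytest.approx(math.log(3 / 7), abs=1e-8)
        assert model.a == 0.0 and model.b == 0.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12345)
        n = 5000
        a, b, c = 2.0, 50.0, -3.0
        f = rng.uniform(0, 2, n)
        s = rng.uniform(0, 0.1, n)
        p = 1 / (1 + np.exp(-(a * f + b * s + c)))
        y = (rng.random(n) < p).astype(int)
        model = fit_logistic_model(np.column_stack([f, s]), y)
        # standard errors from the observed information at the MLE
        import statsmodels.api as sm
        glm = sm.GLM(y, sm.add_constant(np.column_stack([f, s])),
                     family=sm.families.Binomial()).fit()
        assert model.a == pytest.approx(glm.params[1], abs=1e-6)
        assert model.b == pytest.approx(glm.params[2], abs=1e-5)
        assert model.c == pytest.approx(glm.params[0], abs=1e-6)
        for est, true, se in [(model.a, a, glm.bse[1]), (model.b, b, glm.bse[2]),
                              (model.c, c, glm.bse[0])]:
            assert abs(est - true) < 3 * se

    def test_complete_separation_detected(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [1.1, 1.0]])
        y = [0, 0, 1, 1]
        model = fit_logistic_model(X, y)
        assert model.separation_detected
        eta = model.linear_predictor(X[:, 0], X[:, 1])
        assert np.all(np.diff(model.predict(X[:, 0], X[:, 1])[np.argsort(eta)]) >= 0)
        assert np.all(eta[:2] < 0) and np.all(eta[2:] > 0)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            fit_logistic_model(np.zeros((4, 2)), [1, 1, 1, 1])


class TestPredict:
    def test_midpoint(self):
        m = DiagnosticModel(a=1.0, b=1.0, c=-2.0)
        assert predict_coa_probability(m, 1.0, 1.0) == pytest.approx(0.5)

    def test_saturation_without_overflow(self):
        m = DiagnosticModel(a=1.0, b=0.0, c=0.0)
        assert predict_coa_probability(m, 1000.0, 0.0) == pytest.approx(1.0, abs=1e-12)
        assert predict_coa_probability(m, -1000.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_features_for_positive_coefficients(self):
        m = DiagnosticModel(a=2.0, b=3.0, c=-1.0)
        fs = np.linspace(0, 2, 20)
        assert np.all(np.diff(predict_coa_probability(m, fs, 0.5)) > 0)
        assert np.all(np.diff(predict_coa_probability(m, 0.5, fs)) > 0)


class TestRocAuc:
    def test_four_point_example(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        roc = roc_auc([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties(self):
        roc = roc_auc([1.0] * 6, [0, 0, 0, 1, 1, 1])
        assert roc.auc == 0.5

    @given(st.integers(2, 12), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_exhaustive_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            return
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        total, wins = 0, 0.0
        for sp in scores[y == 1]:
            for sn in scores[y == 0]:
                total += 1
                wins += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
        assert roc_auc(scores, y).auc == pytest.approx(wins / total, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        assert roc_auc(scores, y).auc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_curve_integrates_to_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40) + np.repeat([0, 1], 20)
        y = np.repeat([0, 1], 20)
        roc = roc_auc(scores, y)
        fpr = 1.0 - roc.specificities
        trapezoid = float(np.trapezoid(roc.sensitivities, fpr))
        assert trapezoid == pytest.approx(roc.auc, abs=1e-12)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        y = (rng.random(30) < 0.5).astype(int)
        roc = roc_auc(scores, y)
        assert roc.ci_low <= roc.auc <= roc.ci_high


class TestDeLong:
    def test_identical_classifiers(self):
        scores = [0.2, 0.8, 0.4, 0.9, 0.1]
        y = [0, 1, 0, 1, 0]
        auc_a, auc_b, z, p = delong_compare(scores, scores, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 15)
        a = rng.random(30) + 0.3 * y
        b = rng.random(30) + 0.1 * y
        _, _, z_ab, p_ab = delong_compare(a, b, y)
        _, _, z_ba, p_ba = delong_compare(b, a, y)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_variance_against_stratified_bootstrap(self):
        rng = np.random.default_rng(20240201)
        n = 60
        y = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=n) + 1.2 * y
        auc, var = delong_variance(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        boots = np.empty(2000)
        for i in range(2000):
            bp = rng.choice(pos, len(pos))
            bn = rng.choice(neg, len(neg))
            cmp_ = (bp[:, None] > bn[None, :]) + 0.5 * (bp[:, None] == bn[None, :])
            boots[i] = cmp_.mean()
        assert var == pytest.approx(boots.var(ddof=1), rel=0.15)


class TestOperatingPoints:
    def test_confusion_arithmetic(self):
        scores = [1] * 3 + [1] * 1 + [0] * 6 + [0] * 3
        labels = [1] * 3 + [0] * 1 + [0] * 6 + [1] * 3
        rep = classification_metrics(scores, labels, threshold=0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 6, 3)
        assert rep.sensitivity == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(6 / 7)
        assert rep.accuracy == pytest.approx(9 / 13)

    def test_threshold_extremes(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 1, 0, 1]
        low = classification_metrics(scores, labels, threshold=0.0)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        high = classification_metrics(scores, labels, threshold=1.0)
        assert high.sensitivity == 0.0 and high.specificity == 1.0

    def test_youden_picks_separating_threshold(self):
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        t = youden_threshold(scores, labels)
        rep = classification_metrics(scores, labels, t)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0


class TestEscClassifier:
    @pytest.mark.parametrize("narrowing,expected", [
        (0.60, True), (0.49, False), (0.50, True), (0.0, False),
    ])
    def test_fifty_percent_rule(self, narrowing, expected):
        assert esc_classifier(narrowing) is expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            esc_classifier(1.2)


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 5.0, 9.0]
        mat = spearman_matrix({"x": x, "up": [v**2 for v in x],
                               "down": [-v for v in x]})
        assert mat.rho.loc["x", "up"] == pytest.approx(1.0)
        assert mat.rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_ties_match_average_rank_bruteforce(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 6.0, 9.0, 9.0, 8.0])

        def avg_ranks(v):
            r = np.empty(len(v))
            for i, vi in enumerate(v):
                less = np.sum(v < vi)
                eq = np.sum(v == vi)
                r[i] = less + (eq + 1) / 2.0
            return r

        rx, ry = avg_ranks(x), avg_ranks(y)
        rho_brute = (np.corrcoef(rx, ry))[0, 1]
        mat = spearman_matrix({"x": x, "y": y})
        assert mat.rho.loc["x", "y"] == pytest.approx(rho_brute, abs=1e-12)

    def test_constant_column_flagged(self):
        mat = spearman_matrix({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        assert "const" in mat.undefined
        assert math.isnan(mat.rho.loc["x", "const"])
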