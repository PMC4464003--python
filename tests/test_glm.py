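"""Logistic fitting, metrics, ROC/AUC and effect summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopanel import (AnalysisSpec, SingularDesignError, auc,
                      classification_metrics, fit_logistic, odds_ratio_2sd,
                      roc_curve, univariate_screen)
from biopanel.glm import trapezoid_auc
from conftest import make_table


def brute_force_auc(scores, labels):
    """Exhaustive pairwise P(case > control) with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


class TestFitLogistic:
    def test_intercept_only_closed_form(self, spec_ab):
        t = make_table({"x": np.zeros(100)}, ["B"] * 30 + ["A"] * 70)
        m = fit_logistic(t, [], spec_ab)
        assert m.intercept == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_matches_statsmodels_oracle(self, spec_ab):
        import statsmodels.api as sm
        rng = np.random.default_rng(17)
        n = 50
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        eta = 0.5 + 1.2 * x1 - 0.8 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        if y.sum() < 2 or y.sum() > n - 2:
            pytest.skip("degenerate draw")
        t = make_table({"x1": x1, "x2": x2}, ["B" if v else "A" for v in y])
        m = fit_logistic(t, ["x1", "x2"], spec_ab)
        sm_fit = sm.GLM(y, sm.add_constant(np.column_stack([x1, x2])),
                        family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [m.intercept, m.coefficients["x1"], m.coefficients["x2"]],
            sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            [m.se["x1"], m.se["x2"]], sm_fit.bse[1:], atol=1e-5)

    def test_uninformative_feature_has_null_coefficient(self, spec_ab):
        # identical per-class distributions in a balanced design
        x = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 4)
        labels = ["A"] * 5 + ["B"] * 5 + ["A"] * 5 + ["B"] * 5
        m = fit_logistic(make_table({"x": x}, labels), ["x"], spec_ab)
        assert abs(m.coefficients["x"]) < 1e-6
        assert m.wald_p["x"] > 0.9

    def test_collinear_design_raises(self, spec_ab):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        t = make_table({"a": x, "b": 2 * x}, ["A", "B"] * 20)
        with pytest.raises(SingularDesignError):
            fit_logistic(t, ["a", "b"], spec_ab)

    def test_separation_flagged(self, spec_ab):
        x = np.concatenate([np.full(10, -2.0) + np.arange(10) * 0.01,
                            np.full(10, 2.0) + np.arange(10) * 0.01])
        t = make_table({"x": x}, ["A"] * 10 + ["B"] * 10)
        with pytest.warns(UserWarning, match="converge"):
            m = fit_logistic(t, ["x"], spec_ab)
        assert not m.converged


class TestPredict:
    def test_worked_probabilities(self, spec_ab):
        t = make_table({"x": [0.0, 2.0]}, ["A", "B"])
        from biopanel import FittedLogisticModel
        m = FittedLogisticModel(features=["x"], intercept=-0.8473,
                                coefficients={"x": 0.31})
        p = m.predict_prob(t)
        assert p.iloc[0] == pytest.approx(1 / (1 + np.exp(0.8473)), abs=1e-6)
        assert p.iloc[1] == pytest.approx(0.4434, abs=1e-3)
        m0 = FittedLogisticModel(features=["x"], intercept=0.0,
                                 coefficients={"x": 1.0})
        assert m0.predict_prob(t).iloc[0] == pytest.approx(0.5)


class TestMetrics:
    def test_perfect_and_degenerate(self):
        rep = classification_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert rep.accuracy.point == rep.sensitivity.point == \
            rep.specificity.point == 1.0
        rep2 = classification_metrics([0.1, 0.2, 0.3, 0.4], [1, 1, 0, 0])
        assert rep2.sensitivity.point == 0.0
        assert rep2.specificity.point == 1.0

    def test_hand_counted_example(self):
        rep = classification_metrics([0.6, 0.4, 0.7, 0.2], [1, 1, 0, 0])
        assert rep.sensitivity.point == 0.5
        assert rep.specificity.point == 0.5
        assert rep.accuracy.point == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            classification_metrics([0.5, 0.6], [1, 1])


class TestAuc:
    def test_worked_examples(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_trapezoid_under_roc_equals_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 80))
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.sum() in (0, n):
            return
        scores = np.round(rng.random(n), 1)
        pts = roc_curve(scores, labels)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))
        assert trapezoid_auc(pts) == pytest.approx(auc(scores, labels),
                                                   abs=1e-12)


class TestOddsRatio2SD:
    def test_published_coefficient_anchors(self):
        # printed two-decimal coefficients reproduce the printed ORs
        assert round(odds_ratio_2sd(0.31), 2) == 1.86
        assert round(odds_ratio_2sd(0.32), 1) == 1.9
        assert odds_ratio_2sd(0.0) == 1.0
        assert odds_ratio_2sd(-2.8) == pytest.approx(np.exp(5.6))

    @given(st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_sign_symmetry_and_multiplicativity(self, b1, b2):
        assert odds_ratio_2sd(b1) == pytest.approx(odds_ratio_2sd(-b1))
        if b1 * b2 >= 0:  # agreeing signs act multiplicatively at 2 SD
            assert odds_ratio_2sd(b1) * odds_ratio_2sd(b2) == pytest.approx(
                odds_ratio_2sd(abs(b1) + abs(b2)), rel=1e-9)


class TestUnivariateScreen:
    def test_exact_small_sample_p(self, spec_ab):
        t = make_table({"x": [1, 2, 3, 4, 5, 6]}, list("AAABBB"))
        out = univariate_screen(t, spec_ab)
        assert out["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        # m = 1: adjusted equals raw
        assert out["p_bonferroni"].iloc[0] == out["p_value"].iloc[0]

    def test_null_features_not_significant_after_bonferroni(self, spec_ab):
        rng = np.random.default_rng(13)
        vals = {f"f{i}": rng.standard_normal(200) for i in range(20)}
        t = make_table(vals, ["A", "B"] * 100)
        out = univariate_screen(t, spec_ab)
        assert (out["p_bonferroni"] > 0.05).all()
        assert (out["p_bonferroni"] <= 1.0).all()
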