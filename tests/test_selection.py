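"""Correlation merging, forward selection and backward elimination."""

import numpy as np
import pandas as pd
import pytest

from biopanel import (AnalysisSpec, FeatureRanking, backward_eliminate,
                      fit_logistic, forward_select, merge_correlated)
from biopanel.ga import FrequencyTable
from conftest import make_table


def _freqs(counts: dict, fitness: dict | None = None) -> FrequencyTable:
    c = pd.Series(counts, dtype=int).sort_values(ascending=False)
    mf = pd.Series(fitness or {f: 0.5 for f in counts})
    return FrequencyTable(counts=c, mean_fitness=mf.loc[c.index],
                          n_models=sum(counts.values()) // 5 or 1,
                          chromosome_size=5)


def _corr_table(corr: np.ndarray, names: list[str], n: int = 1000,
                seed: int = 0, labels=None):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr)
    X = rng.standard_normal((n, len(names))) @ L.T
    labels = labels or ["A", "B"] * (n // 2)
    return make_table({nm: X[:, j] for j, nm in enumerate(names)}, labels)


class TestMergeCorrelated:
    def test_pairwise_absorption(self, spec_ab):
        t = _corr_table(np.array([[1.0, 0.9], [0.9, 1.0]]), ["f1", "f2"])
        ranking = merge_correlated(_freqs({"f1": 30, "f2": 10}), t, spec_ab)
        assert ranking.entries == [("f1", 40)]
        (discarded, into, rho, p), = ranking.merge_log
        assert (discarded, into) == ("f2", "f1")
        assert abs(rho) > 0.8 and p < 0.05

    def test_below_threshold_untouched(self, spec_ab):
        t = _corr_table(np.array([[1.0, 0.5], [0.5, 1.0]]), ["f1", "f2"])
        ranking = merge_correlated(_freqs({"f1": 30, "f2": 10}), t, spec_ab)
        assert ranking.entries == [("f1", 30), ("f2", 10)]
        assert ranking.merge_log == []

    def test_chain_greedy_pass(self, spec_ab):
        # f1-f2 and f2-f3 strongly correlated, f1-f3 below threshold:
        # f1 absorbs f2; f3 survives because its only partner is gone
        corr = np.array([[1.0, 0.85, 0.60],
                         [0.85, 1.0, 0.85],
                         [0.60, 0.85, 1.0]])
        t = _corr_table(corr, ["f1", "f2", "f3"], n=2000, seed=5)
        emp = t.values.corr()
        assert emp.loc["f1", "f2"] > 0.8 and emp.loc["f2", "f3"] > 0.8
        assert emp.loc["f1", "f3"] <= 0.8
        ranking = merge_correlated(_freqs({"f1": 30, "f2": 20, "f3": 10}),
                                   t, spec_ab)
        assert ranking.entries == [("f1", 50), ("f3", 10)]

    def test_total_frequency_conserved(self, spec_ab):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(400)
        vals = {"a": base + 0.1 * rng.standard_normal(400),
                "b": base + 0.1 * rng.standard_normal(400),
                "c": rng.standard_normal(400),
                "d": rng.standard_normal(400)}
        t = make_table(vals, ["A", "B"] * 200)
        freqs = _freqs({"a": 17, "b": 11, "c": 7, "d": 3})
        ranking = merge_correlated(freqs, t, spec_ab)
        assert ranking.total == 38


def _fs_table(n_per_class=150, n_noise=20, deltas=(1.5, 1.5), seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    vals = {}
    for i, d in enumerate(deltas):
        x = rng.standard_normal(n)
        x[n_per_class:] += d
        vals[f"sig{i}"] = x
    for i in range(n_noise):
        vals[f"noise{i:02d}"] = rng.standard_normal(n)
    t = make_table(vals, ["A"] * n_per_class + ["B"] * n_per_class)
    return t


def _ranking(features) -> FeatureRanking:
    return FeatureRanking(entries=[(f, 100 - i) for i, f in
                                   enumerate(features)])


class TestForwardSelect:
    def test_recovers_planted_with_at_most_chance_noise(self, spec_ab):
        """Both planted features pass the gate; noise admissions stay at
        the gate's chance level (about one expected over a 20-candidate
        walk at the 5% level — backward elimination later removes them).
        """
        good = 0
        n_sim = 10
        for s in range(n_sim):
            t = _fs_table(seed=s)
            # noise features ranked above and between the planted ones
            order = (["noise00", "sig0", "noise01", "noise02", "sig1"]
                     + [f"noise{i:02d}" for i in range(3, 20)])
            model = forward_select(_ranking(order), t,
                                   spec_ab.replace(rng_seed=1000 + s))
            feats = set(model.features)
            noise = feats - {"sig0", "sig1"}
            if {"sig0", "sig1"} <= feats and len(noise) <= 1:
                good += 1
        assert good >= 9

    def test_redundant_duplicate_skipped(self, spec_ab):
        rng = np.random.default_rng(2)
        n = 400
        sig = rng.standard_normal(n)
        sig[200:] += 2.0
        dup = 0.97 * sig + np.sqrt(1 - 0.97**2) * rng.standard_normal(n)
        t = make_table({"sig": sig, "dup": dup}, ["A"] * 200 + ["B"] * 200)
        model = forward_select(_ranking(["sig", "dup"]), t, spec_ab)
        assert model.features == ["sig"]

    def test_empty_ranking_errors(self, gaussian_two_class, spec_ab):
        with pytest.raises(ValueError):
            forward_select(FeatureRanking(entries=[]), gaussian_two_class,
                           spec_ab)

    def test_deterministic_given_seed(self, spec_ab):
        t = _fs_table(seed=42)
        order = ["sig0", "sig1"] + [f"noise{i:02d}" for i in range(20)]
        m1 = forward_select(_ranking(order), t, spec_ab)
        m2 = forward_select(_ranking(order), t, spec_ab)
        assert m1.features == m2.features
        np.testing.assert_allclose(m1.beta_vector(), m2.beta_vector())

    def test_no_passing_feature_warns_intercept_only(self, spec_ab):
        rng = np.random.default_rng(0)
        t = make_table({"x": rng.standard_normal(60)}, ["A", "B"] * 30)
        with pytest.warns(UserWarning, match="intercept-only"):
            model = forward_select(_ranking(["x"]), t, spec_ab)
        assert model.features == []


class TestBackwardEliminate:
    def test_all_significant_model_unchanged(self, spec_ab):
        t = _fs_table(deltas=(1.5, 1.5), seed=7)
        model = fit_logistic(t, ["sig0", "sig1"], spec_ab)
        out = backward_eliminate(model, t, spec_ab)
        assert set(out.features) == {"sig0", "sig1"}

    def test_appended_noise_removed(self, spec_ab):
        removed = 0
        n_sim = 10
        for s in range(n_sim):
            t = _fs_table(deltas=(1.5, 1.5), seed=100 + s)
            model = fit_logistic(t, ["sig0", "sig1", "noise00"],
                                 spec_ab.replace(rng_seed=s))
            out = backward_eliminate(model, t, spec_ab.replace(rng_seed=s))
            if set(out.features) == {"sig0", "sig1"}:
                removed += 1
        assert removed >= 8

    def test_single_weak_feature_reduces_to_intercept(self, spec_ab):
        rng = np.random.default_rng(3)
        t = make_table({"x": rng.standard_normal(100)}, ["A", "B"] * 50)
        model = fit_logistic(t, ["x"], spec_ab)
        out = backward_eliminate(model, t, spec_ab)
        assert out.features == []

    def test_never_grows(self, gaussian_two_class, spec_ab):
        model = fit_logistic(gaussian_two_class, ["sig", "n1", "n2"], spec_ab)
        out = backward_eliminate(model, gaussian_two_class, spec_ab)
        assert len(out.features) <= 3
        assert set(out.features) <= {"sig", "n1", "n2"}
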