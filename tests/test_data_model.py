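"""Standardization, missingness filtering and complete-case semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopanel import (AnalysisSpec, EmptyClassError, ZeroVarianceError,
                      apply_standardization, complete_case_subset,
                      filter_missing, read_feature_table, write_feature_table,
                      z_standardize)
from conftest import make_table


class TestZStandardize:
    def test_derived_column(self):
        # [1, 2, 3, 6]: mean 3, sample SD sqrt(14/3) = 2.1602
        t = make_table({"x": [1, 2, 3, 6]}, ["A", "A", "B", "B"])
        z = z_standardize(t)
        np.testing.assert_allclose(
            z.values["x"], [-0.9258, -0.4629, 0.0, 1.3887], atol=1e-4)
        mu, sigma = z.standardization["x"]
        assert mu == 3.0
        assert sigma == pytest.approx(2.1602469, abs=1e-6)

    def test_mean_cell_maps_to_zero_and_one_sd_to_one(self):
        t = make_table({"x": [2.0, 4.0, 6.0]}, ["A", "B", "A"])
        z = z_standardize(t)
        assert z.values["x"].iloc[1] == pytest.approx(0.0)  # cell == mean
        sd = 2.0  # sample SD of [2,4,6]
        assert z.values["x"].iloc[2] == pytest.approx((6 - 4) / sd)

    def test_missing_cells_stay_missing(self):
        t = make_table({"x": [1, np.nan, 3, 6, 2]}, list("AABBA"))
        z = z_standardize(t)
        assert np.isnan(z.values["x"].iloc[1])
        assert z.values["x"].notna().sum() == 4

    def test_standardized_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        t = make_table({"a": rng.normal(10, 3, 50), "b": rng.uniform(0, 1, 50)},
                       ["A", "B"] * 25)
        z = z_standardize(t)
        for col in ("a", "b"):
            assert abs(z.values[col].mean()) < 1e-9
            assert abs(z.values[col].std(ddof=1) - 1) < 1e-9

    def test_idempotent_with_recorded_parameters(self):
        rng = np.random.default_rng(1)
        t = make_table({"a": rng.normal(5, 2, 30)}, ["A", "B"] * 15)
        z1 = z_standardize(t)
        z2 = apply_standardization(t, z1.standardization)
        pd.testing.assert_frame_equal(z1.values, z2.values)
        # re-standardizing an already-standardized table is a no-op
        z3 = z_standardize(z1)
        np.testing.assert_allclose(z3.values["a"], z1.values["a"], atol=1e-9)

    def test_zero_variance_names_column(self):
        t = make_table({"ok": [1, 2, 3, 4], "flat": [5, 5, 5, 5]},
                       list("AABB"))
        with pytest.raises(ZeroVarianceError, match="flat"):
            z_standardize(t)

    def test_binary_flags_standardized_like_continuous(self):
        t = make_table({"flag": [0, 0, 1, 1, 0, 1]}, list("AAABBB"))
        z = z_standardize(t)
        assert abs(z.values["flag"].mean()) < 1e-9
        assert abs(z.values["flag"].std(ddof=1) - 1) < 1e-9
        assert len(z.values["flag"].unique()) == 2


class TestFilterMissing:
    def _table(self):
        # 10 A + 10 B; f_drop missing for 3/10 A (30%); f_edge missing
        # exactly 2/10 (20%) in both classes; f_full complete
        a_drop = [np.nan] * 3 + [1.0] * 7 + [1.0] * 10
        edge = ([np.nan] * 2 + [1.0] * 8) * 2
        return make_table(
            {"f_drop": a_drop, "f_edge": edge, "f_full": [1.0] * 19 + [2.0]},
            ["A"] * 10 + ["B"] * 10)

    def test_strictly_more_than_threshold_drops(self):
        spec = AnalysisSpec(class_control="A", class_case="B")
        filt, log = filter_missing(self._table(), spec)
        assert "f_drop" not in filt.feature_names     # 30% > 20%
        assert "f_edge" in filt.feature_names         # exactly 20% retained
        assert "f_full" in filt.feature_names
        assert list(log["feature"]) == ["f_drop"]
        assert log["missing_frac_A"].iloc[0] == pytest.approx(0.3)

    def test_counted_fixture(self):
        # 6 features, 2 exceed the threshold in one class -> 4 survive
        rng = np.random.default_rng(3)
        vals = {f"f{i}": rng.normal(size=20) for i in range(6)}
        vals["f0"][:5] = np.nan       # 50% of class A
        vals["f1"][10:15] = np.nan    # 50% of class B
        t = make_table(vals, ["A"] * 10 + ["B"] * 10)
        filt, log = filter_missing(t, AnalysisSpec(class_control="A",
                                                   class_case="B"))
        assert filt.n_features == 4
        assert set(log["feature"]) == {"f0", "f1"}

    def test_never_drops_fully_observed_and_monotone_in_threshold(self):
        t = self._table()
        specs = [AnalysisSpec(class_control="A", class_case="B",
                              missing_threshold=th) for th in (0.1, 0.25, 0.35)]
        dropped = []
        for spec in specs:
            _, log = filter_missing(t, spec)
            assert "f_full" not in set(log["feature"])
            dropped.append(set(log["feature"]))
        # lower threshold -> superset of dropped features
        assert dropped[0] >= dropped[1] >= dropped[2]

    def test_empty_class_errors(self):
        t = make_table({"x": [1.0, 2.0]}, ["A", "A"])
        with pytest.raises(EmptyClassError):
            filter_missing(t, AnalysisSpec(class_control="A", class_case="B"))


class TestCompleteCase:
    def _table(self):
        return make_table({
            "f1": [1, np.nan, 3, 4, 5, 6],
            "f2": [1, 2, np.nan, 4, 5, 6],
            "f3": [1, 2, 3, 4, np.nan, 6],
        }, list("AABBAB"))

    def test_no_missing_is_identity(self):
        t = make_table({"x": [1.0, 2, 3, 4]}, list("AABB"))
        sub = complete_case_subset(t, ["x"])
        assert sub.subject_ids == t.subject_ids

    def test_patterned_missingness_enumerated(self):
        t = self._table()
        sub = complete_case_subset(t, ["f1", "f2"])
        assert sub.subject_ids == ["s000", "s003", "s004", "s005"]
        sub_all = complete_case_subset(t, ["f1", "f2", "f3"], min_per_class=1)
        assert sub_all.subject_ids == ["s000", "s003", "s005"]

    def test_union_is_subset_of_single(self):
        t = self._table()
        single = set(complete_case_subset(t, ["f1"]).subject_ids)
        union = set(complete_case_subset(t, ["f1", "f2"]).subject_ids)
        assert union <= single

    def test_too_few_subjects_errors(self):
        t = make_table({"x": [1, np.nan, np.nan, 4]}, list("AABB"))
        with pytest.raises(EmptyClassError):
            complete_case_subset(t, ["x"])

    @given(st.lists(st.booleans(), min_size=8, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_order_preserved(self, miss):
        vals = [np.nan if m else float(i) for i, m in enumerate(miss)]
        t = make_table({"x": vals, "y": np.arange(8.0)}, list("ABABABAB"))
        try:
            sub = complete_case_subset(t, ["x"])
        except EmptyClassError:
            return
        kept = [s for s, m in zip(t.subject_ids, miss) if not m]
        assert sub.subject_ids == kept


def test_csv_round_trip(tmp_path):
    t = make_table({"x": [1.0, np.nan, 3.0], "y": [0.5, 1.5, np.nan]},
                   list("ABA"), modality={"x": "PET", "y": "fluid"})
    csv = tmp_path / "t.csv"
    mod = tmp_path / "t.modality.tsv"
    write_feature_table(t, csv, mod)
    back = read_feature_table(csv, mod)
    pd.testing.assert_frame_equal(back.values, t.values)
    assert list(back.labels) == list(t.labels)
    assert back.modality == t.modality
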