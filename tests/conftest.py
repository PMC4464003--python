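import numpy as np
import pandas as pd
import pytest

from biopanel import AnalysisSpec, FeatureTable


def make_table(values: dict, labels: list, ids=None, modality=None):
    """Build a FeatureTable from plain dicts/lists (NaN = missing)."""
    n = len(labels)
    ids = ids if ids is not None else [f"s{i:03d}" for i in range(n)]
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()},
                      index=ids)
    return FeatureTable(values=df, labels=pd.Series(labels, index=ids),
                        modality=modality or {})


@pytest.fixture
def spec_hc_ad() -> AnalysisSpec:
    return AnalysisSpec(class_control="HC", class_case="AD", k_folds=4,
                        rng_seed=7)


@pytest.fixture
def spec_ab() -> AnalysisSpec:
    return AnalysisSpec(class_control="A", class_case="B", k_folds=3,
                        rng_seed=11)


@pytest.fixture
def gaussian_two_class():
    """Balanced two-class table: one separating feature, three noise."""
    rng = np.random.default_rng(5)
    n = 100
    labels = ["A"] * 50 + ["B"] * 50
    x_sig = rng.standard_normal(n)
    x_sig[50:] += 1.5
    return make_table(
        {"sig": x_sig, "n1": rng.standard_normal(n),
         "n2": rng.standard_normal(n), "n3": rng.standard_normal(n)},
        labels)
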