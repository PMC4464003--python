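"""Feature table container, z-standardization and missingness rules.

The central object is :class:`FeatureTable`: a subjects x features matrix
of continuous measurements and binary {0,1} clinical flags, with a
diagnostic label per subject and ``NaN`` marking missing cells.  Every
downstream stage (genetic-algorithm search, selection, validation) works
on complete-case subsets of this table, so the three operations here —
:func:`z_standardize`, :func:`filter_missing` and
:func:`complete_case_subset` — define the population semantics of the
whole pipeline.

Conventions
-----------
* Standardization is computed over the *whole loaded population* (all
  diagnostic classes), per feature, using the sample SD (n-1), and the
  per-feature (mu, sigma) pair is recorded on the returned table.
* Missingness filtering is per two-class contrast: a feature is dropped
  when its missing fraction strictly exceeds the threshold in *either*
  class ("more than 20%" keeps exact ties).
* No imputation anywhere: model fits and comparisons use the subjects
  with complete data on the features involved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITIES = (
    "MRI-volume",
    "MRI-thickness",
    "MRI-surface",
    "PET",
    "fluid",
    "clinical",
)


class ZeroVarianceError(ValueError):
    """A feature has zero variance, so its z-score is undefined."""


class EmptyClassError(ValueError):
    """An operation required subjects from a class that has none (or too few)."""


@dataclass(frozen=True)
class AnalysisSpec:
    """Parameters of one binary diagnostic contrast.

    Defaults follow the published study design: five-gene chromosomes,
    1,000 evolved models over 300 generations, 20% missingness cutoff,
    Pearson rho > 0.8 (p < 0.05) merging, IDI gate at p < 0.05, 1,000
    bootstrap resamples, 1,000 random null models and a 4:1
    calibration:test split.  ``k_folds`` is 3 or 4 depending on the
    contrast (4 for HC-AD, 3 otherwise).  ``selection_missing_quantile``
    controls which subjects form the feature-selection population in the
    pipeline: the least-missing fraction; the rest become APIS
    candidates at validation time.
    """

    class_control: str = "HC"
    class_case: str = "AD"
    k_folds: int = 4
    missing_threshold: float = 0.20
    correlation_threshold: float = 0.8
    correlation_p: float = 0.05
    idi_p: float = 0.05
    n_ga_models: int = 1000
    ga_generations: int = 300
    model_chromosome_size: int = 5
    ga_population: int = 50
    ga_tournament_size: int = 2
    ga_elite: int = 1
    ga_mutation_rate: float = 0.02
    n_bootstrap: int = 1000
    n_random_models: int = 1000
    calibration_test_ratio: float = 4.0
    classification_threshold: float = 0.5
    fs_max_candidates: int = 50
    fs_stop_at_first_failure: bool = False
    selection_missing_quantile: float = 0.75
    stratified_apis_sample: bool = False
    bootstrap_refit: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.k_folds,
            self.n_ga_models,
            self.ga_generations,
            self.model_chromosome_size,
            self.ga_population,
            self.n_bootstrap,
            self.n_random_models,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for name in ("missing_threshold", "correlation_threshold",
                     "correlation_p", "idi_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.class_control == self.class_case:
            raise ValueError("class_control and class_case must differ")
        if self.calibration_test_ratio <= 0:
            raise ValueError("calibration_test_ratio must be positive")
        if not 0.0 < self.selection_missing_quantile <= 1.0:
            raise ValueError("selection_missing_quantile must lie in (0, 1]")

    def replace(self, **kwargs) -> "AnalysisSpec":
        return dataclasses.replace(self, **kwargs)

    @property
    def classes(self) -> tuple[str, str]:
        return (self.class_control, self.class_case)


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and a standardization record.

    Parameters
    ----------
    values
        DataFrame indexed by subject id; columns are feature names; cells
        are floats with ``NaN`` for missing.  Binary clinical flags are
        {0, 1, NaN} until standardized.
    labels
        Series of diagnostic class per subject, aligned with ``values``.
    modality
        Optional feature -> modality tag map (see :data:`MODALITIES`).
    standardization
        Feature -> (mu, sigma) recorded by :func:`z_standardize`, or
        ``None`` for raw tables.
    """

    values: pd.DataFrame
    labels: pd.Series
    modality: dict[str, str] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("subject ids must be unique")
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])[:5]
            raise ValueError(f"subjects without a label: {missing}")

    # -- basic views -------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()

    # -- subsetting --------------------------------------------------
    def subset(self, subjects: Sequence | None = None,
               features: Sequence[str] | None = None) -> "FeatureTable":
        """Row/column subset preserving order and metadata."""
        values = self.values
        labels = self.labels
        if subjects is not None:
            values = values.loc[list(subjects)]
            labels = labels.loc[list(subjects)]
        if features is not None:
            unknown = set(features) - set(values.columns)
            if unknown:
                raise KeyError(f"unknown features: {sorted(unknown)}")
            values = values[list(features)]
        modality = {f: m for f, m in self.modality.items() if f in values.columns}
        standardization = None
        if self.standardization is not None:
            standardization = {f: s for f, s in self.standardization.items()
                               if f in values.columns}
        return FeatureTable(values=values.copy(), labels=labels.copy(),
                            modality=modality, standardization=standardization)

    def restrict_classes(self, classes: Iterable[str]) -> "FeatureTable":
        classes = list(classes)
        keep = self.labels.isin(classes)
        return self.subset(subjects=self.values.index[keep])

    def binary_labels(self, spec: AnalysisSpec) -> pd.Series:
        """Case class coded 1, control 0; errors on foreign labels."""
        extra = set(self.labels.unique()) - set(spec.classes)
        if extra:
            raise ValueError(f"labels outside the contrast: {sorted(extra)}")
        return (self.labels == spec.class_case).astype(int)


# ---------------------------------------------------------------------
# operations


def z_standardize(table: FeatureTable) -> FeatureTable:
    """Replace every feature by its z-score over the whole population.

    z_ij = (x_ij - mu_j) / sigma_j with mu_j, sigma_j the mean and sample
    SD (n-1 denominator) of feature j over all non-missing cells of all
    subjects in ``table`` — the standardization population is the entire
    loaded cohort, not a per-contrast subset.  Binary flags are
    standardized exactly like continuous features.  Missing cells stay
    missing; the (mu_j, sigma_j) pairs are recorded on the result.

    Raises
    ------
    ZeroVarianceError
        If any feature is constant (sigma_j = 0) or has fewer than two
        non-missing values.
    """
    values = table.values
    n_obs = values.notna().sum(axis=0)
    too_few = n_obs[n_obs < 2]
    if len(too_few):
        raise ZeroVarianceError(
            f"features with <2 non-missing values: {list(too_few.index)[:5]}")
    mu = values.mean(axis=0)
    sigma = values.std(axis=0, ddof=1)
    zero = sigma[sigma == 0.0]
    if len(zero):
        raise ZeroVarianceError(
            f"zero-variance features (sigma_j = 0): {list(zero.index)[:5]}")
    z = (values - mu) / sigma
    record = {f: (float(mu[f]), float(sigma[f])) for f in values.columns}
    return FeatureTable(values=z, labels=table.labels.copy(),
                        modality=dict(table.modality), standardization=record)


def apply_standardization(table: FeatureTable,
                          record: dict[str, tuple[float, float]]) -> FeatureTable:
    """Apply previously recorded (mu, sigma) pairs to a raw table."""
    missing = set(table.feature_names) - set(record)
    if missing:
        raise KeyError(f"no standardization recorded for: {sorted(missing)[:5]}")
    mu = pd.Series({f: record[f][0] for f in table.feature_names})
    sigma = pd.Series({f: record[f][1] for f in table.feature_names})
    z = (table.values - mu) / sigma
    return FeatureTable(values=z, labels=table.labels.copy(),
                        modality=dict(table.modality),
                        standardization={f: record[f] for f in table.feature_names})


def filter_missing(table: FeatureTable,
                   spec: AnalysisSpec) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features too often missing within either class of the contrast.

    The table must already be restricted to the contrast's two classes.
    A feature is excluded when its missing fraction *strictly* exceeds
    ``spec.missing_threshold`` in the control class or in the case class;
    a feature missing in exactly 20% of both classes is retained.

    Returns the filtered table and a drop log with one row per removed
    feature (its missing fraction per class).
    """
    for cls in spec.classes:
        if (table.labels == cls).sum() == 0:
            raise EmptyClassError(f"no subjects with label {cls!r}")
    extra = set(table.labels.unique()) - set(spec.classes)
    if extra:
        raise ValueError(
            f"table contains classes outside the contrast: {sorted(extra)}")
    miss = table.missing_mask
    frac = {cls: miss[table.labels == cls].mean(axis=0) for cls in spec.classes}
    drop = (frac[spec.class_control] > spec.missing_threshold) | (
        frac[spec.class_case] > spec.missing_threshold)
    dropped = [f for f in table.feature_names if drop[f]]
    log = pd.DataFrame({
        "feature": dropped,
        f"missing_frac_{spec.class_control}":
            [float(frac[spec.class_control][f]) for f in dropped],
        f"missing_frac_{spec.class_case}":
            [float(frac[spec.class_case][f]) for f in dropped],
    })
    kept = [f for f in table.feature_names if not drop[f]]
    return table.subset(features=kept), log


def complete_case_subset(table: FeatureTable,
                         features: Sequence[str],
                         min_per_class: int = 2) -> FeatureTable:
    """Subjects with no missing value on any of ``features``, order kept.

    Raises :class:`EmptyClassError` when fewer than ``min_per_class``
    subjects of any class survive (such a subset cannot support a fit).
    An empty feature list is the identity.
    """
    features = list(features)
    unknown = set(features) - set(table.feature_names)
    if unknown:
        raise KeyError(f"unknown features: {sorted(unknown)}")
    if not features:
        return table.subset()
    ok = table.values[features].notna().all(axis=1)
    sub = table.subset(subjects=table.values.index[ok])
    counts = sub.labels.value_counts()
    for cls in table.labels.unique():
        if counts.get(cls, 0) < min_per_class:
            raise EmptyClassError(
                f"complete cases leave {counts.get(cls, 0)} subjects of class "
                f"{cls!r} (< {min_per_class}) on features {features}")
    return sub


# ---------------------------------------------------------------------
# CSV interface

NA_STRINGS = ("", "NA")


def read_feature_table(csv_path, modality_path=None) -> FeatureTable:
    """Read the standard input CSV (id, label, features...).

    First column: subject id; second column: diagnostic label; remaining
    columns: features.  Empty cells or ``NA`` are missing.  An optional
    two-column TSV maps feature name -> modality tag.
    """
    df = pd.read_csv(csv_path, na_values=list(NA_STRINGS), keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("expected at least id, label and one feature column")
    ids = df.iloc[:, 0].astype(str)
    labels = pd.Series(df.iloc[:, 1].astype(str).values, index=ids.values,
                       name="label")
    values = df.iloc[:, 2:].astype(float)
    values.index = ids.values
    modality: dict[str, str] = {}
    if modality_path is not None:
        mod = pd.read_csv(modality_path, sep="\t", header=None,
                          names=["feature", "modality"])
        modality = dict(zip(mod["feature"], mod["modality"]))
    return FeatureTable(values=values, labels=labels, modality=modality)


def write_feature_table(table: FeatureTable, csv_path,
                        modality_path=None) -> None:
    """Write the table in the same CSV dialect (missing cells empty)."""
    out = table.values.copy()
    out.insert(0, "label", table.labels)
    out.insert(0, "subject_id", out.index)
    out.to_csv(csv_path, index=False, na_rep="")
    if modality_path is not None and table.modality:
        pd.Series(table.modality, name="modality").rename_axis(
            "feature").to_csv(modality_path, sep="\t", header=False)
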