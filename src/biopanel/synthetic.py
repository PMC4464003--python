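"""Synthetic multimodal cohorts with known ground truth.

Emulates the structure of a case-control neuroimaging/biofluid study of
cognitive decline: three diagnostic classes (healthy controls, mild
cognitive impairment, dementia), several hundred features organised in
modality blocks (MRI volume/thickness/surface, PET metabolism, CSF and
plasma assays, binary clinical-history flags), a small set of planted
class-separating features with known standardized effect sizes, highly
correlated duplicate features, and per-modality missing-completely-at-
random rates.

The generative model is a mean-shift design: every feature is standard
normal within class; a feature planted for the contrast (A, B) has its
class means shifted so that they differ by exactly ``delta`` standard
deviations between A and B, with the remaining class placed on the same
linear disease gradient (stage order HC < MCI < AD).  Because the
within-class covariance is the identity, the implied logistic-regression
coefficient of a planted feature equals its signed ``delta``, which makes
parameter recovery directly checkable.  Correlated duplicates are built
as ``rho * parent + sqrt(1 - rho^2) * noise`` so their empirical Pearson
correlation targets ``rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import MODALITIES, FeatureTable

#: disease stage used to place the third class of a pairwise contrast
STAGE = {"HC": 0.0, "MCI": 1.0, "AD": 2.0}

DEFAULT_MODALITY_FRACTIONS = {
    "MRI-volume": 0.16,
    "MRI-thickness": 0.21,
    "MRI-surface": 0.21,
    "PET": 0.12,
    "fluid": 0.20,
    "clinical": 0.10,
}

#: MCAR missing probability per modality; fluid assays are the most
#: incomplete in practice, core imaging the least.
DEFAULT_MISSING_RATES = {
    "MRI-volume": 0.05,
    "MRI-thickness": 0.05,
    "MRI-surface": 0.05,
    "PET": 0.10,
    "fluid": 0.15,
    "clinical": 0.02,
}


@dataclass(frozen=True)
class PlantedFeature:
    """A class-separating feature: ``delta`` SD mean shift on a contrast."""

    index: int
    contrast: tuple[str, str]
    delta: float
    sign: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of one synthetic cohort.

    Defaults mirror the emulated study: 48 HC / 98 MCI / 48 AD subjects
    in the feature-selection population and ~650 baseline features.  Five
    features separating HC from AD at 1.5 SD are planted by default;
    25 duplicate features at rho = 0.9 exercise correlation merging.
    """

    n_per_class: tuple[tuple[str, int], ...] = (("HC", 48), ("MCI", 98), ("AD", 48))
    n_features: int = 650
    planted: tuple[PlantedFeature, ...] = tuple(
        PlantedFeature(index=i, contrast=("HC", "AD"), delta=1.5) for i in range(5)
    )
    n_correlated_pairs: int = 25
    duplicate_rho: float = 0.9
    missing_rates: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_MISSING_RATES.items())
    modality_fractions: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_MODALITY_FRACTIONS.items())
    binary_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.8 < self.duplicate_rho <= 1.0:
            raise ValueError("duplicate_rho must lie in (0.8, 1]")
        for mod, rate in self.missing_rates:
            if not 0.0 <= rate <= 0.5:
                raise ValueError(f"missing rate for {mod} outside [0, 0.5]")
        if self.n_features < 2 * self.n_correlated_pairs:
            raise ValueError("too many correlated pairs for n_features")

    @property
    def class_names(self) -> list[str]:
        return [c for c, _ in self.n_per_class]

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.n_per_class)


@dataclass
class GroundTruth:
    """What was planted: effects, duplicate pairs, generating means.

    ``generating_coefficients`` are the implied logistic coefficients of
    the planted features for their contrast (signed delta, identity
    within-class covariance).
    """

    planted: dict[str, PlantedFeature]
    duplicate_map: dict[str, tuple[str, float]]
    class_means: dict[str, dict[str, float]]

    @property
    def generating_coefficients(self) -> dict[str, float]:
        return {name: p.sign * p.delta for name, p in self.planted.items()}

    def signal_features(self) -> set[str]:
        """Planted features plus their correlated duplicates."""
        out = set(self.planted)
        for child, (parent, _) in self.duplicate_map.items():
            if parent in self.planted:
                out.add(child)
        return out

    def to_json(self, path) -> None:
        payload = {
            "planted": {
                name: {"contrast": list(p.contrast), "delta": p.delta,
                       "sign": p.sign}
                for name, p in self.planted.items()
            },
            "duplicate_map": {c: [p, r] for c, (p, r) in self.duplicate_map.items()},
            "class_means": self.class_means,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _modality_layout(config: CohortConfig) -> list[str]:
    """Assign a modality tag to each feature index, in blocks."""
    fractions = dict(config.modality_fractions)
    counts = {m: int(round(fractions.get(m, 0.0) * config.n_features))
              for m in MODALITIES}
    # absorb rounding drift into the fluid block
    drift = config.n_features - sum(counts.values())
    counts["fluid"] += drift
    layout: list[str] = []
    for m in MODALITIES:
        layout.extend([m] * counts[m])
    return layout[: config.n_features]


def _feature_names(layout: list[str]) -> list[str]:
    short = {"MRI-volume": "mrivol", "MRI-thickness": "mrithk",
             "MRI-surface": "mrisrf", "PET": "pet", "fluid": "fluid",
             "clinical": "clin"}
    counter: dict[str, int] = {}
    names = []
    for m in layout:
        counter[m] = counter.get(m, 0) + 1
        names.append(f"{short[m]}_{counter[m]:03d}")
    return names


def _planted_class_means(planted: PlantedFeature,
                         classes: list[str]) -> dict[str, float]:
    """Class means on a linear disease gradient anchored at the contrast."""
    a, b = planted.contrast
    sa = STAGE.get(a, 0.0)
    sb = STAGE.get(b, 1.0)
    shift = planted.sign * planted.delta
    means = {}
    for cls in classes:
        sc = STAGE.get(cls, sa)
        means[cls] = shift * (sc - sa) / (sb - sa)
    return means


def generate_cohort(config: CohortConfig) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort; bit-for-bit reproducible from ``config.seed``.

    Pipeline: latent N(0,1) noise per class -> planted mean shifts ->
    correlated duplicates overwrite their child columns -> clinical
    columns thresholded to {0,1} at the configured prevalence -> MCAR
    mask per modality (duplicate children inherit their parent's missing
    cells and add their own draws).
    """
    rng = np.random.default_rng(config.seed)
    classes = config.class_names
    layout = _modality_layout(config)
    names = _feature_names(layout)
    n, p = config.n_subjects, config.n_features

    labels = np.repeat(classes, [dict(config.n_per_class)[c] for c in classes])
    subject_ids = [f"S{i:04d}" for i in range(n)]

    X = rng.standard_normal((n, p))

    # plant the mean shifts
    planted: dict[str, PlantedFeature] = {}
    class_means: dict[str, dict[str, float]] = {}
    for pf in config.planted:
        if pf.index >= p:
            raise ValueError(f"planted index {pf.index} out of range")
        name = names[pf.index]
        means = _planted_class_means(pf, classes)
        for cls, mu in means.items():
            X[labels == cls, pf.index] += mu
        planted[name] = pf
        class_means[name] = means

    # correlated duplicates: the last continuous (non-clinical) columns
    # become children of randomly chosen earlier continuous columns
    # (binary flags are thresholded later, which would destroy the
    # target correlation)
    continuous = [j for j, m in enumerate(layout) if m != "clinical"]
    if len(continuous) < 2 * config.n_correlated_pairs:
        raise ValueError("too many correlated pairs for the continuous block")
    child_idx = continuous[len(continuous) - config.n_correlated_pairs:]
    bad = [pf.index for pf in config.planted if pf.index in child_idx]
    if bad:
        raise ValueError(
            f"planted indices collide with duplicate children: {bad}")
    parent_pool = [j for j in continuous[: len(continuous)
                                         - config.n_correlated_pairs]]
    parents = rng.choice(parent_pool, size=config.n_correlated_pairs,
                         replace=False)
    duplicate_map: dict[str, tuple[str, float]] = {}
    rho = config.duplicate_rho
    for ci, pi in zip(child_idx, parents):
        eps = rng.standard_normal(n)
        X[:, ci] = rho * X[:, pi] + np.sqrt(1.0 - rho**2) * eps
        duplicate_map[names[ci]] = (names[pi], rho)

    # binary clinical flags: threshold the latent normal
    cut = norm.ppf(1.0 - config.binary_prevalence)
    for j, m in enumerate(layout):
        if m == "clinical":
            X[:, j] = (X[:, j] > cut).astype(float)

    # MCAR per modality; children inherit parent missingness
    rates = dict(config.missing_rates)
    miss = np.zeros((n, p), dtype=bool)
    for j, m in enumerate(layout):
        rate = rates.get(m, 0.0)
        if rate > 0:
            miss[:, j] = rng.random(n) < rate
    name_to_idx = {nm: j for j, nm in enumerate(names)}
    for child, (parent, _) in duplicate_map.items():
        miss[:, name_to_idx[child]] |= miss[:, name_to_idx[parent]]
    X[miss] = np.nan

    values = pd.DataFrame(X, index=subject_ids, columns=names)
    table = FeatureTable(
        values=values,
        labels=pd.Series(labels, index=subject_ids, name="label"),
        modality=dict(zip(names, layout)),
    )
    truth = GroundTruth(planted=planted, duplicate_map=duplicate_map,
                        class_means=class_means)
    return table, truth


def plant_correlates(table: FeatureTable,
                     pairs: dict[str, tuple[str, float]],
                     seed: int = 0) -> FeatureTable:
    """Append duplicate columns ``child = rho*parent + sqrt(1-rho^2)*eps``.

    ``pairs`` maps new child name -> (existing parent name, target rho).
    Children are missing wherever the parent is missing, plus nothing
    else (callers wanting extra MCAR apply it themselves).  A target rho
    of 1 yields an exact copy.  Targets at or below 0.8 emit a warning:
    such a pair will not trigger correlation merging downstream.
    """
    import warnings

    rng = np.random.default_rng(seed)
    values = table.values.copy()
    for child, (parent, rho) in pairs.items():
        if parent not in values.columns:
            raise KeyError(f"parent feature {parent!r} not in table")
        if rho <= 0.8:
            warnings.warn(
                f"target rho {rho} for {child!r} is <= 0.8; pair will not "
                "qualify for correlation merging", stacklevel=2)
        x = values[parent].to_numpy()
        eps = rng.standard_normal(len(x))
        values[child] = rho * x + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        # NaN propagates from the parent automatically via arithmetic
    modality = dict(table.modality)
    for child, (parent, _) in pairs.items():
        if parent in modality:
            modality[child] = modality[parent]
    return FeatureTable(values=values, labels=table.labels.copy(),
                        modality=modality,
                        standardization=None)


def two_class_config(n_control: int = 300, n_case: int = 300,
                     n_features: int = 600, n_planted: int = 5,
                     delta: float = 1.5, n_correlated_pairs: int = 25,
                     seed: int = 0,
                     classes: tuple[str, str] = ("HC", "AD")) -> CohortConfig:
    """Convenience config for a two-class planted-signal cohort.

    The default — 5 features separating the classes at 1.5 SD among 600,
    300 subjects per class — is the standard ground-truth-recovery
    scenario used throughout the test suite.
    """
    a, b = classes
    return CohortConfig(
        n_per_class=((a, n_control), (b, n_case)),
        n_features=n_features,
        planted=tuple(PlantedFeature(index=i, contrast=(a, b), delta=delta)
                      for i in range(n_planted)),
        n_correlated_pairs=n_correlated_pairs,
        seed=seed,
    )
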