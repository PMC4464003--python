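"""Validation: a-posteriori subjects, calibration/test split, bootstrap
confidence intervals and the random-model null experiment.

Subjects excluded from feature selection for missing data may still have
complete data on the *final* model's few features; these a-posteriori
included subjects (APIS) enlarge the study.  The calibration set is the
feature-selection population plus a seeded random sample of APIS, sized
so that calibration:test = 4:1 (the test set is the remaining APIS).
Coefficients are refit ("calibrated") on the calibration set; the fixed
calibrated model is then evaluated with stratified bootstrap resampling
(mean and 2.5/97.5 percentile CI per metric) and blind-tested on the
held-out test set.

The chance-performance experiment draws many random feature sets of the
final model's size from the surviving feature pool, fits each on the
calibration set and bootstrap-evaluates it identically; the probability
of matching the proposed model by chance is the proportion of random
models outperforming it (computed separately on bootstrap-mean accuracy
and AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AnalysisSpec, FeatureTable, complete_case_subset
from .glm import (EvaluationReport, FittedLogisticModel, MetricSummary, auc,
                  classification_metrics, fit_logistic, roc_curve)


@dataclass
class SplitPlan:
    """Who goes where: feature-selection, APIS, calibration and test ids."""

    feature_selection_ids: list
    apis_ids: list
    calibration_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.test_ids):
            raise ValueError("calibration and test sets overlap")
        if not set(self.test_ids) <= set(self.apis_ids):
            raise ValueError("test subjects must come from APIS")

    @property
    def ratio(self) -> float:
        return len(self.calibration_ids) / max(len(self.test_ids), 1)


def build_apis(full_table: FeatureTable, final_model: FittedLogisticModel,
               selection_ids, spec: AnalysisSpec,
               seed: int | None = None) -> SplitPlan:
    """Split subjects into calibration and test sets around the APIS pool.

    APIS = subjects of the contrast's two classes outside the
    feature-selection set with complete data on the final model's
    features.  A seeded simple random sample of m APIS subjects joins the
    feature-selection set to form the calibration set, with m solving

        |selection| + m = ratio * (|APIS| - m)

    (rounded, clamped to [0, |APIS|]); the remaining APIS subjects are
    the test set.  An empty APIS pool degenerates to bootstrap-only
    validation with a warning.  With ``spec.stratified_apis_sample`` the
    sample is drawn per class proportionally.
    """
    seed = spec.rng_seed if seed is None else seed
    selection_ids = list(selection_ids)
    two_class = full_table.restrict_classes(spec.classes)
    feats = final_model.features
    ok = two_class.values[feats].notna().all(axis=1) if feats else \
        pd.Series(True, index=two_class.values.index)
    outside = ~two_class.values.index.isin(selection_ids)
    apis_ids = list(two_class.values.index[ok & outside])
    if not apis_ids:
        warnings.warn("APIS pool is empty: no held-out test set; validation "
                      "degenerates to bootstrap on the selection set",
                      stacklevel=2)
        return SplitPlan(selection_ids, [], list(selection_ids), [], seed)
    r = spec.calibration_test_ratio
    m_exact = (r * len(apis_ids) - len(selection_ids)) / (1.0 + r)
    m = int(round(m_exact))
    if m < 0 or m > len(apis_ids):
        warnings.warn(
            f"calibration:test ratio {r} unreachable (|selection|="
            f"{len(selection_ids)}, |APIS|={len(apis_ids)}); clamping",
            stacklevel=2)
        m = min(max(m, 0), len(apis_ids))
    rng = np.random.default_rng(seed)
    if spec.stratified_apis_sample and m > 0:
        labels = two_class.labels.loc[apis_ids]
        sampled: list = []
        for cls in spec.classes:
            pool = [i for i in apis_ids if labels[i] == cls]
            take = int(round(m * len(pool) / len(apis_ids)))
            take = min(take, len(pool))
            sampled.extend(rng.choice(pool, size=take, replace=False))
        sampled = sampled[:m]
    else:
        sampled = list(rng.choice(apis_ids, size=m, replace=False))
    sampled_set = set(sampled)
    test_ids = [i for i in apis_ids if i not in sampled_set]
    calibration_ids = selection_ids + [i for i in apis_ids if i in sampled_set]
    return SplitPlan(selection_ids, apis_ids, calibration_ids, test_ids, seed)


def calibrate(model_features, calibration_table: FeatureTable,
              spec: AnalysisSpec,
              reference: FittedLogisticModel | None = None
              ) -> FittedLogisticModel:
    """Refit the fixed feature set's coefficients on the calibration set.

    No reselection happens here.  When a ``reference`` fit is supplied,
    any coefficient sign flip relative to it is logged with a warning
    (a sign flip means the effect found during selection did not survive
    recalibration).
    """
    model = fit_logistic(calibration_table, list(model_features), spec)
    if reference is not None:
        flips = [f for f in model.features
                 if np.sign(model.coefficients[f])
                 * np.sign(reference.coefficients.get(f, 0.0)) < 0]
        if flips:
            warnings.warn(
                f"coefficient sign flips after calibration: {flips}",
                stacklevel=2)
    return model


def _resample_metrics(probs: np.ndarray, y: np.ndarray, idx: np.ndarray,
                      threshold: float) -> tuple[float, float, float, float]:
    p, yy = probs[idx], y[idx]
    pred = (p > threshold).astype(int)
    case = yy == 1
    sens = float(np.mean(pred[case] == 1))
    spec_ = float(np.mean(pred[~case] == 0))
    acc = float(np.mean(pred == yy))
    return acc, sens, spec_, auc(p, yy)


def bootstrap_evaluate(model: FittedLogisticModel, table: FeatureTable,
                       spec: AnalysisSpec, seed: int | None = None,
                       n_bootstrap: int | None = None) -> EvaluationReport:
    """Bootstrap the FIXED model's metrics on a population.

    ``n_bootstrap`` class-stratified resamples with replacement are drawn
    from the complete cases of the model's features; accuracy,
    sensitivity, specificity and AUC are recomputed per resample from
    the model's (fixed) predicted probabilities — the model is not refit
    (set ``spec.bootstrap_refit`` for the refitting variant).  Each
    metric is reported as the full-sample point value plus the bootstrap
    mean and 2.5/97.5 percentile interval.  A degenerate resample (e.g.
    all tied probabilities of one class) is redrawn, at most 10 times.
    """
    seed = spec.rng_seed if seed is None else seed
    n_boot = spec.n_bootstrap if n_bootstrap is None else n_bootstrap
    sub = complete_case_subset(table, model.features)
    y = sub.binary_labels(spec).to_numpy()
    probs = model.predict_prob(sub).to_numpy()
    ids = np.array(sub.subject_ids)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    rows = np.empty((n_boot, 4))
    for b in range(n_boot):
        for attempt in range(10):
            idx = np.concatenate([
                rng.choice(idx_case, size=len(idx_case), replace=True),
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True)])
            if spec.bootstrap_refit:
                refit = fit_logistic(sub.subset(subjects=ids[idx]),
                                     model.features, spec,
                                     complete_cases=False)
                p_b = refit.predict_prob(sub).to_numpy()[idx]
            else:
                p_b = probs[idx]
            vals = _resample_metrics(p_b, y[idx],
                                     np.arange(len(idx)),
                                     spec.classification_threshold)
            if all(np.isfinite(vals)):
                rows[b] = vals
                break
        else:
            raise RuntimeError("bootstrap resample degenerate 10 times in a row")
    point = classification_metrics(probs, y, spec.classification_threshold)
    names = ("accuracy", "sensitivity", "specificity", "auc")
    summaries = {}
    for j, name in enumerate(names):
        col = rows[:, j]
        summaries[name] = MetricSummary(
            point=getattr(point, name).point,
            boot_mean=float(col.mean()),
            ci_low=float(np.percentile(col, 2.5)),
            ci_high=float(np.percentile(col, 97.5)))
    return EvaluationReport(roc_points=roc_curve(probs, y), **summaries)


@dataclass
class NullExperiment:
    """Chance-performance reference: random same-size models' bootstrap means."""

    n_random_models: int
    model_size: int
    accuracies: np.ndarray           # bootstrap-mean accuracy per random model
    aucs: np.ndarray                 # bootstrap-mean AUC per random model
    proposed_accuracy: float
    proposed_auc: float
    prob_outperform_accuracy: float = field(init=False)
    prob_outperform_auc: float = field(init=False)
    band_accuracy: tuple[float, float] = field(init=False)
    band_auc: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.prob_outperform_accuracy = float(
            np.mean(self.accuracies > self.proposed_accuracy))
        self.prob_outperform_auc = float(
            np.mean(self.aucs > self.proposed_auc))
        self.band_accuracy = (float(np.percentile(self.accuracies, 2.5)),
                              float(np.percentile(self.accuracies, 97.5)))
        self.band_auc = (float(np.percentile(self.aucs, 2.5)),
                         float(np.percentile(self.aucs, 97.5)))

    def densities(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model_index": np.arange(1, self.n_random_models + 1),
            "mean_accuracy": self.accuracies,
            "mean_auc": self.aucs,
        })


def random_model_null(final_model: FittedLogisticModel,
                      proposed_report: EvaluationReport,
                      table: FeatureTable, feature_pool,
                      spec: AnalysisSpec, seed: int | None = None,
                      n_random_models: int | None = None,
                      n_bootstrap: int | None = None) -> NullExperiment:
    """Bootstrap-evaluate random same-size models on the calibration set.

    ``feature_pool`` is the set of features that survived the missingness
    filter; each random model draws ``final_model.size`` features from it
    uniformly without replacement, is fit on ``table`` (the calibration
    set) and evaluated exactly like the proposed model.  Aborts when more
    than 10% of random models cannot be fit.
    """
    seed = spec.rng_seed if seed is None else seed
    n_models = spec.n_random_models if n_random_models is None else n_random_models
    size = final_model.size
    pool = list(feature_pool)
    if size == 0 or len(pool) < size:
        raise ValueError("feature pool smaller than the model size")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_models)
    aucs = np.empty(n_models)
    failures = 0
    i = 0
    while i < n_models:
        feats = list(rng.choice(pool, size=size, replace=False))
        try:
            m = fit_logistic(table, feats, spec)
            rep = bootstrap_evaluate(
                m, table, spec, seed=int(rng.integers(2**31)),
                n_bootstrap=n_bootstrap)
        except Exception:  # noqa: BLE001 - unfittable random draw
            failures += 1
            if failures > 0.10 * n_models:
                raise RuntimeError(
                    f"more than 10% of random models unfittable "
                    f"({failures} failures)") from None
            continue
        accs[i] = rep.accuracy.boot_mean
        aucs[i] = rep.auc.boot_mean
        i += 1
    return NullExperiment(
        n_random_models=n_models, model_size=size,
        accuracies=accs, aucs=aucs,
        proposed_accuracy=float(proposed_report.accuracy.boot_mean),
        proposed_auc=float(proposed_report.auc.boot_mean))
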