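"""Logistic-regression diagnostic models and classification metrics.

A hand-rolled iteratively-reweighted-least-squares (IRLS) fitter with
Wald inference, a rank-based AUC (the Mann-Whitney statistic with ties
counted one half), ROC curves thresholded at every distinct score, the
odds-ratio-at-two-SD effect summary for z-scored predictors, and the
univariate Wilcoxon/Bonferroni screen used as a comparator to the
multivariate search.

The case class is always coded 1 and the control class 0, so
"sensitivity" is the fraction of correctly predicted case (disease-
progressed) subjects and "specificity" the same for controls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from .data_model import AnalysisSpec, FeatureTable, complete_case_subset


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (collinear features)."""


class SeparationWarning(UserWarning):
    """Perfect separation: coefficients diverge; fit flagged unconverged."""


# ---------------------------------------------------------------------
# IRLS core


def irls_logistic(X: np.ndarray, y: np.ndarray,
                  max_iter: int = 100, score_tol: float = 1e-8,
                  dev_tol: float = 1e-10) -> tuple[np.ndarray, bool, int]:
    """Maximum-likelihood logistic fit by IRLS on [1 | X].

    Returns (beta, converged, n_iter) with beta[0] the intercept.
    Convergence: max |score| < ``score_tol`` or relative deviance change
    < ``dev_tol``.  Divergence of the coefficients (separation) leaves
    ``converged`` False.  Raises :class:`SingularDesignError` on a rank-
    deficient design.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        # name the offending columns via QR pivoting on the feature block
        raise SingularDesignError(
            "design matrix is rank deficient (collinear features)")
    beta = np.zeros(p + 1)
    dev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = A.T @ (y - mu)
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SingularDesignError(str(exc)) from exc
        beta = beta + step
        with np.errstate(divide="ignore", invalid="ignore"):
            new_dev = -2.0 * float(
                np.sum(y * np.log(np.clip(mu, 1e-300, 1.0))
                       + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1.0))))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        if np.isfinite(dev) and abs(dev - new_dev) < dev_tol * (abs(dev) + 1e-12):
            converged = True
            break
        dev = new_dev
        if np.max(np.abs(beta)) > 1e3:  # separation: likelihood unbounded
            converged = False
            break
    # perfect prediction = separation: the score vanishes only because the
    # clipped linear predictor saturates, not because the MLE exists
    eta = np.clip(A @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if converged and np.all(np.abs(y - mu) < 1e-6):
        converged = False
    return beta, converged, it


@dataclass
class FittedLogisticModel:
    """A fitted binary diagnostic model on named z-scored features.

    Wald z and two-sided p per coefficient come from the observed
    information at the optimum.  ``odds_ratios_2sd`` summarises each
    effect as exp(2*|beta|), the odds ratio of a two-SD move on a
    z-standardized predictor.
    """

    features: list[str]
    intercept: float
    coefficients: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    wald_z: dict[str, float] = field(default_factory=dict)
    wald_p: dict[str, float] = field(default_factory=dict)
    n_control: int = 0
    n_case: int = 0
    converged: bool = True
    class_control: str = "control"
    class_case: str = "case"

    @property
    def size(self) -> int:
        return len(self.features)

    def beta_vector(self) -> np.ndarray:
        return np.array([self.intercept]
                        + [self.coefficients[f] for f in self.features])

    def odds_ratios_2sd(self) -> dict[str, float]:
        return {f: odds_ratio_2sd(b) for f, b in self.coefficients.items()}

    def predict_prob(self, table: FeatureTable) -> pd.Series:
        """Per-subject probability of the case class.

        Subjects missing any model feature are flagged unscorable (NaN).
        """
        if self.features:
            Z = table.values[self.features].to_numpy(dtype=float)
            eta = self.intercept + Z @ np.array(
                [self.coefficients[f] for f in self.features])
        else:
            eta = np.full(table.n_subjects, self.intercept)
        eta = np.clip(eta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
        return pd.Series(p, index=table.values.index, name="prob_case")

    def to_json(self, path=None):
        payload = {
            "class_control": self.class_control,
            "class_case": self.class_case,
            "features": self.features,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "se": self.se,
            "wald_z": self.wald_z,
            "wald_p": self.wald_p,
            "odds_ratio_2sd": self.odds_ratios_2sd(),
            "n_control": self.n_control,
            "n_case": self.n_case,
            "converged": self.converged,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    @classmethod
    def from_json(cls, payload: dict) -> "FittedLogisticModel":
        return cls(features=list(payload["features"]),
                   intercept=float(payload["intercept"]),
                   coefficients=dict(payload["coefficients"]),
                   se=dict(payload.get("se", {})),
                   wald_z=dict(payload.get("wald_z", {})),
                   wald_p=dict(payload.get("wald_p", {})),
                   n_control=int(payload.get("n_control", 0)),
                   n_case=int(payload.get("n_case", 0)),
                   converged=bool(payload.get("converged", True)),
                   class_control=payload.get("class_control", "control"),
                   class_case=payload.get("class_case", "case"))


def fit_logistic(table: FeatureTable, features, spec: AnalysisSpec,
                 complete_cases: bool = True) -> FittedLogisticModel:
    """Fit the diagnostic logistic model on the complete cases of ``features``.

    The case class (``spec.class_case``) is coded 1.  Perfect separation
    is reported via :class:`SeparationWarning` and ``converged=False``;
    collinear features raise :class:`SingularDesignError`.
    """
    features = list(features)
    sub = complete_case_subset(table, features) if complete_cases else table
    y = sub.binary_labels(spec).to_numpy()
    X = sub.values[features].to_numpy(dtype=float) if features else \
        np.empty((len(y), 0))
    beta, converged, _ = irls_logistic(X, y)
    if not converged:
        warnings.warn(
            f"logistic fit on {features} did not converge (possible perfect "
            "separation); coefficients are not trustworthy", SeparationWarning,
            stacklevel=2)
    # Wald inference from the observed information at the optimum
    A = np.column_stack([np.ones(len(y)), X])
    eta = np.clip(A @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (A * (mu * (1 - mu))[:, None]).T @ A
    cov = np.linalg.pinv(H)
    se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    z = np.divide(beta, se_all, out=np.zeros_like(beta), where=se_all > 0)
    p = 2.0 * norm.sf(np.abs(z))
    return FittedLogisticModel(
        features=features,
        intercept=float(beta[0]),
        coefficients={f: float(b) for f, b in zip(features, beta[1:])},
        se={f: float(s) for f, s in zip(features, se_all[1:])},
        wald_z={f: float(v) for f, v in zip(features, z[1:])},
        wald_p={f: float(v) for f, v in zip(features, p[1:])},
        n_control=int((y == 0).sum()),
        n_case=int((y == 1).sum()),
        converged=converged,
        class_control=spec.class_control,
        class_case=spec.class_case,
    )


def predict_prob(model: FittedLogisticModel, table: FeatureTable) -> pd.Series:
    return model.predict_prob(table)


# ---------------------------------------------------------------------
# metrics


@dataclass
class MetricSummary:
    point: float
    boot_mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class EvaluationReport:
    """Accuracy / sensitivity / specificity / AUC, optionally with
    bootstrap means and 95% percentile confidence intervals, plus the
    ROC curve as ordered (FPR, TPR) points."""

    accuracy: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    auc: MetricSummary
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def metrics(self) -> dict[str, MetricSummary]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}

    def to_json(self, path=None):
        payload = {name: m.as_dict() for name, m in self.metrics().items()}
        payload["roc_points"] = [list(pt) for pt in self.roc_points]
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    def roc_to_csv(self, path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            path, index=False)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def classification_metrics(probs, labels, threshold: float = 0.5
                           ) -> EvaluationReport:
    """Point accuracy/sensitivity/specificity/AUC at a probability cutoff.

    ``labels`` are 0/1 with 1 the case class; sensitivity is the fraction
    of case subjects predicted as cases, specificity the fraction of
    controls predicted as controls.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = (probs > threshold).astype(int)
    case = labels == 1
    tp = int(np.sum(pred[case] == 1))
    fn = int(np.sum(pred[case] == 0))
    tn = int(np.sum(pred[~case] == 0))
    fp = int(np.sum(pred[~case] == 1))
    return EvaluationReport(
        accuracy=MetricSummary((tp + tn) / len(labels)),
        sensitivity=MetricSummary(tp / (tp + fn)),
        specificity=MetricSummary(tn / (tn + fp)),
        auc=MetricSummary(auc(probs, labels)),
        roc_points=roc_curve(probs, labels),
    )


def auc(scores, labels) -> float:
    """Rank-based AUC: P(case score > control score), ties counted 1/2.

    Equals the Mann-Whitney U statistic divided by n_case * n_control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    from scipy.stats import rankdata
    r = rankdata(scores)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    u = float(np.sum(r[labels == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """ROC points thresholded at every distinct score, from (0,0) to (1,1).

    Points are ordered by increasing FPR/TPR; tied scores move diagonally,
    so the trapezoidal area under this curve equals the rank-based
    :func:`auc` exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # process tied scores together
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        points.append((fp / n0, tp / n1))
        i = j
    return points


def trapezoid_auc(points) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def odds_ratio_2sd(beta: float) -> float:
    """Odds ratio for a two-SD move on a z-scored predictor: exp(2|beta|).

    Symmetric in the sign of beta; the signed coefficient is reported
    alongside it in model summaries.
    """
    return float(np.exp(2.0 * abs(beta)))


# ---------------------------------------------------------------------
# univariate comparator


def univariate_screen(table: FeatureTable, spec: AnalysisSpec,
                      features=None) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum with Bonferroni adjustment.

    Each feature is tested on its own complete cases (case vs control
    distributions).  Exact p-values when the combined n is <= 20 and the
    data are tie-free; the normal approximation with tie correction
    otherwise.  Adjusted p = min(1, p * m) with m the number of features
    tested.  Features with fewer than 2 observations in either class get
    NaN p-values and do not count towards m.
    """
    features = list(features) if features is not None else table.feature_names
    y = table.binary_labels(spec)
    rows = []
    for f in features:
        x = table.values[f]
        ok = x.notna()
        a = x[ok & (y == 1)].to_numpy()
        b = x[ok & (y == 0)].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((f, np.nan))
            continue
        combined = np.concatenate([a, b])
        ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (len(combined) <= 20 and not ties) else "asymptotic"
        p = float(mannwhitneyu(a, b, alternative="two-sided",
                               method=method).pvalue)
        rows.append((f, p))
    out = pd.DataFrame(rows, columns=["feature", "p_value"])
    m = int(out["p_value"].notna().sum())
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * max(m, 1))
    return out
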