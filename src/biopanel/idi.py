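"""Integrated discrimination improvement (IDI) with cross-validated inputs.

The IDI compares a nested ("old") and an extended ("new") risk model on
the same subjects: it is the change in mean predicted case probability
among events minus the same change among nonevents,

    IDI = (mean dp | events) - (mean dp | nonevents),   dp = p_new - p_old,

with standard error

    SE = sqrt(s_e^2 / n_e + s_n^2 / n_n)

where s_e, s_n are the sample SDs of dp within events and nonevents, and
a normal z-test on IDI/SE.

Both forward selection and backward elimination gate on this statistic
computed from *out-of-fold* probabilities: each subject is scored by the
model fitted on the other k-1 folds, with the identical fold sets shared
between the nested and extended model so the comparison is paired.

The reported p-value is one-sided in the improvement direction,
p = P(Z >= z).  Out-of-fold probabilities drift the null z *negative*
(the extended model pays a cross-validation penalty for its extra
coefficient), so a two-sided test rejects mostly on the negative tail —
evidence of *harm*, which no selection step ever acts on — and its
rejection rate is well above nominal.  The directional test matches the
gate's hypothesis ("does the candidate improve discrimination?") and is
calibrated at its nominal level under a null added feature; the
simulation in the test suite verifies this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import AnalysisSpec, EmptyClassError, FeatureTable, \
    complete_case_subset
from .glm import fit_logistic


@dataclass(frozen=True)
class IdiResult:
    """IDI estimate with its z-test.

    ``p`` is the one-sided improvement p-value P(Z >= z); the two-sided
    companion is available as :attr:`p_two_sided`.
    """

    idi: float
    se: float
    z: float
    p: float
    n_events: int
    n_nonevents: int
    degenerate: bool = False

    @property
    def p_two_sided(self) -> float:
        if not np.isfinite(self.z):
            return 0.0
        return 2.0 * float(norm.sf(abs(self.z)))

    def as_row(self) -> dict:
        return {"idi": self.idi, "se": self.se, "z": self.z, "p": self.p,
                "n_events": self.n_events, "n_nonevents": self.n_nonevents}


def idi_statistic(probs_old, probs_new, labels) -> IdiResult:
    """Pencina-type IDI estimate, SE, z and two-sided p.

    ``probs_old`` and ``probs_new`` are paired probabilities for the same
    subjects; ``labels`` are 0/1 with 1 = event (case class).  The
    p-value is one-sided toward improvement, P(Z >= z).  When both
    within-group SDs are zero the z-test is degenerate: z = 0, p = 1 if
    the IDI itself is zero, otherwise the result is flagged degenerate
    (z infinite in sign of the IDI, p = 0 or 1 accordingly).
    """
    p_old = np.asarray(probs_old, dtype=float)
    p_new = np.asarray(probs_new, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p_old.shape != p_new.shape or p_old.shape != y.shape:
        raise ValueError("probs_old, probs_new and labels must align")
    ev = y == 1
    ne = y == 0
    n_e, n_n = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_n == 0:
        raise EmptyClassError("both events and nonevents are required")
    dp = p_new - p_old
    idi = float(dp[ev].mean() - dp[ne].mean())
    s_e = float(dp[ev].std(ddof=1)) if n_e > 1 else 0.0
    s_n = float(dp[ne].std(ddof=1)) if n_n > 1 else 0.0
    se = float(np.sqrt(s_e**2 / n_e + s_n**2 / n_n))
    if se > 0:
        z = idi / se
        p = float(norm.sf(z))
        return IdiResult(idi, se, z, p, n_e, n_n)
    if idi == 0.0:
        return IdiResult(0.0, 0.0, 0.0, 1.0, n_e, n_n)
    z = float(np.sign(idi) * np.inf)
    p = 0.0 if idi > 0 else 1.0
    return IdiResult(idi, 0.0, z, p, n_e, n_n, degenerate=True)


def stratified_folds(labels, k: int, seed: int,
                     max_attempts: int = 10) -> np.ndarray:
    """Per-subject fold ids in {0..k-1}, stratified by the 0/1 label.

    Redraws (new derived seed) until every fold contains both classes;
    after ``max_attempts`` failures an error is raised.  Deterministic in
    ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k_folds must be >= 2")
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + 1000003 * attempt) % 2**31)
        fold = np.empty(n, dtype=np.int64)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            perm = rng.permutation(idx)
            fold[perm] = np.arange(len(perm)) % k
        ok = all(len(np.unique(y[fold == f])) == 2 for f in range(k))
        if ok:
            return fold
    raise EmptyClassError(
        f"could not build {k} stratified folds with both classes present "
        f"after {max_attempts} attempts")


def cv_probabilities(table: FeatureTable, features, spec: AnalysisSpec,
                     fold_ids: np.ndarray | None = None,
                     seed: int | None = None) -> pd.Series:
    """Out-of-fold case probabilities for the model on ``features``.

    The table is first reduced to the complete cases of ``features``;
    each surviving subject is scored by the logistic model fitted on the
    other k-1 folds.  ``fold_ids`` (aligned with the *complete-case*
    subjects) lets a caller share fold sets between a nested and an
    extended model; otherwise stratified folds are drawn from ``seed``
    (default ``spec.rng_seed``).  For an empty feature list the model is
    intercept-only, so each held-out subject's probability is the
    training-fold case fraction.
    """
    features = list(features)
    sub = complete_case_subset(table, features)
    y = sub.binary_labels(spec).to_numpy()
    if fold_ids is None:
        fold_ids = stratified_folds(
            y, spec.k_folds, spec.rng_seed if seed is None else seed)
    fold_ids = np.asarray(fold_ids)
    if len(fold_ids) != sub.n_subjects:
        raise ValueError("fold_ids must align with the complete-case subjects")
    probs = np.full(sub.n_subjects, np.nan)
    ids = np.array(sub.subject_ids)
    for f in np.unique(fold_ids):
        train = fold_ids != f
        test = ~train
        if len(np.unique(y[train])) < 2:
            raise EmptyClassError(f"training folds for fold {f} are one-class")
        model = fit_logistic(sub.subset(subjects=ids[train]), features, spec,
                             complete_cases=False)
        probs[test] = model.predict_prob(
            sub.subset(subjects=ids[test])).to_numpy()
    return pd.Series(probs, index=sub.values.index, name="cv_prob")


def cv_idi(table: FeatureTable, parent_features, extra_features,
           spec: AnalysisSpec, seed: int | None = None) -> IdiResult:
    """Cross-validated IDI of (parent + extra) versus parent.

    Both models are evaluated on the complete cases of the *union* of
    their features with one shared stratified fold assignment, so the
    per-subject probability differences are paired.
    """
    parent = list(parent_features)
    extra = [f for f in extra_features if f not in parent]
    union = parent + extra
    sub = complete_case_subset(table, union)
    y = sub.binary_labels(spec).to_numpy()
    folds = stratified_folds(y, spec.k_folds,
                             spec.rng_seed if seed is None else seed)
    p_old = cv_probabilities(sub, parent, spec, fold_ids=folds)
    p_new = cv_probabilities(sub, union, spec, fold_ids=folds)
    return idi_statistic(p_old.to_numpy(), p_new.to_numpy(), y)
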