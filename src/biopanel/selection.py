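"""Correlation-merged ranking, IDI-gated forward selection, backward
elimination.

The GA frequency table is first deduplicated: walking the features in
descending raw frequency, each retained feature absorbs the frequency of
every not-yet-absorbed lower-ranked feature it is strongly correlated
with (|Pearson rho| > 0.8 at p < 0.05 on complete pairs).  Total
frequency is conserved exactly.

Forward selection then walks the merged ranking from the intercept-only
model, admitting a candidate only when its addition yields a positive
cross-validated IDI at p below the gate (default 0.05); failing
candidates are skipped, not terminal.  Backward elimination repeatedly
removes the feature whose contribution has the smallest IDI z-score,
provided that score is non-significant (p > 0.05), refitting after each
removal, until every remaining feature is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data_model import AnalysisSpec, FeatureTable
from .ga import FrequencyTable
from .glm import FittedLogisticModel, fit_logistic
from .idi import cv_idi

# stage tags keep FS / BE fold draws on separate, reproducible streams
FS_SEED_OFFSET = 101
BE_SEED_OFFSET = 202


@dataclass
class FeatureRanking:
    """Features ordered by merged frequency, with the merge audit trail."""

    entries: list[tuple[str, int]]                 # (feature, merged freq)
    merge_log: list[tuple[str, str, float, float]] = field(
        default_factory=list)                      # (discarded, into, rho, p)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def total(self) -> int:
        return sum(c for _, c in self.entries)

    def to_frame(self) -> pd.DataFrame:
        absorbed: dict[str, list[str]] = {}
        for discarded, into, _, _ in self.merge_log:
            absorbed.setdefault(into, []).append(discarded)
        return pd.DataFrame({
            "feature": [f for f, _ in self.entries],
            "merged_frequency": [c for _, c in self.entries],
            "absorbed": [";".join(absorbed.get(f, [])) for f, _ in self.entries],
        })


def pearson_p(rho: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform."""
    if n < 3:
        return float("nan")
    rho = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * float(t_dist.sf(abs(t), n - 2))


def merge_correlated(freqs: FrequencyTable, table: FeatureTable,
                     spec: AnalysisSpec) -> FeatureRanking:
    """Greedy frequency merge of strongly correlated features.

    Features are visited in descending raw frequency (ties broken by
    higher mean CV fitness, then name).  Each visited, not-yet-absorbed
    feature absorbs every lower-ranked unabsorbed feature whose
    pairwise |rho| exceeds the threshold at p below ``correlation_p``;
    the absorbed features leave the ranking and donate their counts.
    Pairs with fewer than 3 complete observations are skipped with a
    warning (the correlation p is undefined).
    """
    import warnings

    order = sorted(
        freqs.counts.index,
        key=lambda f: (-int(freqs.counts[f]),
                       -float(freqs.mean_fitness.get(f, 0.0)), f))
    sub = table.values[order]
    corr = sub.corr(min_periods=3)
    n_pairs = sub.notna().astype(int).T @ sub.notna().astype(int)
    few = 0
    merged = {f: int(freqs.counts[f]) for f in order}
    absorbed: set[str] = set()
    log: list[tuple[str, str, float, float]] = []
    for i, f in enumerate(order):
        if f in absorbed:
            continue
        for g in order[i + 1:]:
            if g in absorbed:
                continue
            n = int(n_pairs.loc[f, g])
            if n < 3:
                few += 1
                continue
            rho = float(corr.loc[f, g])
            if np.isnan(rho) or abs(rho) <= spec.correlation_threshold:
                continue
            p = pearson_p(rho, n)
            if p < spec.correlation_p:
                merged[f] += merged.pop(g)
                absorbed.add(g)
                log.append((g, f, rho, p))
    if few:
        warnings.warn(f"{few} feature pairs had <3 complete observations; "
                      "their correlations were not tested", stacklevel=2)
    entries = sorted(((f, c) for f, c in merged.items()),
                     key=lambda fc: (-fc[1],
                                     -float(freqs.mean_fitness.get(fc[0], 0.0)),
                                     fc[0]))
    return FeatureRanking(entries=entries, merge_log=log)


@dataclass
class SelectionAudit:
    """One row per gate decision during forward selection / elimination."""

    rows: list[dict] = field(default_factory=list)

    def add(self, stage: str, step: int, candidate: str, idi_result,
            decision: str) -> None:
        row = {"stage": stage, "step": step, "candidate": candidate,
               "decision": decision}
        row.update(idi_result.as_row() if idi_result is not None else {})
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def forward_select(ranking: FeatureRanking, table: FeatureTable,
                   spec: AnalysisSpec,
                   audit: SelectionAudit | None = None) -> FittedLogisticModel:
    """IDI-gated forward selection along the merged ranking.

    Starting from the intercept-only model, each of the top
    ``fs_max_candidates`` ranked features is tried in order; it enters
    the model iff its cross-validated IDI against the current parent is
    positive with p < ``idi_p``.  Failing candidates are skipped (or, if
    ``fs_stop_at_first_failure``, terminate the walk).  The final model
    is refit on all complete cases of its features.
    """
    import warnings

    if not ranking.entries:
        raise ValueError("empty ranking: nothing to select from")
    seed = (spec.rng_seed + FS_SEED_OFFSET) % 2**31
    current: list[str] = []
    for step, cand in enumerate(ranking.features[: spec.fs_max_candidates]):
        res = cv_idi(table, current, [cand], spec, seed=seed)
        if res.idi > 0 and res.p < spec.idi_p:
            current.append(cand)
            decision = "included"
        else:
            decision = "skipped"
        if audit is not None:
            audit.add("forward", step, cand, res, decision)
        if decision == "skipped" and spec.fs_stop_at_first_failure:
            break
    if not current:
        warnings.warn("no feature passed the IDI gate; returning the "
                      "intercept-only model", stacklevel=2)
    return fit_logistic(table, current, spec)


def backward_eliminate(model: FittedLogisticModel, table: FeatureTable,
                       spec: AnalysisSpec,
                       audit: SelectionAudit | None = None
                       ) -> FittedLogisticModel:
    """IDI-z backward elimination.

    Each cycle computes, for every feature f in the current model, the
    cross-validated IDI of the model against the model without f (the
    contribution of f).  The feature with the smallest IDI z is removed
    when its p exceeds ``idi_p``; the model is refit and the cycle
    repeats until every remaining contribution is significant.
    """
    seed = (spec.rng_seed + BE_SEED_OFFSET) % 2**31
    current = list(model.features)
    step = 0
    while current:
        results = {}
        for f in current:
            parent = [g for g in current if g != f]
            results[f] = cv_idi(table, parent, [f], spec, seed=seed)
        worst = min(current, key=lambda f: (results[f].z, f))
        if results[worst].p > spec.idi_p:
            current.remove(worst)
            decision = "removed"
        else:
            decision = "kept-all"
        if audit is not None:
            for f in sorted(results):
                audit.add("backward", step, f, results[f],
                          decision if f == worst else "kept")
        if decision == "kept-all":
            break
        step += 1
    return fit_logistic(table, current, spec)
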