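"""Genetic-algorithm wrapper search for fixed-size logistic models.

Many independent GA runs each evolve a population of fixed-size feature
subsets ("chromosomes", default five features) for a fixed number of
generations; fitness is the stratified k-fold cross-validated accuracy
of the logistic model on the chromosome's complete-case subjects.  The
final (best) chromosome of every run is collected, and features are
tallied by how often they appear across those final models — the
frequency table that seeds the downstream ranking and selection.

GA internals: population of 50, tournament selection of size 2, elitism
keeping the single best, uniform crossover with repair to distinct
genes, and per-gene mutation (probability 0.02) to a uniformly random
unused feature.  Each run is an independent restart seeded as
``rng_seed + run_index``, so a batch is exactly reproducible.

Fitness evaluation is the pipeline's hot loop (a full search fits
millions of small logistic models), so it is implemented as a compiled
Newton/IRLS kernel; the test suite checks the kernel against the
reference fitter in :mod:`biopanel.glm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .data_model import AnalysisSpec, FeatureTable


@njit(cache=True, fastmath={'reassoc', 'contract'})
def cv_accuracy_kernel(Xt, y, fold_ids, k, threshold, max_iter=5):
    """k-fold CV accuracy of the logistic model on feature rows ``Xt``.

    ``Xt`` is the (features x subjects) slice for one chromosome, kept
    transposed so every inner accumulation is a dot product over a
    contiguous row (SIMD-friendly — this kernel is the pipeline's hot
    loop).  Subjects with any NaN (incomplete on the chromosome) are
    excluded via a 0/1 weight mask.  Each fold's held-out subjects are
    scored by a Newton/IRLS logistic fit on the remaining folds, with a
    hand-coded Cholesky solve of the small (g+1)-dimensional system and
    a tiny Levenberg damping for degenerate folds.  Coefficient blow-up
    (separation) and slow tail convergence are truncated by the
    iteration cap: only the induced classification (probability vs
    threshold) is consumed, and the decision boundary is stable well
    before the score vanishes.  Folds whose training part is one-class
    are skipped; accuracy is pooled over the valid folds' test subjects;
    0.0 when no fold is valid.
    """
    g, n = Xt.shape
    d = g + 1
    complete = np.ones(n, dtype=np.bool_)
    for i in range(n):
        for j in range(g):
            if np.isnan(Xt[j, i]):
                complete[i] = False
                break
    # work on a NaN-free copy: incomplete subjects are zeroed out and
    # carry zero weight, so they drop out of every accumulation
    Xz = np.empty((g, n))
    for j in range(g):
        for i in range(n):
            Xz[j, i] = Xt[j, i] if complete[i] else 0.0
    Xt = Xz
    m = np.empty(n)
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    wx = np.empty((g, n))
    beta = np.empty(d)
    H = np.empty((d, d))
    score = np.empty(d)
    L = np.empty((d, d))
    step = np.empty(d)
    correct = 0
    total = 0
    for f in range(k):
        n_te = 0
        n_tr = 0
        ones = 0.0
        for i in range(n):
            if complete[i] and fold_ids[i] != f:
                m[i] = 1.0
                n_tr += 1
                ones += y[i]
            else:
                m[i] = 0.0
                if complete[i]:
                    n_te += 1
        if n_te == 0 or ones == 0.0 or ones == n_tr:
            continue
        for j in range(d):
            beta[j] = 0.0
        for _ in range(max_iter):
            for i in range(n):
                eta[i] = beta[0]
            for j in range(g):
                bj = beta[j + 1]
                row = Xt[j]
                for i in range(n):
                    eta[i] += bj * row[i]
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                mu = 1.0 / (1.0 + np.exp(-e))
                w[i] = mu * (1.0 - mu) * m[i]
                r[i] = (y[i] - mu) * m[i]
            s0 = 0.0
            h00 = 0.0
            for i in range(n):
                s0 += r[i]
                h00 += w[i]
            score[0] = s0
            H[0, 0] = h00
            for a in range(g):
                rowa = Xt[a]
                wxa = wx[a]
                sa = 0.0
                ha = 0.0
                for i in range(n):
                    v = w[i] * rowa[i]
                    wxa[i] = v
                    sa += r[i] * rowa[i]
                    ha += v
                score[a + 1] = sa
                H[0, a + 1] = ha
                for b in range(a + 1):
                    rowb = Xt[b]
                    s = 0.0
                    for i in range(n):
                        s += wxa[i] * rowb[i]
                    H[b + 1, a + 1] = s
            for a in range(d):
                H[a, a] += 1e-9
                for b in range(a):
                    H[a, b] = H[b, a]
            # Cholesky solve H step = score
            ok = True
            for a in range(d):
                s = H[a, a]
                for kk in range(a):
                    s -= L[a, kk] * L[a, kk]
                if s <= 0.0:
                    ok = False
                    break
                L[a, a] = np.sqrt(s)
                for b in range(a + 1, d):
                    s2 = H[b, a]
                    for kk in range(a):
                        s2 -= L[b, kk] * L[a, kk]
                    L[b, a] = s2 / L[a, a]
            if not ok:
                break
            for a in range(d):
                s = score[a]
                for kk in range(a):
                    s -= L[a, kk] * step[kk]
                step[a] = s / L[a, a]
            for a in range(d - 1, -1, -1):
                s = step[a]
                for kk in range(a + 1, d):
                    s -= L[kk, a] * step[kk]
                step[a] = s / L[a, a]
            stepmax = 0.0
            bmax = 0.0
            for j in range(d):
                beta[j] += step[j]
                if abs(step[j]) > stepmax:
                    stepmax = abs(step[j])
                if abs(beta[j]) > bmax:
                    bmax = abs(beta[j])
            if stepmax < 1e-3 or bmax > 1e3:
                break
        for i in range(n):
            if not complete[i] or fold_ids[i] != f:
                continue
            e = beta[0]
            for j in range(g):
                e += beta[j + 1] * Xt[j, i]
            pred = 1.0 if e > 0.0 else 0.0
            if threshold != 0.5:
                prob = 1.0 / (1.0 + np.exp(-e))
                pred = 1.0 if prob > threshold else 0.0
            if pred == y[i]:
                correct += 1
            total += 1
    if total == 0:
        return 0.0
    return correct / total


@dataclass(frozen=True)
class ChromosomeModel:
    """One GA solution: a fixed-size feature subset and its CV accuracy."""

    genes: tuple[str, ...]
    fitness: float
    run_index: int = 0
    generations_run: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome genes must be distinct")
        if not 0.0 <= self.fitness <= 1.0:
            raise ValueError("fitness must lie in [0, 1]")


@dataclass
class FrequencyTable:
    """Per-feature appearance counts across the runs' final chromosomes."""

    counts: pd.Series          # feature -> count, descending
    mean_fitness: pd.Series    # feature -> mean fitness of its models
    n_models: int
    chromosome_size: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.counts,
                             "mean_fitness": self.mean_fitness}
                            ).rename_axis("feature")


class _FitnessCache:
    """Memoizes chromosome -> fitness within one GA run."""

    def __init__(self, X: np.ndarray, y: np.ndarray, fold_ids: np.ndarray,
                 k: int, threshold: float):
        self.XT = np.ascontiguousarray(X.T)  # (features, subjects)
        self.y = y
        self.fold_ids = fold_ids
        self.k = k
        self.threshold = threshold
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, genes: tuple[int, ...]) -> float:
        hit = self._cache.get(genes)
        if hit is not None:
            return hit
        fit = float(cv_accuracy_kernel(
            self.XT[genes, :], self.y, self.fold_ids,
            self.k, self.threshold))
        self._cache[genes] = fit
        return fit


def _tournament(rng, fits: list[float], size: int) -> int:
    best = -1
    best_fit = -1.0
    for _ in range(size):
        i = int(rng.integers(len(fits)))
        if fits[i] > best_fit:
            best_fit = fits[i]
            best = i
    return best


def _offspring(rng, p1, p2, n_features: int, mutation_rate: float):
    """Uniform crossover + repair to distinct genes + per-gene mutation."""
    size = len(p1)
    child = []
    used = set()
    for a, b in zip(p1, p2):
        g = a if rng.random() < 0.5 else b
        if g in used:
            continue
        used.add(g)
        child.append(g)
    while len(child) < size:  # repair duplicates with random unused genes
        g = int(rng.integers(n_features))
        if g not in used:
            used.add(g)
            child.append(g)
    for i in range(size):  # mutation
        if rng.random() < mutation_rate:
            g = int(rng.integers(n_features))
            if g not in used:
                used.discard(child[i])
                used.add(g)
                child[i] = g
    return tuple(sorted(child))


def _ga_arrays(table: FeatureTable, spec: AnalysisSpec
               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = table.feature_names
    X = table.values.to_numpy(dtype=np.float64)
    y = table.binary_labels(spec).to_numpy(dtype=np.float64)
    return np.ascontiguousarray(X), y, names


def _stratified_fold_ids(y: np.ndarray, k: int, rng) -> np.ndarray:
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % k
    return fold


def evolve_one(table: FeatureTable, spec: AnalysisSpec, run_seed: int,
               run_index: int = 0,
               track_best: list | None = None) -> ChromosomeModel:
    """One independent GA run; returns the best final chromosome.

    Deterministic in ``run_seed``: population initialisation, CV fold
    assignment, selection, crossover and mutation all draw from one
    generator seeded with it.  With elitism the best fitness is
    non-decreasing across generations (pass ``track_best`` to record the
    per-generation best).
    """
    X, y, names = _ga_arrays(table, spec)
    size = spec.model_chromosome_size
    if len(names) < size:
        raise ValueError("fewer features than the chromosome size")
    rng = np.random.default_rng(run_seed)
    fold_ids = _stratified_fold_ids(y, spec.k_folds, rng)
    fitness = _FitnessCache(X, y, fold_ids, spec.k_folds,
                            spec.classification_threshold)
    pop = [tuple(sorted(rng.choice(len(names), size=size, replace=False)))
           for _ in range(spec.ga_population)]
    fits = [fitness(c) for c in pop]
    for _gen in range(spec.ga_generations):
        elite_order = np.argsort(fits)[::-1]
        new_pop = [pop[i] for i in elite_order[: spec.ga_elite]]
        while len(new_pop) < spec.ga_population:
            i = _tournament(rng, fits, spec.ga_tournament_size)
            j = _tournament(rng, fits, spec.ga_tournament_size)
            new_pop.append(_offspring(rng, pop[i], pop[j], len(names),
                                      spec.ga_mutation_rate))
        pop = new_pop
        fits = [fitness(c) for c in pop]
        if track_best is not None:
            track_best.append(max(fits))
    best = int(np.argmax(fits))
    genes = tuple(names[g] for g in pop[best])
    return ChromosomeModel(genes=genes, fitness=float(fits[best]),
                           run_index=run_index,
                           generations_run=spec.ga_generations)


def tally_frequencies(models: list[ChromosomeModel],
                      spec: AnalysisSpec) -> FrequencyTable:
    counts: dict[str, int] = {}
    fit_sum: dict[str, float] = {}
    for m in models:
        for g in m.genes:
            counts[g] = counts.get(g, 0) + 1
            fit_sum[g] = fit_sum.get(g, 0.0) + m.fitness
    c = pd.Series(counts, dtype=int).sort_values(ascending=False)
    mf = pd.Series({f: fit_sum[f] / counts[f] for f in counts})
    return FrequencyTable(counts=c, mean_fitness=mf.loc[c.index],
                          n_models=len(models),
                          chromosome_size=spec.model_chromosome_size)


def search(table: FeatureTable, spec: AnalysisSpec,
           progress: bool = False
           ) -> tuple[list[ChromosomeModel], FrequencyTable]:
    """Run ``spec.n_ga_models`` independent GA runs and tally frequencies.

    Run r is seeded ``rng_seed + r`` (r = 1..n).  Individual run failures
    are tolerated and logged; the batch aborts if more than 10% of runs
    fail.  The returned counts satisfy the conservation law
    sum(counts) = n_successful_runs * chromosome_size.
    """
    models: list[ChromosomeModel] = []
    failures: list[tuple[int, str]] = []
    for r in range(1, spec.n_ga_models + 1):
        try:
            models.append(evolve_one(table, spec, (spec.rng_seed + r) % 2**31,
                                     run_index=r))
        except Exception as exc:  # noqa: BLE001 - per-run isolation
            failures.append((r, str(exc)))
            if len(failures) > 0.10 * spec.n_ga_models:
                raise RuntimeError(
                    f"more than 10% of GA runs failed; first failures: "
                    f"{failures[:3]}") from exc
        if progress and r % 50 == 0:
            print(f"  GA run {r}/{spec.n_ga_models}")
    return models, tally_frequencies(models, spec)
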