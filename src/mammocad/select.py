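"""Simulated-annealing wrapper feature selection with a dynamic subset size.

The selector searches for a compact, discriminative feature subset by
annealing over the *number* of retained features rather than over arbitrary
index sets: features are ranked once per training partition by Fisher score,
a candidate solution is the top-``nf`` prefix of that ranking, and the
annealer perturbs ``nf`` by small steps (±1, ±2), clamped to
[``nf_min``, ``nf_max``].  Each candidate is scored by the composite cost

    cost = (1 - Acc) + beta * nf / D

where Acc is the seeded stratified 5-fold cross-validated accuracy of an
RBF-SVM restricted to the candidate columns, D is the total feature count,
and beta trades accuracy against subset size.  Worse candidates are accepted
with the Metropolis probability exp(-delta/T) under a geometric cooling
schedule, which lets the search escape local cost plateaus.

A classic fixed-size annealer (:func:`run_classic_sa`) is included as the
baseline: the subset size stays constant and moves swap one selected feature
for one unselected feature, so the penalty term is constant and the search
is accuracy-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable


@dataclass(frozen=True)
class ISAConfig:
    """Annealer parameters (defaults are the study's operating point)."""

    t0: float = 4.0
    alpha: float = 0.9
    max_iter: int = 40
    sub_iter: int = 10
    beta: float = 0.01
    nf_min: int = 10
    nf_max: int = 40
    seed: int = 0
    neighbor_deltas: tuple[int, ...] = (-2, -1, 1, 2)
    move_mode: str = "rank_truncation"  # or "rank_truncation_plus_swap"
    cv_folds: int = 5
    svm_c: float = 10.0
    svm_gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if not 1 <= self.nf_min <= self.nf_max:
            raise ValueError("need 1 <= nf_min <= nf_max")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.move_mode not in ("rank_truncation", "rank_truncation_plus_swap"):
            raise ValueError(f"unknown move_mode {self.move_mode!r}")


@dataclass(frozen=True)
class FeatureRanking:
    """Feature indices ordered best-first, with their (non-increasing) scores."""

    order: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of 0..D-1")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing along the ranking")


@dataclass(frozen=True)
class FeatureSubset:
    """An index set of selected features (stored sorted for stable hashing)."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(set(self.indices))))
        if not self.indices:
            raise ValueError("subset must be non-empty")

    @property
    def nf(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class FitnessValue:
    cost: float
    accuracy: float
    penalty: float


@dataclass
class ISAResult:
    """Best subset found, its fitness, and the per-move trace."""

    subset: FeatureSubset
    fitness: FitnessValue
    trace: list[dict] = field(default_factory=list)
    ranking: Optional[FeatureRanking] = None


def fitness_cost(accuracy: float, nf: int, n_features: int, beta: float) -> FitnessValue:
    """The composite cost (1 - Acc) + beta * nf / D."""
    penalty = beta * nf / n_features
    return FitnessValue((1.0 - accuracy) + penalty, accuracy, penalty)


def rank_features(table: FeatureTable, eps: float = 1e-12) -> FeatureRanking:
    """Rank features by Fisher score (mu1-mu0)^2 / (s1^2 + s0^2 + eps).

    Features are z-scored from the table's own statistics before scoring
    (the score is affine-invariant, so this only regularizes the eps guard);
    ties break toward the lower feature index.
    """
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking requires both classes present")
    if min(np.bincount(labels)) < 2:
        raise ValueError("ranking requires >= 2 samples per class")
    x = StandardScaler().fit_transform(table.values)
    x0, x1 = x[labels == 0], x[labels == 1]
    score = (x1.mean(axis=0) - x0.mean(axis=0)) ** 2 / (
        x1.var(axis=0, ddof=0) + x0.var(axis=0, ddof=0) + eps
    )
    order = np.lexsort((np.arange(len(score)), -score))
    return FeatureRanking(tuple(int(i) for i in order), tuple(float(score[i]) for i in order))


def subset_from_ranking(ranking: FeatureRanking, nf: int) -> FeatureSubset:
    """The top-``nf`` prefix of a ranking, as an index set."""
    if not 1 <= nf <= len(ranking.order):
        raise ValueError(f"nf must be in [1, {len(ranking.order)}]")
    return FeatureSubset(ranking.order[:nf])


def evaluate_fitness(
    subset: FeatureSubset,
    table: FeatureTable,
    config: ISAConfig,
    eval_seed: int,
    cache: Optional[dict] = None,
) -> FitnessValue:
    """Composite cost of a subset under seeded stratified k-fold CV accuracy.

    Standardization is fitted on each training fold only.  The same
    (subset, seed) pair always yields the same value, so results are
    memoizable via ``cache``.
    """
    key = (subset.indices, eval_seed)
    if cache is not None and key in cache:
        return cache[key]
    x = table.values[:, list(subset.indices)]
    y = table.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError("each class needs >= cv_folds samples for fitness CV")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=eval_seed)
    accuracies = []
    for train_idx, test_idx in skf.split(x, y):
        scaler = StandardScaler().fit(x[train_idx])
        clf = SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma)
        clf.fit(scaler.transform(x[train_idx]), y[train_idx])
        accuracies.append(clf.score(scaler.transform(x[test_idx]), y[test_idx]))
    value = fitness_cost(float(np.mean(accuracies)), subset.nf, table.n_features, config.beta)
    if cache is not None:
        cache[key] = value
    return value


def propose_neighbor(
    current: FeatureSubset,
    ranking: FeatureRanking,
    config: ISAConfig,
    rng: np.random.Generator,
) -> FeatureSubset:
    """Perturb the subset length by a random delta, clamped to the nf bounds.

    In ``rank_truncation`` mode the candidate is the new-length ranking
    prefix; ``rank_truncation_plus_swap`` additionally swaps one selected
    index for an unselected one with probability 1/2.
    """
    delta = int(rng.choice(config.neighbor_deltas))
    nf_new = int(np.clip(current.nf + delta, config.nf_min, config.nf_max))
    candidate = subset_from_ranking(ranking, nf_new)
    if config.move_mode == "rank_truncation_plus_swap" and rng.random() < 0.5:
        selected = list(candidate.indices)
        unselected = [i for i in range(len(ranking.order)) if i not in candidate.indices]
        if unselected:
            out_pos = int(rng.integers(len(selected)))
            in_idx = unselected[int(rng.integers(len(unselected)))]
            selected[out_pos] = in_idx
            candidate = FeatureSubset(tuple(selected))
    return candidate


def metropolis_accept(
    delta_cost: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept improvements always; otherwise with probability exp(-delta/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_cost <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_cost / temperature))


FitnessFn = Callable[[FeatureSubset], FitnessValue]


def _anneal(
    initial: FeatureSubset,
    propose: Callable[[FeatureSubset, np.random.Generator], FeatureSubset],
    fitness: FitnessFn,
    config: ISAConfig,
    rng: np.random.Generator,
    reinitialize: Optional[Callable[[np.random.Generator], FeatureSubset]] = None,
) -> tuple[FeatureSubset, FitnessValue, list[dict]]:
    current, current_fit = initial, fitness(initial)
    best, best_fit = current, current_fit
    temperature = config.t0
    trace = [
        dict(iteration=0, move=0, temperature=temperature, nf=current.nf,
             cost=current_fit.cost, accuracy=current_fit.accuracy,
             accepted=True, best_cost=best_fit.cost)
    ]
    for iteration in range(1, config.max_iter + 1):
        if reinitialize is not None and iteration > 1:
            # dynamic-length variant: every temperature level starts from a
            # freshly drawn subset length before exploring its neighborhood
            current = reinitialize(rng)
            current_fit = fitness(current)
            if current_fit.cost < best_fit.cost:
                best, best_fit = current, current_fit
            trace.append(
                dict(iteration=iteration, move=0, temperature=temperature,
                     nf=current.nf, cost=current_fit.cost,
                     accuracy=current_fit.accuracy, accepted=True,
                     best_cost=best_fit.cost)
            )
        for move in range(1, config.sub_iter + 1):
            candidate = propose(current, rng)
            cand_fit = fitness(candidate)
            accepted = metropolis_accept(
                cand_fit.cost - current_fit.cost, temperature, rng
            )
            if accepted:
                current, current_fit = candidate, cand_fit
            if cand_fit.cost < best_fit.cost:
                best, best_fit = candidate, cand_fit
            trace.append(
                dict(iteration=iteration, move=move, temperature=temperature,
                     nf=candidate.nf, cost=cand_fit.cost,
                     accuracy=cand_fit.accuracy, accepted=accepted,
                     best_cost=best_fit.cost)
            )
        temperature *= config.alpha
    return best, best_fit, trace


def run_isa(
    table: FeatureTable,
    config: ISAConfig = ISAConfig(),
    fitness_fn: Optional[FitnessFn] = None,
    ranking: Optional[FeatureRanking] = None,
) -> ISAResult:
    """Dynamic-length annealing selection over rank-truncation subsets.

    Each outer temperature level opens with a subset length drawn uniformly
    from [nf_min, nf_max] (a restart that keeps the search global) and then
    explores its neighborhood for ``sub_iter`` Metropolis moves; every
    returned subset honors the length bounds.  ``fitness_fn`` may replace
    the CV-accuracy objective (used for oracle/stub evaluations); the
    default is the memoized composite-cost evaluation seeded by
    ``config.seed``.
    """
    if table.n_features < config.nf_min:
        raise ValueError("table has fewer features than nf_min")
    nf_max = min(config.nf_max, table.n_features)
    config = replace(config, nf_max=nf_max)
    rng = np.random.default_rng(config.seed)
    if ranking is None:
        ranking = rank_features(table)
    if fitness_fn is None:
        cache: dict = {}
        fitness_fn = lambda s: evaluate_fitness(s, table, config, config.seed, cache)
    def draw_uniform(r: np.random.Generator) -> FeatureSubset:
        return subset_from_ranking(
            ranking, int(r.integers(config.nf_min, config.nf_max + 1))
        )

    propose = lambda cur, r: propose_neighbor(cur, ranking, config, r)
    best, best_fit, trace = _anneal(
        draw_uniform(rng), propose, fitness_fn, config, rng, reinitialize=draw_uniform
    )
    return ISAResult(best, best_fit, trace, ranking)


def run_classic_sa(
    table: FeatureTable,
    nf_fixed: int,
    config: ISAConfig = ISAConfig(),
    fitness_fn: Optional[FitnessFn] = None,
) -> ISAResult:
    """Fixed-size annealing baseline: single-feature swap moves.

    The subset size never changes, so the beta * nf / D penalty is constant
    and the search is effectively accuracy-driven.  Initialized from the
    top-``nf_fixed`` Fisher prefix.
    """
    d = table.n_features
    if not 1 <= nf_fixed <= d:
        raise ValueError(f"nf_fixed must be in [1, {d}]")
    rng = np.random.default_rng(config.seed)
    ranking = rank_features(table)
    if fitness_fn is None:
        cache: dict = {}
        fitness_fn = lambda s: evaluate_fitness(s, table, config, config.seed, cache)

    def propose(current: FeatureSubset, r: np.random.Generator) -> FeatureSubset:
        selected = list(current.indices)
        unselected = [i for i in range(d) if i not in current.indices]
        if not unselected:
            return current
        out_pos = int(r.integers(len(selected)))
        selected[out_pos] = unselected[int(r.integers(len(unselected)))]
        return FeatureSubset(tuple(selected))

    initial = subset_from_ranking(ranking, nf_fixed)
    best, best_fit, trace = _anneal(initial, propose, fitness_fn, config, rng)
    return ISAResult(best, best_fit, trace, ranking)


def brute_force_rank_truncation(
    table: FeatureTable,
    config: ISAConfig,
    ranking: Optional[FeatureRanking] = None,
    fitness_fn: Optional[FitnessFn] = None,
) -> tuple[FeatureSubset, FitnessValue]:
    """Exhaustive scan over every prefix length in [nf_min, nf_max].

    The rank-truncation search space is one-dimensional and small, so the
    exact optimum is cheap to compute; it serves as the independent oracle
    for the annealer.
    """
    if ranking is None:
        ranking = rank_features(table)
    if fitness_fn is None:
        cache: dict = {}
        fitness_fn = lambda s: evaluate_fitness(s, table, config, config.seed, cache)
    nf_max = min(config.nf_max, table.n_features)
    best: tuple[FeatureSubset, FitnessValue] | None = None
    for nf in range(config.nf_min, nf_max + 1):
        subset = subset_from_ranking(ranking, nf)
        fit = fitness_fn(subset)
        if best is None or fit.cost < best[1].cost:
            best = (subset, fit)
    assert best is not None
    return best
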