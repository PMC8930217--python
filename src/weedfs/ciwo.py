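"""Chaotic invasive weed optimization (CIWO) for binary feature selection.

Invasive weed optimization is a population metaheuristic: candidate
solutions ("weeds") spawn offspring ("seeds") in proportion to their fitness
rank, each offspring dispersed around its parent by a Gaussian whose SD
decays nonlinearly over iterations, and competitive exclusion caps the
population once it exceeds ``p_max``. The chaotic variant diversifies the
initial population with a logistic-map sequence x_{k+1} = u x_k (1 - x_k),
which at u = 4 is chaotic and ergodic on (0, 1).

A weed's continuous position in [0, 1]^N encodes a gene subset by
thresholding (position >= threshold selects the gene). Fitness scalarises
the wrapper objective

    fitness = alpha * error + beta * |Y| / |T|

where ``error`` is the stratified cross-validated misclassification rate of
an inner classifier restricted to the selected genes Y, and |Y|/|T| is the
selected-to-total feature ratio. Lower is better. The empty subset is given
the worst-case error 1.0 so the search space stays closed.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .matrix import ExpressionMatrix

CHAOS_FIXED_POINTS = (0.25, 0.5, 0.75)


@dataclasses.dataclass
class CIWOParams:
    """Control constants of the weed colony.

    Defaults follow the orders of magnitude customary in the invasive-weed
    literature and finish at desk scale.
    """

    n_weed: int = 10
    s_min: int = 0
    s_max: int = 5
    sigma_initial: float = 0.5
    sigma_final: float = 0.01
    modulation_n: float = 3.0
    max_iter: int = 50
    p_max: int = 30
    u: float = 4.0
    x0: float = 0.7
    binarize_threshold: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.s_min <= self.s_max):
            raise ValueError("require 0 <= s_min <= s_max")
        if not (0 < self.sigma_final <= self.sigma_initial):
            raise ValueError("require 0 < sigma_final <= sigma_initial")
        if not (self.p_max >= self.n_weed >= 2):
            raise ValueError("require p_max >= n_weed >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not (0 < self.u <= 4):
            raise ValueError("u must lie in (0, 4]")
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must lie in (0, 1)")
        _check_x0(self.x0)


@dataclasses.dataclass
class FitnessConfig:
    """Weights and inner-classifier settings of the wrapper fitness."""

    alpha: float = 0.99
    beta: float = 0.01
    inner_classifier: str = "centroid"  # or "dnn"
    cv_folds: int = 5
    cv_seed: int = 0
    cv_repeats: int = 1
    dnn_hidden: tuple[int, int] = (8, 4)
    dnn_epochs: int = 50

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.inner_classifier not in ("centroid", "dnn"):
            raise ValueError("inner_classifier must be 'centroid' or 'dnn'")


@dataclasses.dataclass
class Weed:
    position: np.ndarray  # in [0,1]^N
    mask: np.ndarray  # bool, mask[i] <=> position[i] >= threshold
    fitness: float | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class HistoryRow:
    iteration: int
    best_fitness: float
    mean_fitness: float
    population_size: int
    sigma: float


@dataclasses.dataclass
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    history: list[HistoryRow]
    evaluations: int

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_mask)


# ---------------------------------------------------------------------------
# chaos
# ---------------------------------------------------------------------------

def _check_x0(x0: float) -> None:
    if not (0.0 < x0 < 1.0):
        raise ValueError("x0 must lie in the open interval (0, 1)")
    if x0 in CHAOS_FIXED_POINTS:
        raise ValueError(
            "x0 must avoid {0.25, 0.5, 0.75}: these hit fixed points/short "
            "cycles of the logistic map at u=4 and kill the chaotic orbit"
        )


def logistic_map(x0: float, u: float = 4.0, length: int = 1, *, _unsafe: bool = False) -> np.ndarray:
    """Iterate x_{k+1} = u x_k (1 - x_k); returns the length-``length`` orbit.

    The orbit starts at ``x0`` (included). ``_unsafe`` bypasses the x0 guard
    (used only to demonstrate the degenerate fixed points).
    """
    if not _unsafe:
        _check_x0(x0)
    if not (0 < u <= 4):
        raise ValueError("u must lie in (0, 4]")
    if length < 1:
        raise ValueError("length must be >= 1")
    out = np.empty(length)
    x = float(x0)
    for k in range(length):
        out[k] = x
        x = u * x * (1.0 - x)
        # guard against round-off ejecting the orbit from [0, 1]
        x = min(max(x, 0.0), 1.0)
    return out


def init_chaotic_population(
    n_weed: int, n_features: int, params: CIWOParams
) -> list[Weed]:
    """Seed the colony: uniform base positions modulated by a logistic orbit.

    Each of the ``n_weed * n_features`` uniform draws is multiplied by the
    next value of the chaotic sequence and clipped to [0, 1]; masks follow by
    thresholding. Deterministic given ``rng_seed`` and ``x0``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    base = rng.uniform(size=(n_weed, n_features))
    chaos = logistic_map(params.x0, params.u, n_weed * n_features).reshape(
        n_weed, n_features
    )
    positions = np.clip(chaos * base, 0.0, 1.0)
    return [
        Weed(position=p, mask=p >= params.binarize_threshold) for p in positions
    ]


# ---------------------------------------------------------------------------
# reproduction schedule
# ---------------------------------------------------------------------------

def seeds_for_rank(rank: int, n_weed: int, s_min: int, s_max: int) -> int:
    """Seed count for a weed of the given fitness rank (1 = best).

    Round(s_min + (s_max - s_min) * (n_weed - rank) / (n_weed - 1)) with
    half-up rounding, so rank 1 gets s_max and rank n_weed gets s_min.
    """
    if n_weed < 2:
        raise ValueError("seed schedule undefined for n_weed < 2 (caller should use s_max)")
    if not (1 <= rank <= n_weed):
        raise ValueError("rank must lie in [1, n_weed]")
    x = s_min + (s_max - s_min) * (n_weed - rank) / (n_weed - 1)
    return int(math.floor(x + 0.5))


def dispersal_sd(iteration: int, params: CIWOParams) -> float:
    """Nonlinearly decaying dispersal SD for the given iteration.

    ((max_iter - iter) / max_iter)^n * (sigma_initial - sigma_final)
    + sigma_final; equals sigma_initial at iteration 0 and sigma_final at
    max_iter.
    """
    if not (0 <= iteration <= params.max_iter):
        raise ValueError("iteration must lie in [0, max_iter]")
    if params.max_iter == 0:
        return params.sigma_final
    frac = (params.max_iter - iteration) / params.max_iter
    return frac ** params.modulation_n * (
        params.sigma_initial - params.sigma_final
    ) + params.sigma_final


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Callable wrapper fitness over a fixed dataset and CV fold assignment.

    Folds are built once (stratified, seeded) so every mask is scored against
    the identical partition: fitness is a deterministic function of the mask.
    The instance counts evaluations.
    """

    def __init__(self, X: ExpressionMatrix, cfg: FitnessConfig | None = None):
        self.cfg = cfg or FitnessConfig()
        self.cfg.validate()
        if X.labels is None:
            raise ValueError("fitness evaluation requires labeled samples")
        if X.missing_mask.any():
            raise ValueError("fitness evaluation requires a complete (imputed) matrix")
        self._X = X.sample_matrix()  # samples x genes
        self._y = X.label_codes()
        self.n_features = X.n_genes
        counts = np.bincount(self._y)
        folds = min(self.cfg.cv_folds, counts.min())
        if folds < 2:
            raise ValueError("each class needs at least 2 samples for CV")
        # fixed fold assignment(s) so fitness is a deterministic function of
        # the mask; cv_repeats > 1 averages over several seeded partitions
        self._folds = []
        for r in range(self.cfg.cv_repeats):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=self.cfg.cv_seed + r
            )
            self._folds.extend(skf.split(self._X, self._y))
        self._n_predictions = len(self._y) * self.cfg.cv_repeats
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError(
                f"mask length {mask.size} != feature count {self.n_features}"
            )
        self.evaluations += 1
        n_sel = int(mask.sum())
        if n_sel == 0:
            error = 1.0  # empty-subset convention: total misclassification
        else:
            error = self._cv_error(mask)
        return self.cfg.alpha * error + self.cfg.beta * n_sel / self.n_features

    # nearest-centroid CV, vectorised; ties go to class 0
    def _cv_error(self, mask: np.ndarray) -> float:
        Xs = self._X[:, mask]
        y = self._y
        if self.cfg.inner_classifier == "dnn":
            return self._cv_error_dnn(Xs)
        wrong = 0
        for train, test in self._folds:
            Xtr, ytr = Xs[train], y[train]
            c0 = Xtr[ytr == 0].mean(axis=0)
            c1 = Xtr[ytr == 1].mean(axis=0)
            Xte = Xs[test]
            d0 = ((Xte - c0) ** 2).sum(axis=1)
            d1 = ((Xte - c1) ** 2).sum(axis=1)
            pred = (d1 < d0).astype(int)
            wrong += int((pred != y[test]).sum())
        return wrong / self._n_predictions

    def _cv_error_dnn(self, Xs: np.ndarray) -> float:
        from . import dnn

        wrong = 0
        for train, test in self._folds:
            spec = dnn.NetworkSpec(
                layer_sizes=(Xs.shape[1], *self.cfg.dnn_hidden, 2),
                init_seed=self.cfg.cv_seed,
            )
            opts = dnn.TrainingOptions(
                epochs=self.cfg.dnn_epochs,
                batch_size=min(16, len(train)),
                shuffle_seed=self.cfg.cv_seed,
                record_history=False,
            )
            params, _ = dnn.train(spec, Xs[train], self._y[train], opts)
            pred, _ = dnn.predict(params, Xs[test])
            wrong += int((pred != self._y[test]).sum())
        return wrong / self._n_predictions


def evaluate_fitness(
    mask: np.ndarray, X: ExpressionMatrix, cfg: FitnessConfig | None = None
) -> float:
    """One-shot wrapper fitness of a gene mask on a labeled matrix."""
    return FitnessEvaluator(X, cfg)(mask)


# ---------------------------------------------------------------------------
# colony dynamics
# ---------------------------------------------------------------------------

def _sort_key(indexed_weed: tuple[int, Weed]) -> tuple[float, int, int]:
    i, w = indexed_weed
    return (w.fitness, w.n_selected, i)


def _ranked(pop: list[Weed]) -> list[Weed]:
    """Ascending fitness; ties broken by fewer selected features, then
    insertion order."""
    return [w for _, w in sorted(enumerate(pop), key=_sort_key)]


def reproduce(
    pop: list[Weed],
    iteration: int,
    params: CIWOParams,
    evaluate: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> list[Weed]:
    """Spawn rank-proportional offspring around each weed; returns parents
    plus evaluated offspring."""
    if not pop:
        raise ValueError("population is empty")
    if any(w.fitness is None for w in pop):
        raise ValueError("all parent fitnesses must be evaluated before reproduction")
    sigma = dispersal_sd(iteration, params)
    ranked = _ranked(pop)
    n = len(ranked)
    offspring: list[Weed] = []
    for rank, parent in enumerate(ranked, start=1):
        k = params.s_max if n == 1 else seeds_for_rank(rank, n, params.s_min, params.s_max)
        for _ in range(k):
            pos = np.clip(
                parent.position + rng.normal(0.0, sigma, size=parent.position.shape),
                0.0,
                1.0,
            )
            child = Weed(position=pos, mask=pos >= params.binarize_threshold)
            child.fitness = evaluate(child.mask)
            offspring.append(child)
    return list(pop) + offspring


def exclude_weakest(pop: list[Weed], p_max: int) -> list[Weed]:
    """Competitive exclusion: keep the ``p_max`` fittest weeds (ties: fewer
    selected features, then insertion order). The best weed always survives."""
    if any(w.fitness is None for w in pop):
        raise ValueError("all fitnesses must be evaluated before exclusion")
    if len(pop) <= p_max:
        return list(pop)
    return _ranked(pop)[:p_max]


def run_ciwo(
    X: ExpressionMatrix,
    params: CIWOParams | None = None,
    cfg: FitnessConfig | None = None,
) -> SelectionResult:
    """Full CIWO search over gene subsets of a preprocessed labeled matrix.

    Initialises a chaotic population, then iterates reproduction +
    competitive exclusion for ``max_iter`` iterations, tracking the best-ever
    weed. Fully deterministic given ``params.rng_seed``, ``params.x0`` and
    ``cfg.cv_seed``.
    """
    params = params or CIWOParams()
    cfg = cfg or FitnessConfig()
    params.validate()
    evaluator = FitnessEvaluator(X, cfg)
    rng = np.random.default_rng(params.rng_seed + 1)

    pop = init_chaotic_population(params.n_weed, evaluator.n_features, params)
    for w in pop:
        w.fitness = evaluator(w.mask)
    best = _ranked(pop)[0]
    history = [
        HistoryRow(
            iteration=0,
            best_fitness=best.fitness,
            mean_fitness=float(np.mean([w.fitness for w in pop])),
            population_size=len(pop),
            sigma=dispersal_sd(0, params),
        )
    ]
    for it in range(1, params.max_iter + 1):
        pop = reproduce(pop, it, params, evaluator, rng)
        pop = exclude_weakest(pop, params.p_max)
        cand = _ranked(pop)[0]
        if (cand.fitness, cand.n_selected) < (best.fitness, best.n_selected):
            best = cand
        history.append(
            HistoryRow(
                iteration=it,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean([w.fitness for w in pop])),
                population_size=len(pop),
                sigma=dispersal_sd(it, params),
            )
        )
    return SelectionResult(
        best_mask=best.mask.copy(),
        best_fitness=float(best.fitness),
        history=history,
        evaluations=evaluator.evaluations,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_best_subset(
    X: ExpressionMatrix, cfg: FitnessConfig | None = None, max_features: int = 16
) -> tuple[np.ndarray, float]:
    """Exhaustively score every subset (feature count <= 16) and return the
    argmin mask and fitness, with the same tie-break as competitive
    exclusion (fitness, then subset size, then enumeration order)."""
    n = X.n_genes
    if n > max_features:
        raise ValueError(
            f"refusing exhaustive search over 2^{n} subsets (limit {max_features} features)"
        )
    evaluator = FitnessEvaluator(X, cfg)
    best_mask: np.ndarray | None = None
    best_key: tuple[float, int, int] | None = None
    for code in range(2 ** n):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        f = evaluator(mask)
        key = (f, int(mask.sum()), code)
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
    return best_mask, float(best_key[0])
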