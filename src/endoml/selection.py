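"""Hybrid whale-optimization / Harris-hawks wrapper feature selection.

Agents are continuous position vectors in [0, 1]^D; a sigmoid transfer
plus 0.5 cut turns a position into a binary column mask, and the
fitness of a mask is the holdout error rate of an extreme learning
machine trained on the masked columns (ties at equal error go to the
smaller subset).

The whale phase alternates three moves per agent and iteration:

* spiral:    Y <- |Y* - Y| * e^(a l) cos(2 pi l) + Y*
* encircle:  Y <- Y* - W |U Y* - Y|          (|W| < 1, exploitation)
* search:    Y <- Yr - W |U Yr - Y|          (|W| >= 1, random agent Yr)

with W = 2 c d - c, U = 2 d, and c declining linearly from 2 to 0 over
the iterations. The spiral-vs-encircle choice compares a uniform draw
P against the *median* of the agent's own position values rather than
a fixed 0.5. The Harris-hawks refinement phase then runs the
two-branch perch exploration

* Q >= mean:  Y <- Yrand - d1 |Yrand - 2 d2 Y|
* Q <  mean:  Y <- (Yrabbit - Ymean) - d3 (lb + d4 (ub - lb))

where the branch cut is the mean of the agent's position values, on
the column subset the whale phase selected. The best mask is retained
elitistically throughout, so the best-fitness history is monotone
non-increasing and the refinement can never return a worse mask than
its start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .elm import ELMClassifier

__all__ = [
    "SelectionConfig",
    "coefficient_c",
    "compute_md",
    "binarize_position",
    "fitness",
    "woa_update",
    "hho_step",
    "hho_refine",
    "hybrid_select",
    "HybridWOAHHOSelector",
    "SwarmState",
]

SPIRAL_A = 1.0  # logarithmic-spiral shape constant


@dataclass
class SelectionConfig:
    """Knobs of the hybrid search; defaults follow the study settings."""

    population: int = 10
    iterations: int = 200          # whale-phase iteration budget V
    hho_iterations: int = 50       # hawk-refinement budget
    transfer: str = "sigmoid"
    median_source: str = "agent"   # "agent" | "population_fitness"
    fitness_hidden: int = 100
    fitness_ridge: float = 1e-6
    fitness_folds: int = 4         # 1 = single seeded holdout
    val_fraction: float = 0.3      # holdout size when fitness_folds == 1
    hho_on_submatrix: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.median_source not in ("agent", "population_fitness"):
            raise ValueError("bad median_source")


def coefficient_c(v: int, V: int) -> float:
    """Convergence coefficient c = 2 - 2 v / V, linear from 2 to 0."""
    if V <= 0:
        raise ValueError("V must be positive")
    if not 0 <= v <= V:
        raise ValueError("iteration index outside [0, V]")
    return 2.0 - 2.0 * v / V


def compute_md(values) -> float:
    """Median: middle order statistic, or mean of the two middles."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    srt = np.sort(arr)
    n = arr.size
    if n % 2 == 1:
        return float(srt[n // 2])
    return float(0.5 * (srt[n // 2 - 1] + srt[n // 2]))


def binarize_position(position: np.ndarray, transfer: str = "sigmoid") -> np.ndarray:
    """Continuous position -> boolean mask; never returns an empty mask."""
    position = np.asarray(position, dtype=float)
    if transfer == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-10.0 * (position - 0.5)))
    elif transfer == "vshape":
        s = np.abs(2.0 * position - 1.0)
    else:
        raise ValueError(f"unknown transfer {transfer!r}")
    mask = s >= 0.5
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    return mask


def fitness(mask: np.ndarray, features: np.ndarray, labels: np.ndarray,
            cfg: SelectionConfig) -> float:
    """Validation error rate of an ELM on the masked columns.

    Seeded stratified k-fold mean error by default
    (``cfg.fitness_folds``); a single seeded holdout of size
    ``cfg.val_fraction`` with ``fitness_folds=1``. The cross-validated
    estimate has per-sample resolution over the whole table, which a
    wrapper search needs to rank nearby subsets reliably.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no columns")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    x = np.asarray(features, dtype=float)[:, mask]
    if cfg.fitness_folds <= 1:
        xtr, xva, ytr, yva = train_test_split(
            x, labels, test_size=cfg.val_fraction, random_state=cfg.seed,
            stratify=labels)
        clf = ELMClassifier(hidden_units=cfg.fitness_hidden,
                            ridge=cfg.fitness_ridge,
                            random_state=cfg.seed).fit(xtr, ytr)
        return float(np.mean(clf.predict(xva) != yva))
    skf = StratifiedKFold(n_splits=cfg.fitness_folds, shuffle=True,
                          random_state=cfg.seed)
    errs = []
    for tr, va in skf.split(x, labels):
        clf = ELMClassifier(hidden_units=cfg.fitness_hidden,
                            ridge=cfg.fitness_ridge,
                            random_state=cfg.seed).fit(x[tr], labels[tr])
        errs.append(np.mean(clf.predict(x[va]) != labels[va]))
    return float(np.mean(errs))


@dataclass
class SwarmState:
    """Population positions plus the elitist best-so-far record."""

    positions: np.ndarray          # (pop, D) in [0, 1]
    fitnesses: np.ndarray          # (pop,)
    best_position: np.ndarray
    best_mask: np.ndarray
    best_fitness: float
    v: int                         # current iteration
    V: int                         # iteration budget


def _mask_key(mask: np.ndarray) -> bytes:
    return np.packbits(mask).tobytes()


class _FitnessCache:
    """Memoizes (error, count) per mask; the search revisits masks often."""

    def __init__(self, features, labels, cfg):
        self.features = features
        self.labels = labels
        self.cfg = cfg
        self._cache: dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        key = _mask_key(mask)
        if key not in self._cache:
            self._cache[key] = fitness(mask, self.features, self.labels, self.cfg)
        return self._cache[key]


def _better(err_a: float, count_a: int, err_b: float, count_b: int) -> bool:
    """Lexicographic fitness comparison: error first, subset size second."""
    return (err_a, count_a) < (err_b, count_b)


def woa_update(state: SwarmState, rng: np.random.Generator,
               fitness_fn, cfg: SelectionConfig) -> SwarmState:
    """One whale-optimization generation (in place); returns the state.

    W and U are per-dimension vectors (the equations' arrow
    quantities): W = 2 c d - c and U = 2 d' with independent uniform
    draws d, d' per dimension, so components of W carry mixed signs
    and the population does not contract uniformly. The
    exploration/exploitation branch compares mean(|W|) against 1.

    Per-agent draw order (relied on by trace tests): P; spiral branch
    draws l; otherwise the vector d for W, the vector d' for U, and -
    only in the search branch - the random-agent index.
    """
    pop, d_dim = state.positions.shape
    c = coefficient_c(state.v, state.V)
    if cfg.median_source == "population_fitness":
        md_pop = compute_md(state.fitnesses)
    new_positions = np.empty_like(state.positions)
    for i in range(pop):
        y = state.positions[i]
        p = rng.random()
        md = compute_md(y) if cfg.median_source == "agent" else md_pop
        if p >= md:  # logarithmic spiral around the best agent
            ell = rng.uniform(-1.0, 1.0)
            dist = np.abs(state.best_position - y)
            new = dist * np.exp(SPIRAL_A * ell) * np.cos(2.0 * np.pi * ell) \
                + state.best_position
        else:
            d = rng.random(d_dim)
            w = 2.0 * c * d - c
            u = 2.0 * rng.random(d_dim)
            if np.abs(w).mean() < 1.0:  # encircle the best
                dist = np.abs(u * state.best_position - y)
                new = state.best_position - w * dist
            else:  # search around a random agent
                j = int(rng.integers(pop))
                dist = np.abs(u * state.positions[j] - y)
                new = state.positions[j] - w * dist
        new_positions[i] = np.clip(new, 0.0, 1.0)
    state.positions = new_positions
    for i in range(pop):
        mask = binarize_position(state.positions[i], cfg.transfer)
        err = fitness_fn(mask)
        state.fitnesses[i] = err
        if _better(err, int(mask.sum()), state.best_fitness, int(state.best_mask.sum())):
            state.best_fitness = err
            state.best_mask = mask
            state.best_position = state.positions[i].copy()
    state.v += 1
    return state


def hho_step(position: np.ndarray, y_rand: np.ndarray, y_rabbit: np.ndarray,
             y_mean: np.ndarray, q: float, d: tuple[float, float, float, float],
             lb: float = 0.0, ub: float = 1.0) -> np.ndarray:
    """Pure single-agent Harris-hawks exploration move (both branches)."""
    position = np.asarray(position, dtype=float)
    d1, d2, d3, d4 = d
    if q >= float(np.mean(position)):
        new = y_rand - d1 * np.abs(y_rand - 2.0 * d2 * position)
    else:
        new = (y_rabbit - y_mean) - d3 * (lb + d4 * (ub - lb))
    return np.clip(new, lb, ub)


def hho_refine(features: np.ndarray, labels: np.ndarray, start_mask: np.ndarray,
               cfg: SelectionConfig, rng: np.random.Generator,
               n_iter: int | None = None) -> tuple[np.ndarray, list[float]]:
    """Hawk-exploration refinement; never worse in fitness than the start.

    By default the search runs over the columns ``start_mask`` selects
    (submatrix reading); with ``cfg.hho_on_submatrix=False`` it runs
    over all columns warm-started from the mask.
    """
    start_mask = np.asarray(start_mask, dtype=bool)
    n_iter = cfg.hho_iterations if n_iter is None else n_iter
    if cfg.hho_on_submatrix:
        columns = np.flatnonzero(start_mask)
        sub = features[:, columns]
        start_sub = np.ones(columns.size, dtype=bool)
    else:
        columns = np.arange(features.shape[1])
        sub = features
        start_sub = start_mask.copy()
    cache = _FitnessCache(sub, labels, cfg)
    best_mask = start_sub.copy()
    best_err = cache(best_mask)
    history = [best_err]
    if n_iter <= 0 or columns.size < 2:
        out = np.zeros(features.shape[1], dtype=bool)
        out[columns[best_mask]] = True
        return out, history
    pop, d_dim = cfg.population, columns.size
    positions = rng.random((pop, d_dim))
    positions[0] = start_sub.astype(float)
    errs = np.empty(pop)
    for i in range(pop):
        mask = binarize_position(positions[i], cfg.transfer)
        errs[i] = cache(mask)
        if _better(errs[i], int(mask.sum()), best_err, int(best_mask.sum())):
            best_err, best_mask = errs[i], mask
    best_pos = positions[int(np.argmin(errs))].copy()
    for _ in range(n_iter):
        y_m = positions.mean(axis=0)
        for i in range(pop):
            q = rng.random()
            j = int(rng.integers(pop))
            d = tuple(rng.random(4))
            positions[i] = hho_step(positions[i], positions[j], best_pos, y_m, q, d)
            mask = binarize_position(positions[i], cfg.transfer)
            errs[i] = cache(mask)
            if _better(errs[i], int(mask.sum()), best_err, int(best_mask.sum())):
                best_err, best_mask = errs[i], mask
                best_pos = positions[i].copy()
        history.append(best_err)
    out = np.zeros(features.shape[1], dtype=bool)
    out[columns[best_mask]] = True
    return out, history


def hybrid_select(features: np.ndarray, labels: np.ndarray,
                  cfg: SelectionConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Whale phase then hawk refinement; returns (mask, X[:, mask], history)."""
    cfg = cfg or SelectionConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] < 10 or features.shape[1] < 2:
        raise ValueError("need an N x D feature matrix with N >= 10, D >= 2")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(cfg.seed)
    cache = _FitnessCache(features, labels, cfg)
    pop, d_dim = cfg.population, features.shape[1]
    positions = rng.random((pop, d_dim))
    errs = np.empty(pop)
    best_err, best_mask, best_pos = np.inf, None, None
    for i in range(pop):
        mask = binarize_position(positions[i], cfg.transfer)
        errs[i] = cache(mask)
        if best_mask is None or _better(errs[i], int(mask.sum()), best_err,
                                        int(best_mask.sum())):
            best_err, best_mask, best_pos = errs[i], mask, positions[i].copy()
    state = SwarmState(positions=positions, fitnesses=errs,
                       best_position=best_pos, best_mask=best_mask,
                       best_fitness=best_err, v=0, V=cfg.iterations)
    history = [state.best_fitness]
    for _ in range(cfg.iterations):
        woa_update(state, rng, cache, cfg)
        history.append(state.best_fitness)
    final_mask, hho_history = hho_refine(features, labels, state.best_mask, cfg, rng)
    # a submatrix mask trains on exactly the columns the corresponding global
    # mask selects, with the same seeds, so the two fitness scales coincide
    history.extend(hho_history[1:])
    history = np.minimum.accumulate(history).tolist()
    return final_mask, features[:, final_mask], history


class HybridWOAHHOSelector(SelectorMixin, BaseEstimator):
    """sklearn-style wrapper selector around :func:`hybrid_select`."""

    def __init__(self, population=10, iterations=200, hho_iterations=50,
                 transfer="sigmoid", median_source="agent", fitness_hidden=100,
                 fitness_ridge=1.0, val_fraction=0.3, hho_on_submatrix=True,
                 random_state=0):
        self.population = population
        self.iterations = iterations
        self.hho_iterations = hho_iterations
        self.transfer = transfer
        self.median_source = median_source
        self.fitness_hidden = fitness_hidden
        self.fitness_ridge = fitness_ridge
        self.val_fraction = val_fraction
        self.hho_on_submatrix = hho_on_submatrix
        self.random_state = random_state

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            population=self.population, iterations=self.iterations,
            hho_iterations=self.hho_iterations, transfer=self.transfer,
            median_source=self.median_source, fitness_hidden=self.fitness_hidden,
            fitness_ridge=self.fitness_ridge, val_fraction=self.val_fraction,
            hho_on_submatrix=self.hho_on_submatrix, seed=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        mask, _, history = hybrid_select(X, y, self._config())
        self.support_ = mask
        self.history_ = history
        self.best_error_ = history[-1]
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
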