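"""Cost-sensitive relabeling (MetaCost) and GA wrapper feature selection.

MetaCost makes the PLS-DA classifier cost-sensitive without modifying it:
m bagged models estimate class probabilities P(j|x) for every training
point (votes averaged over the models whose resample excluded the point),
and each point is relabeled to the class minimising conditional risk
sum_j P(j|x) C(i, j). A plain PLS-DA fit on the relabeled data is then the
cost-sensitive model. The default cost matrix charges errors on a class
inversely to its size, C(i, j) = n_max / n_j for i != j, so mistakes on
the minority class (here the six-member ANBP group) weigh most.

Feature selection is a binary-chromosome genetic algorithm: tournament
selection, uniform crossover, per-bit mutation, elitism; fitness is the
stratified-CV accuracy of PLS-DA restricted to the candidate mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, MetaEstimatorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from microbiometab.plsda import PLSDAClassifier, cross_validate


def cost_from_class_sizes(labels) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-class-size cost matrix: C(i, j) = n_max / n_j off-diagonal.

    Returns ``(classes, cost)`` with the classes in sorted order; the cost
    of predicting class i when the truth is class j sits at ``cost[i, j]``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (counts == 0).any():
        raise ValueError("empty class")
    cost = np.tile(counts.max() / counts, (len(classes), 1)).astype(float)
    np.fill_diagonal(cost, 0.0)
    return classes, cost


def metacost_relabel(X, y, cost: np.ndarray | None = None, m: int = 30,
                     frac: float = 0.67, seed: int = 0,
                     n_components: int = 2, oob_only: bool = False) -> np.ndarray:
    """MetaCost relabeling of the training targets.

    Parameters follow Domingos' procedure: *m* resamples of size
    ``frac * n``, hard votes averaged into P(j|x), then conditional-risk
    relabeling under the cost matrix (computed from class sizes when not
    given). ``oob_only`` selects which of Domingos' two vote-pooling
    variants is used: votes from all models (default) or only from models
    whose resample excluded the point (with an all-models fallback). At
    cohort sizes where the minority class has only a handful of members,
    out-of-bag votes inherit the bagged models' bias against that class
    and the relabeling can erase it; the all-models variant keeps each
    point's self-information and is the stable choice there.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if m < 1:
        raise ValueError("need at least 1 bootstrap model")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    classes = np.unique(y)
    if cost is None:
        _, cost = cost_from_class_sizes(y)
    cost = np.asarray(cost, dtype=float)
    if cost.shape != (len(classes), len(classes)):
        raise ValueError("cost matrix shape mismatch")

    n = len(y)
    size = max(len(classes) + 1, int(round(frac * n)))
    rng = np.random.default_rng(seed)
    votes = np.zeros((n, len(classes)))          # out-of-bag votes
    votes_all = np.zeros((n, len(classes)))      # all-model fallback
    oob_count = np.zeros(n)
    for _ in range(m):
        if frac >= 1.0 and m == 1:
            idx = np.arange(n)  # degenerate single-model case: exact fit data
        else:
            idx = rng.choice(n, size=size, replace=True)
        if len(np.unique(y[idx])) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PLSDAClassifier(n_components=n_components).fit(X[idx], y[idx])
        pred = model.predict(X)
        pred_idx = np.searchsorted(classes, pred)
        onehot = np.zeros((n, len(classes)))
        onehot[np.arange(n), pred_idx] = 1.0
        votes_all += onehot
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        votes[oob] += onehot[oob]
        oob_count[oob] += 1
    if votes_all.sum() == 0:
        raise ValueError("no usable bootstrap model")
    if oob_only:
        proba = np.where(oob_count[:, None] > 0,
                         votes / np.maximum(oob_count[:, None], 1),
                         votes_all / votes_all.sum(axis=1, keepdims=True))
    else:
        proba = votes_all / votes_all.sum(axis=1, keepdims=True)
    risk = proba @ cost.T  # risk[x, i] = sum_j P(j|x) C(i, j)
    relabeled = classes[np.argmin(risk, axis=1)]
    if len(np.unique(relabeled)) < len(classes):
        warnings.warn("a class vanished during MetaCost relabeling")
    return relabeled


class MetaCostClassifier(ClassifierMixin, MetaEstimatorMixin, BaseEstimator):
    """Cost-sensitive PLS-DA via MetaCost relabeling.

    ``fit`` relabels the training set under the cost matrix (inverse class
    sizes by default) and fits a plain :class:`PLSDAClassifier` on the
    relabeled targets.
    """

    def __init__(self, n_components: int = 2, cost: np.ndarray | None = None,
                 m: int = 30, frac: float = 0.67, random_state: int = 0):
        self.n_components = n_components
        self.cost = cost
        self.m = m
        self.frac = frac
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.relabeled_y_ = metacost_relabel(
            X, y, cost=self.cost, m=self.m, frac=self.frac,
            seed=self.random_state, n_components=self.n_components)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.estimator_ = PLSDAClassifier(n_components=self.n_components).fit(
                X, self.relabeled_y_)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.decision_function(X)


@dataclass
class GaParams:
    """Genetic-algorithm controls for wrapper feature selection."""

    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1/p per bit
    elitism: int = 2
    tournament: int = 3
    min_features: int = 1
    max_features: int | None = None
    cv_folds: int = 5
    n_components: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if r is not None and not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class GaResult:
    mask: np.ndarray
    fitness: float
    trace: np.ndarray = field(repr=False)


def ga_select(X, y, params: GaParams | None = None) -> GaResult:
    """Binary-chromosome GA feature selection.

    Fitness is the stratified-CV accuracy of PLS-DA restricted to the
    candidate mask (empty masks score 0). Returns the best mask ever seen
    and the per-generation best-fitness trace, which elitism makes
    non-decreasing.
    """
    params = params or GaParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / p
    rng = np.random.default_rng(params.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        k = int(mask.sum())
        if k < params.min_features:
            return 0.0
        if params.max_features is not None and k > params.max_features:
            return 0.0
        key = mask.tobytes()
        if key not in cache:
            cv = cross_validate(X[:, mask], y, a_max=min(params.n_components, k),
                                folds=params.cv_folds, repeats=1,
                                seed=int(rng.integers(2 ** 31)))
            cache[key] = cv.chosen_accuracy
        return cache[key]

    pop = rng.random((params.population, p)) < 0.5
    for chrom in pop:
        if not chrom.any():
            chrom[rng.integers(p)] = True
    fits = np.array([fitness(c) for c in pop])
    best_mask = pop[np.argmax(fits)].copy()
    best_fit = fits.max()
    trace = [best_fit]

    for _ in range(params.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: params.elitism]]
        while len(new_pop) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(params.population, size=params.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < params.crossover_rate:
                swap = rng.random(p) < 0.5
                a[swap], b[swap] = parents[1][swap], parents[0][swap]
            for child in (a, b):
                flip = rng.random(p) < mut
                child[flip] = ~child[flip]
                if not child.any():
                    child[rng.integers(p)] = True
                if len(new_pop) < params.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([fitness(c) for c in pop])
        if fits.max() > best_fit:
            best_fit = fits.max()
            best_mask = pop[np.argmax(fits)].copy()
        trace.append(best_fit)

    return GaResult(best_mask, float(best_fit), np.array(trace))


class GeneticSelector(BaseEstimator):
    """sklearn-style transformer wrapping :func:`ga_select`.

    ``fit`` stores ``support_`` (the best mask) and ``trace_``;
    ``transform`` restricts X to the selected features.
    """

    def __init__(self, population: int = 50, generations: int = 100,
                 crossover_rate: float = 0.8, mutation_rate: float | None = None,
                 elitism: int = 2, tournament: int = 3, cv_folds: int = 5,
                 n_components: int = 2, random_state: int = 0):
        self.population = population
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.tournament = tournament
        self.cv_folds = cv_folds
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y):
        params = GaParams(population=self.population, generations=self.generations,
                          crossover_rate=self.crossover_rate, mutation_rate=self.mutation_rate,
                          elitism=self.elitism, tournament=self.tournament,
                          cv_folds=self.cv_folds, n_components=self.n_components,
                          seed=self.random_state)
        result = ga_select(X, y, params)
        self.support_ = result.mask
        self.best_fitness_ = result.fitness
        self.trace_ = result.trace
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X, dtype=float)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
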