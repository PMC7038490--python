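"""Flavor classification: RBF-SVM with genetic-algorithm hyperparameter search.

The penalty factor ``c`` and kernel width ``g`` of a soft-margin RBF-SVM
are searched over [2^-10, 2^10] by a real-coded genetic algorithm whose
fitness is stratified k-fold cross-validation accuracy on the training
set.  Individuals are encoded on the log2 scale (matching the search
range), evolved with tournament selection (size 2), uniform crossover,
Gaussian mutation in log2 space, and elitism of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .errors import InvalidConfigError, StratificationError

__all__ = [
    "SVMParams",
    "GAConfig",
    "GAResult",
    "GASVMClassifier",
    "cv_fitness",
    "ga_search",
    "train_predict",
]

_LOG_RANGE = (-10.0, 10.0)


@dataclass(frozen=True)
class SVMParams:
    """RBF-SVM hyperparameters: penalty factor c and kernel width g."""

    c: float
    g: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise InvalidConfigError(f"c and g must be positive, got {self}")


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 20
    max_generations: int = 200
    c_range: tuple[float, float] = (2.0**-10, 2.0**10)
    g_range: tuple[float, float] = (2.0**-10, 2.0**10)
    cv_folds: int = 5
    seed: int = 0
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.5
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise InvalidConfigError("pop_size must be >= 2")
        if self.cv_folds < 2:
            raise InvalidConfigError("cv_folds must be >= 2")
        for lo, hi in (self.c_range, self.g_range):
            if not (0 < lo < hi):
                raise InvalidConfigError("ranges must be positive and increasing")


@dataclass
class GAResult:
    best_params: SVMParams
    best_fitness: float  # CV accuracy, percent
    fitness_history: list[tuple[float, float]] = field(default_factory=list)
    # (mean, best) per generation; best is monotone under elitism


def cv_fitness(
    params: SVMParams,
    X,
    y,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV accuracy (%) of an RBF-SVM with given (c, g)."""
    X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members < {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = SVC(C=params.c, gamma=params.g, kernel="rbf")
        clf.fit(X[tr], y[tr])
        correct += int(np.sum(clf.predict(X[te]) == y[te]))
    return 100.0 * correct / len(y)


def _decode(ind: np.ndarray, config: GAConfig) -> SVMParams:
    lo_c, hi_c = np.log2(config.c_range)
    lo_g, hi_g = np.log2(config.g_range)
    c = 2.0 ** float(np.clip(ind[0], lo_c, hi_c))
    g = 2.0 ** float(np.clip(ind[1], lo_g, hi_g))
    return SVMParams(c, g)


def ga_search(X, y, config: GAConfig) -> GAResult:
    """Evolve (c, g) by the genetic algorithm; returns the best individual.

    The best fitness per generation is non-decreasing (elitism of one);
    the search stops early once CV accuracy reaches 100%.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0 or y.size == 0:
        raise InvalidConfigError("training table is empty")
    rng = np.random.default_rng(config.seed)
    cv_seed = int(rng.integers(2**31 - 1))
    bounds = np.array(
        [np.log2(config.c_range), np.log2(config.g_range)]
    )  # (2, 2): rows = gene, cols = (lo, hi)

    def fitness(ind: np.ndarray) -> float:
        return cv_fitness(_decode(ind, config), X, y, config.cv_folds, cv_seed)

    pop = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.pop_size, 2))
    fits = np.array([fitness(ind) for ind in pop])
    history: list[tuple[float, float]] = []
    best_ind = pop[int(np.argmax(fits))].copy()
    best_fit = float(fits.max())

    for gen in range(config.max_generations):
        history.append((float(fits.mean()), best_fit))
        if config.early_stop and best_fit >= 100.0:
            break
        if gen == config.max_generations - 1:
            break
        children = [best_ind.copy()]  # elitism
        while len(children) < config.pop_size:
            parents = []
            for _k in range(2):  # tournament selection, size 2
                i, j = rng.integers(config.pop_size, size=2)
                parents.append(pop[i] if fits[i] >= fits[j] else pop[j])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_rate:  # uniform crossover
                swap = rng.random(2) < 0.5
                a[swap], b[swap] = b[swap], a[swap]
            for child in (a, b):
                mutate = rng.random(2) < config.mutation_rate
                child[mutate] += rng.normal(0.0, config.mutation_sigma, int(mutate.sum()))
                np.clip(child, bounds[:, 0], bounds[:, 1], out=child)
                if len(children) < config.pop_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_ind = pop[gen_best].copy()

    if not history:
        history.append((float(fits.mean()), best_fit))
    return GAResult(_decode(best_ind, config), best_fit, history)


def train_predict(train_X, train_y, test_X, params: SVMParams) -> np.ndarray:
    """Fit the soft-margin RBF-SVM on train and predict test labels."""
    clf = SVC(C=params.c, gamma=params.g, kernel="rbf")
    clf.fit(np.asarray(train_X, dtype=float), np.asarray(train_y))
    return clf.predict(np.asarray(test_X, dtype=float))


class GASVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-SVM flavor classifier with GA-tuned (c, g).

    ``fit`` runs the genetic search (CV-accuracy fitness) and then refits
    a single SVC with the best hyperparameters on the full training set.

    Attributes
    ----------
    best_params_ : SVMParams
    best_fitness_ : float
        Best CV accuracy found, in percent.
    fitness_history_ : list of (mean, best) per generation.
    """

    def __init__(
        self,
        pop_size: int = 20,
        max_generations: int = 200,
        c_range: tuple[float, float] = (2.0**-10, 2.0**10),
        g_range: tuple[float, float] = (2.0**-10, 2.0**10),
        cv_folds: int = 5,
        crossover_rate: float = 0.7,
        mutation_rate: float = 0.1,
        mutation_sigma: float = 0.5,
        early_stop: bool = True,
        random_state: int = 0,
    ):
        self.pop_size = pop_size
        self.max_generations = max_generations
        self.c_range = c_range
        self.g_range = g_range
        self.cv_folds = cv_folds
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.mutation_sigma = mutation_sigma
        self.early_stop = early_stop
        self.random_state = random_state

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            pop_size=self.pop_size,
            max_generations=self.max_generations,
            c_range=tuple(self.c_range),
            g_range=tuple(self.g_range),
            cv_folds=self.cv_folds,
            seed=self.random_state,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            mutation_sigma=self.mutation_sigma,
            early_stop=self.early_stop,
        )

    def fit(self, X, y) -> "GASVMClassifier":
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = unique_labels(y)
        result = ga_search(X, y, self._ga_config())
        self.best_params_ = result.best_params
        self.best_fitness_ = result.best_fitness
        self.fitness_history_ = result.fitness_history
        self.svc_ = SVC(
            C=result.best_params.c, gamma=result.best_params.g, kernel="rbf"
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.predict(check_array(np.asarray(X, dtype=float)))
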