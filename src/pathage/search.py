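"""Per-class age-deviation grid search (the core algorithm).

Each diagnostic class k gets a candidate deviation d_k (years). For a
candidate vector d the age model is trained on deviation-shifted labels
age_i + d_{class(i)}, applied to the validation set, and scored by the
fitness lambda = corr(predicted age, class label). Exhaustive enumeration
of the grid returns the maximizing deviations; real age plus the optimal
deviation of the subject's class is the brain pathological age. The
traditional baseline trains on unshifted real ages and minimizes the
epsilon-insensitive error instead.

A structural property worth knowing (see docs/methods.md): any global
constant added to all deviations shifts training labels uniformly, and the
epsilon-SVR dual is target-translation equivariant, so only deviation
*differences* are identified; the fitness surface is (numerically) constant
along diagonals d -> d + c*1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .criterion import fitness
from .exceptions import DegenerateInputError
from .regression import AgeSVR, AgeEstimatorConfig, fit_age_model

__all__ = [
    "DeviationGrid",
    "SearchResult",
    "BaselineResult",
    "PathologicalAgeSVR",
    "enumerate_candidates",
    "shifted_labels",
    "pathological_age",
    "run_search",
    "run_baseline",
    "default_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeviationGrid:
    """Per-class deviation search ranges (years) and a common step.

    ``ranges[k] = (min_k, max_k)`` bounds class k's deviation; candidates
    are the Cartesian product of the per-class ladders
    ``min_k, min_k + step, ..., max_k`` (both endpoints included).
    """

    ranges: tuple[tuple[float, float], ...]
    step: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", tuple((float(a), float(b)) for a, b in self.ranges))
        if self.step <= 0:
            raise ValueError("step must be positive")
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) has min > max")

    @property
    def n_classes(self) -> int:
        return len(self.ranges)

    def axis(self, k: int) -> np.ndarray:
        lo, hi = self.ranges[k]
        count = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + self.step * np.arange(count)

    @property
    def n_candidates(self) -> int:
        n = 1
        for k in range(self.n_classes):
            n *= len(self.axis(k))
        return n


def default_grid(n_classes: int, step: float = 1.0) -> DeviationGrid:
    """The study's prior ranges: [-10, 10] per class for two classes,
    [-8, 8] per class for three or more (time cost)."""
    bound = 10.0 if n_classes == 2 else 8.0
    return DeviationGrid(ranges=tuple((-bound, bound) for _ in range(n_classes)), step=step)


def enumerate_candidates(grid: DeviationGrid) -> np.ndarray:
    """All candidate deviation vectors, lexicographic, shape (n_candidates, K)."""
    axes = [grid.axis(k) for k in range(grid.n_classes)]
    return np.array(list(product(*axes)), dtype=float)


def shifted_labels(ages, class_labels, deviations) -> np.ndarray:
    """Training labels: ``ages[i] + deviations[class_labels[i]]``."""
    ages = np.asarray(ages, dtype=float).ravel()
    labels = np.asarray(class_labels, dtype=int).ravel()
    dev = np.asarray(deviations, dtype=float).ravel()
    if ages.shape != labels.shape:
        raise ValueError(f"length mismatch: {len(ages)} ages vs {len(labels)} labels")
    if labels.size and (labels.min() < 0 or labels.max() >= len(dev)):
        raise ValueError(
            f"class code {labels.max()} outside deviation vector of length {len(dev)}"
        )
    return ages + dev[labels]


def pathological_age(ages, class_labels, optimal_deviations) -> np.ndarray:
    """Brain pathological age: real age plus the class's optimal deviation.

    Same arithmetic as :func:`shifted_labels`; separate name because here
    the deviations are the search's *result*, not a training candidate.
    """
    return shifted_labels(ages, class_labels, optimal_deviations)


class PathologicalAgeSVR(BaseEstimator, RegressorMixin):
    """Deviation-searched epsilon-SVR age model (scikit-learn estimator).

    ``fit(X, y, labels=...)`` runs the exhaustive deviation search: for
    every grid candidate it trains an :class:`AgeSVR` on shifted labels and
    scores it on a validation set (given explicitly via ``X_val``/... or
    split off internally, stratified by class). ``predict`` applies the
    model refitted at the optimal candidate.

    Parameters
    ----------
    ranges : tuple of (min, max) per class, or None
        Deviation bounds in years; ``None`` uses the study defaults for the
        number of classes seen in ``fit`` ([-10,10] for 2, [-8,8] otherwise).
    step : float, default 1.0
        Grid step in years.
    kernel, C, epsilon, degree, gamma, standardize, tol :
        Passed to :class:`AgeSVR`.
    validation_fraction : float, default 0.25
        Fraction split off for scoring when no validation set is supplied.
    tie_tol : float, default 0.0
        Candidates whose fitness is within ``tie_tol`` of the maximum count
        as tied; ties resolve to the smallest L2-norm deviation vector,
        then lexicographic order. The default breaks only exact ties.
    random_state : int or None
        Seed for the internal validation split.

    Attributes
    ----------
    deviations_ : ndarray, shape (K,)
        Optimal per-class deviations (years).
    max_fitness_ : float
        Maximum finite fitness over the grid.
    fitness_surface_ : dict[tuple, float]
        Candidate -> fitness (-inf marks degenerate fits).
    model_ : AgeSVR
        Refit at the optimal candidate on the training portion.
    classes_ : ndarray
        Sorted class codes seen in ``fit``.
    """

    def __init__(self, ranges=None, step=1.0, kernel="linear", C=1.0, epsilon=0.1,
                 degree=3, gamma="scale", standardize=True, tol=1e-3,
                 validation_fraction=0.25, tie_tol=0.0, random_state=None):
        self.ranges = ranges
        self.step = step
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.degree = degree
        self.gamma = gamma
        self.standardize = standardize
        self.tol = tol
        self.validation_fraction = validation_fraction
        self.tie_tol = tie_tol
        self.random_state = random_state

    def _base_model(self) -> AgeSVR:
        return AgeSVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon,
                      degree=self.degree, gamma=self.gamma,
                      standardize=self.standardize, tol=self.tol)

    def fit(self, X, y, labels=None, X_val=None, y_val=None, labels_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if labels is None:
            raise ValueError("class labels are required: fit(X, y, labels=...)")
        labels = np.asarray(labels, dtype=int).ravel()
        if not (len(X) == len(y) == len(labels)):
            raise ValueError("X, y and labels must agree in length")

        if X_val is None:
            X_tr, X_va, y_tr, y_va, lab_tr, lab_va = train_test_split(
                X, y, labels, test_size=self.validation_fraction,
                stratify=labels, random_state=self.random_state)
        else:
            X_tr, y_tr, lab_tr = X, y, labels
            X_va = np.asarray(X_val, dtype=float)
            y_va = np.asarray(y_val, dtype=float).ravel()
            lab_va = np.asarray(labels_val, dtype=int).ravel()
        if len(np.unique(lab_va)) < 2:
            raise DegenerateInputError("validation set must contain at least 2 classes")

        self.classes_ = np.unique(np.concatenate([lab_tr, lab_va]))
        n_classes = int(self.classes_.max()) + 1
        grid = (DeviationGrid(tuple(self.ranges), self.step)
                if self.ranges is not None else default_grid(n_classes, self.step))
        if grid.n_classes != n_classes:
            raise ValueError(
                f"grid covers {grid.n_classes} classes but data has {n_classes}")
        candidates = enumerate_candidates(grid)
        if candidates.size == 0:
            raise ValueError("empty deviation grid")

        surface: dict[tuple, float] = {}
        for d in candidates:
            model = self._base_model()
            model.fit(X_tr, shifted_labels(y_tr, lab_tr, d))
            try:
                lam = fitness(model.predict(X_va), lab_va)
            except DegenerateInputError:
                lam = -np.inf
            surface[tuple(d)] = lam

        finite = [v for v in surface.values() if np.isfinite(v)]
        if not finite:
            raise DegenerateInputError("every grid candidate produced a degenerate fit")
        best = max(finite)
        tied = [np.array(d) for d, v in surface.items() if v >= best - self.tie_tol]
        tied.sort(key=lambda d: (np.dot(d, d), tuple(d)))
        opt = tied[0]

        self.grid_ = grid
        self.fitness_surface_ = surface
        self.max_fitness_ = float(best)
        self.deviations_ = opt
        self.model_ = self._base_model().fit(X_tr, shifted_labels(y_tr, lab_tr, opt))
        self.n_features_in_ = X.shape[1]
        logger.info("deviation search: optimum %s, fitness %.4f over %d candidates",
                    opt.tolist(), best, len(candidates))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def pathological_ages(self, ages, class_labels) -> np.ndarray:
        """Real ages plus the fitted optimal deviation of each subject's class."""
        check_is_fitted(self, "deviations_")
        return pathological_age(ages, class_labels, self.deviations_)


@dataclass
class SearchResult:
    """Outcome of :func:`run_search`.

    ``pathological_ages`` holds validation-set real ages plus the optimal
    deviation of each subject's class, aligned with the validation cohort.
    """

    optimal_deviations: np.ndarray
    max_fitness: float
    fitness_surface: dict[tuple, float]
    best_model: AgeSVR
    pathological_ages: np.ndarray
    grid: DeviationGrid = field(repr=False, default=None)


@dataclass
class BaselineResult:
    """Traditional brain-age baseline: predictions on the test set and MAE."""

    predictions: np.ndarray
    mae: float


def _resolve_config(config) -> AgeSVR:
    if config is None:
        return AgeSVR()
    if isinstance(config, AgeSVR):
        return AgeSVR(**config.get_params())
    if isinstance(config, AgeEstimatorConfig):
        return config.build()
    raise TypeError(f"cannot interpret {type(config).__name__} as an age-model config")


def run_search(train: Cohort, validation: Cohort, grid: DeviationGrid,
               config: AgeEstimatorConfig | AgeSVR | None = None,
               tie_tol: float = 0.0) -> SearchResult:
    """Exhaustive deviation search on explicit train/validation cohorts."""
    if train.feature_names != validation.feature_names:
        raise ValueError("train and validation cohorts must share feature columns")
    base = _resolve_config(config)
    est = PathologicalAgeSVR(ranges=grid.ranges, step=grid.step, tie_tol=tie_tol,
                             **{k: v for k, v in base.get_params().items()
                                if k in ("kernel", "C", "epsilon", "degree", "gamma",
                                         "standardize", "tol")})
    est.fit(train.features.to_numpy(), train.age, labels=train.class_label,
            X_val=validation.features.to_numpy(), y_val=validation.age,
            labels_val=validation.class_label)
    return SearchResult(
        optimal_deviations=est.deviations_,
        max_fitness=est.max_fitness_,
        fitness_surface=est.fitness_surface_,
        best_model=est.model_,
        pathological_ages=est.pathological_ages(validation.age, validation.class_label),
        grid=grid,
    )


def run_baseline(train: Cohort, test: Cohort,
                 config: AgeEstimatorConfig | AgeSVR | None = None,
                 train_classes: tuple[int, ...] | None = None) -> BaselineResult:
    """Traditional brain-age estimation: train on real ages, predict the test set.

    The epsilon-SVR minimizes the epsilon-insensitive error to the real
    age, so this realizes the error-minimizing fitness of the traditional
    approach; the mean absolute error on the test set is reported alongside
    the predictions. ``train_classes`` restricts training to a subset of
    class codes (e.g. ``(0,)`` for the healthy-controls-only convention
    some brain-age studies use); the default trains on all classes.
    """
    if train.feature_names != test.feature_names:
        raise ValueError("train and test cohorts must share feature columns")
    if train_classes is not None:
        keep = np.flatnonzero(np.isin(train.class_label, train_classes))
        if len(keep) < 2:
            raise ValueError(f"train has fewer than 2 subjects in classes {train_classes}")
        train = train.subset(keep)
    model = fit_age_model(train.features.to_numpy(), train.age, _resolve_config(config))
    pred = model.predict(test.features.to_numpy())
    return BaselineResult(predictions=pred, mae=float(np.mean(np.abs(pred - test.age))))
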