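"""Epsilon-SVR age-estimation model with selectable kernel.

The age model is a scikit-learn estimator (:class:`AgeSVR`) wrapping
``sklearn.svm.SVR``: features in, estimated ages out. Kernels are the
three studied variants — linear, polynomial (degree 3) and gaussian
(RBF) — with the canonical epsilon-SVR defaults pinned explicitly
(C = 1, epsilon = 0.1 years, gamma = "scale", degree = 3) so results are
reproducible across library versions.

Numerical notes
---------------
* Training targets are centred before the solve and the mean added back
  at prediction. For the exact solver this is a no-op (the dual's
  equality constraint makes it target-translation equivariant), but it
  keeps libsvm's scale-dependent stopping criterion meaningful when ages
  are far from zero.
* Features are z-scored by default (``standardize=True``). On raw
  volumetric scales (means in the thousands, small variance) the linear
  Gram matrix is so ill-conditioned that libsvm stops far from the
  optimum and mathematically equivalent encodings of the same problem
  return fits differing by years; standardization removes that solver
  noise. Set ``standardize=False`` to fit in raw feature coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConfigurationError, FitError

__all__ = ["AgeSVR", "AgeEstimatorConfig", "fit_age_model", "predict_age", "KERNEL_ALIASES"]

#: Accepted kernel names mapped onto sklearn SVR kernel identifiers.
KERNEL_ALIASES = {
    "linear": "linear",
    "polynomial": "poly",
    "poly": "poly",
    "gaussian": "rbf",
    "rbf": "rbf",
}


class AgeSVR(BaseEstimator, RegressorMixin):
    """Epsilon support vector regression of age on image features.

    Parameters
    ----------
    kernel : {"linear", "polynomial", "gaussian"} (aliases "poly", "rbf")
    C : float, default 1.0
        Regularization weight.
    epsilon : float, default 0.1
        Width of the epsilon-insensitive tube, in years.
    degree : int, default 3
        Polynomial-kernel degree (ignored otherwise).
    gamma : {"scale", "auto"} or float, default "scale"
        Gaussian/polynomial kernel width convention.
    standardize : bool, default True
        Z-score features (fit on training statistics) before the solve.
    tol : float, default 1e-3
        Solver stopping tolerance.

    Attributes
    ----------
    svr_ : fitted ``sklearn.svm.SVR``
    n_features_in_ : int
    y_mean_ : float
        Training-target mean, added back at prediction.
    x_mean_, x_scale_ : ndarray
        Feature standardization statistics (identity when disabled).
    """

    def __init__(self, kernel="linear", C=1.0, epsilon=0.1, degree=3,
                 gamma="scale", standardize=True, tol=1e-3, cache_size=200):
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.degree = degree
        self.gamma = gamma
        self.standardize = standardize
        self.tol = tol
        self.cache_size = cache_size

    def _sk_kernel(self) -> str:
        try:
            return KERNEL_ALIASES[self.kernel]
        except KeyError:
            raise ConfigurationError(
                f"unknown kernel {self.kernel!r}; choose from {sorted(set(KERNEL_ALIASES))}"
            ) from None

    def fit(self, X, y):
        kernel = self._sk_kernel()
        X, y = check_X_y(X, y, y_numeric=True)
        if len(y) < 2:
            raise ValueError("need at least 2 training subjects")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.x_scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        self.y_mean_ = float(np.mean(y))
        svr = SVR(kernel=kernel, C=self.C, epsilon=self.epsilon, degree=self.degree,
                  gamma=self.gamma, tol=self.tol, cache_size=self.cache_size)
        try:
            svr.fit((X - self.x_mean_) / self.x_scale_, y - self.y_mean_)
        except Exception as exc:  # pragma: no cover - solver failure is exotic
            raise FitError(f"epsilon-SVR fit failed for {self!r}: {exc}") from exc
        self.svr_ = svr
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return self.svr_.predict((X - self.x_mean_) / self.x_scale_) + self.y_mean_


@dataclass
class AgeEstimatorConfig:
    """Declarative form of the :class:`AgeSVR` parameters (CLI/YAML surface)."""

    kernel: str = "linear"
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_ALIASES:
            raise ConfigurationError(
                f"unknown kernel {self.kernel!r}; choose from {sorted(set(KERNEL_ALIASES))}"
            )

    def build(self) -> AgeSVR:
        return AgeSVR(kernel=self.kernel, **self.hyperparameters)


def fit_age_model(features, targets, config: AgeEstimatorConfig | AgeSVR | None = None) -> AgeSVR:
    """Fit an epsilon-SVR mapping ``features`` to training ages ``targets``."""
    if config is None:
        model = AgeSVR()
    elif isinstance(config, AgeSVR):
        model = AgeSVR(**config.get_params())
    else:
        model = config.build()
    return model.fit(features, targets)


def predict_age(model: AgeSVR, features) -> np.ndarray:
    """Estimated age per row of ``features``."""
    return model.predict(features)
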