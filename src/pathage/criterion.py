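"""Correlation machinery and the search's fitness function.

The deviation search scores a candidate by the Pearson correlation
lambda = corr(y_hat, y_label) between validation-set predicted ages and
the ordinal class codes. Three algebraically equivalent forms of the
correlation are implemented — the deviation-product ratio, the raw-moment
form, and covariance normalised by the standard deviations — so they can
cross-check one another; :func:`pearson_correlation` (the covariance form)
is the one used everywhere else in the package.

Zero-variance inputs raise :class:`~pathage.exceptions.DegenerateInputError`
rather than returning 0: a constant prediction vector carries no ranking
information and must not look like a mid-grid fitness value.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError

__all__ = [
    "covariance",
    "pearson_correlation",
    "pearson_correlation_ratio_form",
    "pearson_correlation_moment_form",
    "fitness",
    "shift_scale_invariance_check",
]


def _check_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def covariance(x, y) -> float:
    """Sample covariance with the n-1 denominator."""
    x, y = _check_pair(x, y)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1))


def _require_variance(x: np.ndarray, name: str) -> None:
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{name} has zero variance; correlation undefined")


def pearson_correlation(x, y) -> float:
    """Pearson correlation as covariance over the product of SDs.

    Raises
    ------
    DegenerateInputError
        If either vector is constant.
    """
    x, y = _check_pair(x, y)
    _require_variance(x, "x")
    _require_variance(y, "y")
    r = covariance(x, y) / np.sqrt(covariance(x, x) * covariance(y, y))
    # guard against round-off just outside [-1, 1]
    return float(np.clip(r, -1.0, 1.0))


def pearson_correlation_ratio_form(x, y) -> float:
    """Pearson correlation as the ratio of deviation-product sums."""
    x, y = _check_pair(x, y)
    _require_variance(x, "x")
    _require_variance(y, "y")
    dx, dy = x - x.mean(), y - y.mean()
    r = np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2))
    return float(np.clip(r, -1.0, 1.0))


def pearson_correlation_moment_form(x, y) -> float:
    """Pearson correlation from raw moments (sum x*y minus n*mean*mean)."""
    x, y = _check_pair(x, y)
    _require_variance(x, "x")
    _require_variance(y, "y")
    n = len(x)
    mx, my = x.mean(), y.mean()
    num = np.sum(x * y) - n * mx * my
    den = np.sqrt((np.sum(x**2) - n * mx**2) * (np.sum(y**2) - n * my**2))
    return float(np.clip(num / den, -1.0, 1.0))


def fitness(estimated_ages, class_labels) -> float:
    """Search objective lambda = corr(estimated ages, ordinal class codes).

    Requires at least two distinct class labels and non-constant
    predictions; both failure modes raise :class:`DegenerateInputError`.
    """
    y_hat = np.asarray(estimated_ages, dtype=float).ravel()
    labels = np.asarray(class_labels).astype(float).ravel()
    if y_hat.shape != labels.shape:
        raise ValueError(f"length mismatch: {len(y_hat)} vs {len(labels)}")
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("fitness needs at least 2 distinct class labels")
    _require_variance(y_hat, "estimated ages")
    return pearson_correlation(y_hat, labels)


def shift_scale_invariance_check(x, y, a: float, b: float, tol: float = 1e-10) -> bool:
    """True iff corr(a*x + b, y) equals corr(x, y) within ``tol``.

    Holds for any a > 0 (Pearson correlation is invariant to positive
    affine maps); a negative ``a`` flips the sign and the check fails.
    """
    if a == 0:
        raise DegenerateInputError("a = 0 collapses x to a constant")
    x = np.asarray(x, dtype=float)
    return abs(pearson_correlation(a * x + b, y) - pearson_correlation(x, y)) < tol
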