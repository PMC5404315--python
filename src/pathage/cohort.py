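"""Cohort data model and CSV round-trip.

A :class:`Cohort` is the universal input of the package: one row per
subject, with chronological age in years, an ordinal diagnostic class code
(severity order, e.g. NC=0 < MCI=1 < AD=2), and a matrix of numeric
MRI-derived features such as left/right hippocampal volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import CohortFormatError, CohortParseError

__all__ = ["Cohort", "ColumnMap", "read_cohort_csv", "write_cohort_csv", "balance_classes"]

#: Default diagnostic classes in disease-severity order.
DEFAULT_CLASS_ORDER = ("NC", "MCI", "AD")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping of CSV column roles for :func:`read_cohort_csv`.

    Parameters
    ----------
    subject_id, age, class_column :
        Column names holding the subject identifier, chronological age
        (years) and diagnostic class string.
    class_order :
        Class names in severity order; determines the ordinal coding
        (first name -> 0). ``None`` uses NC/MCI/AD restricted to the names
        present, or, failing that, sorted order of the observed names.
    feature_columns :
        Explicit feature columns; ``None`` takes every remaining column.
    """

    subject_id: str = "subject_id"
    age: str = "age"
    class_column: str = "class"
    class_order: tuple[str, ...] | None = None
    feature_columns: tuple[str, ...] | None = None


@dataclass
class Cohort:
    """Feature table for a set of subjects.

    Attributes
    ----------
    subject_id : ndarray of str
        Identifiers; preserved through I/O but never used in computation.
    age : ndarray of float
        Chronological ages in years; strictly positive, finite.
    class_label : ndarray of int
        Ordinal class codes forming a contiguous 0..K-1 set, K >= 2.
    class_names : tuple of str
        Names for the K codes, severity-ordered.
    features : pandas.DataFrame
        One row per subject, named numeric columns, no missing values.
    """

    subject_id: np.ndarray
    age: np.ndarray
    class_label: np.ndarray
    class_names: tuple[str, ...]
    features: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.class_label = np.asarray(self.class_label, dtype=int)
        self.class_names = tuple(self.class_names)
        if not isinstance(self.features, pd.DataFrame):
            self.features = pd.DataFrame(np.asarray(self.features, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.age)
        if len(self.subject_id) != n or len(self.class_label) != n:
            raise CohortFormatError("subject_id, age and class_label must have equal length")
        if self.features.shape[0] != n:
            raise CohortFormatError(
                f"features has {self.features.shape[0]} rows for {n} subjects"
            )
        if n == 0:
            raise CohortFormatError("cohort is empty")
        if not np.all(np.isfinite(self.age)) or np.any(self.age <= 0):
            raise CohortFormatError("ages must be strictly positive and finite")
        k = len(self.class_names)
        if k < 2:
            raise CohortFormatError("a cohort needs at least 2 classes")
        present = np.unique(self.class_label)
        if present.min() < 0 or present.max() >= k:
            raise CohortFormatError(
                f"class labels {present.tolist()} outside 0..{k - 1}"
            )
        vals = self.features.to_numpy()
        if vals.size and not np.all(np.isfinite(vals.astype(float))):
            raise CohortParseError("features contain missing or non-finite values")

    # -- convenience ----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.age)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.features.columns]

    def class_counts(self) -> np.ndarray:
        """Number of subjects per class code (length K)."""
        return np.bincount(self.class_label, minlength=self.n_classes)

    def subset(self, indices: np.ndarray) -> "Cohort":
        """New cohort restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        return replace(
            self,
            subject_id=self.subject_id[idx],
            age=self.age[idx],
            class_label=self.class_label[idx],
            features=self.features.iloc[idx].reset_index(drop=True),
        )


def _resolve_class_order(observed: list[str], class_order: tuple[str, ...] | None) -> tuple[str, ...]:
    if class_order is not None:
        unknown = sorted(set(observed) - set(class_order))
        if unknown:
            raise ValueError(f"unknown class name(s) {unknown}; expected one of {list(class_order)}")
        return tuple(class_order)
    if set(observed) <= set(DEFAULT_CLASS_ORDER):
        return tuple(c for c in DEFAULT_CLASS_ORDER if c in observed)
    return tuple(sorted(set(observed)))


def read_cohort_csv(path, column_map: ColumnMap | None = None) -> Cohort:
    """Read a cohort table from CSV.

    The canonical layout is ``subject_id,age,class,<feature1>,...`` with a
    header row; ``column_map`` renames roles and fixes the severity order of
    class names (default NC=0, MCI=1, AD=2).
    """
    cm = column_map or ColumnMap()
    df = pd.read_csv(path, dtype=str)
    for role, col in (("subject_id", cm.subject_id), ("age", cm.age), ("class", cm.class_column)):
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r} (role: {role})")
    feat_cols = (
        list(cm.feature_columns)
        if cm.feature_columns is not None
        else [c for c in df.columns if c not in {cm.subject_id, cm.age, cm.class_column}]
    )
    missing = [c for c in feat_cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing feature column(s) {missing}")
    if not feat_cols:
        raise CohortFormatError("at least one feature column is required")

    def _numeric(col: str) -> np.ndarray:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric or missing value in column {col!r} at data row {row}"
                f" (value {raw.iloc[row]!r})"
            )
        return out.to_numpy(dtype=float)

    age = _numeric(cm.age)
    features = pd.DataFrame({c: _numeric(c) for c in feat_cols})
    observed = df[cm.class_column].astype(str).tolist()
    class_names = _resolve_class_order(observed, cm.class_order)
    code = {name: i for i, name in enumerate(class_names)}
    try:
        labels = np.array([code[c] for c in observed], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class name {exc.args[0]!r}") from None
    return Cohort(
        subject_id=df[cm.subject_id].to_numpy(dtype=object),
        age=age,
        class_label=labels,
        class_names=class_names,
        features=features,
    )


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write ``cohort`` as UTF-8 CSV: ``subject_id,age,class,<features...>``.

    Class codes are written as their name strings so the file is
    self-describing and round-trips through :func:`read_cohort_csv`.
    """
    if cohort.features.shape[1] == 0:
        raise CohortFormatError("at least one feature is required to write a cohort")
    out = pd.DataFrame({
        "subject_id": cohort.subject_id,
        "age": cohort.age,
        "class": [cohort.class_names[k] for k in cohort.class_label],
    })
    for c in cohort.features.columns:
        out[str(c)] = cohort.features[c].to_numpy()
    out.to_csv(path, index=False, encoding="utf-8")


def balance_classes(cohort: Cohort, seed: int) -> Cohort:
    """Subsample every class, without replacement, to the smallest class size.

    Mirrors the balanced-class setup in which 540/534/411 subjects are
    reduced to 411 per class. Deterministic given ``seed``; original row
    order is preserved among the kept subjects.
    """
    rng = np.random.default_rng(seed)
    counts = cohort.class_counts()
    if np.any(counts == 0):
        raise ValueError("every class must have at least one subject")
    target = int(counts.min())
    keep: list[np.ndarray] = []
    for k in range(cohort.n_classes):
        members = np.flatnonzero(cohort.class_label == k)
        keep.append(rng.choice(members, size=target, replace=False))
    idx = np.sort(np.concatenate(keep))
    return cohort.subset(idx)
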