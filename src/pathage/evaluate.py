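"""Repeated-split evaluation protocol and reporting.

Orchestrates the experimental design around the deviation search: random
(stratified) train/validation/test partitions repeated ``n_repeats``
times, a per-kernel comparison, one-sample t-tests of the recovered
deviations against zero, and the correlation report — correlation of each
age variant with the class label (CwC), with each MRI feature (CwF_j) and
averaged over features (ACwF). Three age variants mirror the method
comparison: raw real age ("without age estimation"), the traditional
error-minimizing brain age (baseline SVR prediction) and the brain
pathological age (real age plus the searched class deviations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .criterion import fitness, pearson_correlation
from .regression import AgeSVR, AgeEstimatorConfig
from .search import DeviationGrid, run_baseline, run_search, default_grid

__all__ = [
    "SplitPolicy",
    "EvaluationReport",
    "split_cohort",
    "repeat_experiment",
    "deviation_significance",
    "correlation_report",
    "compare_kernels",
    "markdown_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPolicy:
    """Train/validation/test partition proportions and determinism."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n into three parts."""
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # most short-changed first
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_cohort(cohort: Cohort, policy: SplitPolicy) -> tuple[Cohort, Cohort, Cohort]:
    """Disjoint, exhaustive train/validation/test partition.

    Stratified by class when requested (each class apportioned
    separately); deterministic given ``policy.seed``.
    """
    rng = np.random.default_rng(policy.seed)
    groups: list[np.ndarray]
    if policy.stratified:
        groups = [np.flatnonzero(cohort.class_label == k) for k in range(cohort.n_classes)]
        if any(len(g) < 3 for g in groups):
            raise ValueError("stratified split needs at least 3 subjects per class")
    else:
        groups = [np.arange(cohort.n_subjects)]
    parts: list[list[np.ndarray]] = [[], [], []]
    for g in groups:
        perm = rng.permutation(g)
        sizes = _partition_sizes(len(g), policy.fractions)
        if any(s == 0 for s in sizes):
            raise ValueError(f"split of {len(g)} subjects yields an empty part: {sizes}")
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].append(perm[:a])
        parts[1].append(perm[a:b])
        parts[2].append(perm[b:])
    return tuple(cohort.subset(np.sort(np.concatenate(p))) for p in parts)  # type: ignore[return-value]


def repeat_seed(master_seed: int, repeat: int) -> int:
    """Deterministic per-repeat seed; any repeat is re-runnable in isolation."""
    return int(np.random.SeedSequence([master_seed, repeat]).generate_state(1)[0] % (2**31))


@dataclass
class EvaluationReport:
    """Per-repeat rows plus aggregates of the repeated-split protocol.

    ``per_repeat`` has one row per repeat (seed, optimal deviation per
    class, validation fitness, and test-set fitness of the pathological
    age, the baseline brain age and the raw real age, plus the per-variant
    correlation-report columns). ``aggregates`` holds mean/SD per column,
    recomputable exactly from ``per_repeat``. ``deviation_p_values`` are
    two-sided one-sample t-tests of the recovered deviations against 0
    (NaN marks the degenerate all-identical case).
    """

    per_repeat: pd.DataFrame
    aggregates: pd.DataFrame
    deviation_p_values: np.ndarray
    correlation_table: pd.DataFrame
    class_names: tuple[str, ...] = ()
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "aggregates": {c: {"mean": float(self.aggregates.loc["mean", c]),
                               "std": float(self.aggregates.loc["std", c])}
                           for c in self.aggregates.columns},
            "deviation_p_values": [None if np.isnan(p) else float(p)
                                   for p in self.deviation_p_values],
            "correlation_table": self.correlation_table.reset_index()
                                     .to_dict(orient="records"),
            "class_names": list(self.class_names),
            "notes": self.notes,
        }


def _aggregate(per_repeat: pd.DataFrame) -> pd.DataFrame:
    num = per_repeat.drop(columns=["seed"], errors="ignore")
    return pd.DataFrame({c: {"mean": num[c].mean(), "std": num[c].std(ddof=1)}
                         for c in num.columns})


def deviation_significance(per_repeat_deviations) -> np.ndarray:
    """Two-sided one-sample t-test of each class's recovered deviations vs 0.

    Returns one p-value per class; NaN marks the exact-degenerate case
    where every repeat recovered the identical deviation (zero variance
    across repeats, t undefined).
    """
    dev = np.atleast_2d(np.asarray(per_repeat_deviations, dtype=float))
    if dev.shape[0] < 2:
        raise ValueError("need at least 2 repeats for a significance test")
    out = np.empty(dev.shape[1])
    for k in range(dev.shape[1]):
        col = dev[:, k]
        if np.ptp(col) == 0:
            out[k] = np.nan
        else:
            out[k] = stats.ttest_1samp(col, 0.0).pvalue
    return out


def correlation_report(cohort: Cohort, age_variants: dict[str, np.ndarray],
                       abs_values: bool = False) -> pd.DataFrame:
    """CwC / CwF_j / ACwF per age variant.

    CwC is the correlation of the variant with the ordinal class codes;
    CwF_j with feature j; ACwF the mean of the CwF_j. Signed correlations
    by default; ``abs_values`` reports magnitudes.
    """
    rows = {}
    feats = cohort.features.to_numpy()
    for name, variant in age_variants.items():
        v = np.asarray(variant, dtype=float).ravel()
        if len(v) != cohort.n_subjects:
            raise ValueError(f"variant {name!r} has {len(v)} values for "
                             f"{cohort.n_subjects} subjects")
        row = {"CwC": pearson_correlation(v, cohort.class_label.astype(float))}
        cwf = [pearson_correlation(v, feats[:, j]) for j in range(feats.shape[1])]
        for j, c in enumerate(cwf, start=1):
            row[f"CwF{j}"] = c
        row["ACwF"] = float(np.mean(cwf))
        if abs_values:
            row = {k: abs(val) for k, val in row.items()}
        rows[name] = row
    return pd.DataFrame(rows).T


def repeat_experiment(cohort: Cohort, grid: DeviationGrid | None = None,
                      config: AgeEstimatorConfig | AgeSVR | None = None,
                      policy: SplitPolicy = SplitPolicy(),
                      n_repeats: int = 10,
                      baseline_train: str = "all") -> EvaluationReport:
    """The repeated random-split protocol.

    Per repeat: split, run the deviation search on train/validation, then
    score on the held-out test set the fitness of (a) pathological ages
    (real age + class deviation learned on validation), (b) the baseline
    brain-age predictions, (c) the raw real ages, together with the
    correlation report of all three variants. ``baseline_train`` chooses
    whether the traditional baseline trains on every class ("all") or on
    the lowest-severity class only ("nc"), the convention of brain-age
    studies that fit healthy controls alone.
    """
    if baseline_train not in ("all", "nc"):
        raise ValueError('baseline_train must be "all" or "nc"')
    base_classes = None if baseline_train == "all" else (0,)
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    grid = grid or default_grid(cohort.n_classes)
    rows = []
    for r in range(n_repeats):
        seed = repeat_seed(policy.seed, r)
        try:
            tr, va, te = split_cohort(cohort, SplitPolicy(policy.fractions,
                                                          policy.stratified, seed))
            res = run_search(tr, va, grid, config)
            base = run_baseline(tr, te, config, train_classes=base_classes)
            path_age = te.age + res.optimal_deviations[te.class_label]
            row = {"seed": seed}
            for k, name in enumerate(cohort.class_names):
                row[f"deviation_{name}"] = float(res.optimal_deviations[k])
            row["validation_fitness"] = res.max_fitness
            row["test_fitness"] = fitness(path_age, te.class_label)
            row["test_fitness_baseline"] = fitness(base.predictions, te.class_label)
            row["test_fitness_real_age"] = fitness(te.age, te.class_label)
            row["baseline_mae"] = base.mae
            variants = {"real_age": te.age, "brain_age": base.predictions,
                        "pathological_age": path_age}
            corr = correlation_report(te, variants)
            for vname in corr.index:
                for col in corr.columns:
                    row[f"{vname}:{col}"] = float(corr.loc[vname, col])
            rows.append(row)
            logger.info("repeat %d/%d: deviations %s, validation fitness %.4f",
                        r + 1, n_repeats, res.optimal_deviations.tolist(),
                        res.max_fitness)
        except Exception as exc:
            raise type(exc)(f"repeat {r}: {exc}") from exc
    per_repeat = pd.DataFrame(rows)
    dev_cols = [f"deviation_{n}" for n in cohort.class_names]
    pvals = deviation_significance(per_repeat[dev_cols].to_numpy())
    corr_cols = [c for c in per_repeat.columns if ":" in c]
    corr_mean = per_repeat[corr_cols].agg(["mean", "std"]).T
    corr_mean.index = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in corr_mean.index], names=["variant", "metric"])
    notes = [f"deviation p-value for class {cohort.class_names[k]} is degenerate "
             "(identical across repeats)"
             for k in range(len(pvals)) if np.isnan(pvals[k])]
    return EvaluationReport(
        per_repeat=per_repeat,
        aggregates=_aggregate(per_repeat),
        deviation_p_values=pvals,
        correlation_table=corr_mean,
        class_names=cohort.class_names,
        notes=notes,
    )


def compare_kernels(cohort: Cohort, grid: DeviationGrid | None = None,
                    policy: SplitPolicy = SplitPolicy(), n_repeats: int = 10,
                    kernels: tuple[str, ...] = ("linear", "polynomial", "gaussian"),
                    ) -> dict[str, EvaluationReport]:
    """Run the repeated protocol once per kernel with identical splits.

    The same master seed (hence the same per-repeat partitions) is used
    for every kernel, giving a paired comparison.
    """
    out = {}
    for kernel in kernels:
        out[kernel] = repeat_experiment(cohort, grid, AgeSVR(kernel=kernel),
                                        policy, n_repeats)
    return out


def markdown_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    """Small GitHub-markdown renderer for report tables."""
    df = df.reset_index() if df.index.name or not df.index.equals(pd.RangeIndex(len(df))) else df

    def fmt(v):
        if isinstance(v, float):
            return "nan" if np.isnan(v) else floatfmt.format(v)
        return str(v)

    headers = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "|" + "|".join("---" for _ in headers) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)
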