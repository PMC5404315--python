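# Methods

## Model and procedure

Subjects carry a chronological age `a` (years), an ordinal diagnostic
class `k ∈ {0, …, K−1}` in severity order (NC=0, MCI=1, AD=2), and a
vector of numeric MRI features `x` (here: left/right hippocampal
volumes). The working hypothesis is accelerated brain aging: the age
encoded in the features is `a + d_k` for a class-specific deviation
`d_k`, negative-to-positive across increasing severity.

The deviation search estimates `d = (d_0, …, d_{K−1})`:

* enumerate the Cartesian grid `d_k ∈ {min_k, min_k+s, …, max_k}`
  (defaults: ±10 years per class for K=2, ±8 for K≥3, step `s` = 1 year);
* for each candidate, fit an epsilon-SVR on the training set with labels
  `a_i + d_{k(i)}`;
* score the candidate by the fitness
  `λ(d) = corr(ŷ_val, k_val)` — the Pearson correlation between
  validation-set predictions and the class codes;
* report the maximizing candidate; `a + d*_k` is the brain pathological
  age. The traditional baseline instead trains on the raw ages and is
  scored by the same correlation plus its test MAE.

The correlation is implemented three ways (deviation-product ratio, raw
moments, covariance normalized by the standard deviations); they agree to
1e-10 and cross-check one another in the tests. Constant inputs raise a
degenerate-input error rather than returning 0, and the search maps that
error to a fitness of −∞, so a collapsed SVR fit can never look like a
mid-grid candidate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `C` | 1.0 | SVR regularization weight |
| `epsilon` | 0.1 y | insensitive-tube half width |
| `kernel` | linear | linear / polynomial (degree 3) / gaussian (`gamma="scale"`) |
| `standardize` | on | z-score features inside the estimator |
| grid ranges | ±10 y (K=2), ±8 y (K≥3) | prior bound on plausible deviations |
| grid `step` | 1 y | deviation resolution; cost grows as `((range/step)+1)^K` |
| split fractions | 0.6/0.2/0.2 | train / validation / test, stratified by class |
| `n_repeats` | 10 | random-split repetitions in the evaluation protocol |

SVR hyperparameters are pinned to these canonical defaults rather than
left to the backend's current release. The split fractions balance a
stable validation correlation (the search's objective) against an
untouched test set; the master seed spawns per-repeat seeds through
`SeedSequence([master, repeat])`, so any single repeat can be reproduced
in isolation.

## Numerical choices

* **Target centering.** Training labels are centered before the SVR solve
  and the mean restored at prediction. The epsilon-SVR dual depends on
  targets only through differences (its equality constraint), so this is
  mathematically a no-op — verified equivariant to ~1e-11 — but it keeps
  libsvm's scale-dependent stopping rule meaningful for targets near 75.
* **Feature standardization (default on).** On raw volumetric scales
  (means ≈ 3500 units, SD ≈ 20) the linear-kernel Gram matrix is so badly
  conditioned that the solver stops far from the optimum: we measured a
  primal objective of 2124 versus 1760 for the converged fit of the same
  problem, and predictions from two equivalent encodings differing by
  4.8 years. Standardization makes fits reproducible and 5–50× faster.
  `standardize=False` restores raw-coordinate geometry when wanted.
* **Tie-breaking.** Exact fitness ties resolve to the smallest-L2-norm
  deviation vector, then lexicographic order. A `tie_tol` parameter can
  treat near-ties (e.g. the shift diagonals below) as exact; the default
  0 preserves the strict argmax.
* **Degenerate candidates** score −∞; an all-degenerate surface raises.
* **Grid endpoints** are included on both sides; counts use a 1e-9 slack
  so fractional steps do not drop the last point.

## Identifiability: what the fitness can and cannot see

Two structural facts shape every result of this method:

1. **Only deviation differences are identified.** Adding a constant `c`
   to all class deviations shifts every training label by `c`; the SVR is
   translation-equivariant, and Pearson correlation is shift-invariant,
   so `λ(d) = λ(d + c·1)` (within solver noise, ~1e-11). The fitness
   surface is constant along diagonals. Reported absolute deviations
   therefore depend entirely on tie-breaking convention; only `q − w`,
   `r − q`, … carry information.
2. **With a linear kernel the surface depends on `d` only through the
   fitted weight direction.** Predictions are affine in the features, and
   the correlation is invariant to positive affine maps, so
   `λ(d) = corr(u_d·x_val, k_val)` where `u_d` is the unit weight vector.
   With two (nearly exchangeable) features, `u_d` lives on a circle, and
   in a generative model where both features carry the same brain-age
   signal with symmetric noise the population-optimal direction does not
   depend on `d` at all: the population surface is *flat* across the
   entire half of the grid whose fitted slope is sign-aligned with
   severity. Which candidate wins in a finite sample is then decided by
   validation sampling noise (SE ≈ 1/√n_val ≈ 0.06 at n_val ≈ 250,
   versus a surface relief of ~0.01–0.02).

Consequence, measured on the default generator (accelerations (0, 4, 8),
atrophy slope 3 units/year, feature noise SD 5, 411 subjects/class):
the *sign* of the two-class deviation gap `q − w` is recovered in roughly
60–80% of runs (seed- and split-dependent), while the full three-class
ordering `w < q < r` is near chance
(~1–2 out of 8 seeded runs, both linear and gaussian kernels). The
fitness value itself is stable — the searched optimum always dominates
the zero candidate and the baseline on the validation split — but the
*location* of the optimum is weakly identified at this signal-to-noise.
Cohorts with more (or asymmetric) features, lower feature noise or larger
validation sets would sharpen it. This is a property of the
correlation-criterion objective under these study conditions, not of the
implementation; the tests assert the recovery fractions so the behaviour
stays visible.

## Synthetic generator: what it does and does not emulate

`generate_cohort` reproduces the reported structure of the balanced
hippocampus table: 411 subjects per class, ages drawn from normals
truncated to [65, 85] whose *realized* means match the reported
76.092/75.362/75.503 (the location parameter is solved for, since
truncation shifts the mean by ~0.3 y; realized SDs are necessarily
smaller than the reported pre-truncation SDs on a 20-year window — noted,
not resolved). Features decline linearly with brain age
(slope 3 units/year from baselines 3600/3500), with correlated bilateral
noise (SD 5, correlation 0.6) and a 1-year brain-age jitter. Defaults are
fixed once; the true accelerations (0, 4, 8) are an arbitrary documented
choice within the search ranges.

Not emulated: nonlinear atrophy, covariate effects (sex, education),
longitudinal trajectories, measurement/segmentation artifacts, or any
image-level processing. Passing tests on this generator show the
machinery is correct and characterize the method's behaviour under a
known ground truth; they do not certify performance on real ADNI feature
tables.

## Problem sizes used by the shipped experiments

Searches in the test suite and `scripts/acceptance.py` use a 2-year grid
step (9³ = 729 candidates for three classes, 11² = 121 for two) at the
full 411-per-class cohort size, 5–10 evaluation repeats, and 10–20 seeded
recovery runs; per-run deviations averaged over repeats are reported to
one decimal. A 1-year step quadruples-to-octuples the candidate count and
is supported (as is 0.1) at proportional cost.

## Known limitations

* Deviation *levels* are conventional (tie-break), only differences are
  meaningful; compare methods on differences or on fitness.
* Grid search cost is exponential in the number of classes.
* The evaluation's test-set pathological age applies the class-wise
  deviations learned on validation to *labeled* test subjects; it
  measures separability of the construct, not diagnostic prediction for
  unlabeled subjects.
* p-values for deviations use a one-sample t-test across repeats; repeats
  share subjects through resampled splits, so they are not fully
  independent and the test is approximate.
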