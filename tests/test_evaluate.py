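import numpy as np
import pytest
from scipy import stats

from pathage import (
    AgeSVR,
    DeviationGrid,
    SplitPolicy,
    compare_kernels,
    correlation_report,
    deviation_significance,
    repeat_experiment,
    split_cohort,
)
from pathage.evaluate import markdown_table, repeat_seed


class TestSplitCohort:
    def test_exact_proportions(self, adni_like):
        # 270 subjects at (0.6, 0.2, 0.2) -> 162/54/54
        tr, va, te = split_cohort(adni_like, SplitPolicy((0.6, 0.2, 0.2), False, 0))
        assert (tr.n_subjects, va.n_subjects, te.n_subjects) == (162, 54, 54)

    def test_partition_is_disjoint_and_exhaustive(self, adni_like):
        tr, va, te = split_cohort(adni_like, SplitPolicy(seed=1))
        ids = np.concatenate([tr.subject_id, va.subject_id, te.subject_id])
        assert sorted(ids) == sorted(adni_like.subject_id)
        assert len(set(ids)) == adni_like.n_subjects

    def test_stratified_split_balanced_within_one(self, adni_like):
        tr, va, te = split_cohort(adni_like, SplitPolicy(seed=2))
        for part in (tr, va, te):
            counts = part.class_counts()
            assert counts.max() - counts.min() <= 1

    def test_same_seed_identical_different_seed_not(self, adni_like):
        a1, _, _ = split_cohort(adni_like, SplitPolicy(seed=3))
        a2, _, _ = split_cohort(adni_like, SplitPolicy(seed=3))
        b1, _, _ = split_cohort(adni_like, SplitPolicy(seed=4))
        assert list(a1.subject_id) == list(a2.subject_id)
        assert list(a1.subject_id) != list(b1.subject_id)

    def test_empty_part_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            split_cohort(tiny_cohort, SplitPolicy((0.98, 0.01, 0.01), False, 0))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitPolicy((0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SplitPolicy((0.8, 0.2, 0.0))


class TestDeviationSignificance:
    def test_degenerate_all_zero(self):
        p = deviation_significance(np.zeros((10, 2)))
        assert np.isnan(p).all()

    def test_tight_nonzero_deviations_highly_significant(self):
        rng = np.random.default_rng(0)
        dev = rng.normal(5.0, 0.1, size=(10, 1))
        p = deviation_significance(dev)
        assert p[0] < 0.001

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        dev = rng.normal(0.5, 1.0, size=(12, 3))
        p = deviation_significance(dev)
        for k in range(3):
            assert p[k] == pytest.approx(stats.ttest_1samp(dev[:, k], 0.0).pvalue)

    def test_null_pvalues_approximately_uniform(self):
        # type-I calibration: p under N(0,1) deviations is Uniform(0,1)
        rng = np.random.default_rng(2)
        ps = [deviation_significance(rng.normal(0, 1, size=(10, 1)))[0]
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCorrelationReport:
    def test_class_codes_variant_gives_unit_cwc(self, adni_like):
        rep = correlation_report(adni_like,
                                 {"codes": adni_like.class_label.astype(float)})
        assert rep.loc["codes", "CwC"] == pytest.approx(1.0)

    def test_feature_variant_gives_unit_cwf(self, adni_like):
        f1 = adni_like.features.iloc[:, 0].to_numpy()
        rep = correlation_report(adni_like, {"f1": f1})
        assert rep.loc["f1", "CwF1"] == pytest.approx(1.0)

    def test_acwf_is_mean_of_cwf(self, adni_like):
        rep = correlation_report(adni_like, {"age": adni_like.age})
        cwf = [rep.loc["age", c] for c in rep.columns if c.startswith("CwF")]
        assert rep.loc["age", "ACwF"] == pytest.approx(np.mean(cwf), abs=1e-15)

    def test_real_age_uncorrelated_with_class_when_no_acceleration(self):
        from pathage import CohortSpec, generate_cohort
        spec = CohortSpec(n_per_class=400, class_accel=(0.0, 0.0, 0.0),
                          class_age_means=(75.5,) * 3, class_age_sds=(5.0,) * 3,
                          seed=8)
        c = generate_cohort(spec)
        rep = correlation_report(c, {"age": c.age})
        assert abs(rep.loc["age", "CwC"]) < 3 / np.sqrt(c.n_subjects)

    def test_abs_flag_reports_magnitudes(self, adni_like):
        signed = correlation_report(adni_like, {"f1": -adni_like.features.iloc[:, 0]})
        mag = correlation_report(adni_like, {"f1": -adni_like.features.iloc[:, 0]},
                                 abs_values=True)
        assert signed.loc["f1", "CwF1"] == pytest.approx(-1.0)
        assert mag.loc["f1", "CwF1"] == pytest.approx(1.0)


GRID = DeviationGrid(((-2, 2), (-2, 2), (-2, 2)), step=2.0)


class TestRepeatExperiment:
    @pytest.fixture(scope="class")
    @classmethod
    def report(cls, adni_like):
        return repeat_experiment(adni_like, GRID, AgeSVR(), SplitPolicy(seed=0),
                                 n_repeats=3)

    def test_one_row_per_repeat_with_three_method_columns(self, report):
        assert len(report.per_repeat) == 3
        for col in ("test_fitness", "test_fitness_baseline", "test_fitness_real_age"):
            assert col in report.per_repeat.columns

    def test_aggregates_recomputable_from_rows(self, report):
        for col in report.aggregates.columns:
            assert report.aggregates.loc["mean", col] == pytest.approx(
                report.per_repeat[col].mean(), rel=1e-12)
            assert report.aggregates.loc["std", col] == pytest.approx(
                report.per_repeat[col].std(ddof=1), rel=1e-12, abs=1e-15)

    def test_correlations_bounded(self, report):
        cols = [c for c in report.per_repeat.columns
                if "fitness" in c or ":" in c]
        vals = report.per_repeat[cols].to_numpy()
        assert (np.abs(vals) <= 1.0 + 1e-12).all()

    def test_validation_fitness_dominates_zero_candidate(self, adni_like):
        # with 0 in the grid the searched fitness can never fall below the
        # zero-deviation (plain brain-age) candidate on the same split
        rep = repeat_experiment(adni_like, GRID, AgeSVR(), SplitPolicy(seed=1),
                                n_repeats=2)
        zero_grid = DeviationGrid(((0, 0),) * 3)
        rep0 = repeat_experiment(adni_like, zero_grid, AgeSVR(), SplitPolicy(seed=1),
                                 n_repeats=2)
        assert (rep.per_repeat["validation_fitness"].to_numpy()
                >= rep0.per_repeat["validation_fitness"].to_numpy() - 1e-12).all()

    def test_zero_grid_pathological_equals_real_age_row(self, adni_like):
        rep = repeat_experiment(adni_like, DeviationGrid(((0, 0),) * 3), AgeSVR(),
                                SplitPolicy(seed=2), n_repeats=2)
        np.testing.assert_allclose(rep.per_repeat["test_fitness"],
                                   rep.per_repeat["test_fitness_real_age"])

    def test_reproducible_given_master_seed(self, adni_like):
        a = repeat_experiment(adni_like, GRID, AgeSVR(), SplitPolicy(seed=5), 2)
        b = repeat_experiment(adni_like, GRID, AgeSVR(), SplitPolicy(seed=5), 2)
        assert a.per_repeat.equals(b.per_repeat)

    def test_repeat_seeds_are_stable_scheme(self):
        assert repeat_seed(0, 0) == repeat_seed(0, 0)
        assert repeat_seed(0, 1) != repeat_seed(0, 0)
        assert 0 <= repeat_seed(12345, 99) < 2**31


class TestCompareKernels:
    def test_three_kernel_sections_with_paired_splits(self, small_two_class):
        grid = DeviationGrid(((-1, 1), (-1, 1)), step=1.0)
        out = compare_kernels(small_two_class, grid, SplitPolicy(seed=3),
                              n_repeats=2)
        assert set(out) == {"linear", "polynomial", "gaussian"}
        seeds = {k: out[k].per_repeat["seed"].tolist() for k in out}
        assert seeds["linear"] == seeds["polynomial"] == seeds["gaussian"]


class TestMarkdown:
    def test_renders_header_and_rows(self, adni_like):
        rep = correlation_report(adni_like, {"age": adni_like.age})
        text = markdown_table(rep)
        lines = text.splitlines()
        assert lines[0].startswith("|") and "CwC" in lines[0]
        assert len(lines) == 3
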