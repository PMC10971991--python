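"""Reports, correlations, ANOVA, group summaries, age filtering."""

import numpy as np
import pytest
import scipy.stats

from metaboselect import (
    SyntheticConfig,
    age_filter,
    anova_oneway,
    confusion_matrix,
    correlation_matrix,
    generate_cohort,
    loo_evaluate,
    pearson,
    posterior_table,
    report_from_confusion,
    summarize_by_group,
)
from metaboselect.lda import PosteriorRecord

CLASSES = ("control", "glaucoma", "diabetes")


class TestConfusion:
    def test_perfect_stratification_all_metrics_one(self):
        """The printed full-cohort confusion table: diagonal 31/8/7."""
        report = report_from_confusion(np.diag([31, 8, 7]), CLASSES)
        assert report.overall_accuracy == 1.0
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            assert np.allclose(report.per_class[metric], 1.0)
            assert report.macro[metric] == 1.0

    def test_one_misplaced_control(self):
        """Age-filtered cohort table: one control called diabetes, 34/35 correct."""
        conf = np.array([[19, 0, 1], [0, 8, 0], [0, 0, 7]])
        report = report_from_confusion(conf, CLASSES)
        assert report.overall_accuracy == pytest.approx(34 / 35)
        assert conf.sum() - np.trace(conf) == 1
        assert report.per_class["sensitivity"][0] == pytest.approx(19 / 20)
        assert report.per_class["ppv"][2] == pytest.approx(7 / 8)

    def test_reversed_two_class_assignment(self):
        real = ["a"] * 3 + ["b"] * 3
        pred = ["b"] * 3 + ["a"] * 3
        report = confusion_matrix(real, pred, class_order=("a", "b"))
        assert report.overall_accuracy == 0.0
        assert np.allclose(report.per_class["sensitivity"], 0.0)

    def test_undefined_ratio_flagged_not_zero(self):
        """A class never predicted has PPV 0/0: NaN with a flag, and the
        macro average skips it instead of counting zero."""
        report = confusion_matrix(["a", "a", "b", "b"], ["a", "a", "a", "a"], class_order=("a", "b"))
        assert np.isnan(report.per_class["ppv"][1])
        assert report.undefined["ppv"][1]
        assert report.macro["ppv"] == pytest.approx(0.5)  # only class a counted

    def test_row_sums_conserve_class_sizes(self):
        rng = np.random.default_rng(0)
        real = rng.choice(["a", "b", "c"], 60)
        pred = rng.choice(["a", "b", "c"], 60)
        report = confusion_matrix(real, pred, class_order=("a", "b", "c"))
        for k, c in enumerate(("a", "b", "c")):
            assert report.confusion[k].sum() == np.sum(real == c)
        assert report.overall_accuracy == np.trace(report.confusion) / 60

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["a"], ["a", "b"], class_order=("a", "b"))
        with pytest.raises(ValueError, match="class_order"):
            confusion_matrix(["a"], ["z"], class_order=("a", "b"))


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson(x, y).r == pytest.approx(0.0, abs=1e-15)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=46)
            y = rng.normal(size=46) + 0.3 * x
            res = pearson(x, y)
            ref_r, ref_p = scipy.stats.pearsonr(x, y)
            assert abs(res.r - ref_r) < 1e-10
            assert abs(res.p - ref_p) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("m, expected", [(2, 1), (4, 6), (6, 15)])
    def test_matrix_entry_counts(self, m, expected):
        rng = np.random.default_rng(m)
        import pandas as pd

        df = pd.DataFrame(rng.normal(size=(20, m)), columns=[f"f{i}" for i in range(m)])
        assert len(correlation_matrix(df)) == expected

    def test_identical_features_r_one(self):
        import pandas as pd

        x = np.arange(1.0, 11.0)
        df = pd.DataFrame({"a": x, "b": x})
        [(f1, f2, res)] = correlation_matrix(df)
        assert res.r == pytest.approx(1.0)


class TestAnova:
    def test_equal_groups_give_zero_f(self):
        values = np.array([1.0, 2.0, 3.0] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        res = anova_oneway(values, groups)
        assert res.F <= 1e-20
        assert res.df_between == 2 and res.df_within == 6

    def test_two_groups_reduce_to_t_squared(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=15) + 0.5
        res = anova_oneway(np.concatenate([x, y]), np.array(["a"] * 12 + ["b"] * 15))
        t, _ = scipy.stats.ttest_ind(x, y)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            vals = [rng.normal(size=rng.integers(5, 15)) + rng.normal() for _ in range(3)]
            values = np.concatenate(vals)
            groups = np.concatenate([[f"g{i}"] * len(v) for i, v in enumerate(vals)])
            res = anova_oneway(values, groups)
            ref = scipy.stats.f_oneway(*vals)
            assert abs(res.F - ref.statistic) < 1e-10
            assert abs(res.p - ref.pvalue) < 1e-10

    def test_synthetic_age_differences_detected(self):
        table = generate_cohort(SyntheticConfig(seed=5, n_metabolites=2))
        res = anova_oneway(table.age, table.groups)
        assert res.df_between == 2 and res.df_within == 43
        assert res.p < 0.05  # 56 vs 67.5 vs 72 year group means


class TestSummaries:
    def test_constant_feature_degenerate_box(self, separable_table):
        t = separable_table
        t2 = generate_cohort(SyntheticConfig(n_per_group=(5, 5), class_names=("a", "b"), n_metabolites=2, seed=0, age_spec=None))
        t2.concentrations[:, 0] = 4.2
        df = summarize_by_group(t2, ["M001"])
        row = df.iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 4.2

    def test_linear_interpolation_quartiles(self):
        t = generate_cohort(SyntheticConfig(n_per_group=(5, 5), class_names=("a", "b"), n_metabolites=1, seed=0, age_spec=None))
        t.concentrations[:5, 0] = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = summarize_by_group(t, ["M001"])
        row = df[df.group == "a"].iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)

    def test_shifted_marker_orders_group_medians(self):
        cfg = SyntheticConfig(
            n_per_group=(20, 20, 20), n_metabolites=3, marker_spec=((1, (1.0, 2.0, 4.0)),), seed=6
        )
        df = summarize_by_group(generate_cohort(cfg), ["M002"])
        med = df.set_index("group")["median"]
        assert med["control"] < med["glaucoma"] < med["diabetes"]


class TestAgeFilter:
    def test_threshold_below_all_is_identity(self):
        t = generate_cohort(SyntheticConfig(seed=7, n_metabolites=2))
        out = age_filter(t, min_age=1.0, restrict_class="control")
        assert out.n_subjects == t.n_subjects

    def test_only_restricted_class_removed(self):
        t = generate_cohort(SyntheticConfig(seed=8, n_metabolites=2))
        cutoff = float(np.sort(t.age[t.groups == "control"])[11])  # drop 11 youngest controls
        out = age_filter(t, min_age=cutoff, restrict_class="control")
        sizes = out.class_sizes()
        assert sizes["glaucoma"] == 8 and sizes["diabetes"] == 7
        assert sizes["control"] == 31 - int(np.sum(t.age[t.groups == "control"] < cutoff))

    def test_emptying_a_class_rejected(self):
        t = generate_cohort(SyntheticConfig(seed=9, n_metabolites=2))
        with pytest.raises(ValueError, match="< 2 subjects"):
            age_filter(t, min_age=200.0, restrict_class="control")


class TestPosteriorTable:
    def test_separated_cohort_all_true_posteriors_high(self, separable_table):
        report, records = loo_evaluate(separable_table, ["M003", "M006"])
        truth = dict(zip(separable_table.subject_ids, separable_table.groups))
        df, summary = posterior_table(records, truth, separable_table.class_names)
        assert report.overall_accuracy == 1.0
        assert summary["true_posterior_gt_half"] == separable_table.n_subjects
        assert len(df) == summary["n"]
        assert np.allclose(df[[f"p_{c}" for c in separable_table.class_names]].sum(axis=1), 1.0)

    def test_boundary_half_not_counted(self):
        rec = PosteriorRecord("s1", np.array([0.5, 0.5]), "a")
        df, summary = posterior_table([rec], {"s1": "a"}, ("a", "b"))
        assert summary["true_posterior_gt_half"] == 0
        assert summary["true_posterior_le_half"] == 1
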