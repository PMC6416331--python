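"""Statistical battery: classical tests against frozen R oracles, type-I
calibration, and the logistic ROC with its rank-based AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from postforce.cohort import (CohortModel, anova_tukey, chi_square,
                              logistic_roc, multivariate_logistic_lr,
                              paired_t, pearson_r, rank_auc, shapiro_wilk,
                              unpaired_t)
from postforce.synthetic import (CohortSpec, GroupSpec, binormal_auc,
                                 generate_cohort)

# Fixed fixture samples; expected values frozen from an independent R run
# (t.test, aov/TukeyHSD, shapiro.test, cor.test, chisq.test, glm-binomial).
SAMPLE_A = np.array([112.725, 104.097, 91.03, 121.714, 99.87, 91.675, 53.522,
                     111.021, 81.504, 88.743, 121.753, 95.982])
SAMPLE_B = np.array([94.535, 84.329, 79.549, 121.971, 90.343, 97.626, 40.779,
                     123.855, 56.15, 74.866, 110.825, 100.582])
SAMPLE_C = np.array([93.905, 69.802, 83.843, 124.497, 112.385, 78.919,
                     127.978, 83.834, 79.366, 74.317])


class TestAgainstReferenceImplementation:
    def test_paired_t(self):
        out = paired_t(SAMPLE_A, SAMPLE_B)
        assert out["t"] == pytest.approx(2.445595006569, abs=1e-8)
        assert out["p"] == pytest.approx(0.032498696654, abs=1e-8)

    def test_unpaired_t(self):
        out = unpaired_t(SAMPLE_A, SAMPLE_C)
        assert out["t"] == pytest.approx(0.573875323745, abs=1e-8)
        assert out["p"] == pytest.approx(0.572450114185, abs=1e-8)

    def test_anova_f_and_tukey(self):
        out = anova_tukey({"a": SAMPLE_A, "b": SAMPLE_B, "c": SAMPLE_C})
        assert out["F"] == pytest.approx(0.427712298267, abs=1e-8)
        assert out["p"] == pytest.approx(0.655788178691, abs=1e-8)
        assert out["tukey"][("a", "b")] == pytest.approx(0.632327849946, abs=1e-4)
        assert out["tukey"][("a", "c")] == pytest.approx(0.858884337624, abs=1e-4)
        assert out["tukey"][("b", "c")] == pytest.approx(0.934887272344, abs=1e-4)

    def test_shapiro_wilk(self):
        out = shapiro_wilk(SAMPLE_A)
        assert out["W"] == pytest.approx(0.928100364221, abs=1e-6)
        assert out["p"] == pytest.approx(0.360411776444, abs=1e-6)

    def test_pearson(self):
        out = pearson_r(SAMPLE_A, SAMPLE_B)
        assert out["r"] == pytest.approx(0.891799310240, abs=1e-8)
        assert out["p"] == pytest.approx(0.000097146923, abs=1e-8)

    def test_chi_square(self):
        out = chi_square([[13, 7], [5, 15]])
        assert out["chi2"] == pytest.approx(6.464646464646, abs=1e-8)
        assert out["p"] == pytest.approx(0.011004153177, abs=1e-8)

    def test_logistic_slope(self):
        df = pd.DataFrame({
            "force_nN": np.r_[SAMPLE_A, SAMPLE_C],
            "transfused": np.r_[np.ones(12, int), np.zeros(10, int)],
        })
        roc = logistic_roc(df)
        assert roc.slope == pytest.approx(0.013447319818, abs=1e-7)
        assert roc.intercept == pytest.approx(-1.099850738550, abs=1e-6)


class TestDegenerateInputs:
    def test_identical_paired_samples(self):
        out = paired_t(SAMPLE_A, SAMPLE_A)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_difference_flagged_degenerate(self):
        out = paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert out["degenerate"]
        assert out["p"] <= np.finfo(float).tiny

    def test_broken_pairing_lists_keys(self):
        with pytest.raises(ValueError, match="d2"):
            paired_t([1.0, 2.0], [3.0, 4.0],
                     pairing=(["d1", "d3"], ["d1", "d2"]))

    def test_anova_identical_constant_groups(self):
        out = anova_tukey([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert out["degenerate"] and out["F"] == 0.0

    def test_anova_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_tukey([[1.0], [1.0, 2.0], [3.0, 4.0]])

    def test_anova_needs_three_groups(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], [3.0, 4.0]])

    def test_pearson_perfect_correlation(self):
        assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4])["r"] == pytest.approx(1.0)

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_chi_square_uniform_table(self):
        out = chi_square([[10, 10], [10, 10]])
        assert out["chi2"] == 0.0 and out["p"] == 1.0

    def test_shapiro_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0, 2.0, 2.0])


class TestTypeIErrorCalibration:
    """Null rejection rates at alpha = 0.05 stay within 5% +/- 2% over
    1,000 replicates."""

    def test_paired_t_null(self):
        rng = np.random.default_rng(10)
        rejects = sum(paired_t(rng.normal(0, 1, 20), rng.normal(0, 1, 20))["p"]
                      < 0.05 for _ in range(1000))
        assert 30 <= rejects <= 70

    def test_anova_null(self):
        rng = np.random.default_rng(11)
        rejects = 0
        for _ in range(1000):
            g = [rng.normal(0, 1, 15) for _ in range(3)]
            from scipy.stats import f_oneway
            rejects += f_oneway(*g)[1] < 0.05
        assert 30 <= rejects <= 70

    def test_shapiro_null(self):
        rng = np.random.default_rng(12)
        rejects = sum(shapiro_wilk(rng.normal(0, 1, 50))["p"] < 0.05
                      for _ in range(1000))
        assert 30 <= rejects <= 70

    def test_tukey_flags_only_true_differences(self):
        """Groups with means 0, 0, 5 (sd 1, n 20): only the two contrasts
        with the shifted group reject, in >=95% of replicates."""
        rng = np.random.default_rng(13)
        good = 0
        n_rep = 100
        for _ in range(n_rep):
            out = anova_tukey({"g1": rng.normal(0, 1, 20),
                               "g2": rng.normal(0, 1, 20),
                               "g3": rng.normal(5, 1, 20)})
            tk = out["tukey"]
            correct = (tk[("g1", "g3")] < 0.05 and tk[("g2", "g3")] < 0.05
                       and tk[("g1", "g2")] >= 0.05)
            good += correct
        # family-wise control keeps the g1-g2 false-flag rate ~2%
        assert good >= 0.95 * n_rep


class TestRankAuc:
    def test_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0, 1, 60)          # continuous -> tie-free
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1                 # ensure both classes
        u = mannwhitneyu(x[y == 1], x[y == 0]).statistic
        assert rank_auc(x, y) == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()),
                                               abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(21)
        x = rng.normal(50, 10, 80)
        y = (rng.uniform(size=80) < 0.3).astype(int)
        y[:2] = [0, 1]
        base = rank_auc(x, y)
        for f in (np.exp, lambda v: v**3, lambda v: np.log(v - v.min() + 1)):
            assert rank_auc(f(x), y) == pytest.approx(base, abs=1e-12)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 4000)
        y = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        assert rank_auc(x, y) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([1.0, 2.0], [1, 1])


class TestLogisticRoc:
    def _two_class(self, rng, n1=40, n0=60, shift=0.0):
        return pd.DataFrame({
            "force_nN": np.r_[rng.normal(100 + shift, 10, n1),
                              rng.normal(100, 10, n0)],
            "transfused": np.r_[np.ones(n1, int), np.zeros(n0, int)],
        })

    def test_separated_classes_auc_one_with_warning(self):
        df = pd.DataFrame({"force_nN": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                           "transfused": [0, 0, 0, 1, 1, 1]})
        with pytest.warns(UserWarning, match="separates"):
            roc = logistic_roc(df)
        assert roc.auc == 1.0 and roc.separation_warning

    def test_single_class_rejected(self):
        df = pd.DataFrame({"force_nN": [1.0, 2.0], "transfused": [1, 1]})
        with pytest.raises(ValueError):
            logistic_roc(df)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(30)
        roc = logistic_roc(self._two_class(rng, shift=6.0))
        assert np.all(np.diff(roc.curve[:, 0]) >= 0)
        assert np.all(np.diff(roc.curve[:, 1]) >= 0)
        assert roc.curve[0] == pytest.approx([0.0, 0.0])
        assert roc.curve[-1] == pytest.approx([1.0, 1.0])

    def test_unit_odds_ratio_consistency(self):
        rng = np.random.default_rng(31)
        roc = logistic_roc(self._two_class(rng, shift=-5.0))
        assert roc.unit_odds_ratio == pytest.approx(np.exp(roc.slope), rel=1e-12)
        assert roc.percent_odds_change == pytest.approx(
            100 * (1 - roc.unit_odds_ratio), rel=1e-12)

    def test_replicate_mean_auc_matches_binormal_oracle(self):
        """Mean empirical AUC over 200 trauma-sized cohorts agrees with the
        closed-form two-normal value within 0.02."""
        groups = (GroupSpec("trauma_transfused", 82.8, 40.5, 17, 1),
                  GroupSpec("trauma_not_transfused", 122.9, 60.1, 93, 0))
        aucs = []
        for seed in range(200):
            df = generate_cohort(CohortSpec(groups=groups,
                                            with_covariates=False, seed=seed))
            aucs.append(logistic_roc(df).auc)
        oracle = binormal_auc(82.8, 40.5, 122.9, 60.1)
        assert np.mean(aucs) == pytest.approx(oracle, abs=0.02)


class TestMultivariateLogistic:
    def _cohort(self, rng, n=120, force_effect=-0.02):
        force = rng.normal(110, 50, n).clip(1)
        hct = rng.normal(0.40, 0.05, n)
        fluids = rng.integers(0, 2, n)
        logit = 1.0 + force_effect * force
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        if y.sum() in (0, n):
            y[:2] = [0, 1]
        return pd.DataFrame({"force_nN": force, "hematocrit": hct,
                             "prehospital_fluids": fluids, "transfused": y})

    def test_null_covariate_lr_calibrated(self):
        """An outcome-independent covariate's LR test rejects at ~5% over
        500 null replicates."""
        rng = np.random.default_rng(40)
        rejects = 0
        for _ in range(500):
            df = self._cohort(rng)
            out = multivariate_logistic_lr(df, ["force_nN", "hematocrit"])
            rejects += out["effects"]["hematocrit"]["p"] < 0.05
        assert 0.03 * 500 <= rejects <= 0.07 * 500

    def test_duplicated_covariate_rank_deficient(self):
        rng = np.random.default_rng(41)
        df = self._cohort(rng)
        df["force_copy"] = df["force_nN"]
        with pytest.raises(ValueError, match="rank"):
            multivariate_logistic_lr(df, ["force_nN", "force_copy"])

    def test_force_dominates_when_it_drives_outcome(self):
        """When only force determines the outcome, its LR p-value beats the
        noise covariates' in >=95% of replicates."""
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(50):
            df = self._cohort(rng, force_effect=-0.03)
            out = multivariate_logistic_lr(df)
            e = out["effects"]
            wins += (e["force_nN"]["p"] < e["hematocrit"]["p"]
                     and e["force_nN"]["p"] < e["prehospital_fluids"]["p"])
        assert wins >= 47

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(43)
        df = self._cohort(rng)
        df.loc[:4, "hematocrit"] = np.nan
        out = multivariate_logistic_lr(df)
        assert out["n_dropped"] == 5 and out["n"] == len(df) - 5


class TestCohortModel:
    def test_summary_reports_group_means_anova_and_roc(self, trauma_cohort):
        res = CohortModel(trauma_cohort).fit()
        text = res.summary()
        assert "One-way ANOVA" in text and "AUC" in text
        gs = res.group_summary
        assert gs.loc["healthy", "n"] == 10
        assert gs.loc["trauma_transfused", "mean_nN"] == pytest.approx(82.8, abs=25)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            CohortModel(pd.DataFrame({"x": [1]}))

    def test_single_group_skips_anova(self):
        df = pd.DataFrame({"force_nN": np.arange(1.0, 11.0),
                           "group": ["g"] * 10,
                           "transfused": [0, 1] * 5})
        res = CohortModel(df).fit()
        assert res.anova is None and res.roc is not None

    def test_constant_outcome_skips_roc(self):
        df = pd.DataFrame({"force_nN": np.arange(1.0, 11.0),
                           "group": ["a"] * 5 + ["b"] * 5,
                           "transfused": [0] * 10})
        res = CohortModel(df).fit()
        assert res.roc is None


def test_roc_plot_has_curve_and_diagonal(trauma_cohort):
    import matplotlib
    matplotlib.use("Agg")
    roc = logistic_roc(trauma_cohort[trauma_cohort.group != "healthy"])
    ax = roc.plot()
    assert len(ax.lines) == 2
    assert "AUC" in ax.get_legend().get_texts()[0].get_text()
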