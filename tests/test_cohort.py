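"""Cohort statistics: stratification, balancing, folds, models and tables."""

import numpy as np
import pandas as pd
import pytest

from swaylab.cohort import (
    age_prediction,
    balance_by_age,
    correlation_table,
    group_difference_tests,
    interleave_and_fold,
    rq_cohort_analysis,
    sex_classification_cv,
    stratify_age_groups,
)
from swaylab.exceptions import BalanceError, InputError, SwaylabError


class TestStratify:
    @pytest.mark.parametrize(
        "age,group", [(65, 1), (69, 1), (70, 2), (74, 2), (79, 3), (84, 4),
                      (85, 5), (95, 5)]
    )
    def test_bin_boundaries(self, age, group):
        assert stratify_age_groups([age])[0] == group

    def test_below_range_rejected(self):
        with pytest.raises(SwaylabError):
            stratify_age_groups([64])


def _metadata(n_m, n_f, rng, ages_m=None, ages_f=None):
    ages_m = rng.integers(65, 96, n_m) if ages_m is None else ages_m
    ages_f = rng.integers(65, 96, n_f) if ages_f is None else ages_f
    return pd.DataFrame(
        {
            "sex": ["male"] * n_m + ["female"] * n_f,
            "age": np.concatenate([ages_m, ages_f]),
        }
    )


class TestBalanceByAge:
    def test_equal_totals_and_strata(self):
        rng = np.random.default_rng(0)
        ages_m = rng.integers(65, 96, 200)
        # every male age duplicated among the females guarantees feasibility
        ages_f = np.concatenate([ages_m, rng.integers(65, 96, 100)])
        df = _metadata(200, 300, rng, ages_m=ages_m, ages_f=ages_f)
        out = balance_by_age(df, seed=1)
        g = out.groupby(
            [out.sex, stratify_age_groups(out.age.to_numpy())]
        ).size().unstack()
        assert (g.loc["male"] == g.loc["female"]).all()
        assert (out.sex == "male").sum() == (out.sex == "female").sum()

    def test_already_balanced_noop(self):
        rng = np.random.default_rng(1)
        ages = rng.integers(65, 96, 50)
        df = _metadata(50, 50, rng, ages_m=ages, ages_f=ages.copy())
        out = balance_by_age(df, seed=2)
        assert len(out) == 100

    def test_short_stratum_raises(self):
        df = _metadata(5, 2, np.random.default_rng(2),
                       ages_m=np.full(5, 66), ages_f=np.full(2, 66))
        with pytest.raises(BalanceError):
            balance_by_age(df, seed=3)

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(3)
        df = _metadata(100, 180, rng)
        a = balance_by_age(df, seed=9)
        b = balance_by_age(df, seed=9)
        assert a.index.equals(b.index)


class TestInterleaveAndFold:
    def test_exact_division(self):
        rng = np.random.default_rng(4)
        df = _metadata(20, 20, rng)
        folds = interleave_and_fold(df, k=10, seed=1)
        for f in range(10):
            sub = df[folds == f]
            assert (sub.sex == "male").sum() == 2
            assert (sub.sex == "female").sum() == 2

    def test_partition_with_leftovers(self):
        rng = np.random.default_rng(5)
        df = _metadata(25, 25, rng)
        folds = interleave_and_fold(df, k=10, seed=2)
        assert (folds == -1).sum() == 2 * 5  # 5 leftover pairs stay in training
        covered = [set(df.index[folds == f]) for f in range(10)]
        union = set().union(*covered)
        assert len(union) == sum(len(c) for c in covered)  # pairwise disjoint
        assert union | set(df.index[folds == -1]) == set(df.index)

    def test_unequal_counts_rejected(self):
        df = _metadata(10, 12, np.random.default_rng(6))
        with pytest.raises(InputError):
            interleave_and_fold(df, seed=0)


def _feature_table(n, rng, sex_effect=0.0):
    sex = np.array(["male", "female"])[rng.integers(0, 2, n)]
    shift = np.where(sex == "male", sex_effect, 0.0)
    return pd.DataFrame(
        {
            "sex": sex,
            "age": rng.integers(65, 96, n),
            "cy": np.exp(rng.normal(-1.2 + shift, 0.3, n)),
            "m_my": np.exp(rng.normal(-1.0 + shift, 0.3, n)),
            "zcr_y": np.exp(rng.normal(2.9, 0.2, n)),
            "zcr_vx": np.exp(rng.normal(4.9, 0.2, n)),
            "cri_t": np.exp(rng.normal(0.0, 0.2, n)),
            "st_n": np.exp(rng.normal(4.9, 0.4, n)),
        }
    )


class TestSexClassification:
    def test_null_features_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        df = _feature_table(400, rng, sex_effect=0.0)
        df = df.groupby("sex").head(min((df.sex == "male").sum(),
                                        (df.sex == "female").sum()))
        folds = interleave_and_fold(df, k=10, seed=1)
        rep = sex_classification_cv(df, folds, seed=1)
        n_test = (folds >= 0).sum()
        band = 3 * 100.0 * np.sqrt(0.25 / n_test)
        assert abs(rep.mean_accuracy - 50.0) < band

    def test_separable_feature_gives_high_accuracy(self):
        rng = np.random.default_rng(8)
        df = _feature_table(200, rng)
        df["cy"] = np.where(df.sex == "male", 2.0, 0.5) * np.exp(
            rng.normal(0, 0.01, len(df))
        )
        df = df.groupby("sex").head(min((df.sex == "male").sum(),
                                        (df.sex == "female").sum()))
        folds = interleave_and_fold(df, k=5, seed=2)
        rep = sex_classification_cv(df, folds, seed=2)
        assert rep.mean_accuracy > 95.0
        assert rep.confusion["male_as_female"] + rep.confusion[
            "female_as_male"
        ] + rep.confusion["male_correct"] + rep.confusion[
            "female_correct"
        ] == (folds >= 0).sum()

    def test_calibrated_cohort_beats_permutation_null(self, cohort_features):
        df = cohort_features.copy().reset_index(drop=True)
        folds = interleave_and_fold(df, k=10, seed=3)
        real = sex_classification_cv(df, folds, seed=3)
        n_test = (folds >= 0).sum()
        null_975 = 50.0 + 1.96 * 100.0 * np.sqrt(0.25 / n_test)
        assert real.mean_accuracy > null_975


class TestAgePrediction:
    def _exact_table(self, rng, n=400, noise_sd=0.0):
        df = _feature_table(n, rng)
        X = np.log(df[["cy", "zcr_y", "cri_t", "st_n"]].to_numpy())
        age = 75 + 3.0 * X[:, 0] - 2.0 * X[:, 1] + 4.0 * X[:, 2] - 1.5 * X[:, 3]
        df["age"] = age + rng.normal(0, noise_sd, n)
        return df

    def test_noiseless_linear_recovery(self):
        df = self._exact_table(np.random.default_rng(9))
        rep = age_prediction(df, model="linear", seed=1)
        assert rep.r_squared > 0.999
        assert rep.cv_residual_sd < 0.05

    def test_known_noise_recovery(self):
        df = self._exact_table(np.random.default_rng(10), n=600, noise_sd=5.0)
        rep = age_prediction(df, model="linear", seed=2)
        assert rep.cv_residual_sd == pytest.approx(5.0, abs=0.5)

    def test_uninformative_features_null_model(self):
        rng = np.random.default_rng(11)
        df = _feature_table(600, rng)  # ages independent of features
        rep = age_prediction(df, model="linear", seed=3)
        assert rep.r_squared < 0.03
        assert rep.cv_residual_sd == pytest.approx(df.age.std(), rel=0.1)

    def test_tree_model_runs(self):
        df = self._exact_table(np.random.default_rng(12), noise_sd=5.0)
        rep = age_prediction(df, model="tree", seed=4)
        assert rep.model_type == "tree"
        assert rep.cv_residual_sd > 0


class TestGroupDifferences:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(13)
        base = _feature_table(300, rng)
        males = base.copy()
        males["sex"] = "male"
        females = base.copy()
        females["sex"] = "female"
        table = group_difference_tests(
            pd.concat([males, females], ignore_index=True), "sex_within_age_group"
        )
        assert (table.indicators.fillna(0) == 0).all().all()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(14)
        df = _feature_table(600, rng)
        df["age"] = rng.integers(65, 75, len(df))  # groups 1 and 2 only
        sd = df.loc[:, "cy"].std()
        df.loc[df.sex == "male", "cy"] += 5 * sd
        table = group_difference_tests(df, "sex_within_age_group")
        assert table.indicators.loc["1", "cy"] == 1
        assert table.indicators.loc["2", "cy"] == 1

    def test_successive_age_groups_shape(self):
        rng = np.random.default_rng(15)
        df = _feature_table(500, rng)
        table = group_difference_tests(df, "successive_age_groups", sex="female")
        assert list(table.indicators.index) == ["1-2", "2-3", "3-4", "4-5"]
        assert table.indicators.shape == (4, 6)


class TestCorrelationTable:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(16)
        mat = correlation_table(_feature_table(200, rng))
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(17)
        mat = correlation_table(_feature_table(2000, rng))
        off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
        # drop the built-in m_my/cy sex coupling rows? columns are independent
        assert np.mean(np.abs(off) < 0.05) > 0.80

    def test_calibrated_cohort_sign_pattern(self, cohort_features):
        mat = correlation_table(cohort_features)
        assert mat.loc["cy", "st_n"] < 0
        assert mat.loc["cy", "age"] > 0


class TestRombergBattery:
    def _rq_table(self, rng, n=400, sex_effect=0.0, shared_latent=True):
        sex = np.array(["male", "female"])[rng.integers(0, 2, n)]
        latent = np.exp(rng.normal(0.2, 0.3, n))
        noise = 0.05 if shared_latent else 0.5
        return pd.DataFrame(
            {
                "sex": sex,
                "age": rng.integers(65, 96, n),
                "rq_path": latent * np.exp(rng.normal(
                    np.where(sex == "male", sex_effect, 0.0), noise, n)),
                "rq_velocity": latent * np.exp(rng.normal(0, noise, n)),
            }
        )

    def test_no_sex_signal_chance_accuracy(self):
        rng = np.random.default_rng(18)
        rep = rq_cohort_analysis(self._rq_table(rng))
        assert abs(rep["logistic_sex_accuracy_pct"] - 50.0) < 10.0

    def test_shared_latent_high_correlation(self):
        rng = np.random.default_rng(19)
        rep = rq_cohort_analysis(self._rq_table(rng, shared_latent=True))
        assert rep["rq_correlation"] > 0.9

    def test_sex_shift_detected(self):
        rng = np.random.default_rng(20)
        rep = rq_cohort_analysis(self._rq_table(rng, sex_effect=0.6))
        assert rep["sex_ranksum_p"]["path"] < 0.001
        assert rep["logistic_sex_accuracy_pct"] > 60.0

    def test_identical_age_groups_anova_not_significant(self):
        rng = np.random.default_rng(21)
        rep = rq_cohort_analysis(self._rq_table(rng))
        assert rep["age_group_anova"]["velocity"]["p"] > 0.01
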