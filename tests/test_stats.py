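"""Mixed-model inference, contrasts, classification, behaviour prediction."""

import numpy as np
import pandas as pd
import pytest

from tonescene.stats import (
    GroupConditionModel,
    classify_diagnosis,
    per_condition_contrast,
    predict_behavior,
    residualize_age,
)


def _long_table(y, groups, conditions=(6, 12, 18)):
    """y: (n_subjects, n_conditions) -> long-format table."""
    rows = []
    for i, (row, g) in enumerate(zip(y, groups)):
        for j, n in enumerate(conditions):
            rows.append(
                {"participant_id": f"s{i}", "group": g, "condition_N": n,
                 "combined_z": row[j]}
            )
    return pd.DataFrame(rows)


def _toy_table():
    rng = np.random.default_rng(42)
    n_per = 6
    y = np.zeros((2 * n_per, 3))
    groups = []
    for i in range(2 * n_per):
        g = "TD" if i < n_per else "ASD"
        slope = 0.8 if g == "TD" else 0.2
        subj = rng.normal(0, 0.7)
        y[i] = 1.0 + slope * np.arange(3) + subj + rng.normal(0, 0.4, 3)
        groups.append(g)
    return _long_table(y, groups)


class TestGroupConditionModel:
    def test_matches_textbook_mixed_anova(self):
        """Balanced two-group repeated-measures table: F statistics agree
        with an independently computed classical mixed ANOVA to 1e-6."""
        import pingouin as pg

        tab = _toy_table()
        res = GroupConditionModel(tab, "combined_z").fit()
        ref = pg.mixed_anova(
            data=tab, dv="combined_z", within="condition_N",
            subject="participant_id", between="group",
        ).set_index("Source")
        assert res.f_group == pytest.approx(ref.loc["group", "F"], abs=1e-6)
        assert res.f_condition == pytest.approx(ref.loc["condition_N", "F"], abs=1e-6)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], abs=1e-6)
        assert res.p_interaction == pytest.approx(ref.loc["Interaction", "p_unc"], abs=1e-9)

    def test_hand_computed_sums_of_squares(self):
        """Tiny table checked against explicit stratum sums of squares."""
        y = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 3.0, 3.0], [4.0, 4.0, 4.0]])
        groups = ["A", "A", "B", "B"]
        res = GroupConditionModel(_long_table(y, groups)).fit()
        # between stratum: subject means (2,3,3,4); group means 2.5, 3.5
        # SS_group = 3 * (2*(2.5-3)^2 + 2*(3.5-3)^2) = 3; SS_subj = 3*(4*0.25)=3
        assert res.f_group == pytest.approx((3.0 / 1.0) / (3.0 / 2.0))
        # within stratum: A rows rise 1/step, B rows flat
        assert res.f_interaction > 1e20  # zero residual: perfect interaction

    def test_degrees_of_freedom_at_study_size(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((47, 3))
        groups = ["TD"] * 26 + ["ASD"] * 21
        res = GroupConditionModel(_long_table(y, groups)).fit()
        assert res.df_group == (1, 45)
        assert res.df_interaction == (2, 90)

    def test_no_subject_structure_gives_zero_variance_component(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((40, 3)) * 0.01
        y += np.array([0.0, 0.0, 0.0])  # no participant offsets beyond noise
        # force subject means equal within group so the participant
        # variance component collapses to its floor at zero
        y -= y.mean(axis=1, keepdims=True)
        res = GroupConditionModel(_long_table(y, ["A"] * 20 + ["B"] * 20)).fit()
        assert res.var_participant == 0.0

    def test_unbalanced_falls_back_to_permutation(self):
        tab = _toy_table().iloc[:-1]  # drop one cell
        with pytest.warns(UserWarning, match="unbalanced"):
            res = GroupConditionModel(tab, "combined_z").fit(n_permutations=99, seed=1)
        assert res.method.startswith("permutation")
        assert 0.0 <= res.p_interaction <= 1.0

    def test_summary_mentions_all_effects(self):
        s = GroupConditionModel(_toy_table()).fit().summary()
        for token in ("group x condition", "participant var", "F"):
            assert token in s


class TestContrast:
    def test_hand_computed_toy(self):
        tab = _long_table(
            np.array([[1.0] * 3, [2.0] * 3, [3.0] * 3, [4.0] * 3, [5.0] * 3, [6.0] * 3]),
            ["A", "A", "A", "B", "B", "B"],
        )
        t, p, df = per_condition_contrast(tab, 12)
        assert t == pytest.approx(-3.674, abs=0.001)
        assert p == pytest.approx(0.0213, abs=0.001)
        assert df == 4

    def test_identical_groups(self):
        tab = _long_table(np.ones((6, 3)), ["A"] * 3 + ["B"] * 3)
        t, p, _ = per_condition_contrast(tab, 6)
        assert t == 0.0 and p == 1.0

    def test_study_size_df(self):
        rng = np.random.default_rng(2)
        tab = _long_table(rng.standard_normal((47, 3)), ["TD"] * 26 + ["ASD"] * 21)
        _, _, df = per_condition_contrast(tab, 18)
        assert df == 45

    def test_empty_group_rejected(self):
        tab = _long_table(np.ones((3, 3)), ["A"] * 3)
        with pytest.raises(ValueError):
            per_condition_contrast(tab, 6)


class TestClassifier:
    def _features(self, n=47, separated=True, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array(["TD"] * 26 + ["ASD"] * (n - 26))
        x = rng.standard_normal((n, 2)) * 0.1
        if separated:
            x[y == "TD"] += 3.0
        return pd.DataFrame(x, columns=["combined_z", "gamma_logratio"]), pd.Series(y)

    def test_separable_is_perfect(self):
        X, y = self._features(separated=True)
        res = classify_diagnosis(X, y, seed=0)
        assert res.mean_accuracy_pct == 100.0

    def test_permuted_labels_at_chance(self):
        X, y = self._features(separated=True, seed=1)
        perm = pd.Series(np.random.default_rng(3).permutation(y.values))
        res = classify_diagnosis(X, perm, seed=4)
        assert 40.0 <= res.mean_accuracy_pct <= 60.0

    def test_reproducible_and_bootstrap_scheme(self):
        X, y = self._features()
        a = classify_diagnosis(X, y, seed=7)
        b = classify_diagnosis(X, y, seed=7)
        np.testing.assert_array_equal(a.accuracies_pct, b.accuracies_pct)
        c = classify_diagnosis(X, y, seed=7, scheme="bootstrap")
        assert c.scheme == "bootstrap"
        assert len(c.accuracies_pct) == 50

    def test_single_class_rejected(self):
        X, _ = self._features()
        with pytest.raises(ValueError):
            classify_diagnosis(X, pd.Series(["TD"] * len(X)), seed=0)


class TestBehaviorPrediction:
    def test_noiseless_linear_r_is_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"combined_z": rng.standard_normal(21), "gamma_logratio": rng.standard_normal(21)}
        )
        df["srs_sci"] = 70 - 5 * df["combined_z"] + 2 * df["gamma_logratio"]
        res = predict_behavior(df, "srs_sci", ("combined_z", "gamma_logratio"))
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_r_equals_multiple_correlation(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((21, 3)), columns=["a", "b", "y"])
        res = predict_behavior(df, "y", ("a", "b"))
        ols = sm.OLS(df["y"], sm.add_constant(df[["a", "b"]])).fit()
        assert res.r == pytest.approx(np.sqrt(ols.rsquared), abs=1e-9)

    def test_null_in_sample_bias_is_positive(self):
        """With an outcome independent of the features, the in-sample r is
        optimistically biased at n=21 (documented behaviour)."""
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(200):
            df = pd.DataFrame(rng.standard_normal((21, 3)), columns=["a", "b", "y"])
            rs.append(predict_behavior(df, "y", ("a", "b")).r)
        assert 0.2 < np.mean(rs) < 0.45

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            predict_behavior(df, "y", ("a",))


class TestResidualizeAge:
    def test_residuals_uncorrelated_with_age(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(7, 17, 21)
        scores = 20 - 0.5 * ages + rng.standard_normal(21)
        resid = residualize_age(scores, ages)
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10

    def test_perfectly_linear_toy(self):
        resid = residualize_age([10.0, 20.0, 30.0], [8.0, 10.0, 12.0])
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_age_independent_scores_centred(self):
        ages = np.array([8.0, 10.0, 12.0, 14.0])
        scores = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centred age
        np.testing.assert_allclose(residualize_age(scores, ages), scores, atol=1e-12)

    def test_constant_age_warns_and_centres(self):
        with pytest.warns(UserWarning, match="constant age"):
            resid = residualize_age([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])
        np.testing.assert_allclose(resid, [-1.0, 0.0, 1.0])
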