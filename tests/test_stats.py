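"""Correlation, regression with elimination, and canonical discriminant analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from weedsense import stats
from weedsense.stats import (cda_classify, cda_fit, cda_transform,
                             confusion_percentages, multiple_regression, pearson,
                             simple_regression)


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        r = pearson(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=500)
        assert pearson(z[:, 0], z[:, 1]).r == pytest.approx(0.8, abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSimpleRegression:
    def test_exact_line_through_origin(self):
        x = np.arange(1.0, 8.0)
        res = simple_regression(x, 3.5 * x, through_origin=True)
        assert res.slope == pytest.approx(3.5) and res.r_squared == pytest.approx(1.0)
        assert res.intercept == 0.0

    def test_exact_affine_free_fit(self):
        x = np.arange(1.0, 8.0)
        res = simple_regression(x, 2.0 * x + 5.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(5.0)

    def test_through_origin_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 50)
        y = 1.7 * x + rng.normal(0, 0.3, 50)
        res = simple_regression(x, y, through_origin=True)
        assert res.slope == pytest.approx(np.sum(x * y) / np.sum(x * x), abs=1e-12)

    def test_fixed_intercept_option(self):
        x = np.arange(1.0, 6.0)
        y = 2.0 * x + 4.0
        res = simple_regression(x, y, fixed_intercept=4.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == 4.0


class TestMultipleRegression:
    def test_noiseless_fit_is_exact(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": rng.normal(0, 1, 50), "x2": rng.normal(0, 1, 50)})
        df["y"] = 0.3 * df.x1 + 0.4 * df.x2
        res = multiple_regression(df, "y", ["x1", "x2"])
        assert res.table.loc["x1", "coef"] == pytest.approx(0.3, abs=1e-10)
        assert res.table.loc["x2", "coef"] == pytest.approx(0.4, abs=1e-10)
        assert res.adj_r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.excluded == []

    def test_standardized_coefficient_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x1": rng.normal(0, 3, 200), "x2": rng.normal(0, 0.5, 200)})
        df["y"] = df.x1 - 2 * df.x2 + rng.normal(0, 1, 200)
        res = multiple_regression(df, "y", ["x1", "x2"], alpha_drop=None)
        for name in ("x1", "x2"):
            expected = res.table.loc[name, "coef"] * df[name].std() / df["y"].std()
            assert res.table.loc[name, "std_coef"] == pytest.approx(expected, rel=1e-10)

    def test_residuals_orthogonal_to_retained_predictors(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x1": rng.normal(0, 1, 100), "x2": rng.normal(0, 1, 100)})
        df["y"] = df.x1 + rng.normal(0, 1, 100)
        res = multiple_regression(df, "y", ["x1", "x2"], alpha_drop=None)
        for name in ("x1", "x2"):
            assert abs(np.sum(res.resid * df[name])) < 1e-8

    def test_noise_predictor_usually_eliminated(self):
        excluded = 0
        for rep in range(30):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame({"x1": rng.normal(0, 1, 300),
                               "x2": rng.normal(0, 1, 300),
                               "x3": rng.normal(0, 1, 300)})
            df["y"] = 0.5 * df.x1 + 0.5 * df.x2 + rng.normal(0, 1, 300)
            res = multiple_regression(df, "y", ["x1", "x2", "x3"], alpha_drop=0.10)
            excluded += "x3" in res.excluded
        # the rule retains a null predictor with prob ~ alpha_drop
        assert excluded >= 24

    def test_collinear_design_names_offenders(self):
        df = pd.DataFrame({"x1": np.arange(30.0), "x2": 2 * np.arange(30.0)})
        df["y"] = df.x1 + np.random.default_rng(0).normal(0, 1, 30)
        with pytest.raises(ValueError, match="x1"):
            multiple_regression(df, "y", ["x1", "x2"])


def _two_group_frame(rng, n0=40, n1=35, delta=(1.0, 0.5, 0.0), p=3):
    X = np.vstack([rng.normal(0, 1, (n0, p)), rng.normal(0, 1, (n1, p)) + delta])
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    df["g"] = ["a"] * n0 + ["b"] * n1
    return df


class TestCDA:
    def test_two_group_direction_matches_fisher_closed_form(self):
        rng = np.random.default_rng(10)
        df = _two_group_frame(rng)
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        X = df[["f0", "f1", "f2"]].to_numpy()
        g = df["g"].to_numpy()
        Sw = sum((X[g == lab] - X[g == lab].mean(0)).T @ (X[g == lab] - X[g == lab].mean(0))
                 for lab in ("a", "b"))
        fisher = np.linalg.solve(Sw, X[g == "a"].mean(0) - X[g == "b"].mean(0))
        v = model.coef[:, 0]
        cos = abs(fisher @ v) / (np.linalg.norm(fisher) * np.linalg.norm(v))
        assert 1.0 - cos < 1e-8

    def test_identical_group_means_give_zero_eigenvalues(self):
        rng = np.random.default_rng(11)
        df = _two_group_frame(rng, delta=(0.0, 0.0, 0.0))
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        assert model.eigenvalues.max() < 0.2  # sampling noise only

    def test_axis_count_bounded_by_rank(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (80, 2))
        df = pd.DataFrame(X, columns=["f0", "f1"])
        df["g"] = np.repeat(["a", "b", "c", "d"], 20)
        df.loc[df.g == "b", "f0"] += 2
        df.loc[df.g == "c", "f1"] += 2
        df.loc[df.g == "d", "f0"] -= 2
        model = cda_fit(df, "g", ["f0", "f1"])
        assert model.coef.shape[1] == 2  # min(groups-1, features)

    def test_record_at_centroid_classified_to_its_group(self):
        rng = np.random.default_rng(13)
        df = _two_group_frame(rng, delta=(3.0, 0.0, 0.0))
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        # build a record projecting exactly onto group b's centroid
        coef = model.coef[:, 0]
        rec = pd.DataFrame({"f0": [model.centroids[1, 0] / coef[0]], "f1": [0.0],
                            "f2": [0.0]})
        assert cda_classify(model, rec)[0] == "b"

    def test_well_separated_groups_fully_recovered(self):
        rng = np.random.default_rng(14)
        df = _two_group_frame(rng, n0=100, n1=100, delta=(10.0, 0.0, 0.0))
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        pred = cda_classify(model, df)
        assert (pred == df["g"].to_numpy()).all()

    def test_equidistant_tie_goes_to_first_label(self):
        # mirror-symmetric groups about f0 = 0; the probe sits exactly between
        df = pd.DataFrame({"f0": [-1.2, -0.8, 1.2, 0.8], "f1": [0.0, 1.0, 0.0, 1.0],
                           "g": ["a", "a", "b", "b"]})
        model = cda_fit(df, "g", ["f0", "f1"])
        mid = pd.DataFrame({"f0": [0.0], "f1": [0.5]})
        assert cda_classify(model, mid)[0] == "a"

    def test_projections_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(15)
        df = _two_group_frame(rng)
        m1 = cda_fit(df, "g", ["f0", "f1", "f2"])
        df2 = df.copy()
        df2["f0"] = 100.0 * df2["f0"] + 3
        df2["f1"] = -0.01 * df2["f1"]
        m2 = cda_fit(df2, "g", ["f0", "f1", "f2"])
        z1 = cda_transform(m1, df)
        z2 = cda_transform(m2, df2)
        z1 -= z1.mean(0)
        z2 -= z2.mean(0)
        for j in range(z1.shape[1]):
            s = np.sign(z1[:, j] @ z2[:, j])
            np.testing.assert_allclose(z1[:, j], s * z2[:, j], atol=1e-8)

    def test_agreement_with_reference_lda(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(16)
        df = _two_group_frame(rng, delta=(1.5, -0.5, 0.3))
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        lda = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        lda.fit(df[["f0", "f1", "f2"]], df["g"])
        np.testing.assert_array_equal(cda_classify(model, df),
                                      lda.predict(df[["f0", "f1", "f2"]]))

    def test_resubstitution_accuracy_in_calibrated_regime(self):
        # two spherical groups at Mahalanobis distance giving ~0.93 optimal
        # accuracy; resubstitution on n=200 should land near that rate
        delta = 2 * norm.ppf(0.93)
        rng = np.random.default_rng(17)
        df = _two_group_frame(rng, n0=100, n1=100, delta=(delta, 0.0, 0.0))
        model = cda_fit(df, "g", ["f0", "f1", "f2"])
        acc = (cda_classify(model, df) == df["g"].to_numpy()).mean()
        assert 0.88 <= acc <= 0.98

    def test_singular_within_scatter_raises(self):
        df = pd.DataFrame({"f0": [1.0, 1, 1, 1], "f1": [0.0, 1, 0, 1],
                           "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="singular"):
            cda_fit(df, "g", ["f0", "f1"])


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        cm = confusion_percentages(["a", "b", "a"], ["a", "b", "a"])
        assert cm.percentages.loc["a", "a"] == 100.0
        assert cm.percentages.loc["b", "b"] == 100.0
        assert cm.accuracy == 1.0

    def test_single_predicted_class_column(self):
        cm = confusion_percentages(["a", "b", "b"], ["a", "a", "a"])
        assert (cm.percentages["a"] == 100.0).all()

    def test_hand_built_two_by_two(self):
        true = ["pos"] * 14 + ["neg"] * 5
        pred = ["pos"] * 13 + ["neg"] + ["neg"] * 5
        cm = confusion_percentages(true, pred)
        assert cm.percentages.loc["pos", "pos"] == pytest.approx(92.9, abs=0.05)
        assert cm.percentages.loc["pos", "neg"] == pytest.approx(7.1, abs=0.05)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(18)
        true = rng.choice(list("abc"), 60)
        pred = rng.choice(list("abc"), 60)
        cm = confusion_percentages(true, pred)
        np.testing.assert_allclose(cm.percentages.sum(axis=1), 100.0, atol=0.1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_percentages([], [])
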