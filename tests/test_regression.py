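import numpy as np
import pytest

from seston.binning import DEFAULT_SCHEME
from seston.classify import ConfidenceVector
from seston.regression import (
    ConfidenceRegression,
    N_CLASSES,
    PublishedModel,
    fit_wls,
    load_published,
    predict_fnu,
)


def normal_equations_wls(X, y, w):
    """Independent closed-form oracle: (X'WX)^-1 X'Wy with intercept."""
    D = np.column_stack([np.ones(len(y)), X])
    W = np.diag(w)
    return np.linalg.solve(D.T @ W @ D, D.T @ W @ y)


def random_instance(rng, n=50):
    X = rng.uniform(0.0, 1.0, size=(n, N_CLASSES))
    beta = np.linspace(5.0, 110.0, N_CLASSES)
    y = -50.0 + X @ beta + rng.normal(0, 2.0, n)
    y = np.abs(y) + 0.1  # keep positive for the inverse-FNU weight rule
    return X, y


class TestFitWls:
    def test_matches_normal_equations_unit_weights(self, rng):
        X, y = random_instance(rng)
        res = fit_wls(X, y, weight_rule="unit")
        oracle = normal_equations_wls(X, y, np.ones_like(y))
        np.testing.assert_allclose(
            np.concatenate([[res.beta0], res.beta]), oracle, rtol=1e-8
        )

    def test_matches_normal_equations_nonunit_weights(self, rng):
        X, y = random_instance(rng)
        w = rng.uniform(0.2, 5.0, size=len(y))
        res = fit_wls(X, y, weights=w)
        oracle = normal_equations_wls(X, y, w)
        np.testing.assert_allclose(
            np.concatenate([[res.beta0], res.beta]), oracle, rtol=1e-8
        )

    def test_default_inverse_fnu_rule_matches_oracle(self, rng):
        X, y = random_instance(rng)
        res = fit_wls(X, y)  # weight_rule="inverse_fnu"
        oracle = normal_equations_wls(X, y, 1.0 / np.maximum(y, 0.5))
        np.testing.assert_allclose(
            np.concatenate([[res.beta0], res.beta]), oracle, rtol=1e-8
        )

    def test_saturated_one_hot_design_interpolates(self):
        # two copies of each one-hot vector, y at the class midpoints:
        # the fit reproduces y exactly
        X = np.vstack([np.eye(N_CLASSES), np.eye(N_CLASSES)])
        y = np.array([DEFAULT_SCHEME.midpoint(k) for k in range(N_CLASSES)] * 2)
        res = fit_wls(X, y, weight_rule="unit")
        np.testing.assert_allclose(res.predict_matrix(X), y, atol=1e-8)
        assert res.diagnostics["rmse"] == pytest.approx(0.0, abs=1e-8)

    def test_collinear_columns_named(self, rng):
        X, y = random_instance(rng)
        X[:, 3] = X[:, 2]  # duplicate column
        with pytest.raises(ValueError, match="x3.*x4|x4.*x3"):
            fit_wls(X, y)

    def test_nonpositive_weight_rejected(self, rng):
        X, y = random_instance(rng)
        w = np.ones_like(y)
        w[0] = 0.0
        with pytest.raises(ValueError, match="weights"):
            fit_wls(X, y, weights=w)

    def test_too_few_observations_rejected(self, rng):
        X = rng.uniform(0, 1, size=(12, N_CLASSES))
        with pytest.raises(ValueError):
            fit_wls(X, np.ones(12))

    def test_diagnostics_present(self, rng):
        X, y = random_instance(rng)
        d = fit_wls(X, y).diagnostics
        assert d["n_obs"] == 50 and d["df_model"] == 11 and d["df_resid"] == 38
        assert {"r2", "adj_r2", "rmse", "rrmse"} <= set(d)

    def test_parameter_recovery_improves_with_n(self, rng):
        beta_true = np.linspace(5.0, 110.0, N_CLASSES)
        errs = []
        for n in (60, 4000):
            X = rng.uniform(0.0, 1.0, size=(n, N_CLASSES))
            y = -50.0 + X @ beta_true + rng.normal(0, 1.0, n)
            y = np.abs(y) + 0.1
            res = fit_wls(X, y, weight_rule="unit")
            errs.append(np.max(np.abs(res.beta - beta_true)))
        assert errs[1] < errs[0]
        assert errs[1] < 1.0

    def test_summary_contains_fit_surface(self, rng):
        X, y = random_instance(rng)
        text = fit_wls(X, y).summary()
        assert "adj R2" in text and "RRMSE" in text and "x11" in text


class TestPublishedModel:
    def test_bundled_values(self):
        pub = load_published()
        assert pub.beta0 == pytest.approx(-60.90)
        assert pub.beta[0] == pytest.approx(61.34)
        assert pub.beta[-1] == pytest.approx(114.32)
        assert np.all(np.diff(pub.beta) > 0)

    @pytest.mark.parametrize(
        "class_index,expected",
        [(0, 0.44), (10, 53.42)],  # beta0 + beta_i by hand
    )
    def test_one_hot_predictions(self, class_index, expected):
        pub = load_published()
        v = np.zeros(N_CLASSES)
        v[class_index] = 1.0
        assert pub.predict(v) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_vector_gives_intercept(self):
        pub = load_published()
        v = np.zeros(N_CLASSES)
        assert pub.predict(v) == pytest.approx(-60.90)
        assert pub.predict(v, clamp=True) == 0.0

    def test_tampered_monotonicity_rejected(self, tmp_path):
        pub = load_published()
        table = pub.table.copy()
        table.loc[11, "coefficient"] = 50.0  # below the class-9 value
        path = tmp_path / "bad.tsv"
        table.to_csv(path, sep="\t", index=False, header=False)
        with pytest.raises(ValueError, match="increasing"):
            load_published(path)

    def test_truncated_table_rejected(self, tmp_path):
        pub = load_published()
        path = tmp_path / "short.tsv"
        pub.table.iloc[:6].to_csv(path, sep="\t", index=False, header=False)
        with pytest.raises(ValueError, match="rows"):
            load_published(path)


class TestPredictFnu:
    def test_accepts_confidence_vector_objects(self):
        pub = load_published()
        x = np.zeros(N_CLASSES)
        x[3] = 0.8
        v = ConfidenceVector(image_id="i", x=x)
        assert predict_fnu(pub, v) == pytest.approx(-60.90 + 0.8 * 65.53)

    def test_wrong_length_rejected(self):
        pub = load_published()
        with pytest.raises(ValueError):
            predict_fnu(pub, np.zeros(10))

    def test_affine_linearity(self, rng):
        pub = load_published()
        v1 = rng.uniform(0, 1, N_CLASSES)
        v2 = rng.uniform(0, 1, N_CLASSES)
        a, b = 0.3, 0.6
        lhs = predict_fnu(pub, a * v1 + b * v2)
        rhs = a * predict_fnu(pub, v1) + b * predict_fnu(pub, v2) - (a + b - 1) * pub.beta0
        assert lhs == pytest.approx(rhs)

    def test_clamping_bounds_output(self):
        pub = load_published()
        hot = np.zeros(N_CLASSES)
        assert predict_fnu(pub, hot, clamp=True) == 0.0
        hot[10] = 1.0
        assert 0.0 <= predict_fnu(pub, hot, clamp=True) <= 55.0
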