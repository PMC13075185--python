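"""VIF, stratified splitting, coordinate-descent elastic net, CV selection,
prediction equations and fit metrics."""

import numpy as np
import pandas as pd
import pytest

from salttol import predictive_model as pm

# unstandardised germination-stage prediction equation used as a worked
# example throughout: intercept and per-trait coefficients on raw STIs
GERMINATION_COEFS = {
    "GSTI": 0.282, "RLSTI": 0.097, "SLSTI": 0.108, "FWSTI": 0.219,
    "DWSTI": 0.197, "SVISTI": 0.373, "SVIISTI": 0.173,
}
GERMINATION_INTERCEPT = -0.220


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(40, 3))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centred, orthogonal
        out = pm.vif(X)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        out = pm.vif(X, names=["a", "dup", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["dup"])

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 500
        z = rng.normal(size=n)
        x1 = z + (1 / 3) * rng.normal(size=n)   # corr ~0.9 with x2
        x2 = z + (1 / 3) * rng.normal(size=n)
        x3 = rng.normal(size=n)
        X = np.column_stack([x1, x2, x3])
        out = pm.vif(X)
        # brute-force oracle: solve the normal equations per predictor
        for j in range(3):
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(others.T @ others, others.T @ X[:, j])
            resid = X[:, j] - others @ beta
            r2 = 1 - resid @ resid / np.sum((X[:, j] - X[:, j].mean()) ** 2)
            assert out.iloc[j] == pytest.approx(1 / (1 - r2), abs=1e-8)
        assert out.iloc[0] > out.iloc[2]  # collinear pair inflated

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="constant"):
            pm.vif(X)


class TestStratifiedSplit:
    def test_exact_division(self):
        labels = ["A"] * 10
        tr, te = pm.stratified_split(labels, 0.8, seed=0)
        assert len(tr) == 8 and len(te) == 2

    def test_determinism(self):
        labels = np.repeat(["A", "B", "C"], [20, 11, 7])
        a = pm.stratified_split(labels, 0.8, seed=5)
        b = pm.stratified_split(labels, 0.8, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_class_goes_to_training(self):
        labels = ["A"] * 10 + ["B"]
        tr, te = pm.stratified_split(labels, 0.8, seed=0)
        assert 10 in tr

    def test_disjoint_exhaustive_proportions(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["HT", "T", "MT", "S", "HS"], size=201,
                            p=[0.05, 0.1, 0.6, 0.15, 0.1])
        tr, te = pm.stratified_split(labels, 0.8, seed=1)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == 201
        for cls in np.unique(labels):
            size = (labels == cls).sum()
            got = (labels[tr] == cls).sum()
            assert abs(got - 0.8 * size) <= 1


class TestElasticNetCD:
    def test_full_shrinkage(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50) + 3
        est = pm.ElasticNetCD(alpha=1.0, lam=1e3).fit(X, y)
        np.testing.assert_allclose(est.coef_, 0.0)
        assert est.intercept_ == pytest.approx(y.mean())

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_lambda_zero_matches_ols(self, alpha):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        y = X @ [1, -2, 0.5, 0, 3] + rng.normal(size=60)
        est = pm.ElasticNetCD(alpha=alpha, lam=0.0).fit(X, y)
        A = np.column_stack([np.ones(60), X])
        ols = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(est.intercept_, ols[0], atol=1e-6)
        np.testing.assert_allclose(est.coef_, ols[1:], atol=1e-6)

    def test_orthonormal_soft_threshold(self):
        # standardized orthogonal design: beta_j = S(x_j'y/n, lam)
        rng = np.random.default_rng(2)
        n, p = 64, 4
        X = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))  # mean-zero orthonormal
        Xs = Q * np.sqrt(n)                      # Xs'Xs/n = I
        y = rng.normal(size=n)
        yc = y - y.mean()
        lam = 0.05
        beta, _, _ = pm._cd_solve(Xs, yc, alpha=1.0, lam=lam)
        expected = np.array([
            pm.soft_threshold(Xs[:, j] @ yc / n, lam) for j in range(p)])
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 6))
        X[:, 3] = X[:, 0] * 0.95 + rng.normal(size=80) * 0.05  # correlated
        y = X @ [1, 0, -1, 2, 0, 0.3] + rng.normal(size=80)
        est = pm.ElasticNetCD(alpha=0.5, lam=0.01,
                              track_objective=True).fit(X, y)
        obj = np.array(est.objective_path_)
        assert len(obj) >= 2
        assert np.all(np.diff(obj) <= 1e-12)

    def test_ridge_closed_form(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(70, 5))
        y = X @ [0.5, 1, 0, -1, 2] + rng.normal(size=70)
        lam = 0.3
        Xs, yc, mu, sd, ybar = pm._standardize(X, y)
        beta, _, _ = pm._cd_solve(Xs, yc, alpha=0.0, lam=lam)
        n = len(y)
        G = Xs.T @ Xs / n
        closed = np.linalg.solve(G + lam * np.eye(5), Xs.T @ yc / n)
        np.testing.assert_allclose(beta, closed, atol=1e-6)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 6))
        y = X @ [1, 2, 0, 0, -1, 0.5] + rng.normal(size=60)
        norms = []
        for lam in [0.0, 0.01, 0.05, 0.2, 1.0]:
            est = pm.ElasticNetCD(alpha=1.0, lam=lam).fit(X, y)
            Xs_sd = X.std(axis=0)
            norms.append(np.abs(est.coef_ * Xs_sd).sum())
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_matches_sklearn_elastic_net(self):
        # independent oracle: sklearn solves the same objective
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 7))
        y = X @ [1, 0, 2, 0, -1, 0, 0.5] + rng.normal(size=100)
        lam, alpha = 0.07, 0.6
        mine = pm.ElasticNetCD(alpha=alpha, lam=lam).fit(X, y)
        Xs, yc, mu, sd, ybar = pm._standardize(X, y)
        sk = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                        tol=1e-10, max_iter=100000).fit(Xs, yc)
        np.testing.assert_allclose(mine.coef_, sk.coef_ / sd, atol=1e-5)

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-finite"):
            pm.ElasticNetCD().fit(X, [1.0, 2.0])

    def test_sklearn_params_api(self):
        est = pm.ElasticNetCD(alpha=0.3, lam=0.1)
        assert est.get_params()["alpha"] == 0.3
        est.set_params(lam=0.5)
        assert est.lam == 0.5


class TestCvSelect:
    def test_singleton_grid(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        y = X @ [1, 0, 0, 2] + rng.normal(size=50) * 0.1
        cv = pm.cv_select(X, y, alpha_grid=[0.3], k=5, seed=0)
        assert cv.alpha == 0.3

    def test_lambda_1se_at_least_lambda_min(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 5))
        y = X @ [1, -1, 0, 0, 0.5] + rng.normal(size=80) * 0.3
        cv = pm.cv_select(X, y, k=5, seed=1)
        assert cv.lambda_1se >= cv.lambda_min

    def test_true_predictors_recovered(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 8))
        y = 0.3 + X[:, 1] * 0.8 + X[:, 6] * 0.6 + rng.normal(size=200) * 0.2
        model = pm.fit_cv_model(X, y, k=5, seed=2)
        active = set(model.active_set)
        assert {"x1", "x6"} <= active
        assert model.alpha >= 0.5  # sparse problem: L1-heavy mixing wins

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pm.cv_select(np.zeros((4, 2)), np.zeros(4), k=10)


class TestPredictionEquation:
    def test_intercept_at_zero_input(self):
        model = pm.RegularizedModel(
            alpha=1.0, lambda_min=0.0027, lambda_1se=0.0032, lam=0.0027,
            intercept=GERMINATION_INTERCEPT, coefficients=GERMINATION_COEFS)
        zeros = {k: 0.0 for k in GERMINATION_COEFS}
        assert pm.predict_score(model, zeros) == pytest.approx(-0.220)

    def test_all_ones_input(self):
        model = pm.RegularizedModel(
            alpha=1.0, lambda_min=0.0027, lambda_1se=0.0032, lam=0.0027,
            intercept=GERMINATION_INTERCEPT, coefficients=GERMINATION_COEFS)
        ones = {k: 1.0 for k in GERMINATION_COEFS}
        # -0.220 + 1.449
        assert pm.predict_score(model, ones) == pytest.approx(1.229)

    def test_zero_coefficient_model(self):
        model = pm.RegularizedModel(alpha=1, lambda_min=1, lambda_1se=1,
                                    lam=1, intercept=0.7,
                                    coefficients={"a": 0.0})
        assert pm.predict_score(model, {"a": 123.0}) == 0.7

    def test_missing_predictor_rejected(self):
        model = pm.RegularizedModel(alpha=1, lambda_min=1, lambda_1se=1,
                                    lam=1, intercept=0.0,
                                    coefficients={"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="b"):
            pm.predict_score(model, {"a": 1.0})

    def test_equation_rendering(self):
        model = pm.RegularizedModel(
            alpha=1.0, lambda_min=0.0027, lambda_1se=0.0032, lam=0.0027,
            intercept=GERMINATION_INTERCEPT, coefficients=GERMINATION_COEFS)
        eq = model.equation()
        assert eq.startswith("Y = -0.220")
        assert "+ 0.373 × SVISTI" in eq


class TestFitMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2, 3, 4])
        m = pm.fit_metrics(y, y, p=1)
        assert m["mse"] == 0 and m["rmse"] == 0 and m["nmse"] == 0
        assert m["r2"] == 1

    def test_rmse_squared_is_mse(self):
        rng = np.random.default_rng(10)
        y, yh = rng.normal(size=30), rng.normal(size=30)
        m = pm.fit_metrics(y, yh, p=2)
        assert m["rmse"] ** 2 == pytest.approx(m["mse"])

    def test_constant_prediction(self):
        y = np.array([1.0, 2, 3, 4, 5])
        yh = np.full(5, y.mean())
        m = pm.fit_metrics(y, yh, p=1)
        assert m["r2"] == pytest.approx(0.0)
        assert m["nmse"] == pytest.approx(1.0)  # population variance

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pm.fit_metrics([1.0, 1.0], [1.0, 2.0], p=1)


class TestSingleTraitR2:
    def test_identity_and_negation(self):
        a = np.array([0.1, 0.5, 0.9, 0.3])
        assert pm.single_trait_r2(a, a) == pytest.approx(1.0)
        assert pm.single_trait_r2(a, -a) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=160), rng.normal(size=160)
        assert pm.single_trait_r2(a, b) < 0.05

    def test_ranked_table(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=50)
        df = pd.DataFrame({"strong": a + rng.normal(size=50) * 0.1,
                           "weak": rng.normal(size=50)})
        ranked = pm.rank_single_trait_r2(a, df)
        assert list(ranked.index) == ["strong", "weak"]
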