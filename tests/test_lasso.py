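"""The coordinate-descent elastic-net solver against independent oracles:
normal equations at λ=0, the KKT zero bound, the orthonormal closed form, a
brute-force objective grid, and scikit-learn's implementation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusage.errors import DegenerateFeatureError
from fundusage.lasso import (
    CohortTable,
    LassoModel,
    fit,
    lambda_max,
    lambda_path,
    objective,
    penalty,
    soft_threshold,
    standardize,
)


def make_table(X, y):
    X = np.asarray(X, dtype=float)
    return CohortTable(
        ids=tuple(str(i) for i in range(len(X))),
        X=X,
        feature_names=tuple(f"f{j}" for j in range(X.shape[1])),
        y=np.asarray(y, dtype=float),
    )


def random_table(rng, n=30, p=4):
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
    beta = rng.normal(size=p)
    y = 5.0 + X @ beta + rng.normal(scale=0.5, size=n)
    return make_table(X, y)


def hadamard8_table(rng):
    """8x3 design whose standardized Gram is exactly the identity."""
    from scipy.linalg import hadamard

    H = hadamard(8).astype(float)
    X = H[:, 1:4]  # ±1 columns: mean 0, population sd 1, orthogonal
    y = rng.normal(size=8)
    return make_table(X, y)


class TestStandardize:
    def test_three_point_column_closed_form(self):
        Xs, yc, std = standardize(np.array([[1.0], [2.0], [3.0]]), np.array([4.0, 5.0, 6.0]))
        np.testing.assert_allclose(Xs[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert std.x_sds[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)  # divisor N
        assert abs(yc.mean()) < 1e-12

    def test_idempotent_on_standardized_input(self, rng):
        X = rng.normal(size=(20, 3))
        Xs, yc, _ = standardize(X, rng.normal(size=20))
        Xs2, _, std2 = standardize(Xs, yc)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)
        np.testing.assert_allclose(std2.x_sds, 1.0, atol=1e-12)

    def test_constant_column_named_in_error(self):
        X = np.c_[np.full(5, 5.0), np.arange(5.0)]
        with pytest.raises(DegenerateFeatureError, match="colA"):
            standardize(X, np.arange(5.0), feature_names=("colA", "colB"))

    def test_columns_have_mean_zero_sd_one(self, rng):
        X = rng.normal(size=(40, 5)) * 10 + 3
        Xs, _, _ = standardize(X, rng.normal(size=40))
        assert np.abs(Xs.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-12)


class TestPenaltyAndObjective:
    @pytest.mark.parametrize(
        "beta,alpha,expected",
        [([1.0, -2.0], 1.0, 3.0), ([2.0], 0.5, 2.0), ([0.0, 0.0, 0.0], 0.3, 0.0)],
    )
    def test_penalty_values(self, beta, alpha, expected):
        assert penalty(np.array(beta), alpha) == pytest.approx(expected, abs=1e-15)

    @given(
        b1=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        b2=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        alpha=st.floats(0, 1),
        t=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_penalty_is_convex(self, b1, b2, alpha, t):
        b1, b2 = np.array(b1), np.array(b2)
        mid = t * b1 + (1 - t) * b2
        assert penalty(mid, alpha) <= t * penalty(b1, alpha) + (1 - t) * penalty(b2, alpha) + 1e-9

    def test_penalty_zero_iff_beta_zero(self, rng):
        for alpha in (0.2, 0.7, 1.0):
            assert penalty(np.zeros(4), alpha) == 0.0
            b = rng.normal(size=4)
            b[rng.integers(4)] = 1e-8
            assert penalty(b, alpha) > 0.0

    def test_objective_residual_only_when_beta_zero(self, rng):
        y = rng.normal(size=12)
        y = y - y.mean()
        X = rng.normal(size=(12, 3))
        assert objective(0.0, np.zeros(3), X, y, lam=1.0) == pytest.approx(
            (y @ y) / 24.0, rel=1e-12
        )

    def test_objective_zero_at_perfect_fit(self, rng):
        X = rng.normal(size=(10, 2))
        beta = np.array([1.5, -2.0])
        y = 3.0 + X @ beta
        assert objective(3.0, beta, X, y, lam=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_objective_matches_one_line_oracle(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        beta = rng.normal(size=4)
        lam, alpha = 0.7, 0.4
        oracle = float(
            np.sum((y - 2.0 - X @ beta) ** 2) / (2 * 15)
            + lam * np.sum(0.5 * (1 - alpha) * beta**2 + alpha * np.abs(beta))
        )
        assert objective(2.0, beta, X, y, lam, alpha) == pytest.approx(oracle, rel=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize("z,g,expected", [(3, 1, 2.0), (-3, 1, -2.0), (0.5, 1, 0.0)])
    def test_values(self, z, g, expected):
        assert soft_threshold(z, g) == expected

    @given(z=st.floats(-100, 100), g=st.floats(0, 100))
    @settings(derandomize=True, max_examples=200)
    def test_shrinks_toward_zero_and_never_negative_zero(self, z, g):
        out = soft_threshold(z, g)
        assert abs(out) <= max(abs(z) - g, 0.0) + 1e-12
        if out == 0.0:
            assert not np.signbit(out)


class TestFit:
    def test_lambda_zero_matches_normal_equations(self, rng):
        table = random_table(rng, n=10, p=3)
        model = fit(table, 0.0, tol=1e-12)
        Xd = np.c_[np.ones(10), table.X]
        coef, *_ = np.linalg.lstsq(Xd, table.y, rcond=None)
        assert model.beta0 == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(model.beta, coef[1:], atol=1e-6)

    def test_lambda_at_or_above_max_zeroes_everything(self, rng):
        table = random_table(rng)
        Xs, yc, _ = standardize(table.X, table.y)
        lmax = lambda_max(Xs, yc)
        model = fit(table, lmax)
        assert np.all(model.beta_std == 0.0)
        assert model.selected == ()
        # just below the bound at least one coefficient activates
        assert np.any(fit(table, 0.95 * lmax).beta_std != 0.0)

    def test_orthonormal_design_matches_soft_threshold_closed_form(self, rng):
        table = hadamard8_table(rng)
        Xs, yc, _ = standardize(table.X, table.y)
        c = Xs.T @ yc / table.n
        for lam in (0.0, 0.05, 0.2, 1.0):
            model = fit(table, lam)
            expected = np.array([soft_threshold(cj, lam) for cj in c])
            np.testing.assert_allclose(model.beta_std, expected, atol=1e-8)

    def test_objective_beats_brute_force_grid(self, rng):
        grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
        B1, B2 = np.meshgrid(grid, grid, indexing="ij")
        for _ in range(5):
            table = random_table(rng, n=25, p=2)
            Xs, yc, _ = standardize(table.X, table.y)
            lam = rng.uniform(0.01, 0.5)
            model = fit(table, lam)
            G = Xs.T @ Xs
            c = Xs.T @ yc
            n = table.n
            rss = (
                yc @ yc
                - 2 * (B1 * c[0] + B2 * c[1])
                + B1**2 * G[0, 0]
                + 2 * B1 * B2 * G[0, 1]
                + B2**2 * G[1, 1]
            )
            obj_grid = rss / (2 * n) + lam * (np.abs(B1) + np.abs(B2))
            ours = objective(0.0, model.beta_std, Xs, yc, lam)
            assert ours <= obj_grid.min() + 1e-6

    def test_agrees_with_sklearn(self, rng):
        from sklearn.linear_model import Lasso

        for _ in range(5):
            table = random_table(rng, n=40, p=6)
            Xs, yc, _ = standardize(table.X, table.y)
            lam = rng.uniform(0.01, 1.0)
            model = fit(table, lam, tol=1e-10)
            ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=10**6).fit(Xs, yc)
            np.testing.assert_allclose(model.beta_std, ref.coef_, atol=1e-4)

    def test_scale_consistency_between_parameterizations(self, rng):
        table = random_table(rng)
        model = fit(table, 0.1)
        Xs, yc, std = standardize(table.X, table.y)
        raw_pred = model.predict(table.X)
        std_pred = std.y_mean + Xs @ model.beta_std
        np.testing.assert_allclose(raw_pred, std_pred, atol=1e-8)

    def test_sparse_sign_recovery(self, rng):
        n, p = 400, 6
        X = rng.normal(size=(n, p))
        beta_true = np.array([3.0, -2.0, 0.0, 0.0, 1.5, 0.0])
        y = X @ beta_true + rng.normal(scale=0.5, size=n)
        model = fit(make_table(X, y), lam=0.05)
        big = np.abs(beta_true) > 1.0
        assert np.all(np.sign(model.beta_std[big]) == np.sign(beta_true[big]))

    def test_json_round_trip(self, rng, tmp_path):
        model = fit(random_table(rng), 0.2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LassoModel.from_json(path)
        np.testing.assert_array_equal(back.beta_std, model.beta_std)
        assert back.lam == model.lam
        np.testing.assert_allclose(back.predict(np.eye(4)), model.predict(np.eye(4)))


class TestLambdaPath:
    def test_top_of_path_gives_null_model(self, rng):
        table = random_table(rng)
        Xs, yc, _ = standardize(table.X, table.y)
        lams = lambda_path(Xs, yc, n_lambda=10)
        assert np.all(fit(table, lams[0]).beta_std == 0.0)

    def test_strictly_decreasing_and_endpoints(self, rng):
        table = random_table(rng)
        Xs, yc, _ = standardize(table.X, table.y)
        lams = lambda_path(Xs, yc, n_lambda=2, ratio_min=0.01)
        lmax = lambda_max(Xs, yc)
        np.testing.assert_allclose(lams, [lmax, 0.01 * lmax], rtol=1e-12)
        many = lambda_path(Xs, yc, n_lambda=30)
        assert np.all(np.diff(many) < 0)

    def test_support_size_monotone_on_orthonormal_design(self, rng):
        table = hadamard8_table(rng)
        Xs, yc, _ = standardize(table.X, table.y)
        lams = lambda_path(Xs, yc, n_lambda=15, ratio_min=1e-3)
        sizes = [int(np.sum(fit(table, lam).beta_std != 0.0)) for lam in lams]
        assert sizes == sorted(sizes)
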