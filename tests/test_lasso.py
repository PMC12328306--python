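import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onidsc import (
    ExpressionMatrix,
    LassoProblem,
    cross_validate_lambda,
    fit_lasso_cd,
    log1p_normalize,
    make_lambda_path,
    scan_genes_lambda,
    select_common_lambda,
    soft_threshold,
)
from onidsc.io_formats import ValidationError
from onidsc.lasso_opt import LambdaSummary, _modal_value

from _oracles import lasso_qp_oracle
from conftest import random_problem


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,gamma,expected",
        [(3.0, 1.0, 2.0), (0.5, 1.0, 0.0), (-2.0, 0.5, -1.5), (0.0, 0.0, 0.0)],
    )
    def test_known_values(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == expected

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_shrinks_toward_zero_preserving_sign(self, z, gamma):
        s = soft_threshold(z, gamma)
        assert abs(s) <= abs(z)
        assert s == 0 or np.sign(s) == np.sign(z)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


def orthonormal_problem(rng, n=40, p=5):
    """Design with (1/N) X'X = I and exactly zero column means."""
    raw = rng.normal(size=(n, p))
    raw -= raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    X = Q[:, :p] * np.sqrt(n)
    X -= X.mean(axis=0)
    # re-orthonormalize after centering
    Q2, _ = np.linalg.qr(X)
    X = Q2 * np.sqrt(n)
    y = rng.normal(size=n)
    return X, y


class TestFitLassoCD:
    def test_zero_response_gives_zero_fit(self):
        rng = np.random.default_rng(0)
        prob = LassoProblem(rng.normal(size=(20, 4)), np.zeros(20))
        fit = fit_lasso_cd(prob, 0.1)
        assert fit.intercept == 0.0
        np.testing.assert_array_equal(fit.coefficients, 0.0)

    def test_lambda_max_zeroes_all_coefficients(self):
        rng = np.random.default_rng(1)
        X, y = random_problem(rng, n=25, p=6)
        prob = LassoProblem(X, y)
        lam_max = make_lambda_path(prob, 3)[0]
        fit = fit_lasso_cd(prob, lam_max)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-12)
        assert fit.intercept == pytest.approx(y.mean())

    def test_orthonormal_closed_form(self):
        rng = np.random.default_rng(2)
        X, y = orthonormal_problem(rng)
        n = len(y)
        lam = 0.08
        prob = LassoProblem(X, y, standardize=False)
        fit = fit_lasso_cd(prob, lam, tol=1e-12)
        yc = y - y.mean()
        expected = soft_threshold(X.T @ yc / n, lam)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-8)

    def test_matches_qp_oracle_on_random_problem(self):
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=20, p=5)
        lam = 0.1
        fit = fit_lasso_cd(LassoProblem(X, y, standardize=False), lam, tol=1e-12)
        b0, b = lasso_qp_oracle(X, y, lam)
        np.testing.assert_allclose(fit.coefficients, b, atol=1e-6)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)

    def test_objective_below_zero_solution_and_monotone(self):
        rng = np.random.default_rng(4)
        X, y = random_problem(rng, n=30, p=6)
        prob = LassoProblem(X, y)
        fit = fit_lasso_cd(prob, 0.05, track_objective=True)
        diffs = np.diff(fit.objective_history)
        assert np.all(diffs <= 1e-12)
        zero_fit_obj = fit.objective_history[-1]
        # the all-zero vector corresponds to the path-maximum fit
        lam_max = make_lambda_path(prob, 2)[0]
        zero = fit_lasso_cd(prob, lam_max, track_objective=True)
        assert fit.objective <= zero.objective + 1e-12

    def test_nan_input_rejected(self):
        X = np.ones((5, 2))
        y = np.array([1.0, np.nan, 0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            LassoProblem(X, y)

    def test_standardized_and_raw_agree_on_prestandardized_data(self):
        rng = np.random.default_rng(5)
        X, y = random_problem(rng, n=50, p=4)
        X = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        f1 = fit_lasso_cd(LassoProblem(X, y, standardize=True), lam, tol=1e-12)
        f2 = fit_lasso_cd(LassoProblem(X, y, standardize=False), lam, tol=1e-12)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-8)

    def test_monotone_sparsity_on_orthonormal_design(self):
        rng = np.random.default_rng(6)
        X, y = orthonormal_problem(rng, n=60, p=8)
        prob = LassoProblem(X, y, standardize=False)
        nnz = [
            int(np.count_nonzero(fit_lasso_cd(prob, lam).coefficients))
            for lam in (0.2, 0.1, 0.05, 0.01)
        ]
        assert nnz == sorted(nnz)


class TestLambdaPath:
    def test_geometric_spacing(self):
        rng = np.random.default_rng(7)
        X, y = random_problem(rng, n=20, p=4)
        prob = LassoProblem(X, y)
        grid = make_lambda_path(prob, 3, ratio=0.01)
        assert grid[0] / grid[1] == pytest.approx(grid[1] / grid[2])
        assert grid[2] == pytest.approx(grid[0] * 0.01)

    def test_doubling_response_doubles_lambda_max(self):
        rng = np.random.default_rng(8)
        X, y = random_problem(rng, n=20, p=4)
        g1 = make_lambda_path(LassoProblem(X, y), 2)
        g2 = make_lambda_path(LassoProblem(X, 2 * y), 2)
        assert g2[0] == pytest.approx(2 * g1[0])

    def test_constant_response_rejected(self):
        with pytest.raises(ValidationError):
            make_lambda_path(LassoProblem(np.random.default_rng(0).normal(size=(10, 3)), np.ones(10)), 5)


class TestCrossValidation:
    def test_identical_seed_gives_identical_result(self):
        rng = np.random.default_rng(9)
        X, y = random_problem(rng, n=40, p=5)
        prob = LassoProblem(X, y)
        a = cross_validate_lambda(prob, k=5, seed=123, n_lambda=20)
        b = cross_validate_lambda(prob, k=5, seed=123, n_lambda=20)
        np.testing.assert_array_equal(a.mse_mean, b.mse_mean)
        assert a.lambda_min == b.lambda_min and a.lambda_1se == b.lambda_1se

    def test_lambda_1se_at_least_lambda_min(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            X, y = random_problem(rng, n=30, p=4)
            cv = cross_validate_lambda(
                LassoProblem(X, y), k=5, seed=seed, n_lambda=25
            )
            assert cv.lambda_1se >= cv.lambda_min
            assert np.all(cv.mse_mean >= 0)

    def test_support_recovery_with_strong_signal(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 20))
            beta = np.zeros(20)
            beta[[2, 7, 13]] = [2.0, -1.5, 1.8]
            y = X @ beta + 0.1 * rng.normal(size=200)
            cv = cross_validate_lambda(
                LassoProblem(X, y), k=5, seed=seed, n_lambda=40
            )
            fit = fit_lasso_cd(LassoProblem(X, y), cv.lambda_min)
            support = set(np.nonzero(fit.coefficients)[0])
            hits += {2, 7, 13} <= support
        assert hits == 3

    def test_null_model_within_one_se_on_pure_noise(self):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(60, 10))
            y = rng.normal(size=60)
            cv = cross_validate_lambda(
                LassoProblem(X, y), k=5, seed=seed, n_lambda=30
            )
            i_min = int(np.argmin(cv.mse_mean))
            if cv.mse_mean[0] <= cv.mse_mean[i_min] + cv.mse_se[i_min]:
                ok += 1
        assert ok >= 4

    def test_tiny_fold_rejected(self):
        rng = np.random.default_rng(11)
        X, y = random_problem(rng, n=8, p=3)
        with pytest.raises(ValidationError):
            cross_validate_lambda(LassoProblem(X, y), k=8, seed=0, n_lambda=5)


class TestGeneScan:
    def make_matrix(self, n_genes=8, n_cells=60, seed=12):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(size=(n_genes, n_cells)))
        X = ExpressionMatrix(
            vals,
            [f"g{i}" for i in range(n_genes)],
            [f"c{i}" for i in range(n_cells)],
        )
        return log1p_normalize(X)

    def test_single_gene_matrix_rejected(self):
        X = ExpressionMatrix(
            np.abs(np.random.default_rng(0).normal(size=(1, 10))), ["g0"], [f"c{i}" for i in range(10)], normalized=True
        )
        with pytest.raises(ValidationError):
            scan_genes_lambda(X, k=2, seed=0, n_lambda=5)

    def test_modes_match_independent_recount(self):
        X = self.make_matrix()
        summary = scan_genes_lambda(X, k=4, seed=7, n_lambda=15)
        counts_min = summary.per_gene["lambda_min"].value_counts()
        top = counts_min[counts_min == counts_min.max()].index
        assert summary.mode_min == min(top)
        counts_max = summary.per_gene["lambda_1se"].value_counts()
        top = counts_max[counts_max == counts_max.max()].index
        assert summary.mode_max == max(top)
        assert summary.mode_min <= summary.mode_max
        assert len(summary.per_gene) == X.n_genes

    def test_scan_is_deterministic(self):
        X = self.make_matrix()
        a = scan_genes_lambda(X, k=4, seed=3, n_lambda=10)
        b = scan_genes_lambda(X, k=4, seed=3, n_lambda=10)
        assert a.per_gene.equals(b.per_gene)

    def test_shared_grid_makes_modes_grid_members(self):
        X = self.make_matrix(seed=13)
        summary = scan_genes_lambda(X, k=4, seed=1, n_lambda=12)
        assert summary.mode_min in summary.lambda_grid
        assert summary.mode_max in summary.lambda_grid


class TestSelectCommonLambda:
    def summary(self, lam_mins, mses):
        import pandas as pd

        per_gene = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(lam_mins))],
                "lambda_min": lam_mins,
                "lambda_1se": [max(lam_mins)] * len(lam_mins),
                "mse_at_min": mses,
            }
        )
        return LambdaSummary(
            per_gene, _modal_value(per_gene["lambda_min"], "small"), max(lam_mins)
        )

    def test_single_summary_returns_its_mode(self):
        s = self.summary([0.01, 0.01, 0.02], [1.0, 1.0, 1.0])
        assert select_common_lambda([s]) == 0.01

    def test_frequency_tie_broken_by_lower_median_mse(self):
        s1 = self.summary([0.01, 0.01, 0.02], [0.1, 0.2, 5.0])
        s2 = self.summary([0.02, 0.02, 0.01], [4.0, 6.0, 0.3])
        # both candidates appear 3 times pooled; 0.01 has lower median MSE
        assert select_common_lambda([s1, s2]) == 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            select_common_lambda([])


def test_warm_and_cold_starts_agree_along_path():
    rng = np.random.default_rng(14)
    X, y = random_problem(rng, n=40, p=6)
    prob = LassoProblem(X, y)
    grid = make_lambda_path(prob, 10, ratio=0.01)
    from onidsc.lasso_opt import _path_solve, _prepare

    prep = _prepare(prob)
    warm = _path_solve(prep, grid, 1.0, 1e-10, 100000)
    for i, lam in enumerate(grid):
        cold = fit_lasso_cd(prob, lam, tol=1e-10)
        np.testing.assert_allclose(
            warm[i] / prep["scale"], cold.coefficients, atol=1e-7
        )
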