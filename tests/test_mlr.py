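import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_trace
from gepqsar.dataset import DescriptorTable
from gepqsar.errors import DomainError, NumericalError
from gepqsar.mlr import (
    LinearModel,
    breaking_point,
    f_statistic,
    fit_ols,
    forward_select,
    loo_r2cv,
    max_k_for_n,
)
from gepqsar.simulate import SyntheticSpec, generate


def normal_equations(X, y):
    """Brute-force (XtX)^-1 Xt y oracle with explicit intercept column."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitOls:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        m = fit_ols(x[:, None], 2.0 * x)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_r2_zero_with_warning(self, rng):
        with pytest.warns(UserWarning, match="constant response"):
            m = fit_ols(rng.standard_normal((8, 1)), np.full(8, 3.0))
        assert m.r2 == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(12, 51))
        k = int(r.integers(1, 6))
        X = r.standard_normal((n, k))
        y = r.standard_normal(n)
        m = fit_ols(X, y)
        beta = normal_equations(X, y)
        np.testing.assert_allclose(m.intercept, beta[0], atol=1e-10)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-10)
        resid = y - beta[0] - X @ beta[1:]
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert m.r2 == pytest.approx(r2, abs=1e-10)
        assert m.s2 == pytest.approx(resid @ resid / (n - k - 1), abs=1e-10)

    def test_matches_statsmodels(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        m = fit_ols(X, y)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(m.coefficients, sm_fit.params[1:], atol=1e-10)
        assert m.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(NumericalError, match="x2"):
            fit_ols(X, rng.standard_normal(10), descriptor_names=["x1", "x2"])

    def test_too_few_observations(self, rng):
        with pytest.raises(DomainError):
            fit_ols(rng.standard_normal((3, 3)), np.zeros(3))


class TestLooR2cv:
    def test_noiseless_model_is_perfect(self, rng):
        X = rng.standard_normal((15, 2))
        y = 1.0 + X @ np.array([2.0, -0.5])
        assert loo_r2cv(X, y) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_leave_one_out(self, seed):
        r = np.random.default_rng(seed)
        n, k = 15, 2
        X = r.standard_normal((n, k))
        y = X @ np.array([1.0, 0.5]) + r.standard_normal(n)
        preds = np.empty(n)
        for i in range(n):  # literal n-refit oracle
            keep = np.arange(n) != i
            beta = normal_equations(X[keep], y[keep])
            preds[i] = beta[0] + X[i] @ beta[1:]
        press = np.sum((y - preds) ** 2)
        expected = 1 - press / np.sum((y - y.mean()) ** 2)
        assert loo_r2cv(X, y) == pytest.approx(expected, abs=1e-10)

    def test_noise_fit_cv_below_r2(self, rng):
        X = rng.standard_normal((20, 1))
        y = rng.standard_normal(20)  # pure noise: PRESS > SSres
        m = fit_ols(X, y)
        assert loo_r2cv(X, y) < m.r2


class TestFStatistic:
    def _model(self, r2, k, n):
        return LinearModel([f"d{i}" for i in range(k)], np.zeros(k), 0.0, r2, 0.0, n)

    def test_closed_form(self):
        # direct evaluation of F = (r2/k) / ((1-r2)/(n-k-1))
        assert f_statistic(self._model(0.5516, 2, 30)) == pytest.approx(
            (0.5516 / 2) / ((1 - 0.5516) / 27)
        )

    def test_null_model_is_zero(self):
        assert f_statistic(self._model(0.0, 3, 20)) == 0.0

    def test_perfect_fit_guarded(self):
        with pytest.raises(NumericalError, match="perfect fit"):
            f_statistic(self._model(1.0, 2, 20))

    def test_matches_statsmodels_anova(self, rng):
        X = rng.standard_normal((25, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.standard_normal(25)
        m = fit_ols(X, y)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert f_statistic(m) == pytest.approx(sm_fit.fvalue, rel=1e-10)


class TestForwardSelect:
    def test_recovers_planted_pair_first(self):
        spec = SyntheticSpec(
            n_compounds=40, n_descriptors=22, n_degenerate=0, n_collinear_pairs=0,
            true_support=("d003", "d007"), true_coefficients=(1.0, 2.0),
            noise_sd=0.0, seed=5,
        )
        table, _ = generate(spec)
        trace = forward_select(table, k_max=2)
        assert set(trace.models[1].descriptors) == {"d003", "d007"}

    def test_k_max_one_is_best_single_correlation(self, rng):
        vals = rng.standard_normal((20, 6))
        activity = vals[:, 3] + 0.2 * rng.standard_normal(20)
        table = DescriptorTable(
            [f"c{i}" for i in range(20)], [f"d{j+1}" for j in range(6)], vals, activity
        )
        trace = forward_select(table, k_max=1)
        assert len(trace.models) == 1
        best = max(
            table.descriptor_names,
            key=lambda nm: abs(np.corrcoef(table.column(nm), activity)[0, 1]),
        )
        assert trace.models[0].descriptors == [best]

    def test_r2_nondecreasing_on_random_tables(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            table = DescriptorTable(
                [f"c{i}" for i in range(15)],
                [f"d{j+1}" for j in range(6)],
                r.standard_normal((15, 6)),
                r.standard_normal(15),
            )
            r2s = [m.r2 for m in forward_select(table, k_max=4, with_cv=False).models]
            assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_k_max_capped_by_sample_size_rule(self, rng):
        table = DescriptorTable(
            [f"c{i}" for i in range(12)],
            [f"d{j+1}" for j in range(10)],
            rng.standard_normal((12, 10)),
            rng.standard_normal(12),
        )
        with pytest.warns(UserWarning, match="cap"):
            trace = forward_select(table, k_max=8, with_cv=False)
        assert len(trace.models) == max_k_for_n(12)


class TestBreakingPoint:
    def test_synthetic_trace_breaks_at_two(self):
        trace = make_trace([0.40, 0.55, 0.56, 0.565])
        assert breaking_point(trace, tol=0.02, n=30) == 2
        assert trace.chosen_k == 2

    def test_sample_size_cap_at_n30(self):
        trace = make_trace([0.1 * k for k in range(1, 13)], n=30)
        assert breaking_point(trace, tol=0.02, n=30) == 9  # n >= 3(k+1)

    def test_all_gaps_large_falls_back_to_k_max(self):
        trace = make_trace([0.2, 0.45, 0.7])
        assert breaking_point(trace, tol=0.02, n=30) == 3
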