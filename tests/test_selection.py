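"""Wavelength selectors on planted small instances, checked against
exhaustive-subset, KKT and library oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sersquant import (
    BossConfig,
    ConfigurationError,
    GaConfig,
    IvissaConfig,
    LassoConfig,
    boss_select,
    cluster_representatives,
    ga_select,
    ivissa_select,
    lasso_select,
)
from sersquant.model import make_folds


def planted_pair_instance(n=60, p=20, noise=0.3, seed=17):
    """y = 3 x_3 - 2 x_7 + noise with 18 pure-noise variables."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 3.0 * X[:, 3] - 2.0 * X[:, 7] + rng.normal(0, noise, n)
    return X, y


def cv_rmse_oracle(X, y, cols, plan):
    """Least-squares RMSECV via np.linalg.lstsq — independent of the PLS
    implementation under test (full-rank OLS on the subset)."""
    sq = 0.0
    for train, val in plan:
        A = np.column_stack([np.ones(train.size), X[np.ix_(train, cols)]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.column_stack([np.ones(val.size), X[np.ix_(val, cols)]]) @ coef
        sq += np.sum((pred - y[val]) ** 2)
    return np.sqrt(sq / y.size)


class TestBoss:
    def test_single_variable_returns_it_in_one_round(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.1, 30)
        res = boss_select(X, y, BossConfig(n_submodels=20, seed=1))
        assert np.array_equal(res.selected, [0])
        assert len(res.rmsecv_trace) == 1

    def test_recovers_planted_pair_confirmed_by_exhaustive_oracle(self):
        X, y = planted_pair_instance()
        plan = make_folds(60, 5, seed=2)
        pairs = list(itertools.combinations(range(20), 2))
        scores = [cv_rmse_oracle(X, y, list(pair), plan) for pair in pairs]
        assert pairs[int(np.argmin(scores))] == (3, 7)  # oracle agrees on the pair

        res = boss_select(X, y, BossConfig(n_submodels=100, seed=5))
        assert {3, 7} <= set(res.selected.tolist())
        assert res.selected.size <= 8

    def test_deterministic_under_seed(self):
        X, y = planted_pair_instance(n=40)
        config = BossConfig(n_submodels=50, seed=9)
        a = boss_select(X, y, config)
        b = boss_select(X, y, config)
        assert np.array_equal(a.selected, b.selected)
        assert np.array_equal(a.rmsecv_trace, b.rmsecv_trace)

    def test_traces_have_equal_length(self):
        X, y = planted_pair_instance(n=40)
        res = boss_select(X, y, BossConfig(n_submodels=50, seed=4))
        assert res.rmsecv_trace.size == res.n_vars_trace.size


class TestGa:
    def test_two_variables_both_required(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + X[:, 1]  # either alone leaves large residual
        res = ga_select(X, y, GaConfig(pop_size=16, generations=15, seed=2,
                                       init_density=0.5, folds=4))
        assert np.array_equal(res.selected, [0, 1])

    def test_final_subset_in_top_five_percent_of_exhaustive_search(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(40, 10))
        y = 2 * X[:, 1] - X[:, 6] + 0.5 * X[:, 8] + rng.normal(0, 0.3, 40)
        plan = make_folds(40, 5, seed=31)
        all_scores = [
            cv_rmse_oracle(X, y, list(cols), plan)
            for r in range(1, 11)
            for cols in itertools.combinations(range(10), r)
        ]
        res = ga_select(X, y, GaConfig(seed=7, folds=5, init_density=0.3))
        ga_score = cv_rmse_oracle(X, y, res.selected.tolist(), plan)
        assert ga_score <= np.percentile(all_scores, 5)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 8))
        y = X[:, 2] + rng.normal(0, 0.2, 30)
        config = GaConfig(pop_size=16, generations=10, seed=3, folds=3)
        assert np.array_equal(ga_select(X, y, config).selected,
                              ga_select(X, y, config).selected)


class TestLasso:
    @staticmethod
    def _standardised(X, y):
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        return Xs, y - y.mean()

    def test_penalty_at_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        Xs, yc = self._standardised(X, y)
        lam_max = np.abs(Xs.T @ yc).max() / 30
        with pytest.raises(ConfigurationError, match="no variables"):
            lasso_select(X, y, LassoConfig(lambda_grid=[2 * lam_max, 1.5 * lam_max],
                                           seed=0))

    def test_unpenalised_limit_recovers_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.2, 50)
        Xs, yc = self._standardised(X, y)
        from sersquant.selection import _cd_path

        G = Xs.T @ Xs / 50
        c = Xs.T @ yc / 50
        beta = _cd_path(G, c, np.array([1e-12]), tol=1e-12, max_sweeps=20000)[0]
        beta_ols = np.linalg.solve(Xs.T @ Xs, Xs.T @ yc)
        assert np.allclose(beta, beta_ols, atol=1e-6)

    def test_solution_satisfies_kkt_conditions(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 8))
        y = 1.5 * X[:, 1] - X[:, 5] + rng.normal(0, 0.3, 50)
        Xs, yc = self._standardised(X, y)
        from sersquant.selection import _cd_path

        G = Xs.T @ Xs / 50
        c = Xs.T @ yc / 50
        lam = 0.1
        beta = _cd_path(G, c, np.array([lam]), tol=1e-12, max_sweeps=20000)[0]
        grad = c - G @ beta  # (1/n) X'(y - Xb)
        active = beta != 0
        assert np.all(np.abs(grad[~active]) <= lam + 1e-8)
        assert np.allclose(grad[active], lam * np.sign(beta[active]), atol=1e-8)

    def test_matches_sklearn_coordinate_descent(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(19)
        X = rng.normal(size=(60, 10))
        y = 2 * X[:, 0] - X[:, 4] + rng.normal(0, 0.4, 60)
        Xs, yc = self._standardised(X, y)
        from sersquant.selection import _cd_path

        lam = 0.15
        G = Xs.T @ Xs / 60
        c = Xs.T @ yc / 60
        beta = _cd_path(G, c, np.array([lam]), tol=1e-12, max_sweeps=20000)[0]
        ref = sklearn_lm.Lasso(alpha=lam, fit_intercept=False, tol=1e-12)
        ref.fit(Xs, yc)
        assert np.allclose(beta, ref.coef_, atol=1e-6)

    def test_selects_informative_variables_and_is_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 15))
        y = 3 * X[:, 2] - 2 * X[:, 9] + rng.normal(0, 0.3, 60)
        config = LassoConfig(seed=6)
        a = lasso_select(X, y, config)
        b = lasso_select(X, y, config)
        assert np.array_equal(a.selected, b.selected)
        assert {2, 9} <= set(a.selected.tolist())

    def test_bad_lambda_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="decreasing"):
            LassoConfig(lambda_grid=[0.1, 0.2])


class TestIvissa:
    def test_single_informative_variable_probability_converges(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 1))
        y = X[:, 0] * 2 + rng.normal(0, 0.1, 40)
        res = ivissa_select(X, y, IvissaConfig(n_samplings=50, seed=2, folds=4))
        assert 0 in res.selected
        assert res.weights[0] >= 0.5

    def test_planted_pair_contained_in_small_final_set(self):
        X, y = planted_pair_instance()
        res = ivissa_select(X, y, IvissaConfig(n_samplings=200, seed=11,
                                               interval_halfwidth=2))
        assert {3, 7} <= set(res.selected.tolist())
        assert res.selected.size <= 6

    def test_deterministic_under_seed(self):
        X, y = planted_pair_instance(n=40, seed=29)
        config = IvissaConfig(n_samplings=80, max_iter=8, seed=3)
        a = ivissa_select(X, y, config)
        b = ivissa_select(X, y, config)
        assert np.array_equal(a.selected, b.selected)


class TestSelectionResultValidity:
    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_subsets_are_valid_for_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 8))
        y = X[:, 1] - X[:, 5] + rng.normal(0, 0.3, 24)
        results = [
            boss_select(X, y, BossConfig(n_submodels=20, max_iter=10, folds=3, seed=seed)),
            ga_select(X, y, GaConfig(pop_size=12, generations=6, folds=3, seed=seed,
                                     init_density=0.4)),
            ivissa_select(X, y, IvissaConfig(n_samplings=30, max_iter=5, folds=3,
                                             seed=seed)),
        ]
        for res in results:
            sel = res.selected
            assert sel.size > 0
            assert np.all((0 <= sel) & (sel < 8))
            assert np.array_equal(np.unique(sel), sel)
            assert res.rmsecv_trace.size == res.n_vars_trace.size


class TestClusterRepresentatives:
    def test_contiguous_runs_collapse_to_peak_most_member(self):
        wn = np.linspace(400.0, 500.0, 101)
        selected = np.array([10, 11, 12, 40, 41, 90])
        values = np.zeros(101)
        values[[11, 41, 90]] = [5.0, -3.0, 1.0]
        reps = cluster_representatives(selected, wn, values=values)
        assert np.allclose(reps, [wn[11], wn[41], wn[90]])
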