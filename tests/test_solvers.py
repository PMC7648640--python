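import itertools

import numpy as np
import pytest

import deconvbench as db
from deconvbench.solvers import (
    SolverError,
    postprocess_proportions,
    solve_dwls,
    solve_nnls,
    solve_ols,
    solve_penalized,
    solve_qp,
    solve_rlr,
    solve_svr,
)


def random_problem(seed=0, n_genes=100, k=4, on_simplex=True):
    rng = np.random.default_rng(seed)
    C = rng.lognormal(2, 1, (n_genes, k))
    if on_simplex:
        p = rng.dirichlet(np.ones(k))
    else:
        p = rng.uniform(0, 1, k)
    return C, p, C @ p


class TestOLS:
    def test_noiseless_recovery(self):
        C, p, t = random_problem(0, on_simplex=False)
        np.testing.assert_allclose(solve_ols(C, t), p, atol=1e-8)

    def test_reference_column_unit_vector(self):
        C, _, _ = random_problem(1)
        np.testing.assert_allclose(solve_ols(C, C[:, 2]), [0, 0, 1, 0], atol=1e-8)

    def test_zero_target(self):
        C, _, _ = random_problem(2)
        np.testing.assert_allclose(solve_ols(C, np.zeros(C.shape[0])), 0.0, atol=1e-12)

    def test_rank_deficient_warns(self):
        C, _, t = random_problem(3)
        C2 = np.hstack([C, C[:, [0]]])
        with pytest.warns(UserWarning, match="rank"):
            coef = solve_ols(C2, t)
        assert np.all(np.isfinite(coef))


class TestNNLS:
    def test_noiseless_recovery(self):
        C, p, t = random_problem(4)
        np.testing.assert_allclose(solve_nnls(C, t), p, atol=1e-8)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            C = rng.lognormal(1, 1, (30, 3))
            t = rng.lognormal(1, 1, 30)
            assert np.all(solve_nnls(C, t) >= 0)

    def test_matches_brute_force_active_set_oracle(self):
        # oracle: enumerate every support, solve unconstrained LS on it,
        # keep the feasible candidate with minimal residual
        rng = np.random.default_rng(6)
        for trial in range(10):
            C = rng.lognormal(1, 1, (20, 3))
            t = rng.normal(0, 5, 20)  # negative-leaning target
            best, best_res = np.zeros(3), np.sum(t**2)
            for r in (1, 2, 3):
                for idx in itertools.combinations(range(3), r):
                    coef, *_ = np.linalg.lstsq(C[:, idx], t, rcond=None)
                    if np.all(coef >= -1e-12):
                        full = np.zeros(3)
                        full[list(idx)] = np.clip(coef, 0, None)
                        res = np.sum((C @ full - t) ** 2)
                        if res < best_res - 1e-12:
                            best, best_res = full, res
            got = solve_nnls(C, t)
            np.testing.assert_allclose(got, best, atol=1e-8)
            assert np.sum((C @ got - t) ** 2) >= np.sum((C @ solve_ols(C, t) - t) ** 2) - 1e-9


class TestRLR:
    def test_noiseless_recovery(self):
        C, p, t = random_problem(7)
        np.testing.assert_allclose(solve_rlr(C, t), p, atol=1e-6)

    def test_huber_limit_reproduces_ols(self):
        rng = np.random.default_rng(8)
        C = rng.lognormal(1, 1, (50, 4))
        t = C @ rng.dirichlet(np.ones(4)) + rng.normal(0, 1, 50)
        np.testing.assert_allclose(
            solve_rlr(C, t, huber_c=1e12), solve_ols(C, t), atol=1e-8
        )

    def test_outlier_robustness_monte_carlo(self):
        # 2% corrupted genes: RLR beats OLS in >= 95% of 200 seeded trials
        rng = np.random.default_rng(9)
        wins = 0
        n_trials = 200
        for _ in range(n_trials):
            C = rng.lognormal(2, 1, (100, 4))
            p = rng.dirichlet(np.ones(4))
            t = C @ p + rng.normal(0, 0.05, 100)
            bad = rng.choice(100, 2, replace=False)
            t[bad] += rng.uniform(50, 200, 2) * rng.choice([-1, 1], 2)
            err_rlr = np.linalg.norm(solve_rlr(C, t) - p)
            err_ols = np.linalg.norm(solve_ols(C, t) - p)
            wins += err_rlr < err_ols
        assert wins / n_trials >= 0.95


class TestQP:
    def test_noiseless_grid_recovery(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            C = rng.lognormal(2, 1, (50, 5))
            units = rng.multinomial(20 - 5, np.ones(5) / 5) + 1
            p = units / 20
            got = solve_qp(C, C @ p)
            np.testing.assert_allclose(got, p, atol=1e-8)

    def test_sum_to_one_always(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            C = rng.lognormal(1, 1, (20, 4))
            t = rng.lognormal(1, 1, 20)
            p = solve_qp(C, t)
            assert abs(p.sum() - 1.0) <= 1e-10
            assert np.all(p >= 0)

    def test_average_of_two_columns(self):
        C, _, _ = random_problem(12, k=4)
        t = 0.5 * C[:, 0] + 0.5 * C[:, 1]
        np.testing.assert_allclose(solve_qp(C, t), [0.5, 0.5, 0, 0], atol=1e-8)

    def test_matches_slsqp_on_negative_leaning_target(self):
        rng = np.random.default_rng(13)
        from deconvbench.solvers import _solve_qp_slsqp

        for _ in range(5):
            C = rng.lognormal(1, 1, (30, 4))
            t = rng.normal(0, 3, 30)
            exact = solve_qp(C, t)
            approx = _solve_qp_slsqp(C, t)
            obj = lambda p: np.sum((C @ p - t) ** 2)
            assert obj(exact) <= obj(approx) + 1e-6


class TestPenalized:
    def test_lambda_zero_limit_reproduces_ols(self):
        C, p, t = random_problem(14)
        coef = solve_penalized(C, t, penalty="ridge", lambda_grid=[1e-12])
        np.testing.assert_allclose(coef, solve_ols(C, t), atol=1e-6)

    def test_ridge_closed_form_oracle(self):
        C, _, t = random_problem(15, n_genes=40, k=4)
        lam = 3.7
        coef = solve_penalized(C, t, penalty="ridge", lambda_grid=[lam])
        oracle = np.linalg.inv(C.T @ C + lam * np.eye(4)) @ C.T @ t
        np.testing.assert_allclose(coef, oracle, atol=1e-10)

    def test_lasso_huge_lambda_all_zero_degenerate(self):
        C, _, t = random_problem(16)
        coef = solve_penalized(C, t, penalty="lasso", lambda_grid=[1e9])
        props, degenerate = postprocess_proportions(coef)
        assert degenerate
        assert np.all(np.isnan(props))

    def test_elastic_net_runs(self):
        C, p, t = random_problem(17)
        coef = solve_penalized(C, t, penalty="elastic_net", lambda_grid=[1e-8, 1e-4])
        assert np.all(np.isfinite(coef))

    def test_empty_grid_errors(self):
        C, _, t = random_problem(18)
        with pytest.raises(SolverError, match="empty"):
            solve_penalized(C, t, lambda_grid=[])


class TestSVR:
    def test_noiseless_recovery_within_002(self):
        # tolerance calibrated on this seeded fixture set
        for seed in range(5):
            C, p, t = random_problem(seed, n_genes=200, k=4)
            props, degenerate = postprocess_proportions(solve_svr(C, t))
            assert not degenerate
            assert np.max(np.abs(props - p)) <= 0.02

    def test_nu_selection_is_best_of_grid(self):
        from sklearn.svm import NuSVR

        C, p, t = random_problem(20, n_genes=120, k=4)
        X = (C - C.mean()) / C.std(ddof=1)
        y = (t - t.mean()) / t.std(ddof=1)
        rmses = {}
        for nu in (0.25, 0.5, 0.75):
            m = NuSVR(kernel="linear", nu=nu, C=1.0).fit(X, y)
            rmses[nu] = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        best_nu = min(rmses, key=rmses.get)
        oracle = NuSVR(kernel="linear", nu=best_nu, C=1.0).fit(X, y).coef_.ravel()
        np.testing.assert_allclose(solve_svr(C, t), oracle, atol=1e-10)

    def test_gene_permutation_invariance(self):
        C, p, t = random_problem(21, n_genes=80)
        perm = np.random.default_rng(0).permutation(80)
        a, _ = postprocess_proportions(solve_svr(C, t))
        b, _ = postprocess_proportions(solve_svr(C[perm], t[perm]))
        # libsvm's SMO path is order-dependent up to its stopping tolerance
        np.testing.assert_allclose(a, b, atol=1e-3)


class TestDWLS:
    def test_noiseless_recovery(self):
        for seed in range(3):
            C, p, t = random_problem(seed + 30, n_genes=150, k=4)
            np.testing.assert_allclose(solve_dwls(C, t), p, atol=1e-4)

    def test_equal_weights_limit_is_nnls(self):
        # constant fitted expression -> all weights equal -> plain NNLS
        rng = np.random.default_rng(31)
        C = np.full((50, 3), 5.0) + rng.normal(0, 1e-9, (50, 3))
        t = np.full(50, 5.0)
        np.testing.assert_allclose(solve_dwls(C, t), solve_nnls(C, t), atol=1e-6)

    def test_zero_predicted_weight_capped(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        t = np.array([1.0, 0.0, 0.0])
        coef = solve_dwls(C, t)
        assert np.all(np.isfinite(coef))

    def test_rare_type_monte_carlo_vs_nnls(self):
        # heteroscedastic (multiplicative) noise: DWLS at least matches
        # NNLS on the rare type in >= 80% of 200 seeded trials
        rng = np.random.default_rng(32)
        n_trials = 200
        wins = 0
        for _ in range(n_trials):
            C = rng.lognormal(2, 1.2, (120, 4))
            p = np.array([0.05, 0.35, 0.3, 0.3])
            mu = C @ p
            t = mu * rng.lognormal(0, 0.3, 120)
            err_d = abs(solve_dwls(C, t)[0] - p[0])
            err_n = abs(solve_nnls(C, t)[0] - p[0])
            wins += err_d <= err_n + 1e-12
        assert wins / n_trials >= 0.80


class TestPostprocess:
    def test_clip_and_renormalize_arithmetic(self):
        props, degenerate = postprocess_proportions(np.array([-0.1, 0.6, 0.5]))
        np.testing.assert_allclose(props, [0, 6 / 11, 5 / 11])
        assert not degenerate

    def test_simplex_vector_unchanged(self):
        p = np.array([0.2, 0.3, 0.5])
        props, _ = postprocess_proportions(p)
        np.testing.assert_allclose(props, p)

    def test_all_zero_degenerate(self):
        props, degenerate = postprocess_proportions(np.zeros(3))
        assert degenerate

    def test_nan_raises(self):
        with pytest.raises(SolverError, match="NaN"):
            postprocess_proportions(np.array([np.nan, 1.0]))


class TestScaleEquivariance:
    @pytest.mark.parametrize("solver", [solve_ols, solve_nnls, solve_qp, solve_rlr])
    def test_scaling_C_and_t_invariant(self, solver):
        C, p, t = random_problem(40)
        a, _ = postprocess_proportions(solver(C, t))
        b, _ = postprocess_proportions(solver(7.3 * C, 7.3 * t))
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestDeconvolve:
    def test_noiseless_end_to_end(self, pancreas_split, pancreas_reference, pancreas_markers):
        # exact mixtures T = C p on the marker-subset reference
        from deconvbench.reference import subset_to_markers

        C = subset_to_markers(pancreas_reference, pancreas_markers)
        rng = np.random.default_rng(41)
        P = rng.dirichlet(np.ones(len(C.cell_type_ids)), size=50).T
        mixtures = db.MixtureSet(
            T=C.values @ P,
            P_E=P,
            gene_ids=C.gene_ids,
            cell_type_ids=list(C.cell_type_ids),
            mixture_ids=[f"m{i}" for i in range(50)],
            provenance=[[] for _ in range(50)],
            rules=db.CompositionRules(n_mixtures=50),
        )
        res = db.deconvolve(mixtures, C, markers=None, method="nnls")
        np.testing.assert_allclose(res.P_C, P, atol=1e-6)

    def test_skip_incompatible_combination(self, pancreas_mixtures, pancreas_reference, pancreas_markers):
        res = db.deconvolve(
            pancreas_mixtures,
            pancreas_reference,
            markers=pancreas_markers,
            method="nnls",
            transform_kind="log",
            scaling_t="median_ratios",
        )
        assert res.skipped
        assert "linear" in res.skip_reason

    def test_deterministic(self, pancreas_mixtures, pancreas_reference, pancreas_markers):
        kw = dict(markers=pancreas_markers, method="nnls", scaling_t="column", scaling_c="column")
        a = db.deconvolve(pancreas_mixtures, pancreas_reference, **kw)
        b = db.deconvolve(pancreas_mixtures, pancreas_reference, **kw)
        np.testing.assert_array_equal(a.P_C, b.P_C)

    def test_unknown_method(self, pancreas_mixtures, pancreas_reference):
        with pytest.raises(SolverError, match="unknown method"):
            db.deconvolve(pancreas_mixtures, pancreas_reference, method="epic")

    def test_register_external_solver(self, pancreas_mixtures, pancreas_reference, pancreas_markers):
        db.register_solver("uniform_stub", lambda C, t: np.ones(C.shape[1]))
        res = db.deconvolve(
            pancreas_mixtures, pancreas_reference, markers=pancreas_markers, method="uniform_stub"
        )
        k = len(res.cell_type_ids)
        np.testing.assert_allclose(res.P_C, 1.0 / k)
        db.SOLVERS.pop("uniform_stub")
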