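"""Graphical lasso and EBIC selection against closed-form and numeric oracles."""

import numpy as np
import pytest
from scipy import optimize

from ordnet.glasso import (
    ebic,
    glasso,
    glasso_objective,
    select_network,
    to_partial_correlations,
)
from ordnet.polychoric import polychoric_matrix


def random_correlation(p, seed, n=80):
    rng = np.random.default_rng(seed)
    return np.corrcoef(rng.standard_normal((n, p)), rowvar=False)


class TestGlasso:
    def test_all_zero_solution_above_lambda_max(self):
        # KKT: when lambda >= max off-diagonal |S| the empty model is optimal
        S = np.array([[1.0, 0.5, -0.3], [0.5, 1.0, 0.2], [-0.3, 0.2, 1.0]])
        sol = glasso(S, lam=0.5)
        assert sol.edge_count == 0
        np.testing.assert_allclose(sol.K, np.diag(1.0 / np.diag(S)), atol=1e-8)
        assert abs(sol.dual_gap) < 1e-6

    def test_unpenalized_is_closed_form_inverse(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        sol = glasso(S, lam=0.0)
        np.testing.assert_allclose(
            sol.K, np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]]), atol=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_unpenalized_equals_inverse(self, seed):
        S = random_correlation(5, seed)
        sol = glasso(S, lam=0.0)
        np.testing.assert_allclose(sol.K, np.linalg.inv(S), atol=1e-6)

    def test_objective_matches_brute_force_p3(self):
        # generic numeric optimizer over the 6 free parameters of a symmetric
        # 3x3 precision matrix
        S = random_correlation(3, seed=7)
        lam = 0.1
        sol = glasso(S, lam=lam, tol=1e-10)

        def neg_obj(theta):
            K = np.array(
                [
                    [theta[0], theta[3], theta[4]],
                    [theta[3], theta[1], theta[5]],
                    [theta[4], theta[5], theta[2]],
                ]
            )
            v = glasso_objective(K, S, lam)
            return -v if np.isfinite(v) else 1e10

        x0 = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = optimize.minimize(neg_obj, x0, method="Powell",
                                options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
        mine = glasso_objective(sol.K, S, lam)
        assert mine == pytest.approx(-res.fun, abs=1e-5)

    @pytest.mark.parametrize("lam", [0.02, 0.08, 0.2])
    def test_cross_check_against_sklearn(self, lam):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = random_correlation(6, seed=3)
        sol = glasso(S, lam=lam, tol=1e-9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=2000)
        assert glasso_objective(sol.K, S, lam) >= glasso_objective(prec, S, lam) - 1e-6
        np.testing.assert_allclose(sol.K, prec, atol=5e-3)

    def test_non_pd_input_rejected(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            glasso(S, lam=0.1)


class TestEbic:
    def test_gamma_zero_is_bic(self):
        S = random_correlation(4, seed=0)
        sol = glasso(S, lam=0.05)
        n = 500
        K = sol.K
        sign, logdet = np.linalg.slogdet(K)
        L = 0.5 * n * (logdet - np.sum(S * K))
        E = sol.edge_count
        assert ebic(sol, S, n, gamma=0.0) == pytest.approx(-2 * L + E * np.log(n))

    def test_edge_penalty_linearity(self):
        # near-identical likelihood, edge counts differing by one -> EBIC
        # differs by log(n) + 4 gamma log(p)
        from ordnet.glasso import GlassoSolution

        S = random_correlation(5, seed=2)
        n, gamma = 1000, 0.5
        sol = glasso(S, lam=0.12)
        zero_pairs = [
            (i, j)
            for i in range(5)
            for j in range(i + 1, 5)
            if abs(sol.K[i, j]) <= 1e-10
        ]
        assert zero_pairs, "need an absent edge to toggle"
        K2 = sol.K.copy()
        i, j = zero_pairs[0]
        K2[i, j] = K2[j, i] = 1e-9  # counts as an edge, negligible likelihood shift
        sol2 = GlassoSolution(K=K2, Theta_cov=sol.Theta_cov, lam=sol.lam,
                              iterations=sol.iterations, dual_gap=sol.dual_gap)
        assert sol2.edge_count == sol.edge_count + 1
        delta = ebic(sol2, S, n, gamma) - ebic(sol, S, n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(5), abs=1e-4)

    def test_diagonal_beats_saturated_on_independent_data(self, rng):
        # simulated independent 7-variable data: the empty model wins EBIC
        X = rng.standard_normal((2000, 7))
        S = np.corrcoef(X, rowvar=False)
        dense = glasso(S, lam=0.0)
        sparse = glasso(S, lam=float(np.abs(S - np.eye(7)).max()) + 0.01)
        assert ebic(sparse, S, 2000, 0.5) < ebic(dense, S, 2000, 0.5)


class TestPartialCorrelations:
    def test_diagonal_precision_gives_zero_weights(self):
        W = to_partial_correlations(np.diag([2.0, 3.0, 1.0]))
        np.testing.assert_array_equal(W, np.zeros((3, 3)))

    def test_hand_case(self):
        W = to_partial_correlations(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)

    def test_sign_flip_property(self):
        K = np.array([[1.5, 0.3, -0.2], [0.3, 1.2, 0.1], [-0.2, 0.1, 1.8]])
        W = to_partial_correlations(K)
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.sign(W[off]) == -np.sign(K[off]))

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            to_partial_correlations(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestSelectNetwork:
    def test_identity_input_selects_empty_network(self):
        net = select_network(np.eye(6), n=1000)
        assert net.edge_count == 0
        np.testing.assert_array_equal(net.W, np.zeros((6, 6)))

    def test_selection_minimizes_trace(self, recovery_fit):
        _, _, _, net = recovery_fit
        i = int(np.argmin(np.abs(net.lambda_path - net.lambda_selected)))
        assert net.ebic_trace[i] == np.min(net.ebic_trace)

    def test_edge_count_bounds(self, recovery_fit):
        _, _, _, net = recovery_fit
        assert 0 <= net.edge_count <= net.p * (net.p - 1) // 2
        assert net.possible_edges == 21  # 7-node network

    def test_weights_strictly_inside_unit_interval(self, recovery_fit):
        _, _, _, net = recovery_fit
        assert np.all(np.abs(net.W) < 1.0)
        np.testing.assert_allclose(net.W, net.W.T)
        np.testing.assert_allclose(np.diag(net.W), 0.0)

    def test_edge_count_recovered_on_simulated_cohort(self, recovery_fit):
        _, truth, _, net = recovery_fit
        assert abs(net.edge_count - truth.n_edges) <= 2

    def test_no_spurious_edges_across_disconnected_blocks(self):
        # 26-item cohort whose domains are fully disconnected in truth: pairs
        # with no latent path should effectively never gain strong edges
        from ordnet.simulate import balanced_thresholds, make_block_precision, sample_ordinal

        ok = 0
        reps = 20
        for rep in range(reps):
            truth = make_block_precision(
                [3, 3, 6, 4, 4, 4, 2], within_density=0.6, between_density=0.0, seed=rep
            )
            data = sample_ordinal(truth, balanced_thresholds(26, 5), n=1000, seed=100 + rep)
            S = polychoric_matrix(data)
            net = select_network(S, n=data.n, n_lambda=40)
            block = np.repeat(np.arange(7), [3, 3, 6, 4, 4, 4, 2])
            cross = block[:, None] != block[None, :]
            if np.all(np.abs(net.W[cross]) <= 0.1):
                ok += 1
        assert ok >= 0.9 * reps
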