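"""Graphical lasso, EBIC selection, partial correlations, Simpson subgrouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinenet import (
    EBICGraphicalLasso,
    datasets,
    ebic_score,
    glasso_fit,
    partial_correlations,
    select_network,
    simpson_decomposition,
)
from kinenet.network import validate_correlation_matrix

from _oracles import glasso_objective_oracle


def _random_correlation(rng, p=6, strength=0.6):
    A = rng.normal(size=(p, p)) * strength
    S = A @ A.T + p * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestGlassoFit:
    def test_zero_penalty_equals_direct_inversion(self, rng):
        S = _random_correlation(rng)
        omega = glasso_fit(S, 0.0)
        np.testing.assert_allclose(omega, np.linalg.inv(S), atol=1e-5)

    def test_full_shrinkage_gives_empty_network(self, rng):
        S = _random_correlation(rng)
        lam = np.max(np.abs(S - np.eye(6))) * 1.001
        omega = glasso_fit(S, lam)
        off = omega[np.triu_indices(6, 1)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_three_node_solution_matches_numerical_optimizer(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        omega = glasso_fit(S, 0.1)
        oracle = glasso_objective_oracle(S, 0.1)
        np.testing.assert_allclose(omega, oracle, atol=1e-4)

    def test_matches_sklearn_reference_solver(self):
        """Independent cross-check against scikit-learn's graphical lasso."""
        from sklearn.covariance import graphical_lasso

        S = datasets.reference_correlation_matrix().to_numpy()
        for lam in (0.05, 0.1, 0.3):
            mine = glasso_fit(S, lam, tol=1e-9)
            _, theirs = graphical_lasso(S, alpha=lam, tol=1e-8, max_iter=5000)
            np.testing.assert_allclose(mine, theirs, atol=5e-4)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            glasso_fit(_random_correlation(rng), -0.1)


class TestEbicScore:
    def test_gamma_zero_reduces_to_bic(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        omega = np.linalg.inv(S)
        n = 50
        loglik = (n / 2) * (np.linalg.slogdet(omega)[1] - np.trace(S @ omega))
        assert ebic_score(omega, S, n, gamma=0.0) == pytest.approx(-2 * loglik + 1 * np.log(n))

    def test_two_node_hand_computed_value(self):
        omega = np.array([[2.0, -0.5], [-0.5, 1.5]])
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        n, gamma, p, E = 80, 0.5, 2, 1
        logdet = np.log(2.0 * 1.5 - 0.25)
        trace = 2.0 + 1.5 + 2 * 0.3 * (-0.5)
        expected = -2 * (n / 2) * (logdet - trace) + E * np.log(n) + 4 * gamma * E * np.log(p)
        assert ebic_score(omega, S, n, gamma) == pytest.approx(expected, rel=1e-12)

    def test_gamma_penalty_monotone_in_edge_count(self):
        S = datasets.reference_correlation_matrix().to_numpy()
        omega = glasso_fit(S, 0.05)
        E = int(np.sum(np.abs(omega[np.triu_indices(6, 1)]) > 1e-8))
        diff = ebic_score(omega, S, 100, 0.5) - ebic_score(omega, S, 100, 0.0)
        assert diff == pytest.approx(4 * 0.5 * E * np.log(6))


class TestSelectNetwork:
    def test_identity_matrix_gives_empty_network(self):
        model = select_network(np.eye(6), n=100)
        assert model.edge_count == 0

    def test_edge_count_monotone_along_penalty_path(self):
        est = EBICGraphicalLasso().fit_correlation(datasets.reference_correlation_matrix(), 100)
        counts = est.edge_counts_path_  # path runs from large lambda down
        assert np.all(np.diff(counts) >= 0)

    def test_weights_bounded_and_precision_positive_definite(self, rng):
        for _ in range(5):
            S = _random_correlation(rng)
            model = select_network(S, n=200, gamma=0.5)
            assert np.all(np.abs(model.weights) <= 1 + 1e-10)
            assert np.linalg.eigvalsh(model.precision).min() > 0

    def test_dataframe_labels_propagate(self):
        model = select_network(datasets.reference_correlation_matrix(), 100)
        assert model.node_labels == datasets.NODE_ORDER

    def test_n_not_larger_than_p_rejected(self):
        with pytest.raises(ValueError, match="n"):
            select_network(np.eye(6), n=6)


class TestPartialCorrelations:
    def test_diagonal_precision_gives_no_edges(self):
        w = partial_correlations(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(w, 0.0)

    def test_matches_residual_regression_oracle(self, rng):
        """Partial correlation of x and y given z equals the correlation of
        the residuals of x~z and y~z."""
        n = 2000
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)
        y = -0.4 * z + 0.3 * x + rng.normal(size=n)
        X = np.column_stack([x, y, z])
        S = np.corrcoef(X, rowvar=False)
        w = partial_correlations(np.linalg.inv(S))

        def residual(a, b):
            beta = np.polyfit(b, a, 1)
            return a - np.polyval(beta, b)

        oracle = stats.pearsonr(residual(x, z), residual(y, z)).statistic
        assert w[0, 1] == pytest.approx(oracle, abs=1e-6)

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            partial_correlations(np.array([[1.0, 0.2], [0.2, -0.5]]))


class TestValidation:
    def test_asymmetric_matrix_rejected(self):
        S = np.eye(3)
        S[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            validate_correlation_matrix(S)

    def test_indefinite_matrix_rejected(self):
        S = np.array([[1, 0.99, -0.99], [0.99, 1, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="indefinite"):
            validate_correlation_matrix(S)


class TestSupportRecovery:
    def test_known_sparse_model_recovered_at_large_n(self, sparse_model, rng):
        """All true edges found and their weights accurately estimated."""
        X = rng.standard_normal((5000, 6)) @ sparse_model["chol"].T
        est = EBICGraphicalLasso(gamma=0.5).fit(X)
        iu = np.triu_indices(6, 1)
        true_w = sparse_model["weights"][iu]
        found = np.abs(est.weights_[iu]) > 1e-8
        assert found[true_w > 0].all()
        assert np.corrcoef(true_w, est.weights_[iu])[0, 1] > 0.95


class TestSimpson:
    def test_common_effect_reverses_association(self, rng):
        """x and y independent, both raising c: conditioning on c-groups
        induces a negative x-y association absent marginally."""
        n = 6000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        c = x + y + 0.5 * rng.normal(size=n)
        table = pd.DataFrame({"x": x, "y": y, "c": c})
        res = simpson_decomposition(table, "x", "y", "c", n_groups=3)
        pooled = res.loc[res.group == "pooled", "r"].item()
        within = res.loc[res.group != "pooled", "r"]
        assert abs(pooled) < 0.05
        assert (within < -0.2).all()

    def test_independent_features_show_no_association(self, rng):
        n = 5000
        table = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "c"])
        res = simpson_decomposition(table, "x", "y", "c")
        assert np.all(np.abs(res["r"].to_numpy()) < 0.06)

    def test_within_group_correlations_match_direct_recomputation(self, rng):
        n = 4000
        z = rng.normal(size=(n, 3)) @ np.linalg.cholesky(
            np.array([[1, 0.5, 0.3], [0.5, 1, 0.6], [0.3, 0.6, 1.0]])
        ).T
        table = pd.DataFrame(z, columns=["x", "y", "c"])
        res = simpson_decomposition(table, "x", "y", "c", n_groups=3)
        edges = np.quantile(table["c"], [1 / 3, 2 / 3])
        masks = [
            table["c"] <= edges[0],
            (table["c"] > edges[0]) & (table["c"] <= edges[1]),
            table["c"] > edges[1],
        ]
        for k, mask in enumerate(masks):
            oracle = stats.pearsonr(table.loc[mask, "x"], table.loc[mask, "y"]).statistic
            got = res.loc[res.group == f"group_{k}", "r"].item()
            assert got == pytest.approx(oracle, abs=0.02)
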