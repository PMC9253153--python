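"""EBIC-regularized Gaussian graphical model estimation.

The network model is a sparse precision matrix estimated by the graphical
lasso over a log-spaced penalty path, with the penalty selected by minimizing
the Extended Bayesian Information Criterion

    EBIC = -2 L + E log(n) + 4 gamma E log(p),

where ``L = (n/2) (log det Omega - tr(S Omega))`` is the multivariate-normal
profile log-likelihood, ``E`` the number of retained edges, and ``gamma`` the
EBIC hyperparameter (0.5 is the conservative standard; 0 is the exploratory
setting that reduces EBIC to the ordinary BIC).  The selected precision matrix
is reported as a matrix of partial correlations, the edge weights of the
undirected network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .glasso import glasso_path, partial_correlations

__all__ = [
    "PathConfig",
    "NetworkModel",
    "EBICGraphicalLasso",
    "ebic_score",
    "select_network",
    "validate_correlation_matrix",
    "simpson_decomposition",
]

EDGE_ZERO_THRESHOLD = 1e-8


@dataclass(frozen=True)
class PathConfig:
    """Penalty-path settings for the graphical lasso.

    ``n_lambdas`` log-spaced penalties from ``lambda_max`` (the largest
    off-diagonal absolute correlation, at which the network is empty) down to
    ``lambda_max * lambda_min_ratio``.
    """

    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    penalize_diagonal: bool = False

    def __post_init__(self) -> None:
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be at least 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")

    def lambdas(self, lambda_max: float) -> np.ndarray:
        return np.logspace(
            np.log10(lambda_max),
            np.log10(lambda_max * self.lambda_min_ratio),
            self.n_lambdas,
        )


@dataclass
class NetworkModel:
    """A fitted regularized partial-correlation network."""

    precision: np.ndarray
    weights: np.ndarray
    lambda_: float
    gamma: float
    ebic: float
    edge_count: int
    n: int
    node_labels: tuple[str, ...]

    @property
    def weights_frame(self) -> pd.DataFrame:
        labels = list(self.node_labels)
        return pd.DataFrame(self.weights, index=labels, columns=labels)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as (node_a, node_b, weight) rows."""
        rows = []
        labels = self.node_labels
        p = len(labels)
        for i in range(p):
            for j in range(i + 1, p):
                if abs(self.weights[i, j]) > EDGE_ZERO_THRESHOLD:
                    rows.append((labels[i], labels[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_graph(self):
        """Export as a weighted :class:`networkx.Graph`."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return g


def validate_correlation_matrix(S: np.ndarray, *, sym_tol: float = 1e-10) -> np.ndarray:
    """Check symmetry, unit diagonal, and near-PSD; return a float ndarray."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.all(np.isfinite(S)):
        raise ValueError("correlation matrix contains non-finite entries")
    if np.max(np.abs(S - S.T)) > sym_tol:
        raise ValueError("correlation matrix is not symmetric")
    if np.max(np.abs(np.diag(S) - 1.0)) > 1e-8:
        raise ValueError("correlation matrix diagonal must be 1")
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin < -1e-8:
        raise ValueError(f"correlation matrix is indefinite (min eigenvalue {eigmin:.3e})")
    return 0.5 * (S + S.T)


def count_edges(weights: np.ndarray, threshold: float = EDGE_ZERO_THRESHOLD) -> int:
    iu = np.triu_indices(weights.shape[0], 1)
    return int(np.sum(np.abs(weights[iu]) > threshold))


def ebic_score(
    precision: np.ndarray,
    S: np.ndarray,
    n: int,
    gamma: float,
    *,
    edge_threshold: float = EDGE_ZERO_THRESHOLD,
) -> float:
    """Extended BIC of a precision matrix against sample covariance S."""
    precision = np.asarray(precision, dtype=float)
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    loglik = (n / 2.0) * (logdet - float(np.trace(S @ precision)))
    E = count_edges(-precision, edge_threshold)  # same support as the weights
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


class EBICGraphicalLasso(BaseEstimator):
    """Gaussian graphical model with glasso regularization and EBIC selection.

    A scikit-learn style estimator: ``fit(X)`` computes the sample Pearson
    correlation of ``X`` (n_samples x n_features) and estimates the sparse
    precision matrix over the penalty path; ``fit_correlation(S, n)`` runs the
    same selection directly from a correlation matrix (for re-analysing
    published matrices without raw data).

    Parameters
    ----------
    gamma : float, default 0.5
        EBIC hyperparameter; 0 reduces to BIC (exploratory), larger values
        select sparser networks.
    n_lambdas, lambda_min_ratio, penalize_diagonal :
        Penalty-path settings, see :class:`PathConfig`.
    edge_threshold : float
        Absolute partial correlations at or below this value count as absent
        edges (separates exact glasso zeros from numerical dust).

    Attributes
    ----------
    precision_ : (p, p) ndarray of the selected precision matrix.
    weights_ : (p, p) ndarray of partial correlations (zero diagonal).
    lambda_ : selected penalty.
    ebic_ : EBIC value of the selected model.
    edge_count_ : number of retained edges.
    lambda_path_, ebic_path_, edge_counts_path_ : the full selection path.
    node_labels_ : tuple of feature names (column names when X is a DataFrame).
    n_samples_ : sample size behind the correlation matrix.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.01,
        penalize_diagonal: bool = False,
        edge_threshold: float = EDGE_ZERO_THRESHOLD,
        tol: float = 1e-6,
        max_sweeps: int = 1000,
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.penalize_diagonal = penalize_diagonal
        self.edge_threshold = edge_threshold
        self.tol = tol
        self.max_sweeps = max_sweeps

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None):
        """Estimate the network from a samples-by-features data matrix."""
        labels = None
        if isinstance(X, pd.DataFrame):
            labels = tuple(map(str, X.columns))
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more samples ({n}) than features ({p})")
        sds = X.std(axis=0)
        if np.any(sds == 0):
            bad = int(np.argmin(sds))
            raise ValueError(f"feature column {bad} is constant")
        S = np.corrcoef(X, rowvar=False)
        return self._fit(S, n, labels)

    def fit_correlation(self, S, n: int):
        """Estimate the network directly from a correlation matrix and n."""
        labels = None
        if isinstance(S, pd.DataFrame):
            labels = tuple(map(str, S.columns))
            S = S.to_numpy(dtype=float)
        return self._fit(np.asarray(S, dtype=float), int(n), labels)

    def _fit(self, S: np.ndarray, n: int, labels):
        S = validate_correlation_matrix(S)
        p = S.shape[0]
        if n <= p:
            raise ValueError(f"need n ({n}) greater than the number of nodes ({p})")
        path = PathConfig(self.n_lambdas, self.lambda_min_ratio, self.penalize_diagonal)
        offdiag = np.abs(S - np.eye(p))
        lambda_max = float(offdiag.max())
        if lambda_max <= 0:
            lambda_max = 1.0  # diagonal S: any path yields the empty network
        lambdas = path.lambdas(lambda_max)
        precisions = glasso_path(
            S,
            lambdas,
            penalize_diagonal=self.penalize_diagonal,
            max_sweeps=self.max_sweeps,
            tol=self.tol,
        )
        # vectorized EBIC over the whole path
        signs, logdets = np.linalg.slogdet(precisions)
        if np.any(signs <= 0):
            raise RuntimeError("a path solution lost positive definiteness")
        traces = np.einsum("ij,kji->k", S, precisions)
        logliks = (n / 2.0) * (logdets - traces)
        iu = np.triu_indices(p, 1)
        edge_counts = (np.abs(precisions[:, iu[0], iu[1]]) > self.edge_threshold).sum(axis=1)
        ebics = -2.0 * logliks + edge_counts * np.log(n) + 4.0 * self.gamma * edge_counts * np.log(p)
        # ties broken toward the sparser (larger-lambda) model: strict improvement
        best = 0
        for k in range(1, len(lambdas)):
            if ebics[k] < ebics[best] - 1e-12:
                best = k

        self.node_labels_ = labels if labels is not None else tuple(f"X{i}" for i in range(p))
        self.n_samples_ = n
        self.lambda_path_ = lambdas
        self.ebic_path_ = ebics
        self.edge_counts_path_ = edge_counts.astype(int)
        self.precision_ = precisions[best]
        self.weights_ = partial_correlations(self.precision_)
        self.weights_[np.abs(self.weights_) <= self.edge_threshold] = 0.0
        self.lambda_ = float(lambdas[best])
        self.ebic_ = float(ebics[best])
        self.edge_count_ = count_edges(self.weights_, self.edge_threshold)
        self.n_features_in_ = p
        return self

    # -- fitted accessors ------------------------------------------------

    def to_model(self) -> NetworkModel:
        check_is_fitted(self, "precision_")
        return NetworkModel(
            precision=self.precision_.copy(),
            weights=self.weights_.copy(),
            lambda_=self.lambda_,
            gamma=self.gamma,
            ebic=self.ebic_,
            edge_count=self.edge_count_,
            n=self.n_samples_,
            node_labels=tuple(self.node_labels_),
        )


def select_network(
    S,
    n: int,
    gamma: float = 0.5,
    path: PathConfig | None = None,
) -> NetworkModel:
    """Functional wrapper: EBIC-selected network from a correlation matrix."""
    path = path or PathConfig()
    est = EBICGraphicalLasso(
        gamma=gamma,
        n_lambdas=path.n_lambdas,
        lambda_min_ratio=path.lambda_min_ratio,
        penalize_diagonal=path.penalize_diagonal,
    )
    return est.fit_correlation(S, n).to_model()


def simpson_decomposition(
    table: pd.DataFrame,
    x: str,
    y: str,
    conditioner: str,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Marginal vs within-subgroup correlation of two features.

    Splits participants into ``n_groups`` quantile groups of ``conditioner``
    and reports the Pearson correlation of ``x`` and ``y`` pooled and within
    each group.  A sign change between the pooled and within-group rows is the
    Simpson's-paradox pattern produced by conditioning on a common effect.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    for col in (x, y, conditioner):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    groups = pd.qcut(table[conditioner], n_groups, labels=False, duplicates="drop")
    rows = [
        {
            "group": "pooled",
            "n": len(table),
            "r": float(stats.pearsonr(table[x], table[y]).statistic),
        }
    ]
    for g in sorted(pd.unique(groups.dropna())):
        sub = table[groups == g]
        if len(sub) < 5 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            warnings.warn(f"conditioner group {g} degenerate; skipped", stacklevel=2)
            rows.append({"group": f"group_{int(g)}", "n": len(sub), "r": np.nan})
            continue
        rows.append(
            {
                "group": f"group_{int(g)}",
                "n": len(sub),
                "r": float(stats.pearsonr(sub[x], sub[y]).statistic),
            }
        )
    return pd.DataFrame(rows)
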