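import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sparse_model():
    """A known sparse 6-node Gaussian graphical model (8 edges, weights 0.1-0.6).

    Unit-diagonal precision, so the off-diagonal weights ARE the partial
    correlations; used as ground truth for recovery and coverage checks.
    """
    p = 6
    W = np.zeros((p, p))
    edges = [
        (0, 1, 0.30),
        (1, 2, 0.25),
        (2, 3, 0.40),
        (3, 4, 0.30),
        (4, 5, 0.20),
        (0, 5, 0.15),
        (1, 4, 0.10),
        (2, 5, 0.12),
    ]
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    precision = np.eye(p) - W
    assert np.linalg.eigvalsh(precision).min() > 0
    cov = np.linalg.inv(precision)
    return {
        "weights": W,
        "precision": precision,
        "cov": cov,
        "chol": np.linalg.cholesky(cov),
        "edges": edges,
    }


@pytest.fixture(scope="session")
def reference_network():
    """EBIC-glasso network re-estimated from the published correlation matrix."""
    from kinenet import EBICGraphicalLasso, datasets

    S, n = datasets.load_reference_cohort()
    est = EBICGraphicalLasso(gamma=datasets.REFERENCE_GAMMA).fit_correlation(S, n)
    return est.to_model()


@pytest.fixture(scope="session")
def small_cohort_table():
    from kinenet import default_cohort_spec, generate_feature_table

    return generate_feature_table(default_cohort_spec(n=100, seed=7))
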