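"""Reference values for the neck-pain cohort the package models.

The constants below are the published summary statistics of a cross-sectional
cohort of 100 adults with and without a history of neck pain: per-group means
and standard deviations of the six analysis features, and the pairwise Pearson
correlation matrix of the pooled cohort.  They serve two purposes: they are the
defaults of the synthetic-cohort generator, and they are the input of the
"printed matrix" analysis path, which re-estimates the regularized
partial-correlation network directly from the published correlations when raw
recordings are unavailable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical node order of the six-feature network.
NODE_ORDER = ("TSK", "JPE", "ROM", "Velocity", "SPARC", "Strength")

#: Sample size of the published pooled cohort.
REFERENCE_N = 100

# Lower triangle (row-major, in NODE_ORDER) of the published Pearson matrix.
_REFERENCE_LOWER = [
    [1.00],
    [0.16, 1.00],
    [-0.24, -0.01, 1.00],
    [-0.27, 0.18, 0.46, 1.00],
    [-0.21, 0.16, 0.14, 0.65, 1.00],
    [-0.19, 0.24, 0.07, 0.20, 0.08, 1.00],
]

# Published group-level moments: {group: {feature: (mean, sd)}}.  Units:
# TSK questionnaire points (scale 17-68), JPE and ROM degrees, Velocity deg/s,
# SPARC dimensionless (negative), Strength newtons.
GROUP_MOMENTS = {
    "no_history": {
        "n": 15,
        "TSK": (29.3, 4.4),
        "JPE": (7.00, 4.50),
        "ROM": (53.0, 6.8),
        "Velocity": (76.7, 21.5),
        "SPARC": (-1.61, 0.08),
        "Strength": (108.5, 56.38),
    },
    "history": {
        "n": 85,
        "TSK": (35.0, 6.4),
        "JPE": (6.10, 3.70),
        "ROM": (49.7, 6.7),
        "Velocity": (61.6, 20.3),
        "SPARC": (-1.68, 0.11),
        "Strength": (81.8, 30.7),
    },
}

#: EBIC hyperparameter used for the reference-cohort reproduction.  The study
#: this cohort comes from chose the exploratory (discovery-oriented) end of the
#: sparsity/exploration trade-off, which corresponds to gamma = 0; the generic
#: estimator default stays at the conservative standard gamma = 0.5.
REFERENCE_GAMMA = 0.0


def reference_correlation_matrix() -> pd.DataFrame:
    """Published 6x6 Pearson correlation matrix of the pooled cohort.

    Returns a symmetric :class:`~pandas.DataFrame` with unit diagonal, indexed
    by :data:`NODE_ORDER`.
    """
    p = len(NODE_ORDER)
    mat = np.eye(p)
    for i, row in enumerate(_REFERENCE_LOWER):
        for j, value in enumerate(row):
            mat[i, j] = value
            mat[j, i] = value
    return pd.DataFrame(mat, index=list(NODE_ORDER), columns=list(NODE_ORDER))


def pooled_moments() -> pd.DataFrame:
    """Mean and SD of each feature pooled across the two cohort groups.

    Pooling uses the mixture formula: the pooled variance is the weighted mean
    of within-group variances plus the between-group variance of the means.
    """
    groups = list(GROUP_MOMENTS)
    weights = np.array([GROUP_MOMENTS[g]["n"] for g in groups], dtype=float)
    weights /= weights.sum()
    rows = {}
    for feat in NODE_ORDER:
        means = np.array([GROUP_MOMENTS[g][feat][0] for g in groups])
        sds = np.array([GROUP_MOMENTS[g][feat][1] for g in groups])
        m = float(weights @ means)
        var = float(weights @ (sds**2 + (means - m) ** 2))
        rows[feat] = (m, np.sqrt(var))
    return pd.DataFrame(rows, index=["mean", "sd"]).T


def load_reference_cohort() -> tuple[pd.DataFrame, int]:
    """Return ``(correlation_matrix, n)`` for the printed-matrix analysis path."""
    return reference_correlation_matrix(), REFERENCE_N
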