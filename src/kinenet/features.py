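"""Participant-level feature assembly and pre-network transforms.

The six network nodes per participant are: the Tampa Scale for Kinesiophobia
total (TSK), the joint reposition error (JPE, mean absolute relocation error
over six trials), and four movement summaries - ROM, mean velocity, and SPARC
averaged over the six movement directions, plus strength as the mean of the
flexion and extension maximal-contraction peaks.

Before network estimation each column is passed through the nonparanormal
(Gaussian copula) transformation: empirical CDF with average ranks, truncated
to ``[delta_n, 1 - delta_n]``, mapped through the standard-normal quantile
function, and rescaled to unit sample SD.  The transform is rank-based, so
any strictly increasing distortion of a column leaves its output unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import RelocationTrial

__all__ = [
    "joint_reposition_error",
    "aggregate_features",
    "NonparanormalTransformer",
    "nonparanormal_transform",
    "default_truncation_delta",
    "CorrelationResult",
    "pearson_matrix",
    "REQUIRED_DIRECTIONS",
]

#: The six anatomical movement directions every kinematic feature must cover.
REQUIRED_DIRECTIONS = (
    "flexion",
    "extension",
    "right-rotation",
    "left-rotation",
    "right-lateral-flexion",
    "left-lateral-flexion",
)


def joint_reposition_error(trials: list[RelocationTrial]) -> float:
    """Mean absolute repositioning error (degrees) over exactly six trials."""
    if len(trials) != 6:
        raise ValueError(f"joint reposition error requires exactly 6 trials, got {len(trials)}")
    errors = []
    for i, t in enumerate(trials):
        n = t.waveform.samples.size
        if not (0 <= t.start_index < n and 0 <= t.end_index < n):
            raise ValueError(f"trial {i} is missing a valid start/end marker")
        errors.append(abs(t.waveform.samples[t.end_index] - t.waveform.samples[t.start_index]))
    return float(np.mean(errors))


def aggregate_features(
    directional: pd.DataFrame,
    strength_flexion_n: float,
    strength_extension_n: float,
    jpe_deg: float,
    tsk: float,
) -> dict:
    """One participant's six network-node values.

    ``directional`` holds one row per direction (index or ``direction``
    column) with columns ``rom_deg``, ``mean_velocity_deg_s``, ``sparc``;
    all six directions of :data:`REQUIRED_DIRECTIONS` must be present.
    Kinematic nodes are unweighted means over the six directions; strength is
    the mean of the two maximal-contraction peaks.
    """
    if "direction" in directional.columns:
        directional = directional.set_index("direction")
    missing = [d for d in REQUIRED_DIRECTIONS if d not in directional.index]
    if missing:
        raise ValueError(f"missing movement direction(s): {', '.join(missing)}")
    sub = directional.loc[list(REQUIRED_DIRECTIONS)]
    return {
        "TSK": float(tsk),
        "JPE": float(jpe_deg),
        "ROM": float(sub["rom_deg"].mean()),
        "Velocity": float(sub["mean_velocity_deg_s"].mean()),
        "SPARC": float(sub["sparc"].mean()),
        "Strength": float((strength_flexion_n + strength_extension_n) / 2.0),
    }


def default_truncation_delta(n: int) -> float:
    """Winsorization level ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


class NonparanormalTransformer(TransformerMixin, BaseEstimator):
    """Rank-based Gaussian-copula (nonparanormal) columnwise transform.

    Stateless by design: the transform of a sample is a function of that
    sample's ranks (truncated ECDF through the normal quantile, unit-SD
    rescaling), as in copula-based graphical-model estimation, so ``fit``
    only records the input schema.

    Parameters
    ----------
    truncation_delta : float or None
        Winsorization level for the ECDF.  ``None`` (default) uses the
        sample-size-dependent ``delta_n = 1/(4 n^{1/4} sqrt(pi log n))``.
    """

    def __init__(self, truncation_delta: float | None = None):
        self.truncation_delta = truncation_delta

    def fit(self, X, y=None):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        columns = index = None
        if isinstance(X, pd.DataFrame):
            columns, index = X.columns, X.index
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 4:
            raise ValueError("nonparanormal transform needs at least 4 samples")
        if np.any(X.std(axis=0) == 0):
            bad = int(np.argmin(X.std(axis=0)))
            raise ValueError(f"column {bad} is constant (zero variance)")
        delta = self.truncation_delta
        if delta is None:
            delta = default_truncation_delta(n)
        if not 0 < delta < 0.5:
            raise ValueError("truncation_delta must lie in (0, 0.5)")
        u = stats.rankdata(X, axis=0, method="average") / n
        z = ndtri(np.clip(u, delta, 1.0 - delta))
        z = z / z.std(axis=0, ddof=1)
        if columns is not None:
            return pd.DataFrame(z, columns=columns, index=index)
        return z

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def nonparanormal_transform(table: pd.DataFrame, truncation_delta: float | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`NonparanormalTransformer`."""
    return NonparanormalTransformer(truncation_delta).fit_transform(table)


class CorrelationResult:
    """Pearson correlation matrix with two-sided significance flags.

    Attributes: ``values`` (DataFrame), ``p_values`` (DataFrame), ``n``, and
    ``flags`` ('**' for p < .01, '*' for p <= .05, '' otherwise).
    """

    def __init__(self, values: pd.DataFrame, p_values: pd.DataFrame, n: int):
        self.values = values
        self.p_values = p_values
        self.n = n

    @property
    def flags(self) -> pd.DataFrame:
        p = self.p_values.to_numpy()
        f = np.where(p < 0.01, "**", np.where(p <= 0.05, "*", ""))
        f = pd.DataFrame(f, index=self.values.index, columns=self.values.columns)
        np.fill_diagonal(f.values, "")
        return f

    def annotated(self) -> pd.DataFrame:
        return self.values.round(2).astype(str) + self.flags


def pearson_matrix(table: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations with t-test p-values (no correction)."""
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("correlation requires at least 4 participants")
    if np.any(X.std(axis=0) == 0):
        bad = table.columns[int(np.argmin(X.std(axis=0)))]
        raise ValueError(f"column {bad!r} is constant")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pvals, 0.0)
    cols = list(table.columns)
    return CorrelationResult(
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(pvals, index=cols, columns=cols),
        n,
    )
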