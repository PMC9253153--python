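"""Bootstrap accuracy and stability of the estimated network.

Three procedures, all resampling at the participant level:

* edge-weight accuracy: nonparametric bootstrap (resample participants with
  replacement), re-estimating the full pipeline (nonparanormal transform +
  EBIC-glasso) on every resample and summarizing each edge by its empirical
  percentile confidence interval;
* centrality stability: case-dropping bootstrap - subsample without
  replacement at a grid of drop proportions and correlate the subsample
  centrality vectors with the original ones; summarized by the correlation
  stability (CS) coefficient, the largest drop proportion at which at least
  95% of subsamples stay correlated >= 0.7 with the original;
* sample-size planning: simulate Gaussian data from a fitted model's implied
  covariance at a grid of sample sizes and report edge-recovery sensitivity,
  specificity, and weight correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import betweenness, closeness, strength
from .features import NonparanormalTransformer
from .network import EDGE_ZERO_THRESHOLD, EBICGraphicalLasso, NetworkModel

__all__ = [
    "StabilityConfig",
    "bootstrap_edges",
    "casedrop_bootstrap",
    "cs_coefficient",
    "sample_size_simulation",
]


@dataclass(frozen=True)
class StabilityConfig:
    n_boot: int = 1000
    drop_proportions: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))
    cor_threshold: float = 0.7
    confidence: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if any(not 0 <= p < 1 for p in self.drop_proportions):
            raise ValueError("drop proportions must lie in [0, 1)")
        if not 0 < self.cor_threshold < 1:
            raise ValueError("cor_threshold must lie in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")


def _fit_weights(X: np.ndarray, estimator: EBICGraphicalLasso, transform: bool) -> np.ndarray:
    if transform:
        X = NonparanormalTransformer().fit_transform(X)
    est = estimator.__class__(**estimator.get_params())
    return est.fit(X).weights_


def bootstrap_edges(
    table: pd.DataFrame,
    config: StabilityConfig = StabilityConfig(),
    estimator: EBICGraphicalLasso | None = None,
    *,
    transform: bool = True,
) -> pd.DataFrame:
    """Percentile bootstrap confidence intervals for every edge weight.

    Returns one row per node pair with the original weight, bootstrap mean,
    and the (1 - confidence)/2 and 1 - (1 - confidence)/2 quantiles.
    Resamples that produce a constant column are redrawn (with a warning).
    """
    estimator = estimator or EBICGraphicalLasso()
    X = table.to_numpy(dtype=float)
    labels = list(table.columns)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    original = _fit_weights(X, estimator, transform)
    iu = np.triu_indices(p, 1)
    boots = np.empty((config.n_boot, iu[0].size))
    redraws = 0
    for b in range(config.n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            Xb = X[idx]
            if np.all(Xb.std(axis=0) > 0):
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a resample without constant columns")
        boots[b] = _fit_weights(Xb, estimator, transform)[iu]
    if redraws:
        warnings.warn(f"{redraws} resample(s) redrawn due to constant columns", stacklevel=2)
    alpha = 1.0 - config.confidence
    lower = np.quantile(boots, alpha / 2, axis=0)
    upper = np.quantile(boots, 1 - alpha / 2, axis=0)
    return pd.DataFrame(
        {
            "node_a": [labels[i] for i in iu[0]],
            "node_b": [labels[j] for j in iu[1]],
            "weight": original[iu],
            "boot_mean": boots.mean(axis=0),
            "lower": lower,
            "upper": upper,
        }
    )


_INDICES = ("strength", "closeness", "betweenness")


def _centrality_vectors(weights: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "strength": strength(weights),
        "closeness": closeness(weights),
        "betweenness": betweenness(weights),
    }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def casedrop_bootstrap(
    table: pd.DataFrame,
    config: StabilityConfig = StabilityConfig(),
    estimator: EBICGraphicalLasso | None = None,
    *,
    transform: bool = True,
) -> pd.DataFrame:
    """Case-dropping bootstrap of the centrality indices.

    For each drop proportion, draws ``n_boot`` subsamples without replacement
    of size ``round((1 - p) n)``, re-estimates network and centralities, and
    records the Pearson correlation of each index vector with the original.
    Correlations with a constant vector are undefined and recorded as NaN.
    """
    estimator = estimator or EBICGraphicalLasso()
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    reference = _centrality_vectors(_fit_weights(X, estimator, transform))
    rows = []
    for prop in config.drop_proportions:
        size = int(round((1.0 - prop) * n))
        if size < p + 2:
            warnings.warn(f"drop proportion {prop} leaves only {size} cases; skipped", stacklevel=2)
            continue
        for b in range(config.n_boot):
            idx = rng.choice(n, size=size, replace=False)
            Xs = X[idx]
            if np.any(Xs.std(axis=0) == 0):
                rows.extend(
                    {"index": name, "proportion": prop, "replicate": b, "correlation": np.nan}
                    for name in _INDICES
                )
                continue
            vectors = _centrality_vectors(_fit_weights(Xs, estimator, transform))
            for name in _INDICES:
                rows.append(
                    {
                        "index": name,
                        "proportion": prop,
                        "replicate": b,
                        "correlation": _safe_corr(reference[name], vectors[name]),
                    }
                )
    return pd.DataFrame(rows, columns=["index", "proportion", "replicate", "correlation"])


def cs_coefficient(curve: pd.DataFrame, config: StabilityConfig = StabilityConfig()) -> pd.Series:
    """Correlation stability coefficient per centrality index.

    The largest drop proportion ``prop`` in the grid such that, for every
    grid proportion up to and including ``prop``, at least ``confidence`` of
    the subsample correlations reach ``cor_threshold``.  0 when even the
    smallest proportion fails.  NaN correlations count as failures.
    """
    out = {}
    for name, sub in curve.groupby("index"):
        props = sorted(sub["proportion"].unique())
        if len(props) < 3:
            raise ValueError("CS coefficient requires a curve over at least 3 proportions")
        cs = 0.0
        for prop in props:
            vals = sub.loc[sub["proportion"] == prop, "correlation"].to_numpy()
            ok = np.mean(np.nan_to_num(vals, nan=-np.inf) >= config.cor_threshold)
            if ok >= config.confidence:
                cs = prop
            else:
                break
        out[name] = cs
    return pd.Series(out, name="cs")


def sample_size_simulation(
    model: NetworkModel,
    n_grid: tuple[int, ...] = (100, 250, 500, 1000),
    replicates: int = 100,
    seed: int = 0,
    *,
    transform: bool = False,
) -> pd.DataFrame:
    """Edge-recovery performance when re-estimating the model at smaller n.

    Draws Gaussian data from the model's implied covariance (the inverse of
    its precision matrix), re-estimates the network with the same EBIC
    settings, and reports per-n means of sensitivity (true edges recovered),
    specificity (true zeros kept), and the Pearson correlation between the
    true and estimated weight vectors.
    """
    if replicates < 10:
        raise ValueError("need at least 10 replicates")
    cov = np.linalg.inv(model.precision)
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0 or not np.all(np.isfinite(cov)):
        raise ValueError("model's implied covariance is singular")
    p = cov.shape[0]
    iu = np.triu_indices(p, 1)
    true_w = model.weights[iu]
    true_edges = np.abs(true_w) > EDGE_ZERO_THRESHOLD
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    est_proto = EBICGraphicalLasso(gamma=model.gamma)
    rows = []
    for n in n_grid:
        sens, spec, corr = [], [], []
        for _ in range(replicates):
            X = rng.standard_normal((n, p)) @ chol.T
            w = _fit_weights(X, est_proto, transform)[iu]
            found = np.abs(w) > EDGE_ZERO_THRESHOLD
            if true_edges.any():
                sens.append(np.mean(found[true_edges]))
            if (~true_edges).any():
                spec.append(np.mean(~found[~true_edges]))
            corr.append(_safe_corr(true_w, w))
        rows.append(
            {
                "n": n,
                "sensitivity": float(np.mean(sens)) if sens else np.nan,
                "specificity": float(np.mean(spec)) if spec else np.nan,
                "weight_correlation": float(np.nanmean(corr))
                if not np.all(np.isnan(corr))
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
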