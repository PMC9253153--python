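"""End-to-end orchestration: signals -> features -> network -> centrality -> stability.

Three input modes cover the ways the analysis can be entered:

* ``raw-signals``: per-participant angle waveforms, relocation trials and
  scalar measures; runs kinematic feature extraction first;
* ``feature-table``: a ready participants-by-features table; starts at the
  nonparanormal transform;
* ``correlation-matrix``: a correlation matrix plus its sample size (e.g. the
  published matrix of a study whose raw data are unavailable); skips the
  transform and goes straight to network estimation.

Every stage's output is persisted as delimited text under the configured
output directory, and the run is summarized in a single ``report.json`` whose
provenance block (config, seed, version) suffices to repeat the analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .centrality import centrality_profile
from .features import aggregate_features, joint_reposition_error, nonparanormal_transform, pearson_matrix
from .kinematics import SparcParams, extract_plane_features
from .network import EBICGraphicalLasso, NetworkModel, PathConfig, validate_correlation_matrix
from .stability import StabilityConfig, bootstrap_edges, casedrop_bootstrap, cs_coefficient

logger = logging.getLogger("kinenet")

INPUT_MODES = ("raw-signals", "feature-table", "correlation-matrix")


@dataclass
class PipelineConfig:
    """Declarative configuration of one analysis run."""

    mode: str
    signals_dir: str | None = None
    feature_table: str | None = None
    correlation_matrix: str | None = None
    n: int | None = None  # sample size behind a correlation-matrix input
    filter_order: int = 10
    cutoff_hz: float = 10.0
    threshold_ratio: float = 0.05
    sparc: SparcParams = field(default_factory=SparcParams)
    truncation_delta: float | None = None
    gamma: float = 0.5
    path: PathConfig = field(default_factory=PathConfig)
    stability: StabilityConfig | None = None
    out_dir: str = "kinenet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ValueError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")
        inputs = {
            "raw-signals": self.signals_dir,
            "feature-table": self.feature_table,
            "correlation-matrix": self.correlation_matrix,
        }
        if inputs[self.mode] is None:
            raise ValueError(f"mode {self.mode!r} requires its input path")
        if self.mode == "correlation-matrix" and self.n is None:
            raise ValueError("correlation-matrix mode requires the sample size n")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sparc" in raw:
            raw["sparc"] = SparcParams(**raw["sparc"])
        if "path" in raw:
            raw["path"] = PathConfig(**raw["path"])
        if "stability" in raw:
            raw["stability"] = StabilityConfig(**raw["stability"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    descriptives: pd.DataFrame
    correlations: pd.DataFrame | None
    network: NetworkModel
    centrality: pd.DataFrame
    stability_cs: pd.Series | None
    provenance: dict


def descriptive_summary(table: pd.DataFrame, grouping=None) -> pd.DataFrame:
    """Mean and SD per feature, optionally split by group labels."""
    if grouping is None:
        out = table.agg(["mean", "std"]).T
        return out.rename(columns={"std": "sd"})
    grouping = pd.Series(np.asarray(grouping), index=table.index, name="group")
    frames = {}
    for g, sub in table.groupby(grouping):
        frames[g] = sub.agg(["mean", "std"]).T.rename(columns={"std": "sd"})
    return pd.concat(frames, axis=1)


def extract_feature_table(cohort: dict, *, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Kinematic extraction + aggregation for a cohort of raw recordings."""
    config = config or PipelineConfig(mode="feature-table", feature_table="-")
    rows = {}
    for pid, rec in cohort.items():
        per_direction = []
        for plane, waveform in rec["waveforms"].items():
            df = extract_plane_features(
                waveform,
                filter_order=config.filter_order,
                cutoff_hz=config.cutoff_hz,
                threshold_ratio=config.threshold_ratio,
                sparc_params=config.sparc,
            )
            if df.empty:
                logger.warning("participant %s: no cycles in plane %s", pid, plane)
                continue
            per_direction.append(
                df.groupby("direction")[["rom_deg", "mean_velocity_deg_s", "sparc"]].mean()
            )
        directional = pd.concat(per_direction)
        scalars = rec["scalars"]
        rows[pid] = aggregate_features(
            directional.reset_index(),
            strength_flexion_n=float(scalars["strength_flexion_n"]),
            strength_extension_n=float(scalars["strength_extension_n"]),
            jpe_deg=joint_reposition_error(rec["relocation"]),
            tsk=float(scalars["tsk"]),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "participant"
    return table


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the stages implied by the input mode and persist all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: mode=%s seed=%d", config.mode, config.seed)

    table = None
    if config.mode == "raw-signals":
        cohort = kio.read_cohort_recordings(config.signals_dir)
        logger.info("loaded %d participants of raw recordings", len(cohort))
        table = extract_feature_table(cohort, config=config)
        kio.write_feature_table(table, out / "features.csv")
    elif config.mode == "feature-table":
        table = kio.read_feature_table(config.feature_table)
        logger.info("loaded feature table with %d participants", len(table))

    estimator = EBICGraphicalLasso(
        gamma=config.gamma,
        n_lambdas=config.path.n_lambdas,
        lambda_min_ratio=config.path.lambda_min_ratio,
        penalize_diagonal=config.path.penalize_diagonal,
    )

    correlations = None
    if table is not None:
        table = table.dropna()
        logger.info("complete cases: %d", len(table))
        descriptives = descriptive_summary(table)
        corr = pearson_matrix(table)
        correlations = corr.values
        kio.write_matrix(corr.values, out / "correlations.csv")
        kio.write_matrix(corr.p_values, out / "correlation_pvalues.csv")
        transformed = nonparanormal_transform(table, config.truncation_delta)
        estimator.fit(transformed)
    else:
        S = kio.read_matrix(config.correlation_matrix)
        validate_correlation_matrix(S.to_numpy())
        descriptives = pd.DataFrame(index=S.columns)
        estimator.fit_correlation(S, config.n)
        logger.info("correlation-matrix mode: skipped extraction and transformation")

    model = estimator.to_model()
    logger.info("selected lambda=%.4f edges=%d ebic=%.2f", model.lambda_, model.edge_count, model.ebic)
    kio.write_matrix(model.weights_frame, out / "network_weights.csv")
    model.edge_list().to_csv(out / "edges.csv", index=False)
    profile = centrality_profile(model.weights, model.node_labels)
    profile.to_csv(out / "centrality.csv")

    cs = None
    if config.stability is not None and table is not None:
        stab = dataclasses.replace(config.stability, seed=config.seed)
        edge_ci = bootstrap_edges(table, stab, estimator)
        edge_ci.to_csv(out / "edge_bootstrap.csv", index=False)
        curve = casedrop_bootstrap(table, stab, estimator)
        curve.to_csv(out / "casedrop_curve.csv", index=False)
        cs = cs_coefficient(curve, stab)
        cs.rename_axis("index").to_csv(out / "cs_coefficients.csv")

    provenance = {
        "config": _config_dict(config),
        "seed": config.seed,
        "version": _version(),
    }
    report = AnalysisReport(descriptives, correlations, model, profile, cs, provenance)
    with open(out / "report.json", "w") as fh:
        json.dump(_report_dict(report), fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; outputs in %s", out)
    return report


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("kinenet")
    except PackageNotFoundError:
        return "unknown"


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _report_dict(report: AnalysisReport) -> dict:
    model = report.network
    return {
        "descriptives": json.loads(report.descriptives.to_json(orient="index")),
        "correlations": None
        if report.correlations is None
        else report.correlations.round(10).to_dict(),
        "network": {
            "node_labels": list(model.node_labels),
            "weights": np.round(model.weights, 10).tolist(),
            "lambda": model.lambda_,
            "gamma": model.gamma,
            "ebic": model.ebic,
            "edge_count": model.edge_count,
            "n": model.n,
        },
        "centrality": json.loads(report.centrality.to_json(orient="index")),
        "cs_coefficients": None if report.stability_cs is None else report.stability_cs.to_dict(),
        "provenance": report.provenance,
    }
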