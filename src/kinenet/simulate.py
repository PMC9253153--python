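"""Synthetic cohort and signal generation.

No raw recordings are deposited with the cohort this package models, so every
downstream stage is exercised against synthetic data with the published
statistical structure: a participants-by-features table drawn from a Gaussian
copula with the published marginal moments and Pearson correlation targets,
cyclic neck-movement angle waveforms with controllable range, speed, and
smoothness, and head-relocation trials with known repositioning errors.

Correlated sampling uses the Cholesky factor of the target correlation matrix
applied to independent standard normals, so the population correlation is
exact by construction.  Optional strictly monotone marginal distortions (a
right-skewing shifted-exponential map for JPE, integer rounding for the TSK
questionnaire score) are applied after correlating, preserving rank structure
and exercising the nonparanormal step downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from . import datasets
from .kinematics import AngleWaveform

__all__ = [
    "CohortSpec",
    "MovementProfile",
    "RelocationTrialSpec",
    "RelocationTrial",
    "default_cohort_spec",
    "generate_feature_table",
    "generate_angle_waveform",
    "generate_relocation_trials",
    "generate_cohort_recordings",
    "shifted_exponential",
    "integer_scores",
]


# -- marginal distortions -------------------------------------------------

def shifted_exponential(mean: float, sd: float) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone map from a N(mean, sd) marginal to a shifted exponential.

    The image ``(mean - sd) + sd * Exp(1)`` has the same mean and SD but a
    right-skewed shape, appropriate for error magnitudes such as JPE.
    """

    def _map(x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - mean) / sd
        u = stats.norm.cdf(z)
        return (mean - sd) + sd * stats.expon.ppf(u)

    return _map


def integer_scores(lo: float, hi: float) -> Callable[[np.ndarray], np.ndarray]:
    """Round to integers and clip to a questionnaire's scale bounds."""

    def _map(x: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(np.asarray(x, dtype=float)), lo, hi)

    return _map


def _default_distortions(means: Mapping[str, float], sds: Mapping[str, float]):
    out: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    if "JPE" in means:
        out["JPE"] = shifted_exponential(means["JPE"], sds["JPE"])
    if "TSK" in means:
        out["TSK"] = integer_scores(17, 68)
    return out


# -- cohort spec ----------------------------------------------------------

@dataclass
class CohortSpec:
    """Specification of a synthetic participant cohort.

    ``target_correlation`` is the population Pearson correlation of the
    underlying Gaussian draw; ``marginal_distortions`` maps feature names to
    monotone callables applied afterwards (rank structure preserved).
    """

    feature_names: Sequence[str]
    marginal_means: Sequence[float]
    marginal_sds: Sequence[float]
    target_correlation: np.ndarray
    n: int = 100
    seed: int = 0
    marginal_distortions: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.marginal_means = np.asarray(self.marginal_means, dtype=float)
        self.marginal_sds = np.asarray(self.marginal_sds, dtype=float)
        self.target_correlation = np.asarray(self.target_correlation, dtype=float)
        p = len(self.feature_names)
        if self.marginal_means.shape != (p,) or self.marginal_sds.shape != (p,):
            raise ValueError("means/sds must match the number of features")
        if np.any(self.marginal_sds <= 0):
            raise ValueError("marginal_sds must be positive")
        C = self.target_correlation
        if C.shape != (p, p):
            raise ValueError("target_correlation must be p x p")
        if np.max(np.abs(C - C.T)) > 1e-10:
            raise ValueError("target_correlation must be symmetric")
        if np.max(np.abs(np.diag(C) - 1)) > 1e-10:
            raise ValueError("target_correlation must have unit diagonal")
        if np.max(np.abs(C)) > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin <= 0:
            raise ValueError(
                f"target_correlation is not positive definite (smallest eigenvalue {eigmin:.3e})"
            )
        if self.n < 1:
            raise ValueError("n must be positive")
        unknown = set(self.marginal_distortions) - set(self.feature_names)
        if unknown:
            raise ValueError(f"distortions reference unknown features: {sorted(unknown)}")


def default_cohort_spec(n: int = 100, seed: int = 0, *, distortions: bool = True) -> CohortSpec:
    """Cohort spec with the published pooled moments and correlation targets."""
    moments = datasets.pooled_moments()
    means = {f: moments.loc[f, "mean"] for f in datasets.NODE_ORDER}
    sds = {f: moments.loc[f, "sd"] for f in datasets.NODE_ORDER}
    return CohortSpec(
        feature_names=datasets.NODE_ORDER,
        marginal_means=[means[f] for f in datasets.NODE_ORDER],
        marginal_sds=[sds[f] for f in datasets.NODE_ORDER],
        target_correlation=datasets.reference_correlation_matrix().to_numpy(),
        n=n,
        seed=seed,
        marginal_distortions=_default_distortions(means, sds) if distortions else {},
    )


def generate_feature_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participants-by-features table from a cohort spec.

    Sampling: Z ~ iid N(0, 1), X = Z L' with L the Cholesky factor of the
    target correlation, then per-feature location/scale and any monotone
    distortions.  Sample marginals and correlations converge to the spec as
    n grows; bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.target_correlation)
    z = rng.standard_normal((spec.n, len(spec.feature_names)))
    x = z @ L.T
    x = spec.marginal_means + spec.marginal_sds * x
    table = pd.DataFrame(x, columns=list(spec.feature_names))
    for name, distort in spec.marginal_distortions.items():
        table[name] = distort(table[name].to_numpy())
    table.index.name = "participant"
    return table


# -- movement waveforms ---------------------------------------------------

@dataclass
class MovementProfile:
    """Parameters of one cyclic neck-movement recording.

    ``jerk_noise_amplitude`` is the RMS amplitude (degrees) of band-limited
    8-15 Hz angular noise superimposed on the raised-cosine cycles; it leaves
    ROM nearly intact while degrading SPARC monotonically.  ``cycle_cv``
    scales cycle-to-cycle duration variability (5% by default); peak
    amplitudes stay fixed so the noise-free ROM is exact.
    """

    plane: str = "flexion-extension"
    n_cycles: int = 10
    rom_deg: float = 50.0
    mean_velocity_deg_s: float = 62.0
    jerk_noise_amplitude: float = 0.0
    fs_hz: float = 100.0
    seed: int = 0
    cycle_cv: float = 0.05
    lead_in_s: float = 1.0
    lead_out_s: float = 1.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if self.rom_deg <= 0 or self.mean_velocity_deg_s <= 0:
            raise ValueError("rom_deg and mean_velocity_deg_s must be positive")
        if self.jerk_noise_amplitude < 0:
            raise ValueError("jerk_noise_amplitude must be nonnegative")


def _raised_cosine(a: float, b: float, n: int) -> np.ndarray:
    s = np.arange(1, n + 1) / n
    return a + (b - a) * 0.5 * (1 - np.cos(np.pi * s))


def generate_angle_waveform(profile: MovementProfile) -> AngleWaveform:
    """Cyclic angle waveform: raised-cosine half-cycles between +/- ROM.

    The noise-free profile starts at neutral (0 deg), rises to +rom, then
    alternates between -rom and +rom for ``n_cycles`` positive peaks, and
    returns to neutral; each transition is a raised cosine whose duration is
    set so the mean angular speed equals ``mean_velocity_deg_s`` (scaled per
    cycle by the duration variability).  Rest periods bracket the movement so
    downstream neutral-referencing has a baseline.
    """
    p = profile
    cycle_samples = 4.0 * p.rom_deg / p.mean_velocity_deg_s * p.fs_hz
    if cycle_samples < 10:
        raise ValueError(
            f"requested ROM/velocity imply a cycle of {cycle_samples:.1f} samples (< 10); "
            "lower the velocity or raise the ROM"
        )
    rng = np.random.default_rng(p.seed)
    # path lengths of the transitions: onset, 2*n-1 peak-to-peak, return
    spans = [(0.0, p.rom_deg)]
    sign = 1.0
    for _ in range(2 * p.n_cycles - 1):
        spans.append((sign * p.rom_deg, -sign * p.rom_deg))
        sign = -sign
    spans.append((sign * p.rom_deg, 0.0))
    peak_samples = []
    pieces = [np.zeros(int(round(p.lead_in_s * p.fs_hz)))]
    total = pieces[0].size
    for a, b in spans:
        speed = p.mean_velocity_deg_s
        if p.cycle_cv > 0:
            speed *= 1.0 + np.clip(p.cycle_cv * rng.standard_normal(), -2 * p.cycle_cv, 2 * p.cycle_cv)
        n = max(4, int(round(abs(b - a) / speed * p.fs_hz)))
        pieces.append(_raised_cosine(a, b, n))
        total += n
        if abs(b) > 0:  # transition ends on a peak
            peak_samples.append(total - 1)
    pieces.append(np.zeros(int(round(p.lead_out_s * p.fs_hz))))
    angle = np.concatenate(pieces)
    if p.jerk_noise_amplitude > 0:
        noise = rng.standard_normal(angle.size)
        sos = _signal.butter(4, (8.0, 15.0), btype="bandpass", fs=p.fs_hz, output="sos")
        noise = _signal.sosfiltfilt(sos, noise)
        noise *= p.jerk_noise_amplitude / np.std(noise)
        angle = angle + noise
    return AngleWaveform(
        angle,
        p.fs_hz,
        p.plane,
        meta={"peak_samples": peak_samples, "n_cycles": p.n_cycles},
    )


# -- relocation trials ----------------------------------------------------

@dataclass
class RelocationTrialSpec:
    """Six head-relocation trials (alternating sides) with known true errors."""

    true_errors_deg: Sequence[float]
    rotation_amplitude_deg: float = 70.0
    fs_hz: float = 100.0
    seed: int = 0
    mean_velocity_deg_s: float = 60.0

    def __post_init__(self) -> None:
        self.true_errors_deg = tuple(float(e) for e in self.true_errors_deg)
        if len(self.true_errors_deg) != 6:
            raise ValueError(f"exactly 6 trial errors required, got {len(self.true_errors_deg)}")
        if self.rotation_amplitude_deg <= 0:
            raise ValueError("rotation_amplitude_deg must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass
class RelocationTrial:
    """One marked relocation waveform: rotate away, return near neutral."""

    waveform: AngleWaveform
    start_index: int
    end_index: int


def generate_relocation_trials(spec: RelocationTrialSpec) -> list[RelocationTrial]:
    """Generate the six marked trials; alternating rotation sides.

    The angle at the end marker minus the angle at the start marker equals
    the requested signed error exactly.
    """
    rng = np.random.default_rng(spec.seed)
    trials = []
    hold = int(round(1.0 * spec.fs_hz))
    for i, err in enumerate(spec.true_errors_deg):
        side = 1.0 if i % 2 == 0 else -1.0
        target = side * spec.rotation_amplitude_deg
        speed = spec.mean_velocity_deg_s * (1.0 + 0.05 * rng.standard_normal())
        n_out = max(4, int(round(abs(target) / speed * spec.fs_hz)))
        n_back = max(4, int(round(abs(target - err) / speed * spec.fs_hz)))
        angle = np.concatenate(
            [
                np.zeros(hold),
                _raised_cosine(0.0, target, n_out),
                np.full(int(round(0.5 * spec.fs_hz)), target),
                _raised_cosine(target, err, n_back),
                np.full(hold, err),
            ]
        )
        start_index = hold - 1
        end_index = angle.size - 1
        trials.append(
            RelocationTrial(
                AngleWaveform(angle, spec.fs_hz, "rotation", meta={"trial": i, "true_error_deg": err}),
                start_index,
                end_index,
            )
        )
    return trials


# -- full-cohort raw recordings -------------------------------------------

#: Linear map from a target SPARC value to the jerk-noise RMS amplitude
#: (degrees).  Anchored so the smoothest published group mean (about -1.6)
#: maps to a light contamination and values toward -1.9 to a heavy one; the
#: association between requested and extracted smoothness is monotone but,
#: unlike ROM and velocity, not calibrated to be exact.
_SPARC_NOISE_SCALE = 2.0
_SPARC_NOISE_ONSET = -1.55


def _sparc_to_noise(sparc_value: float) -> float:
    return max(0.0, _SPARC_NOISE_SCALE * (_SPARC_NOISE_ONSET - sparc_value))


def generate_cohort_recordings(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    seed: int = 0,
    *,
    n_cycles: int = 10,
) -> dict:
    """Raw recordings (3 planes + relocation trials + scalars) per participant.

    Each participant's waveforms use the table's ROM and velocity for every
    plane, jerk noise mapped monotonically from the table's SPARC, relocation
    errors scaled so the mean absolute error equals the table's JPE exactly,
    and the strength value split into flexion/extension peaks.  When
    ``out_dir`` is given, recordings are also written as delimited text via
    :mod:`kinenet.io`.
    """
    from . import io as kio

    root = np.random.SeedSequence(seed)
    cohort: dict = {}
    for pid, row in table.iterrows():
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(int(pid),))
        seeds = child.generate_state(8)
        rng = np.random.default_rng(seeds[0])
        waveforms = {}
        for k, plane in enumerate(("flexion-extension", "rotation", "lateral-flexion")):
            profile = MovementProfile(
                plane=plane,
                n_cycles=n_cycles,
                rom_deg=float(row["ROM"]),
                mean_velocity_deg_s=float(row["Velocity"]),
                jerk_noise_amplitude=_sparc_to_noise(float(row["SPARC"])),
                seed=int(seeds[1 + k]),
            )
            waveforms[plane] = generate_angle_waveform(profile)
        magnitudes = rng.exponential(1.0, 6)
        magnitudes *= float(row["JPE"]) * 6 / magnitudes.sum()
        signs = np.array([1, -1, 1, -1, 1, -1], dtype=float)
        trials = generate_relocation_trials(
            RelocationTrialSpec(true_errors_deg=signs * magnitudes, seed=int(seeds[4]))
        )
        ratio = 0.6 * np.exp(0.1 * rng.standard_normal())  # flexion/extension force ratio
        ext = 2.0 * float(row["Strength"]) / (1.0 + ratio)
        scalars = {
            "strength_flexion_n": ratio * ext,
            "strength_extension_n": ext,
            "tsk": float(row["TSK"]),
        }
        cohort[pid] = {"waveforms": waveforms, "relocation": trials, "scalars": scalars}
    if out_dir is not None:
        kio.write_cohort_recordings(cohort, out_dir)
    return cohort
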