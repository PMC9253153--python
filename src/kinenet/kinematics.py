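"""Extraction of ROM, mean velocity, and SPARC smoothness from neck-angle signals.

The processing chain mirrors standard IMU movement analysis: zero-phase
Butterworth low-pass filtering of the anatomical angle, numerical
differentiation to angular velocity, detection of directional movement
half-cycles from the angle extrema, trimming of each movement to the span
where speed exceeds 5% of its within-cycle peak, and per-movement feature
computation.  Smoothness uses the spectral arc length (SPARC): the arc length
of the normalized magnitude spectrum of the speed profile up to an adaptive
cutoff — a negative number, closer to zero for smoother movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AngleWaveform",
    "VelocityWaveform",
    "MovementSegment",
    "SparcParams",
    "lowpass_filter",
    "differentiate",
    "neutral_reference",
    "detect_cycles",
    "segment_movement",
    "compute_rom",
    "mean_velocity",
    "sparc",
    "extract_plane_features",
    "DIRECTION_LABELS",
]

#: Anatomical direction labels per movement plane.  The positive angle
#: direction maps to the first label.
DIRECTION_LABELS = {
    "flexion-extension": ("flexion", "extension"),
    "rotation": ("right-rotation", "left-rotation"),
    "lateral-flexion": ("right-lateral-flexion", "left-lateral-flexion"),
}


@dataclass
class AngleWaveform:
    """Uniformly sampled joint-angle time series for one movement plane."""

    samples: np.ndarray
    fs_hz: float
    plane: str = "flexion-extension"
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class VelocityWaveform:
    """Angular velocity (deg/s) with the same sampling contract as its source."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass(frozen=True)
class MovementSegment:
    """Inclusive [start_sample, end_sample] span of one directional movement."""

    cycle_index: int
    start_sample: int
    end_sample: int
    direction: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("segment must satisfy 0 <= start < end")


@dataclass(frozen=True)
class SparcParams:
    """Spectral arc length parameters (defaults of the standard formulation).

    ``max_cutoff_hz`` caps the spectral band; ``amplitude_threshold`` sets the
    adaptive cutoff at the highest frequency where the normalized magnitude
    spectrum still reaches the threshold; ``zero_padding_factor`` pads the FFT
    to ``2 ** (ceil(log2 n) + factor)`` points for spectral resolution.
    """

    max_cutoff_hz: float = 20.0
    amplitude_threshold: float = 0.05
    zero_padding_factor: int = 4

    def __post_init__(self) -> None:
        if self.max_cutoff_hz <= 0:
            raise ValueError("max_cutoff_hz must be positive")
        if not 0 < self.amplitude_threshold < 1:
            raise ValueError("amplitude_threshold must lie in (0, 1)")
        if self.zero_padding_factor < 1:
            raise ValueError("zero_padding_factor must be >= 1")


def _min_filter_length(order: int) -> int:
    # sosfiltfilt requires x.shape[axis] > padlen; padlen for `order` even is
    # 3 * (2 * n_sections + 1) with n_sections = order / 2.
    n_sections = (order + 1) // 2
    return 3 * (2 * n_sections + 1) + 1


def lowpass_filter(w: AngleWaveform, order: int = 10, cutoff_hz: float = 10.0) -> AngleWaveform:
    """Zero-phase Butterworth low-pass filter (forward-backward), DC gain 1."""
    if cutoff_hz >= w.fs_hz / 2:
        raise ValueError("cutoff_hz must be below the Nyquist frequency")
    min_len = max(_min_filter_length(order), 3 * order + 1)
    if w.samples.size < min_len:
        raise ValueError(
            f"waveform too short for order-{order} zero-phase filtering: "
            f"{w.samples.size} samples, need at least {min_len}"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=w.fs_hz, output="sos")
    out = signal.sosfiltfilt(sos, w.samples)
    return AngleWaveform(out, w.fs_hz, w.plane, dict(w.meta))


def differentiate(w: AngleWaveform) -> VelocityWaveform:
    """Numerical differentiation: central differences, one-sided at the ends."""
    if w.samples.size < 3:
        raise ValueError("differentiation needs at least 3 samples")
    v = np.gradient(w.samples, 1.0 / w.fs_hz)
    return VelocityWaveform(v, w.fs_hz)


def neutral_reference(w: AngleWaveform, window_s: float = 0.5) -> float:
    """Neutral-posture angle: median over the initial rest window."""
    n = max(1, int(round(window_s * w.fs_hz)))
    return float(np.median(w.samples[:n]))


def _alternating_extrema(theta: np.ndarray, min_height: float) -> list[int]:
    """Indices of prominent angle extrema, cleaned to alternate in sign."""
    peaks_pos, _ = signal.find_peaks(theta, height=min_height)
    peaks_neg, _ = signal.find_peaks(-theta, height=min_height)
    extrema = sorted(np.concatenate([peaks_pos, peaks_neg]).astype(int))
    cleaned: list[int] = []
    for idx in extrema:
        if cleaned and np.sign(theta[idx]) == np.sign(theta[cleaned[-1]]):
            # consecutive same-direction extrema: keep the larger excursion
            if abs(theta[idx]) > abs(theta[cleaned[-1]]):
                cleaned[-1] = idx
        else:
            cleaned.append(idx)
    return cleaned


def detect_cycles(
    w: AngleWaveform,
    *,
    min_amplitude_ratio: float = 0.25,
    neutral: float | None = None,
) -> list[MovementSegment]:
    """Directional movement half-cycles delimited by the angle extrema.

    Each returned segment spans from the previous extremum (or movement onset,
    for the first) to one detected extremum, so it contains the full approach
    to that cycle's peak.  Direction is the sign of the angular change over
    the segment mapped to the plane's anatomical labels.  Returns an empty
    list (with a warning) when no prominent extrema exist.
    """
    ref = neutral_reference(w) if neutral is None else neutral
    theta = w.samples - ref
    amp = float(np.max(np.abs(theta)))
    if amp <= 0:
        warnings.warn("no angular excursion detected; no cycles", stacklevel=2)
        return []
    extrema = _alternating_extrema(theta, min_amplitude_ratio * amp)
    if not extrema:
        warnings.warn("no movement peaks detected; no cycles", stacklevel=2)
        return []
    pos_label, neg_label = DIRECTION_LABELS.get(w.plane, ("positive", "negative"))
    # movement onset: last near-neutral sample before the first extremum
    first = extrema[0]
    below = np.nonzero(np.abs(theta[:first]) < 0.02 * amp)[0]
    onset = int(below[-1]) if below.size else 0
    segments: list[MovementSegment] = []
    boundaries = [onset] + extrema
    n_pos = 0
    for k in range(len(extrema)):
        start, end = boundaries[k], boundaries[k + 1]
        if end <= start:
            continue
        positive = theta[end] > theta[start]
        if positive:
            n_pos += 1
        segments.append(
            MovementSegment(
                cycle_index=k // 2,
                start_sample=start,
                end_sample=end,
                direction=pos_label if positive else neg_label,
            )
        )
    return segments


def segment_movement(v: VelocityWaveform, cycle: MovementSegment, threshold_ratio: float = 0.05) -> MovementSegment:
    """Trim a cycle to where speed is at least ``threshold_ratio`` of its peak.

    Start is the first sample at/above the threshold, end the last; both are
    relative to the within-cycle peak speed, so the trimmed span brackets the
    velocity peak.
    """
    speed = np.abs(v.samples[cycle.start_sample : cycle.end_sample + 1])
    peak = float(speed.max())
    if peak <= 0:
        raise ValueError("velocity is identically zero inside the cycle")
    above = np.nonzero(speed >= threshold_ratio * peak)[0]
    start = cycle.start_sample + int(above[0])
    end = cycle.start_sample + int(above[-1])
    return MovementSegment(cycle.cycle_index, start, end, cycle.direction)


def compute_rom(w: AngleWaveform, cycle: MovementSegment, *, neutral: float | None = None) -> float:
    """Peak absolute angular excursion from neutral within the cycle (degrees)."""
    ref = neutral_reference(w) if neutral is None else neutral
    seg = w.samples[cycle.start_sample : cycle.end_sample + 1]
    return float(np.max(np.abs(seg - ref)))


def mean_velocity(v: VelocityWaveform, seg: MovementSegment) -> float:
    """Arithmetic mean absolute angular speed over the segment (deg/s)."""
    speed = np.abs(v.samples[seg.start_sample : seg.end_sample + 1])
    return float(speed.mean())


def sparc(v: VelocityWaveform, seg: MovementSegment | None = None, params: SparcParams = SparcParams()) -> float:
    """Spectral arc length of the speed profile within a segment.

    With ``V(f)`` the magnitude spectrum of the speed signal (zero-padded DFT)
    and ``Vn(f) = V(f) / V(0)``, the adaptive cutoff is
    ``f_c = min(max_cutoff_hz, highest f with Vn >= amplitude_threshold)`` and

        SPARC = - integral_0^{f_c} sqrt((1/f_c)^2 + (dVn/df)^2) df .

    Always negative; invariant to amplitude scaling of the speed profile.
    """
    if seg is None:
        speed = np.abs(v.samples)
    else:
        speed = np.abs(v.samples[seg.start_sample : seg.end_sample + 1])
    if speed.size < 8:
        raise ValueError("segment too short for spectral analysis (need >= 8 samples)")
    nfft = 2 ** (int(np.ceil(np.log2(speed.size))) + params.zero_padding_factor)
    spectrum = np.abs(np.fft.rfft(speed, nfft))
    if spectrum[0] <= 0:
        raise ValueError("zero-mean speed profile: V(0) = 0")
    vn = spectrum / spectrum[0]
    freqs = np.fft.rfftfreq(nfft, d=1.0 / v.fs_hz)
    band = freqs <= params.max_cutoff_hz
    vn_band = vn[band]
    above = np.nonzero(vn_band >= params.amplitude_threshold)[0]
    cut = int(above[-1]) if above.size else 1
    cut = max(cut, 1)
    vn_sel = vn_band[: cut + 1]
    f_sel = freqs[band][: cut + 1]
    f_c = f_sel[-1]
    df = np.diff(f_sel) / f_c
    dv = np.diff(vn_sel)
    return float(-np.sum(np.sqrt(df**2 + dv**2)))


def extract_plane_features(
    w: AngleWaveform,
    *,
    filter_order: int = 10,
    cutoff_hz: float = 10.0,
    threshold_ratio: float = 0.05,
    sparc_params: SparcParams = SparcParams(),
    min_amplitude_ratio: float = 0.25,
) -> pd.DataFrame:
    """Per-movement features for one plane: filter, differentiate, segment.

    Returns one row per directional half-cycle with columns
    ``(plane, direction, cycle, rom_deg, mean_velocity_deg_s, sparc)``.
    Cycles whose segmentation or SPARC computation fails are dropped with a
    warning, matching offline-analysis practice.
    """
    filtered = lowpass_filter(w, filter_order, cutoff_hz)
    ref = neutral_reference(filtered)
    v = differentiate(filtered)
    rows = []
    for cyc in detect_cycles(filtered, min_amplitude_ratio=min_amplitude_ratio, neutral=ref):
        try:
            seg = segment_movement(v, cyc, threshold_ratio)
            rows.append(
                {
                    "plane": w.plane,
                    "direction": cyc.direction,
                    "cycle": cyc.cycle_index,
                    "rom_deg": compute_rom(filtered, cyc, neutral=ref),
                    "mean_velocity_deg_s": mean_velocity(v, seg),
                    "sparc": sparc(v, seg, sparc_params),
                }
            )
        except ValueError as err:
            warnings.warn(f"cycle {cyc.cycle_index} ({cyc.direction}) dropped: {err}", stacklevel=2)
    return pd.DataFrame(rows, columns=["plane", "direction", "cycle", "rom_deg", "mean_velocity_deg_s", "sparc"])
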