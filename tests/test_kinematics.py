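"""Kinematic feature extraction: filtering, differentiation, segmentation, SPARC."""

import numpy as np
import pytest
from scipy.integrate import quad

from kinenet import (
    AngleWaveform,
    MovementProfile,
    MovementSegment,
    SparcParams,
    VelocityWaveform,
    compute_rom,
    detect_cycles,
    differentiate,
    extract_plane_features,
    generate_angle_waveform,
    lowpass_filter,
    mean_velocity,
    segment_movement,
    sparc,
)

FS = 100.0


def _sine_wave(freq, seconds=10.0, amp=1.0):
    t = np.arange(0, seconds, 1 / FS)
    return AngleWaveform(amp * np.sin(2 * np.pi * freq * t), FS)


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        w = AngleWaveform(np.full(500, 30.0), FS)
        out = lowpass_filter(w)
        np.testing.assert_allclose(out.samples, 30.0, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        out = lowpass_filter(_sine_wave(1.0))
        mid = out.samples[200:-200]
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_sinusoid_attenuated(self):
        out = lowpass_filter(_sine_wave(25.0))
        assert np.max(np.abs(out.samples[200:-200])) < 0.01

    def test_short_input_rejected_with_minimum(self):
        w = AngleWaveform(np.zeros(10), FS)
        with pytest.raises(ValueError, match="at least"):
            lowpass_filter(w)


class TestDifferentiate:
    def test_constant_gives_zero_velocity(self):
        v = differentiate(AngleWaveform(np.full(100, 5.0), FS))
        np.testing.assert_allclose(v.samples, 0.0, atol=1e-12)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 2, 1 / FS)
        v = differentiate(AngleWaveform(10.0 * t, FS))
        np.testing.assert_allclose(v.samples, 10.0, atol=1e-9)

    def test_sinusoid_matches_symbolic_derivative(self):
        f, A = 1.0, 2.0
        t = np.arange(0, 4, 1 / FS)
        v = differentiate(AngleWaveform(A * np.sin(2 * np.pi * f * t), FS))
        exact = 2 * np.pi * f * A * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 * A / 6 * (1 / FS) ** 2  # central-difference truncation
        assert np.max(np.abs(v.samples[1:-1] - exact[1:-1])) < 1.5 * bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3"):
            differentiate(AngleWaveform(np.array([0.0, 1.0]), FS))


class TestDetectCycles:
    def test_ten_cycle_waveform_gives_ten_flexion_peaks(self):
        w = generate_angle_waveform(MovementProfile(n_cycles=10, jerk_noise_amplitude=0.2))
        segs = detect_cycles(lowpass_filter(w))
        assert sum(s.direction == "flexion" for s in segs) == 10
        assert sum(s.direction == "extension" for s in segs) == 10

    def test_monotone_ramp_has_no_cycles(self):
        t = np.arange(0, 5, 1 / FS)
        with pytest.warns(UserWarning):
            segs = detect_cycles(AngleWaveform(10 * t, FS))
        assert segs == []

    def test_detected_peaks_match_construction(self):
        """Known noise-free peak sample indices recovered within +-2 samples."""
        w = generate_angle_waveform(
            MovementProfile(n_cycles=3, jerk_noise_amplitude=0, cycle_cv=0)
        )
        segs = detect_cycles(w)
        detected = sorted(s.end_sample for s in segs)
        expected = sorted(w.meta["peak_samples"])
        assert len(detected) == len(expected)
        assert all(abs(d - e) <= 2 for d, e in zip(detected, expected))


class TestSegmentMovement:
    def test_linear_ramp_threshold_crossing_closed_form(self):
        """Speed ramp to 100 deg/s over 1 s: 5% threshold = 5 deg/s, crossed
        at sample 5 after motion onset."""
        v = VelocityWaveform(np.arange(101, dtype=float), FS)  # v[i] = i deg/s
        seg = segment_movement(v, MovementSegment(0, 0, 100))
        assert seg.start_sample == 5
        assert seg.end_sample == 100

    def test_rectangular_pulse_kept_whole(self):
        speed = np.zeros(100)
        speed[30:70] = 50.0
        seg = segment_movement(VelocityWaveform(speed, FS), MovementSegment(0, 0, 99))
        assert (seg.start_sample, seg.end_sample) == (30, 69)

    def test_idempotent_on_trapezoid(self):
        speed = np.concatenate([np.linspace(0, 80, 50), np.full(50, 80.0), np.linspace(80, 0, 50)])
        v = VelocityWaveform(speed, FS)
        first = segment_movement(v, MovementSegment(0, 0, 149))
        second = segment_movement(v, first)
        assert (first.start_sample, first.end_sample) == (second.start_sample, second.end_sample)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            segment_movement(VelocityWaveform(np.zeros(50), FS), MovementSegment(0, 0, 49))


class TestRomAndVelocity:
    def test_noise_free_raised_cosine_rom(self):
        n = 200
        angle = 50.0 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
        rom = compute_rom(AngleWaveform(angle, FS), MovementSegment(0, 0, n - 1), neutral=0.0)
        assert rom == pytest.approx(50.0, abs=1e-9)

    def test_rom_with_noise_bounded_by_noise_amplitude(self, rng):
        n = 200
        angle = 50.0 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
        noisy = angle + rng.uniform(-0.5, 0.5, n)
        rom = compute_rom(AngleWaveform(noisy, FS), MovementSegment(0, 0, n - 1), neutral=0.0)
        assert abs(rom - 50.0) <= 0.5

    def test_constant_speed_mean(self):
        v = VelocityWaveform(np.full(80, 60.0), FS)
        assert mean_velocity(v, MovementSegment(0, 0, 79)) == 60.0

    def test_triangular_profile_matches_sample_mean_oracle(self):
        speed = np.concatenate([np.linspace(0, 90, 60), np.linspace(90, 0, 60)])
        v = VelocityWaveform(speed, FS)
        seg = MovementSegment(0, 10, 100)
        assert mean_velocity(v, seg) == pytest.approx(np.mean(speed[10:101]), abs=1e-12)


class TestSparc:
    def _bump(self, sigma=0.15, seconds=4.0):
        t = np.arange(0, seconds, 1 / FS)
        return VelocityWaveform(np.exp(-((t - seconds / 2) ** 2) / (2 * sigma**2)), FS)

    def test_amplitude_invariance(self):
        v = self._bump()
        v2 = VelocityWaveform(2.0 * v.samples, FS)
        assert sparc(v) == pytest.approx(sparc(v2), abs=1e-12)

    def test_gaussian_bump_matches_analytic_spectrum_quadrature(self):
        """The spectrum of a Gaussian speed bump is Gaussian; the arc length
        of the analytic normalized spectrum (dense quadrature) matches the
        FFT-based implementation within 1%."""
        sigma = 0.15
        v = self._bump(sigma)
        params = SparcParams()
        c = 2 * np.pi**2 * sigma**2
        f_c = min(params.max_cutoff_hz, np.sqrt(np.log(1 / params.amplitude_threshold) / c))

        def integrand(f):
            dv = -2 * c * f * np.exp(-c * f**2)
            return np.sqrt((1 / f_c) ** 2 + dv**2)

        oracle = -quad(integrand, 0, f_c, limit=500)[0]
        assert sparc(v, params=params) == pytest.approx(oracle, rel=0.01)

    def test_strictly_decreasing_under_10hz_contamination(self):
        v = self._bump()
        values = []
        for amp in (0.0, 0.02, 0.05, 0.1, 0.2, 0.4):
            contaminated = v.samples + amp * np.sin(2 * np.pi * 10.0 * np.arange(v.samples.size) / FS)
            values.append(sparc(VelocityWaveform(np.abs(contaminated), FS)))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_time_reversal_invariance(self):
        v = self._bump()
        rev = VelocityWaveform(v.samples[::-1].copy(), FS)
        assert sparc(v) == pytest.approx(sparc(rev), abs=1e-9)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError, match="V\\(0\\)"):
            sparc(VelocityWaveform(np.zeros(64), FS))


class TestPipelineRecovery:
    def test_noise_free_extraction_recovers_requested_parameters(self):
        """End-to-end: ROM within 2%, mean velocity within 5% of the request."""
        prof = MovementProfile(
            rom_deg=49.7, mean_velocity_deg_s=61.6, jerk_noise_amplitude=0, cycle_cv=0
        )
        df = extract_plane_features(generate_angle_waveform(prof))
        assert len(df) == 20
        assert abs(df["rom_deg"].mean() - 49.7) / 49.7 < 0.02
        assert abs(df["mean_velocity_deg_s"].mean() - 61.6) / 61.6 < 0.05
        assert (df["sparc"] < 0).all()

    def test_features_invariant_to_time_reversal(self):
        prof = MovementProfile(n_cycles=4, jerk_noise_amplitude=0, cycle_cv=0)
        w = generate_angle_waveform(prof)
        fwd = extract_plane_features(w)
        rev = extract_plane_features(AngleWaveform(w.samples[::-1].copy(), w.fs_hz, w.plane))
        for col in ("rom_deg", "mean_velocity_deg_s", "sparc"):
            assert np.allclose(
                np.sort(fwd[col].to_numpy()), np.sort(rev[col].to_numpy()), atol=1e-6
            )
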