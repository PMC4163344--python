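import numpy as np
import pytest

from conftest import FS, sinusoidal_compression_accel, tone_window
from cprspec.errors import NoCompressionActivityError, NoPeriodicityError
from cprspec.signal_io import AccelerationRecord
from cprspec.spectral import (
    AnalysisWindow,
    FeedbackEstimate,
    HarmonicSet,
    SpectralConfig,
    WindowGap,
    analyze_session,
    estimate_fundamental,
    estimate_harmonics,
    feedback_from_window,
    project_axes,
    reconstruct_cycle,
    window_and_spectrum,
)

BIN_HZ = FS / 2048  # 0.048828125


def triaxial_from_z(z, fs=FS):
    return AccelerationRecord(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]), fs=fs)


class TestProjectAxes:
    def test_single_axis_signal_recovered(self):
        t = np.arange(300) / FS
        z = 3.0 * np.cos(2 * np.pi * 2 * t) + 9.81
        win = project_axes(triaxial_from_z(z), 0.0, 3.0, mode="principal")
        ref = z - z.mean()
        assert min(np.max(np.abs(win.samples - ref)), np.max(np.abs(win.samples + ref))) < 1e-9

    def test_rotation_invariance_18_degrees(self):
        t = np.arange(300) / FS
        a = 3.0 * np.cos(2 * np.pi * 2 * t)
        tau = np.deg2rad(18.0)
        rec0 = triaxial_from_z(a + 9.81)
        tilted = np.column_stack(
            [np.sin(tau) * (a + 9.81), np.zeros_like(a), np.cos(tau) * (a + 9.81)]
        )
        w0 = project_axes(rec0, 0.0, 3.0).samples
        w1 = project_axes(AccelerationRecord(tilted, fs=FS), 0.0, 3.0).samples
        assert min(np.max(np.abs(w1 - w0)), np.max(np.abs(w1 + w0))) < 1e-6

    def test_zero_window_flags_no_activity(self):
        rec = triaxial_from_z(np.zeros(300))
        with pytest.raises(NoCompressionActivityError, match="no compression activity"):
            project_axes(rec, 0.0, 3.0)

    def test_out_of_bounds_window(self):
        rec = triaxial_from_z(np.zeros(300))
        with pytest.raises(ValueError, match="bounds"):
            project_axes(rec, 2.5, 3.0)

    def test_fixed_axis_mode(self):
        t = np.arange(300) / FS
        z = np.cos(2 * np.pi * 2 * t)
        win = project_axes(triaxial_from_z(z), 0.0, 3.0, mode=2)
        np.testing.assert_allclose(win.samples, z)


class TestWindowAndSpectrum:
    def test_constant_segment_is_spectrally_empty(self):
        win = AnalysisWindow(0, 3.0, np.full(300, 5.0), FS)
        sp = window_and_spectrum(win)
        assert np.max(np.abs(sp.X)) < 1e-9

    def test_peak_bin_of_1p5hz_cosine(self):
        # brute-force oracle: |rfft| of the tapered segment peaks at bin 31
        sp = window_and_spectrum(tone_window(1.5))
        i = int(np.argmax(np.abs(sp.X)))
        assert i == 31
        assert sp.freqs[i] == pytest.approx(31 * BIN_HZ)
        assert sp.df == pytest.approx(100 / 2048)

    def test_amplitude_corrected_by_coherent_gain(self):
        sp = window_and_spectrum(tone_window(1.5))
        amp = 2 * np.abs(sp.X[np.argmax(np.abs(sp.X))]) / sp.coherent_sum
        assert amp == pytest.approx(1.0, rel=0.03)

    def test_window_longer_than_nfft_rejected(self):
        win = AnalysisWindow(0, 30.0, np.ones(3000), FS)
        with pytest.raises(ValueError, match="n_fft"):
            window_and_spectrum(win)


class TestEstimateFundamental:
    def test_pure_tone_nearest_bin(self):
        # oracle: peak bin of the zero-padded spectrum of a 2.0 Hz cosine is 41
        sp = window_and_spectrum(tone_window(2.0))
        assert estimate_fundamental(sp) == pytest.approx(41 * BIN_HZ)

    def test_refined_estimate_tighter(self):
        sp = window_and_spectrum(tone_window(2.0))
        f = estimate_fundamental(sp, SpectralConfig(refine_peak=True))
        assert abs(f - 2.0) < 0.005

    def test_subharmonic_guard_recovers_fundamental(self):
        # 2nd harmonic stronger than the fundamental: pick f0, not 2 f0
        t = np.arange(300) / FS
        s = 0.5 * np.cos(2 * np.pi * 1.4 * t) + 1.0 * np.cos(2 * np.pi * 2.8 * t + 0.7)
        f = estimate_fundamental(window_and_spectrum(AnalysisWindow(0, 3, s, FS)))
        assert f == pytest.approx(1.4, abs=1.5 * BIN_HZ)

    def test_white_noise_has_no_periodicity(self, rng):
        win = AnalysisWindow(0, 3.0, rng.normal(0, 1, 300), FS)
        with pytest.raises(NoPeriodicityError):
            estimate_fundamental(window_and_spectrum(win))


class TestEstimateHarmonics:
    def test_displacement_amplitude_hand_value(self):
        # A1 = 1 m/s^2 at f_cc = 2 Hz -> S1 = 1000 / (4 pi)^2 = 6.3326 mm
        h = HarmonicSet(fcc=2.0, A=[1.0, 0, 0], theta=[0.0, 0, 0])
        assert h.S[0] == pytest.approx(1000 / (4 * np.pi) ** 2, rel=1e-12)
        assert h.S[0] == pytest.approx(6.3326, abs=5e-5)

    def test_phase_flip(self):
        h = HarmonicSet(fcc=2.0, A=[1.0], theta=[0.0])
        assert h.phi[0] == pytest.approx(np.pi)

    def test_single_harmonic_input_zeroes_others(self):
        sp = window_and_spectrum(tone_window(2.0))
        h = estimate_harmonics(sp, estimate_fundamental(sp))
        assert h.A[0] == pytest.approx(1.0, rel=0.03)
        assert h.A[1] == 0.0 and h.A[2] == 0.0

    def test_acceleration_reproduced_from_displacement_harmonics(self):
        # differentiating each displacement harmonic twice gives back the
        # acceleration harmonic: (2 pi k fcc)^2 * S_k / 1000 = A_k exactly
        h = HarmonicSet(fcc=1.7, A=[2.0, 0.4, 0.1], theta=[0.3, -1.0, 2.0])
        k = np.arange(1, 4)
        back = (2 * np.pi * k * h.fcc) ** 2 * h.S / 1000.0
        np.testing.assert_allclose(back, h.A, rtol=1e-14)


class TestReconstructCycle:
    def test_single_harmonic_peak_to_peak(self):
        h = HarmonicSet(fcc=2.0, A=[1.0], theta=[0.0], S=np.array([25.0]), phi=np.array([0.0]))
        cyc = reconstruct_cycle(h)
        assert cyc.max() - cyc.min() == pytest.approx(50.0, rel=1e-4)

    def test_two_harmonic_sum_oracle(self):
        # s = 20 cos(x) + 5 cos(2x): max 25 at x=0, min -15 at x=pi
        h = HarmonicSet(fcc=1.0, A=[1, 1, 0], theta=[0, 0, 0],
                        S=np.array([20.0, 5.0, 0.0]), phi=np.zeros(3))
        cyc = reconstruct_cycle(h, samples_per_cycle=4096)
        assert cyc.max() == pytest.approx(25.0, abs=1e-3)
        assert cyc.min() == pytest.approx(-15.0, abs=1e-3)

    def test_all_zero_harmonics_flat(self):
        h = HarmonicSet(fcc=2.0, A=[0.0, 0.0], theta=[0.0, 0.0])
        assert np.all(reconstruct_cycle(h) == 0.0)


class TestFeedbackFromWindow:
    def test_rate_is_sixty_times_fundamental(self):
        fb = feedback_from_window(tone_window(2.0))
        assert fb.rate == pytest.approx(60 * 41 * BIN_HZ)

    def test_closed_form_sinusoidal_compression(self):
        # 50 mm peak-to-peak at 100 min^-1, acceleration amplitude
        # (2 pi 100/60)^2 * 0.025 = 2.742 m/s^2, run through the full chain
        fb = feedback_from_window(sinusoidal_compression_accel(100, 50))
        assert fb.rate == pytest.approx(100, abs=1.5)
        assert fb.depth == pytest.approx(50, abs=1.0)

    def test_zero_window_produces_no_estimate(self):
        win = AnalysisWindow(0, 3.0, np.zeros(300), FS)
        with pytest.raises(NoPeriodicityError):
            feedback_from_window(win)


GRID = [(r, d) for r in (80, 100, 120, 140) for d in (30, 50)]


class TestClosedFormRecovery:
    @pytest.mark.parametrize("rate,depth", GRID)
    def test_rate_within_one_bin_and_depth_within_3pct(self, rate, depth):
        fb = feedback_from_window(sinusoidal_compression_accel(rate, depth))
        assert abs(fb.rate - rate) <= 60 * BIN_HZ
        assert fb.depth == pytest.approx(depth, rel=0.03)

    @pytest.mark.parametrize("rate,depth", [(80, 30), (140, 50)])
    def test_refined_rate_within_0p3(self, rate, depth):
        fb = feedback_from_window(
            sinusoidal_compression_accel(rate, depth), SpectralConfig(refine_peak=True)
        )
        assert abs(fb.rate - rate) <= 0.3


class TestInvariances:
    def test_offset_invariance(self):
        win = sinusoidal_compression_accel(100, 50)
        shifted = AnalysisWindow(0, 3.0, win.samples + 9.81, FS)
        fb0, fb1 = feedback_from_window(win), feedback_from_window(shifted)
        assert abs(fb1.rate - fb0.rate) / fb0.rate < 1e-3
        assert abs(fb1.depth - fb0.depth) / fb0.depth < 1e-3

    def test_scale_equivariance(self):
        win = sinusoidal_compression_accel(100, 50)
        scaled = AnalysisWindow(0, 3.0, 1.7 * win.samples, FS)
        fb0, fb1 = feedback_from_window(win), feedback_from_window(scaled)
        assert fb1.rate == fb0.rate
        assert fb1.depth == pytest.approx(1.7 * fb0.depth, rel=1e-9)

    def test_windows_independent_of_history(self):
        # estimate for window k does not depend on windows before it
        t = np.arange(int(12 * FS)) / FS
        z = 2.5 * np.cos(2 * np.pi * 2.0 * t)
        z[: int(6 * FS)] *= 10  # wildly different early signal
        rec_mod = triaxial_from_z(z)
        rec_ref = triaxial_from_z(np.where(t >= 6, z, 2.5 * np.cos(2 * np.pi * 2.0 * t)))
        out_mod = analyze_session(rec_mod, 3.0)
        out_ref = analyze_session(rec_ref, 3.0)
        for a, b in zip(out_mod[2:], out_ref[2:]):
            assert a.rate == b.rate and a.depth == pytest.approx(b.depth, rel=1e-12)


class TestAnalyzeSession:
    def test_window_counts_floor_rule(self, accel_record):
        assert len(analyze_session(accel_record, 3.0)) == 20
        assert len(analyze_session(accel_record, 7.0)) == 8

    def test_short_record_rejected(self, accel_record):
        with pytest.raises(ValueError, match="shorter"):
            analyze_session(accel_record, 120.0)

    def test_silent_stretch_yields_gap_markers(self, rng):
        t = np.arange(int(9 * FS)) / FS
        z = 2.5 * np.cos(2 * np.pi * 2 * t)
        z[int(3 * FS) : int(6 * FS)] = 0.0
        rec = AccelerationRecord(
            np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
            + rng.normal(0, 0.2, (len(z), 3)),
            fs=FS,
        )
        out = analyze_session(rec, 3.0)
        assert isinstance(out[0], FeedbackEstimate)
        assert isinstance(out[1], WindowGap)
        assert isinstance(out[2], FeedbackEstimate)
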