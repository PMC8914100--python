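"""Filtering, analytic phase/envelope, instantaneous frequency, spectra."""

import numpy as np
import pytest
from scipy import signal as sp_sig

from isapac import (analytic, bandpass_isa, downsample, highpass,
                    instantaneous_frequency, magnitude_spectrum,
                    spectral_slope, wrap_phase)
from isapac.synth import gen_pink_noise

from conftest import tone


def central(x, frac=0.25):
    n = len(x)
    return x[int(n * frac): int(n * (1 - frac))]


class TestWrapPhase:
    def test_range_is_half_open(self):
        th = np.array([-np.pi, np.pi, 0.0, 3 * np.pi / 2, -3 * np.pi / 2])
        w = wrap_phase(th)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)
        assert w[0] == pytest.approx(np.pi)     # -pi maps to +pi
        assert w[1] == pytest.approx(np.pi)
        assert w[3] == pytest.approx(-np.pi / 2)


class TestBandpass:
    def test_passband_center_unity_gain(self):
        _, x = tone(0.05, 256, 4000)
        y = central(bandpass_isa(x, 256))
        amp = (y.max() - y.min()) / 2
        assert 0.9 <= amp <= 1.1

    def test_stopband_attenuation_matches_design_response(self):
        # oracle: the squared (forward-backward) Butterworth magnitude at 1 Hz
        sos = sp_sig.butter(2, (0.01, 0.1), "bandpass", fs=256, output="sos")
        _, h = sp_sig.sosfreqz(sos, worN=[1.0], fs=256)
        design_db = 20 * np.log10(np.abs(h[0]) ** 2)
        assert design_db < -20  # the chosen design does attenuate >= 20 dB

        _, x = tone(1.0, 256, 4000)
        y = central(bandpass_isa(x, 256))
        measured_db = 20 * np.log10(np.abs(y).max())
        assert measured_db < -20
        # measured attenuation should not beat the design response wildly
        assert measured_db < design_db + 6

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass_isa(np.zeros(100_000), 256), 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50_000)
        a = 3.7
        assert np.allclose(bandpass_isa(a * x, 256),
                           a * bandpass_isa(x, 256), atol=1e-10)

    def test_too_short_raises_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            bandpass_isa(np.zeros(100), 256)

    def test_fs_must_exceed_twice_high_edge(self):
        with pytest.raises(ValueError, match="twice"):
            bandpass_isa(np.zeros(1000), 0.15)


class TestHighpass:
    def test_dc_removal(self):
        y = central(highpass(np.full(200_000, 5.0), 256))
        assert np.abs(y).max() < 1e-6 * 5.0

    def test_passband(self):
        _, x = tone(0.05, 256, 4000)
        y = central(highpass(x, 256))
        assert 0.9 <= (y.max() - y.min()) / 2 <= 1.1

    def test_ramp_attenuated(self):
        # oracle: a ramp's energy is concentrated far below 0.01 Hz, so the
        # central output must be a small fraction of the ramp range
        t = np.arange(1_000_000) / 256
        y = central(highpass(t, 256))
        assert np.abs(y).max() < 0.01 * t.max()


class TestAnalytic:
    def test_cosine_phase_at_cycle_boundary(self):
        fs, f = 64, 0.05
        _, x = tone(f, fs, 2000)
        a = analytic(x, fs)
        i = int(20 * fs)  # one full cycle in
        assert abs(a.phase[i]) < 0.05

    def test_sine_lags_cosine_by_quarter_cycle(self):
        fs, f = 64, 0.05
        _, xc = tone(f, fs, 2000, kind="cos")
        _, xs = tone(f, fs, 2000, kind="sin")
        i = int(20 * fs)
        dphi = wrap_phase(analytic(xc, fs).phase[i]
                          - analytic(xs, fs).phase[i])
        assert dphi == pytest.approx(np.pi / 2, abs=0.05)

    def test_envelope_of_scaled_tone(self):
        fs = 64
        _, x = tone(0.05, fs, 2000, amp=3.0)
        a = analytic(x, fs)
        assert np.allclose(a.amplitude[a.valid], 3.0, atol=0.1)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            analytic(np.zeros(1000), 64)

    def test_edge_guard_mask(self):
        _, x = tone(0.05, 4, 1000)
        a = analytic(x, 4, edge_guard_s=100)
        assert not a.valid[:400].any() and not a.valid[-400:].any()
        assert a.valid[400:-400].all()

    @pytest.mark.parametrize("f", [0.02, 0.05, 0.08])
    def test_envelope_phase_reconstruction(self, f):
        fs = 16
        rng = np.random.default_rng(int(f * 1000))
        x = bandpass_isa(np.cos(2 * np.pi * f * np.arange(4000 * fs) / fs)
                         + 0.1 * rng.normal(size=4000 * fs), fs)
        a = analytic(x, fs)
        recon = a.amplitude * np.cos(a.phase)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        rmse = np.sqrt(np.mean((recon[mid] - x[mid]) ** 2))
        assert rmse / np.sqrt(np.mean(x[mid] ** 2)) < 0.05


class TestInstantaneousFrequency:
    @pytest.mark.parametrize("f", [0.05, 0.02])
    def test_pure_tone(self, f):
        fs = 16
        _, x = tone(f, fs, 4000)
        a = analytic(x, fs)
        fr = instantaneous_frequency(a)
        assert np.allclose(central(fr), f, atol=1e-3)

    def test_chirp_midpoint(self):
        # analytic chirp phase: theta = 2*pi*(f0*t + (f1-f0) t^2 / (2T)),
        # instantaneous frequency at T/2 is (f0+f1)/2 = 0.05 Hz
        fs, T, f0, f1 = 16, 4000, 0.01, 0.09
        t = np.arange(int(T * fs)) / fs
        x = np.cos(2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * T)))
        fr = instantaneous_frequency(analytic(x, fs))
        assert fr[len(fr) // 2] == pytest.approx(0.05, abs=0.005)

    def test_too_short_raises(self):
        from isapac import AnalyticSeries
        a = AnalyticSeries(phase=np.array([0.1]), amplitude=np.array([1.0]),
                           fs=1.0)
        with pytest.raises(ValueError):
            instantaneous_frequency(a)


class TestDownsample:
    def test_sample_count(self):
        assert downsample(np.zeros(2560), 256, 1).size == 10

    def test_constant_preserved(self):
        assert np.allclose(downsample(np.full(512, 7.0), 256, 1), 7.0)

    def test_phase_advance_per_output_sample(self):
        # oracle: a 0.05 Hz tone's phase advances 2*pi*0.05 rad per second
        fs, f = 16, 0.05
        _, x = tone(f, fs, 2000)
        ph = downsample(analytic(x, fs).phase, fs, 1)
        d = wrap_phase(np.diff(ph[100:-100]))
        assert np.allclose(d, 2 * np.pi * f, atol=0.01)

    def test_non_integer_ratio_raises(self):
        with pytest.raises(ValueError, match="integer"):
            downsample(np.zeros(100), 10, 3)


class TestMagnitudeSpectrum:
    def test_tone_peak_bin(self):
        _, x = tone(0.05, 1, 2000)
        s = magnitude_spectrum(x, 1)
        assert s.freqs[np.argmax(s.magnitude)] == pytest.approx(0.05)

    def test_constant_all_energy_at_dc(self):
        s = magnitude_spectrum(np.full(1000, 2.0), 1)
        assert np.argmax(s.magnitude) == 0
        assert s.magnitude[1:].max() < 1e-9 * s.magnitude[0]

    def test_pink_noise_slope(self):
        # generator PSD slope -1 => magnitude slope -0.5 in log-log
        x = gen_pink_noise(2 ** 16, 1.0, slope=-1.0, seed=7)
        s = magnitude_spectrum(x, 1.0)
        assert spectral_slope(s, (0.01, 0.1)) == pytest.approx(-0.5, abs=0.15)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            magnitude_spectrum(np.array([]), 1)


def test_hilbert_before_downsampling_order_is_pinned(small_preprocessed):
    """Regression: phase comes from the native-rate analytic signal.

    Decimating first and Hilbert-transforming after distorts the phase;
    the pipeline's output must match the Hilbert-at-native-rate route
    exactly, and differ measurably from the decimate-first route.
    """
    cfg, truth, pre = small_preprocessed
    from isapac import Recording, gen_session
    rec, _ = gen_session(cfg)
    x = bandpass_isa(rec.data[0], cfg.fs)
    native = downsample(analytic(x, cfg.fs).phase, cfg.fs, 1.0)
    assert np.array_equal(pre.eeg_phase[0], native)
    swapped = analytic(downsample(x, cfg.fs, 1.0), 1.0).phase
    v = pre.valid
    assert not np.allclose(native[v], swapped[v], atol=1e-3)
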