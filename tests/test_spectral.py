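import numpy as np
import pytest

from meagamma.errors import ParameterError, UndefinedKineticsError
from meagamma.spectral import (BandDefinition, GAMMA_BAND, PowerSpectrum, band_power,
                               morlet_spectrogram, multitaper_psd, peak_and_q,
                               segment_psd, sliding_band_power)
from meagamma.preprocess import to_lfp


class TestMultitaperPsd:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(60000)
        ps = multitaper_psd(x, 1000.0)
        total = np.trapezoid(ps.power, ps.freqs_hz)
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_sinusoid_mass_and_location(self):
        t = np.arange(60000) / 1000.0
        ps = multitaper_psd(10.0 * np.sin(2 * np.pi * 40.0 * t), 1000.0)
        total = np.trapezoid(ps.power, ps.freqs_hz)
        assert total == pytest.approx(50.0, rel=0.05)  # A^2/2
        # mass concentrated within the taper bandwidth of 40 Hz
        w = ps.nw / 60.0  # NW / T
        near = (ps.freqs_hz >= 40 - 2 * w) & (ps.freqs_hz <= 40 + 2 * w)
        assert np.trapezoid(ps.power[near], ps.freqs_hz[near]) >= 0.95 * total

    def test_constant_signal_power_at_dc(self):
        # taper leakage spreads DC power within the half-bandwidth W = NW/T
        ps = multitaper_psd(np.full(4000, 3.0), 1000.0)
        w = ps.nw / 4.0
        low = ps.freqs_hz <= 2 * w
        assert ps.power[low].sum() >= 0.99 * ps.power.sum()
        assert ps.freqs_hz[np.argmax(ps.power)] <= w

    def test_too_many_tapers_rejected(self, rng):
        with pytest.raises(ParameterError):
            multitaper_psd(rng.standard_normal(1000), 1000.0, nw=3.0, k=6)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            multitaper_psd(np.array([1.0]), 1000.0)


class TestBandPower:
    def test_sinusoid_in_band(self):
        t = np.arange(60000) / 1000.0
        ps = multitaper_psd(10.0 * np.sin(2 * np.pi * 40.0 * t), 1000.0)
        assert band_power(ps, GAMMA_BAND) == pytest.approx(50.0, rel=0.05)

    def test_out_of_band_sinusoid(self):
        t = np.arange(60000) / 1000.0
        ps = multitaper_psd(10.0 * np.sin(2 * np.pi * 10.0 * t), 1000.0)
        assert band_power(ps, GAMMA_BAND) <= 0.5

    def test_white_noise_band_fraction(self, rng):
        ps = multitaper_psd(rng.standard_normal(120000), 1000.0)
        assert band_power(ps, GAMMA_BAND) == pytest.approx((59 - 25) / 500.0, rel=0.10)

    def test_additive_over_disjoint_subbands(self, rng):
        ps = multitaper_psd(rng.standard_normal(10000), 1000.0)
        lo = BandDefinition(25.0, 40.0)
        hi = BandDefinition(40.0, 59.0)
        assert band_power(ps, lo) + band_power(ps, hi) == pytest.approx(
            band_power(ps, GAMMA_BAND), rel=1e-9)

    def test_band_outside_range_rejected(self, rng):
        ps = multitaper_psd(rng.standard_normal(1000), 100.0)
        with pytest.raises(ParameterError):
            band_power(ps, BandDefinition(25.0, 80.0))


class TestSlidingBandPower:
    def test_stationary_sinusoid_constant_series(self, layout):
        from meagamma.synth import Epoch, Recording
        t = np.arange(60000) / 1000.0
        data = np.tile((10 * np.sin(2 * np.pi * 40 * t)).astype(np.float32), (60, 1))
        from meagamma.preprocess import LfpRecording
        lfp = LfpRecording(data=data, fs_hz=1000.0, layout=layout,
                           epochs=[Epoch("vehicle", 0, 60)])
        bps = sliding_band_power(lfp)
        series = bps.power[0]
        assert series.std() / series.mean() <= 0.05

    def test_switch_time_located(self, layout):
        from meagamma.synth import Epoch
        from meagamma.preprocess import LfpRecording
        t = np.arange(60000) / 1000.0
        x = 10 * np.sin(2 * np.pi * 40 * t) * (t >= 30.0)
        lfp = LfpRecording(data=np.tile(x.astype(np.float32), (60, 1)), fs_hz=1000.0,
                           layout=layout, epochs=[Epoch("vehicle", 0, 60)])
        bps = sliding_band_power(lfp)
        series = bps.power[0]
        plateau = series[bps.times_s > 35].mean()
        crossing = bps.times_s[np.argmax(series >= plateau / 2)]
        assert crossing == pytest.approx(30.0, abs=bps.window_s)

    def test_window_longer_than_record_rejected(self, layout):
        from meagamma.synth import Epoch
        from meagamma.preprocess import LfpRecording
        lfp = LfpRecording(data=np.zeros((60, 500), np.float32), fs_hz=1000.0,
                           layout=layout, epochs=[Epoch("vehicle", 0, 0.5)])
        with pytest.raises(ParameterError):
            sliding_band_power(lfp, window_s=2.0)


class TestMorlet:
    def test_ridge_at_sinusoid_frequency(self):
        t = np.arange(30000) / 1000.0
        x = np.sin(2 * np.pi * 40.0 * t)
        sg = morlet_spectrogram(x, 1000.0, freqs_hz=np.arange(20.0, 60.5, 0.5))
        mid = sg.power[:, sg.power.shape[1] // 2]
        assert sg.freqs_hz[np.argmax(mid)] == pytest.approx(40.0, abs=0.5)

    def test_quadratic_amplitude_scaling(self):
        t = np.arange(20000) / 1000.0
        f = np.arange(30.0, 50.5, 0.5)
        p1 = morlet_spectrogram(np.sin(2 * np.pi * 40 * t), 1000.0, freqs_hz=f)
        p2 = morlet_spectrogram(2 * np.sin(2 * np.pi * 40 * t), 1000.0, freqs_hz=f)
        mid = p1.power.shape[1] // 2
        assert p2.power[:, mid] == pytest.approx(4.0 * p1.power[:, mid], rel=1e-6)

    def test_ridge_width_matches_kernel_bandwidth(self):
        # power response of the kernel at input offset df is
        # ~ sigma_t * exp(-df^2 / sigma_f^2) -> FWHM = 2 sigma_f sqrt(ln 2)
        t = np.arange(60000) / 1000.0
        f = np.arange(30.0, 50.05, 0.1)
        sg = morlet_spectrogram(np.sin(2 * np.pi * 40 * t), 1000.0, freqs_hz=f)
        prof = sg.power[:, sg.power.shape[1] // 2]
        half = prof.max() / 2
        above = sg.freqs_hz[prof >= half]
        fwhm = above[-1] - above[0]
        sigma_f = 40.0 / 25.0
        assert fwhm == pytest.approx(2 * sigma_f * np.sqrt(np.log(2.0)), rel=0.15)

    def test_edges_flagged_invalid(self):
        t = np.arange(5000) / 1000.0
        sg = morlet_spectrogram(np.sin(2 * np.pi * 30 * t), 1000.0,
                                freqs_hz=np.array([30.0]))
        sigma_t = 25.0 / (2 * np.pi * 30.0)
        assert not sg.valid[0, 0]
        assert sg.valid[0, sg.times_s.size // 2]
        edge = 3 * sigma_t
        assert np.all(sg.valid[0] == ((sg.times_s >= edge) & (sg.times_s <= 5.0 - edge)))

    def test_unsupported_frequency_dropped(self):
        x = np.zeros(1000)  # 1 s record
        with pytest.warns(UserWarning, match="dropping"):
            sg = morlet_spectrogram(x, 1000.0, freqs_hz=np.array([0.5, 30.0]))
        assert list(sg.freqs_hz) == [30.0]


class TestPeakAndQ:
    def test_triangular_peak(self):
        f = np.linspace(0.0, 100.0, 201)
        p = np.maximum(0.0, 1.0 - np.abs(f - 30.0) / 30.0)
        pk = peak_and_q(PowerSpectrum(f, p), BandDefinition(5.0, 59.0))
        assert pk.f0_hz == 30.0
        assert pk.bandwidth_hz == pytest.approx(30.0)
        assert pk.q == pytest.approx(1.0)

    def test_periodicity_threshold_q_half(self):
        # peak at 30 Hz with half-max crossings at 5 and 65 Hz -> B = 60, Q = 0.5
        f = np.linspace(0.0, 100.0, 401)
        p = np.interp(f, [0.0, 5.0, 30.0, 65.0, 100.0], [0.0, 0.5, 1.0, 0.5, 0.0])
        p[f > 65.0] = np.interp(f[f > 65.0], [65.0, 100.0], [0.499, 0.0])
        pk = peak_and_q(PowerSpectrum(f, p), BandDefinition(5.0, 59.0))
        assert pk.f0_hz == 30.0
        assert pk.q == pytest.approx(0.5, rel=0.01)

    def test_flat_spectrum_undefined(self):
        f = np.linspace(0.0, 100.0, 101)
        with pytest.raises(UndefinedKineticsError):
            peak_and_q(PowerSpectrum(f, np.ones_like(f)), BandDefinition(5.0, 59.0))

    def test_q_invariant_to_amplitude_scaling(self, quick_recording):
        lfp = to_lfp(quick_recording)
        drug = lfp.epoch("kainate")
        x = lfp.segment(drug.t_start_s + 5, drug.t_end_s)[30].astype(float)
        ps1 = segment_psd(x, lfp.fs_hz, window_s=5.0)
        ps2 = segment_psd(7.3 * x, lfp.fs_hz, window_s=5.0)
        q1 = peak_and_q(ps1).q
        q2 = peak_and_q(ps2).q
        assert q1 == pytest.approx(q2, rel=1e-9)
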