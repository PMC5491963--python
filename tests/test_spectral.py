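import numpy as np
import pytest
from scipy.signal import periodogram

from thetagamma import (
    LfpTrace,
    TfrMatrix,
    WaveletParams,
    band_power,
    morlet_kernel,
    normalize_power,
    theta_triggered_tfr,
    wavelet_power,
)
from thetagamma.core import (
    DegenerateInputError,
    EmptySelectionError,
    NyquistError,
    PipelineError,
)
from thetagamma.spectral import band_freq_grid, band_power_timeseries


class TestMorletKernel:
    def test_sigma_relations_at_ratio_seven(self):
        # f = 7 Hz with ratio 7 gives sigma_f = 1 Hz, sigma_t = 1/(2 pi) s
        params = WaveletParams(7.0)
        assert params.sigma_t(7.0) == pytest.approx(1.0 / (2 * np.pi))
        k = morlet_kernel(7.0, 2000.0, params)
        # support spans +/- 4 sigma_t
        assert len(k) == 2 * int(np.ceil(4 * params.sigma_t(7.0) * 2000)) + 1

    @pytest.mark.parametrize("f", [2.0, 3.5, 8.0, 40.0, 80.0])
    def test_unit_energy(self, f):
        k = morlet_kernel(f, 2000.0)
        assert np.sum(np.abs(k) ** 2) / 2000.0 == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("f", [2.0, 3.5, 8.0, 40.0, 80.0])
    def test_peak_frequency_matches_fft_oracle(self, f):
        fs = 2000.0
        k = morlet_kernel(f, fs)
        nfft = 1 << 18
        spec = np.abs(np.fft.fft(k, nfft))
        grid = np.fft.fftfreq(nfft, 1 / fs)
        assert abs(grid[spec.argmax()] - f) <= fs / nfft + 1e-9

    def test_near_zero_mean(self):
        k = morlet_kernel(40.0, 2000.0)
        # truncation at +/- 4 sigma_t leaves a tiny residual
        assert abs(np.sum(k)) / np.sum(np.abs(k)) < 1e-4

    def test_nyquist_rejected(self):
        with pytest.raises(NyquistError):
            morlet_kernel(1000.0, 2000.0)
        with pytest.raises(PipelineError):
            morlet_kernel(-1.0, 2000.0)


class TestWaveletPower:
    def test_zero_signal_gives_zero_power(self):
        tfr = wavelet_power(LfpTrace(np.zeros(4000), 2000.0), [5.0, 10.0])
        assert np.all(tfr.power == 0.0)

    def test_single_tone_peaks_at_tone_frequency(self, tone):
        trace = tone(8.0, duration=60.0, fs=2000.0)
        freqs = np.arange(2.0, 20.0, 0.5)
        tfr = wavelet_power(trace, freqs)
        mean_p = np.array(
            [tfr.power[i][tfr.valid[i]].mean() for i in range(len(freqs))]
        )
        assert freqs[mean_p.argmax()] == pytest.approx(8.0, abs=0.5)
        # independent oracle: periodogram peak
        f_p, pxx = periodogram(trace.samples, fs=2000.0)
        assert abs(f_p[pxx.argmax()] - 8.0) < 0.5

    def test_two_tones_give_two_local_maxima(self):
        fs = 2000.0
        t = np.arange(int(60 * fs)) / fs
        x = np.cos(2 * np.pi * 3.5 * t) + np.cos(2 * np.pi * 40.0 * t)
        freqs = np.concatenate([np.arange(2.0, 10.0, 0.5), np.arange(30.0, 50.0, 1.0)])
        tfr = wavelet_power(LfpTrace(x, fs), freqs)
        mean_p = np.array(
            [tfr.power[i][tfr.valid[i]].mean() for i in range(len(freqs))]
        )
        low = freqs < 10
        assert freqs[low][mean_p[low].argmax()] == pytest.approx(3.5, abs=0.5)
        assert freqs[~low][mean_p[~low].argmax()] == pytest.approx(40.0, abs=1.0)

    def test_scaling_equivariance(self, tone):
        trace = tone(8.0, duration=20.0, fs=500.0)
        scaled = LfpTrace(trace.samples * 3.0, 500.0)
        freqs = [5.0, 8.0, 12.0]
        p1 = wavelet_power(trace, freqs).power
        p2 = wavelet_power(scaled, freqs).power
        np.testing.assert_allclose(p2, 9.0 * p1, rtol=1e-10)

    def test_empty_trace_rejected(self):
        with pytest.raises(EmptySelectionError):
            wavelet_power(LfpTrace(np.empty(0), 2000.0), [5.0])

    def test_parseval_ratio_stable_across_amplitudes(self):
        # total wavelet power over a fine grid is proportional to variance
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(30 * 500))
        freqs = np.arange(2.0, 100.0, 2.0)
        ratios = []
        for amp in (1.0, 2.5):
            tfr = wavelet_power(LfpTrace(amp * x, 500.0), freqs)
            total = tfr.power[tfr.valid].mean() * len(freqs)
            ratios.append(total / np.var(amp * x))
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-6)


class TestNormalizeAndBandPower:
    def _flat_tfr(self, value=4.0):
        freqs = np.arange(1.0, 20.0, 1.0)
        times = np.arange(100) / 100.0
        power = np.full((freqs.size, times.size), value)
        return TfrMatrix(power, freqs, times, np.ones_like(power, dtype=bool))

    def test_divides_by_reference_mean(self):
        tfr = self._flat_tfr(4.0)
        out = normalize_power(tfr, (5.0, 10.0))
        assert np.all(out.power == 1.0)
        assert out.normalized and out.reference_band == (5.0, 10.0)

    def test_double_normalization_rejected(self):
        out = normalize_power(self._flat_tfr(), (5.0, 10.0))
        with pytest.raises(PipelineError):
            normalize_power(out, (5.0, 10.0))

    def test_zero_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_power(self._flat_tfr(0.0), (5.0, 10.0))

    def test_white_noise_self_normalizes_to_one(self):
        rng = np.random.default_rng(1)
        trace = LfpTrace(rng.standard_normal(int(30 * 500)), 500.0)
        tfr = wavelet_power(trace, np.arange(5.0, 10.5, 0.5))
        out = normalize_power(tfr, (5.0, 10.0))
        assert band_power(out, (5.0, 10.0)) == pytest.approx(1.0, abs=1e-9)

    def test_band_power_of_ones_is_one(self):
        assert band_power(self._flat_tfr(1.0), (3.0, 12.0)) == 1.0

    def test_time_mask_on_symmetric_matrix(self):
        tfr = self._flat_tfr(2.0)
        mask = np.zeros(100, dtype=bool)
        mask[::2] = True
        assert band_power(tfr, (3.0, 12.0), mask) == band_power(tfr, (3.0, 12.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySelectionError):
            band_power(self._flat_tfr(), (3.0, 12.0), np.zeros(100, dtype=bool))

    def test_band_outside_grid_rejected(self):
        with pytest.raises(EmptySelectionError):
            band_power(self._flat_tfr(), (200.0, 300.0))

    def test_gamma_bursts_raise_band_power(self, tone):
        fs = 1000.0
        base = tone(3.5, duration=30.0, fs=fs)
        with_bursts = base.samples.copy()
        env_len = int(0.08 * fs)
        env = np.hanning(env_len)
        t = np.arange(env_len) / fs
        for c in np.arange(1.0, 29.0, 1.0):
            i0 = int(c * fs)
            with_bursts[i0:i0 + env_len] += 2.0 * env * np.cos(2 * np.pi * 60 * t)
        p_with, ok = band_power_timeseries(LfpTrace(with_bursts, fs), (30, 100), 4.0)
        p_without, _ = band_power_timeseries(base, (30, 100), 4.0)
        assert p_with[ok].mean() > p_without[ok].mean()


class TestThetaTriggeredTfr:
    def test_single_trigger_equals_window(self, tone):
        trace = tone(3.5, duration=20.0, fs=500.0)
        out = theta_triggered_tfr(trace, [10.0], window=(-0.1, 0.1),
                                  band_grid=[40.0, 60.0])
        assert out.n_triggers == 1
        assert out.power.shape == (2, int(0.2 * 500) + 1)

    def test_injected_bursts_peak_at_fixed_latency(self):
        fs = 1000.0
        rng = np.random.default_rng(2)
        n = int(120 * fs)
        x = 0.1 * rng.standard_normal(n)
        t = np.arange(n) / fs
        x += np.cos(2 * np.pi * 3.5 * t)
        troughs = (np.arange(2, 400) + 0.5) / 3.5  # cosine troughs
        latency = 0.060
        env_len = int(0.04 * fs)
        env = np.hanning(env_len)
        for tr in troughs:
            i0 = int((tr + latency) * fs) - env_len // 2
            x[i0:i0 + env_len] += 3.0 * env * np.cos(2 * np.pi * 60 * np.arange(env_len) / fs)
        out = theta_triggered_tfr(LfpTrace(x, fs), troughs, window=(-0.14, 0.14),
                                  band_grid=np.arange(41.0, 80.0, 2.0))
        gamma_mean = out.power.mean(axis=0)
        assert out.times[gamma_mean.argmax()] == pytest.approx(latency, abs=0.005)

    def test_flat_on_noise(self):
        rng = np.random.default_rng(3)
        fs = 500.0
        trace = LfpTrace(rng.standard_normal(int(300 * fs)), fs)
        triggers = np.arange(2.0, 298.0, 1.0)
        out = theta_triggered_tfr(trace, triggers, window=(-0.1, 0.1),
                                  band_grid=np.arange(41.0, 80.0, 4.0))
        prof = out.power.mean(axis=0)
        # flat in time within 3 SEM of the across-window spread
        sem = prof.std() / np.sqrt(prof.size)
        assert prof.max() - prof.min() < prof.mean() * 0.2 + 6 * sem

    def test_out_of_bounds_triggers_skipped(self, tone):
        trace = tone(3.5, duration=10.0, fs=500.0)
        out = theta_triggered_tfr(trace, [0.01, 5.0, 9.99], window=(-0.2, 0.2),
                                  band_grid=[40.0])
        assert out.n_triggers == 1

    def test_no_usable_trigger_rejected(self, tone):
        trace = tone(3.5, duration=2.0, fs=500.0)
        with pytest.raises(EmptySelectionError):
            theta_triggered_tfr(trace, [0.01], window=(-1.5, 1.5), band_grid=[40.0])


def test_band_freq_grid_inclusive():
    np.testing.assert_allclose(band_freq_grid((2.5, 4.5), 0.2),
                               np.arange(2.5, 4.7, 0.2), atol=1e-12)
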