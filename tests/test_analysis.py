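"""Oscillation-analysis chain: rates, spectra, PAC, cycle averaging, covariation."""

import numpy as np
import pandas as pd
import pytest

from ca1pac import analysis as ana
from ca1pac import synth


def make_table(times_ms, cell_ids=None, population="SYN"):
    times_ms = np.asarray(times_ms, float)
    cell_ids = np.zeros(times_ms.size, int) if cell_ids is None else np.asarray(cell_ids)
    return pd.DataFrame(
        {"population": [population] * times_ms.size, "cell_id": cell_ids,
         "time_ms": times_ms}
    )


class TestBinRates:
    def test_ten_cells_one_spike_each_in_one_bin(self):
        tab = make_table(np.full(10, 2001.0), cell_ids=np.arange(10))
        r = ana.bin_rates(tab, "SYN", duration=2040.0)
        # 10 spikes / (0.004 s * 10 cells) = 250 Hz
        assert r.values[0] == pytest.approx(250.0)
        assert np.all(r.values[1:] == 0.0)

    def test_empty_table_all_zero(self):
        empty = make_table([]).iloc[:0]
        r = ana.bin_rates(empty, "SYN", duration=3000.0, n_cells=4)
        assert r.values.size == 250
        assert np.all(r.values == 0.0)

    def test_spike_conservation(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 6300, size=5000)
        tab = make_table(t, cell_ids=rng.integers(0, 10, 5000))
        r = ana.bin_rates(tab, "SYN", discard=2000.0, duration=6300.0, n_cells=10)
        n_post = int(((t >= 2000) & (t < 6300)).sum())
        assert r.values.sum() * 0.004 * 10 == pytest.approx(n_post)

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError, match="unknown population"):
            ana.bin_rates(make_table([2500.0]), "NOPE")


class TestWelch:
    def test_pure_sinusoid_peak_at_its_frequency(self):
        t = np.arange(0, 3000) * 0.004
        r = ana.RateSeries(values=10 + np.sin(2 * np.pi * 25 * t), t0=0.0)
        psd = ana.welch_psd(r)
        assert abs(psd.freqs[np.argmax(psd.power[1:]) + 1] - 25.0) <= np.diff(psd.freqs)[0]

    def test_constant_series_power_at_dc_only(self):
        r = ana.RateSeries(values=np.full(1024, 7.0), t0=0.0)
        psd = ana.welch_psd(r)
        assert np.argmax(psd.power) <= 1
        assert psd.power[5:].max() < 1e-12

    def test_white_noise_flatness(self):
        rng = np.random.default_rng(3)
        r = ana.RateSeries(values=rng.standard_normal(8192), t0=0.0)
        psd = ana.welch_psd(r)
        gmean = psd.power[1:].mean()
        for lo in np.arange(5, 115, 10.0):
            band = psd.power[(psd.freqs >= lo) & (psd.freqs < lo + 10)]
            assert band.mean() < 3 * gmean

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ana.welch_psd(ana.RateSeries(values=np.zeros(100), t0=0.0))


class TestPeakInBand:
    def make_psd(self, peaks):
        freqs = np.arange(0.0, 125.0, 0.5)
        power = np.full(freqs.size, 1e-3)
        for f, p in peaks:
            power[np.searchsorted(freqs, f)] = p
        return ana.PSD(freqs=freqs, power=power)

    def test_single_delta_peak(self):
        bm = ana.peak_in_band(self.make_psd([(5.0, 2.0)]), (1, 8))
        assert (bm.peak_freq, bm.strength) == (5.0, 2.0)

    def test_larger_of_two_peaks_wins(self):
        bm = ana.peak_in_band(self.make_psd([(3.0, 1.0), (6.0, 4.0)]), (1, 8))
        assert bm.peak_freq == 6.0

    def test_band_edges_included(self):
        bm = ana.peak_in_band(self.make_psd([(8.0, 9.0)]), (1, 8))
        assert bm.peak_freq == 8.0

    def test_empty_or_outside_band_rejected(self):
        psd = self.make_psd([(5.0, 1.0)])
        with pytest.raises(ValueError):
            ana.peak_in_band(psd, (8, 1))
        with pytest.raises(ValueError):
            ana.peak_in_band(psd, (100, 200))

    def test_log_strength(self):
        bm = ana.BandMetrics(peak_freq=5.0, strength=100.0)
        assert bm.log_strength == pytest.approx(2.0)


class TestComodulogram:
    def test_perfect_linear_coupling_r2_near_one(self):
        fs = 250.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 5 * t) + (1 + np.cos(2 * np.pi * 5 * t)) * np.sin(2 * np.pi * 25 * t)
        phi, amp = ana.phase_amplitude(x, fs, 5.0, 25.0)
        assert ana.pac_glm(phi, amp) > 0.98

    def test_depth_zero_not_above_surrogates(self):
        x = synth.gen_pac_signal(
            synth.PACSignalSpec(depth=0.0, noise_sd=1.0, fs=250, duration=30, seed=8)
        )
        obs, surr = ana.surrogate_band_pac(x, n_surrogates=200, fs=250, seed=9,
                                           method="blockshuffle")
        assert obs < np.quantile(surr, 0.95)

    def test_injected_pair_recovered(self):
        x = synth.gen_pac_signal(
            synth.PACSignalSpec(f_phase=4.5, f_amp=25.0, depth=0.8, noise_sd=1.0,
                                fs=500, duration=60, seed=0)
        )
        c = ana.comodulogram(
            x, phase_freqs=np.arange(1, 8.01, 0.5),
            amp_freqs=np.arange(15.0, 50.01, 1.0), fs=500,
        )
        i, j = np.unravel_index(np.argmax(c.pac), c.pac.shape)
        assert abs(c.phase_freqs[i] - 4.5) <= 0.5
        assert abs(c.amp_freqs[j] - 25.0) <= 3.0

    def test_amplitude_scale_invariance(self):
        x = synth.gen_pac_signal(
            synth.PACSignalSpec(depth=0.6, noise_sd=0.5, fs=250, duration=20, seed=3)
        )
        grid = dict(phase_freqs=np.array([4.0, 5.0]), amp_freqs=np.array([20.0, 25.0]))
        c1 = ana.comodulogram(x, fs=250, **grid)
        c2 = ana.comodulogram(1000.0 * x, fs=250, **grid)
        assert np.allclose(c1.pac, c2.pac, atol=1e-10)

    def test_time_reversal_stability(self):
        x = synth.gen_pac_signal(
            synth.PACSignalSpec(depth=0.8, noise_sd=0.5, fs=250, duration=30, seed=4)
        )
        grid = dict(phase_freqs=np.arange(3, 7.01, 1.0), amp_freqs=np.arange(18, 32.01, 2.0))
        a = ana.comodulogram(x, fs=250, **grid).pac
        b = ana.comodulogram(x[::-1].copy(), fs=250, **grid).pac
        assert np.abs(a - b).max() < 0.05 * max(a.max(), 1e-6)

    def test_nyquist_overlap_rejected(self):
        x = np.random.default_rng(0).standard_normal(2000)
        with pytest.raises(ValueError, match="Nyquist"):
            ana.comodulogram(x, phase_freqs=np.array([5.0]),
                             amp_freqs=np.array([120.0]), fs=250)

    def test_band_mean_and_peak_semantics(self):
        c = ana.Comodulogram(
            phase_freqs=np.arange(1.0, 9.0), amp_freqs=np.arange(15.0, 51.0),
            pac=np.full((8, 36), 0.25),
        )
        assert ana.pac_band_mean(c) == pytest.approx(0.25)
        assert ana.pac_band_peak(c) == pytest.approx(0.25)
        c.pac[:] = 0.0
        assert ana.pac_band_mean(c) == 0.0
        c.pac[3, 10] = 0.9
        assert ana.pac_band_peak(c) >= ana.pac_band_mean(c)
        with pytest.raises(ValueError):
            ana.pac_band_mean(c, phase_band=(100, 200))


class TestThetaCycleAverage:
    def test_periodic_rate_recovers_cycle(self):
        t = np.arange(3000) * 0.004
        r = ana.RateSeries(values=2 + np.cos(2 * np.pi * 5 * t), t0=0.0)
        tca = ana.theta_cycle_average({"X": r}, r)
        tmpl = tca.templates["X"]
        truth = 2 + np.cos(2 * np.pi * np.arange(tmpl.size) / tmpl.size + np.pi)
        c = np.corrcoef(tmpl, truth)[0, 1]
        assert c > 0.99
        assert tca.n_segments_used > 10

    def test_segment_retention_rule(self):
        # 5 Hz -> closed tolerance [180 ms, 220 ms]
        keep = ana.retain_segments(np.array([0.200, 0.230, 0.180, 0.300]), 5.0)
        assert list(keep) == [True, False, True, False]
        # boundary values included (closed interval)
        assert list(ana.retain_segments(np.array([0.18, 0.22]), 5.0)) == [True, True]

    def test_constant_rate_error_path(self):
        r = ana.RateSeries(values=np.full(2000, 5.0), t0=0.0)
        with pytest.raises(ValueError, match="theta"):
            ana.theta_cycle_average({"X": r}, r, f_theta=5.0)


class TestSpectrogramBandPower:
    def test_am_carrier_band_power_oscillates_at_modulation_rate(self):
        fs = 250.0
        t = np.arange(0, 120, 1 / fs)
        x = (1 + 0.8 * np.sin(2 * np.pi * 0.5 * t)) * np.sin(2 * np.pi * 25 * t)
        r = ana.RateSeries(values=x, t0=0.0)
        spec = ana.spectrogram(r)
        bp = ana.band_power_timeseries(spec, 25.0, 8.0)
        # dominant frequency of the band-power series ~ 0.5 Hz
        f = np.fft.rfftfreq(bp.size, d=np.diff(spec.times)[0])
        P = np.abs(np.fft.rfft(bp - bp.mean()))
        assert abs(f[np.argmax(P)] - 0.5) < 0.15

    def test_standardization_exact(self):
        rng = np.random.default_rng(1)
        r = ana.RateSeries(values=rng.standard_normal(4000) + 5, t0=0.0)
        bp = ana.band_power_timeseries(ana.spectrogram(r), 25.0, 8.0)
        assert bp.mean() == pytest.approx(0.0, abs=1e-12)
        assert bp.std() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_sinusoid_no_trend(self):
        t = np.arange(0, 60, 0.004)
        r = ana.RateSeries(values=np.sin(2 * np.pi * 25 * t), t0=0.0)
        bp = ana.band_power_timeseries(ana.spectrogram(r), 25.0, 8.0)
        slope = np.polyfit(np.arange(bp.size), bp, 1)[0]
        assert abs(slope) * bp.size < 0.5  # total drift well below 1 sd

    def test_band_outside_axis_rejected(self):
        r = ana.RateSeries(values=np.zeros(1000) + 1.0, t0=0.0)
        with pytest.raises(ValueError):
            ana.band_power_timeseries(ana.spectrogram(r), 1000.0, 1.0)


class TestPowerCovariation:
    def test_identity_and_sign_flip(self):
        x = np.linspace(-1, 1, 50)
        res = ana.power_covariation(x, x)
        assert (res.r_squared, res.slope) == (pytest.approx(1.0), pytest.approx(1.0))
        res = ana.power_covariation(x, -x)
        assert (res.r_squared, res.slope) == (pytest.approx(1.0), pytest.approx(-1.0))

    def test_generated_correlation_recovered(self):
        x, y = synth.gen_covarying_powers(
            synth.CovaryingPowerSpec(rho=0.9, n_windows=600, seed=6)
        )
        res = ana.power_covariation(x, y)
        assert abs(res.r_squared - 0.81) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ana.power_covariation(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError, match="lengths"):
            ana.power_covariation(np.arange(5.0), np.arange(6.0))
        with pytest.raises(ValueError, match="3"):
            ana.power_covariation(np.arange(2.0), np.arange(2.0))


class TestFullChain:
    def test_burst_table_recovers_theta_gamma_and_pac(self):
        tab = synth.gen_burst_spikes(
            synth.BurstSpikesSpec(n_cells=10, theta_f=5.0, gamma_f=25.0,
                                  duration=60_000, seed=10)
        )
        r = ana.bin_rates(tab, "SYN", discard=0.0, duration=60_000.0, n_cells=10)
        psd = ana.welch_psd(r)
        assert 4.0 <= ana.peak_in_band(psd, (3, 8)).peak_freq <= 6.0
        assert 20.0 <= ana.peak_in_band(psd, (15, 50)).peak_freq <= 30.0
        obs, surr = ana.surrogate_band_pac(r, n_surrogates=100, seed=11)
        assert obs > np.quantile(surr, 0.95)

    def test_moving_average_identity_on_constants(self):
        x = np.full(20, 3.5)
        assert np.allclose(ana.moving_average(x, 3), x)
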