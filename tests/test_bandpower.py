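import numpy as np
import pytest

from crossband.bandpower import (BANDS, PowerSeries, Spectrogram,
                                 average_channels, band_power_series,
                                 interpolate_to_tr, multitaper_spectrogram)
from crossband.data import InvalidDataError


def periodogram_band_power(signal, fs, band):
    """Independent single-taper oracle: rectangular-window periodogram,
    normalized to window energy like the DPSS estimator."""
    n = len(signal)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.abs(np.fft.rfft(signal / np.sqrt(n))) ** 2
    spec[1:] *= 2
    if n % 2 == 0:
        spec[-1] /= 2
    spec /= n
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return spec[sel].mean()


class TestMultitaperSpectrogram:
    def test_sinusoid_power_concentrates_in_alpha(self):
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        spec = multitaper_spectrogram(sig, fs)
        band = (spec.freqs >= 8.5) & (spec.freqs <= 12.0)
        frac = spec.power[:, band].sum(axis=1) / spec.power.sum(axis=1)
        assert np.all(frac >= 0.95)

    def test_white_noise_spectrum_is_flat_across_bands(self, rng):
        # delta vs alpha mean per-bin power should agree within 3x
        ratios = []
        for _ in range(100):
            sig = rng.standard_normal(int(10 * 250))
            spec = multitaper_spectrogram(sig, 250.0, window_s=2.0, step_s=0.5)
            d = band_power_series(spec, BANDS["delta"]).values.mean()
            a = band_power_series(spec, BANDS["alpha"]).values.mean()
            ratios.append(d / a)
        assert 1 / 3 < np.mean(ratios) < 3

    def test_window_center_count(self):
        sig = np.zeros(int(10 * 250))
        spec = multitaper_spectrogram(sig, 250.0, window_s=5.0, step_s=0.1)
        assert len(spec.times) == 51
        assert np.isclose(spec.times[0], 2.498)  # (nper-1)/2 / fs
        assert np.isclose(spec.times[-1] - spec.times[0], 5.0)

    def test_short_signal_gives_empty_spectrogram(self):
        with pytest.warns(UserWarning, match="shorter"):
            spec = multitaper_spectrogram(np.zeros(100), 250.0, window_s=5.0)
        assert spec.power.shape[0] == 0

    def test_amplitude_scaling_is_quadratic(self, rng):
        sig = rng.standard_normal(2500)
        s1 = multitaper_spectrogram(sig, 250.0, window_s=2.0, step_s=0.5)
        s3 = multitaper_spectrogram(3.0 * sig, 250.0, window_s=2.0, step_s=0.5)
        np.testing.assert_allclose(s3.power, 9.0 * s1.power, rtol=1e-5)

    def test_agrees_with_periodogram_oracle_on_white_noise(self, rng):
        # mean band power over draws: multitaper vs rectangular periodogram
        mt = {name: [] for name in BANDS}
        pg = {name: [] for name in BANDS}
        for _ in range(50):
            sig = rng.standard_normal(1250)
            spec = multitaper_spectrogram(sig, 250.0, window_s=5.0, step_s=5.0)
            for name, band in BANDS.items():
                mt[name].append(band_power_series(spec, band).values[0])
                pg[name].append(periodogram_band_power(sig, 250.0, band))
        for name in BANDS:
            a, b = np.mean(mt[name]), np.mean(pg[name])
            assert abs(a - b) / b < 0.2


class TestBandPowerSeries:
    def _flat_spec(self, value=1.0):
        freqs = np.arange(0, 125.1, 0.2)
        times = np.arange(5) * 0.1
        return Spectrogram(times, freqs, np.full((5, len(freqs)), value))

    def test_flat_spectrogram_passthrough(self):
        out = band_power_series(self._flat_spec(), (8.5, 12.0))
        np.testing.assert_allclose(out.values, 1.0)

    def test_alpha_bin_count_on_regular_grid(self):
        spec = self._flat_spec()
        sel = (spec.freqs >= 8.5) & (spec.freqs <= 12.0)
        assert sel.sum() == 18

    def test_sinusoid_alpha_delta_ratio(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        spec = multitaper_spectrogram(np.sin(2 * np.pi * 10 * t), fs)
        alpha = band_power_series(spec, BANDS["alpha"]).values
        delta = band_power_series(spec, BANDS["delta"]).values
        assert np.mean(alpha) / np.mean(delta) > 10

    def test_empty_band_rejected(self):
        with pytest.raises(InvalidDataError):
            band_power_series(self._flat_spec(), (12.0, 8.5))

    def test_band_additivity(self, rng):
        spec = Spectrogram(np.arange(3) * 0.1, np.arange(0, 50.0, 0.5),
                           rng.uniform(size=(3, 100)))
        lo = band_power_series(spec, (1.0, 10.0)).values
        hi = band_power_series(spec, (10.5, 20.0)).values
        both = band_power_series(spec, (1.0, 20.0)).values
        n_lo = ((spec.freqs >= 1.0) & (spec.freqs <= 10.0)).sum()
        n_hi = ((spec.freqs >= 10.5) & (spec.freqs <= 20.0)).sum()
        np.testing.assert_allclose(both, (lo * n_lo + hi * n_hi) / (n_lo + n_hi))


class TestAverageChannels:
    def _series(self, values):
        return PowerSeries(np.arange(len(values), dtype=float),
                           np.asarray(values, dtype=float), (8.5, 12.0))

    def test_idempotent_on_copies(self):
        s = self._series([1, 2, 3])
        out = average_channels([s, s, s])
        np.testing.assert_array_equal(out.values, s.values)

    def test_pointwise_mean(self):
        out = average_channels([self._series([1, 1]), self._series([3, 3])])
        np.testing.assert_array_equal(out.values, [2, 2])

    def test_single_series_identity(self):
        s = self._series([5, 6])
        np.testing.assert_array_equal(average_channels([s]).values, s.values)

    def test_mismatched_grids_rejected(self):
        a = self._series([1, 2])
        b = PowerSeries(np.array([0.0, 2.0]), np.array([1.0, 2.0]), (8.5, 12.0))
        with pytest.raises(InvalidDataError):
            average_channels([a, b])


class TestInterpolateToTr:
    def test_exact_passthrough_on_grid_points(self):
        s = PowerSeries(np.array([0.0, 1.0, 2.0]), np.array([1.0, 4.0, 9.0]),
                        (8.5, 12.0))
        out = interpolate_to_tr(s, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_midpoint(self):
        s = PowerSeries(np.array([0.0, 1.0]), np.array([0.0, 2.0]), (8.5, 12.0))
        out = interpolate_to_tr(s, np.array([0.5]))
        assert out.values[0] == 1.0

    def test_outside_support_marked_missing(self):
        s = PowerSeries(np.array([2.5, 3.5]), np.array([1.0, 1.0]), (8.5, 12.0))
        out = interpolate_to_tr(s, np.array([0.0, 3.0, 9.0]))
        assert np.isnan(out.values[0]) and np.isnan(out.values[2])
        assert out.values[1] == 1.0

    def test_empty_series_rejected(self):
        s = PowerSeries(np.array([]), np.array([]), (8.5, 12.0))
        with pytest.raises(InvalidDataError):
            interpolate_to_tr(s, np.array([0.0]))
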