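"""Multitaper spectrograms and EEG band-power series.

Spectrograms use DPSS (Slepian) tapers on 5 s windows slid every 0.1 s,
the standard estimator for sleep/vigilance EEG where band power must be
tracked continuously with low variance. Band power is the mean power
over frequency bins whose centers fall in the band; series from several
occipital channels are averaged and finally interpolated to fMRI TR
times so each EEG point can be paired with an fMRI window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft as _rfft
from scipy.signal import windows as spwin

from .data import InvalidDataError

__all__ = [
    "Spectrogram", "PowerSeries", "BANDS", "multitaper_spectrogram",
    "band_power_series", "average_channels", "interpolate_to_tr",
    "run_band_power",
]

# band definitions (Hz): delta avoids <1.1 Hz scanner artifacts, alpha avoids
# theta/spindle contamination, 40-52 Hz indexes broadband artifact activity
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.1, 4.0),
    "alpha": (8.5, 12.0),
    "artifact": (40.0, 52.0),
}


@dataclass
class Spectrogram:
    times: np.ndarray   # window centers, s
    freqs: np.ndarray   # Hz
    power: np.ndarray   # (n_times, n_freqs), >= 0


@dataclass
class PowerSeries:
    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    channel_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise InvalidDataError("times and values must have equal length")


def multitaper_spectrogram(signal: np.ndarray, fs: float, window_s: float = 5.0,
                           step_s: float = 0.1, time_bandwidth: float = 3.0,
                           n_tapers: int | None = None) -> Spectrogram:
    """DPSS-taper averaged periodograms on a sliding window.

    The first window is centered at ``window_s / 2``; windows that would
    extend past the end of the signal are dropped. Power is in signal
    units squared per window (total, not density), so a unit-amplitude
    sinusoid concentrates power ~0.5 at its frequency bins.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0 or step_s <= 0:
        raise InvalidDataError("fs and step_s must be positive")
    nper = int(round(window_s * fs))
    if nper < 8:
        raise InvalidDataError("window must contain at least 8 samples")
    if n_tapers is None:
        n_tapers = max(int(2 * time_bandwidth) - 1, 1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    if len(signal) < nper:
        warnings.warn("signal shorter than one window; empty spectrogram")
        return Spectrogram(np.empty(0), freqs, np.empty((0, len(freqs))))

    step = int(round(step_s * fs))
    starts = np.arange(0, len(signal) - nper + 1, step)
    centers = (starts + (nper - 1) / 2.0) / fs
    tapers = spwin.dpss(nper, time_bandwidth, Kmax=n_tapers)  # (K, nper)

    # single precision in the FFT inner loop: the power estimate is averaged
    # over tapers and ~60 bins per band, so float32 rounding is negligible
    segs = np.ascontiguousarray(
        sliding_window_view(signal, nper)[starts], dtype=np.float32)
    tapers = tapers.astype(np.float32)
    power = np.zeros((len(starts), len(freqs)))
    for taper in tapers:
        spec = _rfft(segs * taper, axis=1)
        p = (spec.real ** 2 + spec.imag ** 2).astype(np.float64)
        # one-sided: double the interior bins
        p[:, 1:] *= 2.0
        if nper % 2 == 0:
            p[:, -1] /= 2.0
        power += p
    power /= n_tapers * nper
    return Spectrogram(times=centers, freqs=freqs, power=power)


def band_power_series(spec: Spectrogram, band: tuple[float, float],
                      channel: str = "") -> PowerSeries:
    """Mean power across bins with center frequency in the closed band."""
    lo, hi = band
    if hi <= lo:
        raise InvalidDataError("band upper edge must exceed lower edge")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(sel):
        raise InvalidDataError(f"band {band} contains no frequency bins")
    values = spec.power[:, sel].mean(axis=1)
    chans = (channel,) if channel else ()
    return PowerSeries(times=spec.times.copy(), values=values, band=band,
                       channel_set=chans)


def average_channels(series_list: list[PowerSeries]) -> PowerSeries:
    """Pointwise mean of band-power series on identical time grids."""
    if not series_list:
        raise InvalidDataError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if s.band != first.band or len(s.times) != len(first.times) \
                or not np.allclose(s.times, first.times):
            raise InvalidDataError("series must share band and time grid")
    values = np.mean([s.values for s in series_list], axis=0)
    chans = tuple(sorted({c for s in series_list for c in s.channel_set}))
    return PowerSeries(times=first.times.copy(), values=values, band=first.band,
                       channel_set=chans)


def interpolate_to_tr(series: PowerSeries, tr_times: np.ndarray) -> PowerSeries:
    """Linear interpolation to TR times; times outside support become NaN.

    NaN marks the value as missing so downstream QC excludes the TR
    rather than extrapolating power beyond the first/last window center.
    """
    if len(series.times) == 0:
        raise InvalidDataError("cannot interpolate an empty series")
    tr_times = np.asarray(tr_times, dtype=float)
    vals = np.interp(tr_times, series.times, series.values)
    outside = (tr_times < series.times[0]) | (tr_times > series.times[-1])
    vals = np.where(outside, np.nan, vals)
    return replace(series, times=tr_times, values=vals)


def run_band_power(eeg, tr_times: np.ndarray, bands: dict[str, tuple[float, float]] | None = None,
                   window_s: float = 5.0, step_s: float = 0.1,
                   time_bandwidth: float = 3.0, n_tapers: int | None = None,
                   ) -> dict[str, PowerSeries]:
    """Full per-run extraction: spectrogram per channel -> bands -> channel
    average -> interpolation to TR times."""
    if bands is None:
        bands = BANDS
    per_band: dict[str, list[PowerSeries]] = {name: [] for name in bands}
    for ch_name, sig in eeg.channels.items():
        spec = multitaper_spectrogram(sig, eeg.fs, window_s=window_s, step_s=step_s,
                                      time_bandwidth=time_bandwidth, n_tapers=n_tapers)
        spec.times = spec.times + eeg.start_time
        for name, band in bands.items():
            per_band[name].append(band_power_series(spec, band, channel=ch_name))
    out = {}
    for name, series_list in per_band.items():
        avg = average_channels(series_list)
        out[name] = interpolate_to_tr(avg, tr_times)
    return out
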