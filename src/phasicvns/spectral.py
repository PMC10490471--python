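"""Spectral estimation: Hann-tapered FFT power and Morlet TFRs.

Power spectra are computed from the 500 ms directly after stimulus onset
(the window least contaminated by interpolated stimulation gaps) on a
2-14 Hz grid in 0.5 Hz steps.  The window's native Rayleigh resolution is
2 Hz, so the transform is zero-padded to place bins exactly on the finer
grid (spectral interpolation).  Time-frequency representations use complex
Morlet wavelets (5 cycles) sampled in 40 ms bins, with a decibel baseline
relative to a pre-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.signal.windows import hann

from .containers import EpochSet

__all__ = ["SpectralConfig", "default_freq_grid", "fft_power", "morlet_tfr",
           "db_baseline", "group_average"]


def default_freq_grid() -> np.ndarray:
    """2-14 Hz in 0.5 Hz steps."""
    return np.arange(2.0, 14.0 + 0.25, 0.5)


@dataclass(frozen=True)
class SpectralConfig:
    freqs: np.ndarray = field(default_factory=default_freq_grid)
    fft_window_s: Tuple[float, float] = (0.0, 0.5)
    n_cycles: float = 5.0
    tfr_bin_ms: float = 40.0
    tfr_baseline_s: Tuple[float, float] = (-0.5, -0.2)


def fft_power(epochs: EpochSet, cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Per-trial power on the frequency grid from a Hann-tapered window.

    Returns (..., n_trials, n_freqs) matching the epoch layout with the
    time axis replaced by frequency.  Zero-padding interpolates the
    spectrum onto the 0.5 Hz grid.
    """
    rate = epochs.rate
    w0, w1 = cfg.fft_window_s
    if w0 < epochs.times[0] or w1 > epochs.times[-1] + 0.5 / rate:
        raise ValueError("FFT window exceeds epoch support")
    mask = (epochs.times >= w0) & (epochs.times < w1)
    x = epochs.data[..., mask]
    n = x.shape[-1]
    taper = hann(n, sym=False)
    step = float(np.min(np.diff(cfg.freqs)))
    nfft = int(round(rate / step))
    spec = np.fft.rfft(x * taper, n=nfft, axis=-1)
    freqs_full = np.fft.rfftfreq(nfft, 1.0 / rate)
    idx = np.round(cfg.freqs / (rate / nfft)).astype(int)
    if idx.max() >= freqs_full.size or not np.allclose(freqs_full[idx],
                                                       cfg.freqs, atol=1e-6):
        raise ValueError("frequency grid not representable at this padding")
    power = (np.abs(spec) ** 2)[..., idx]
    return power


def morlet_tfr(epochs: EpochSet, cfg: SpectralConfig = SpectralConfig()):
    """Morlet time-frequency power in coarse time bins.

    Returns ``(power, bin_times, edge_valid)`` where power has shape
    (..., n_trials, n_freqs, n_bins).  ``edge_valid`` flags bins at least
    half a wavelet length away from both epoch edges for the lowest
    frequency analysed (bins outside are wavelet-edge contaminated).
    """
    from mne.time_frequency import tfr_array_morlet

    rate = epochs.rate
    data = epochs.data
    if data.ndim == 2:                       # (trials, times) -> 1 channel
        arr = data[:, None, :]
        squeeze = True
    else:                                    # (channels, trials, times)
        arr = np.moveaxis(data, 0, 1)
        squeeze = False
    half_len_s = cfg.n_cycles / (2.0 * cfg.freqs.min())
    if epochs.times[-1] - epochs.times[0] < 2 * half_len_s:
        raise ValueError("epoch too short for the lowest wavelet frequency")
    power = tfr_array_morlet(arr, sfreq=rate, freqs=cfg.freqs,
                             n_cycles=cfg.n_cycles, output="power",
                             zero_mean=True)
    decim = max(int(round(cfg.tfr_bin_ms / 1000.0 * rate)), 1)
    power = power[..., ::decim]
    bin_times = epochs.times[::decim]
    edge_valid = ((bin_times - epochs.times[0] >= half_len_s)
                  & (epochs.times[-1] - bin_times >= half_len_s))
    if squeeze:
        power = power[:, 0]                  # (trials, freqs, bins)
    else:
        power = np.moveaxis(power, 1, 0)     # (channels, trials, freqs, bins)
    return power, bin_times, edge_valid


def db_baseline(power: np.ndarray, bin_times: np.ndarray,
                window: Tuple[float, float] = (-0.5, -0.2)) -> np.ndarray:
    """Decibel transform relative to the mean power in ``window`` per frequency.

    ``power_db = 10 * log10(power / baseline_mean)``; the baseline mean is
    taken over the window bins (and over trials when a trial axis
    precedes the frequency axis, so single-trial fluctuations do not leak
    into the reference).
    """
    mask = (bin_times >= window[0]) & (bin_times <= window[1])
    if not mask.any():
        raise ValueError("baseline window outside TFR support")
    base = power[..., mask].mean(axis=-1)
    if power.ndim >= 3:                       # average the trial axis
        base = base.mean(axis=-2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline power; flagged frequency")
    return 10.0 * np.log10(power / base[..., None])


def group_average(power: np.ndarray, channel_names: list, group: list) -> np.ndarray:
    """Average the leading channel axis over a named sensor group."""
    idx = [channel_names.index(c) for c in group]
    if not idx:
        raise ValueError("empty sensor group")
    return power[idx].mean(axis=0)
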