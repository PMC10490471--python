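"""Stimulation-artifact removal for electrophysiological recordings.

Pulse-locked blanking (10 ms after each pulse marker replaced by NaN)
followed by autoregressive gap filling: an AR model is fit on 25 ms of
context on each side of a gap, forward and backward predictions are
cross-faded linearly across the gap.  The cleaned signal then passes a
zero-phase Butterworth chain (high-pass 1 Hz, low-pass 60 Hz, band-stop
49-51 Hz) and is epoched, decimated to 250 Hz, and baseline-corrected with
the per-trial baseline means retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ContSignal, EpochSet

__all__ = ["ArtifactConfig", "blank_pulses", "ar_fill", "filter_chain",
           "epoch_and_baseline", "clean_session"]


@dataclass(frozen=True)
class ArtifactConfig:
    blank_ms: float = 10.0
    ar_context_ms: float = 25.0
    ar_order_max: int = 8
    hp_hz: float = 1.0
    lp_hz: float = 60.0
    notch_hz: Tuple[float, float] = (49.0, 51.0)
    filter_order: int = 4            # per pass; bidirectional doubles it
    epoch_s: Tuple[float, float] = (-2.0, 5.0)
    out_rate_hz: float = 250.0
    baseline_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.blank_ms <= 0 or self.ar_context_ms <= 0:
            raise ValueError("blank_ms and ar_context_ms must be positive")
        if not self.hp_hz < self.notch_hz[0] < self.notch_hz[1]:
            raise ValueError("filter edges must be ordered")


def blank_pulses(sig: ContSignal, cfg: ArtifactConfig = ArtifactConfig()) -> ContSignal:
    """Mark [marker, marker + blank_ms) missing; overlapping blanks merge."""
    missing = sig.missing.copy()
    n_blank = int(round(cfg.blank_ms / 1000.0 * sig.rate))
    for m in np.sort(sig.markers):
        i0 = int(round((m - sig.time[0]) * sig.rate))
        missing[max(i0, 0):min(i0 + n_blank, sig.time.size)] = True
    chans = sig.channels.copy()
    chans.iloc[missing] = np.nan
    return ContSignal(sig.time, chans, sig.rate, sig.markers, missing=missing)


def _fit_ar(context: np.ndarray, order: int) -> np.ndarray:
    """Burg AR coefficients a s.t. x[t] ~ sum a_k x[t-k].

    Burg's method guarantees a stable model, so forward extrapolation over
    the gap cannot diverge (a least-squares fit on short contexts can).
    """
    from statsmodels.regression.linear_model import burg

    if np.allclose(context, context[0]):
        return np.zeros(order), float(context[0])   # constant fill
    rho, _ = burg(context, order=order, demean=False)
    return np.asarray(rho), 0.0


def _predict(context: np.ndarray, fit, n_ahead: int) -> np.ndarray:
    coef, mean = fit
    order = coef.size
    buf = list(context[-order:] - mean)
    clamp = 2.0 * max(np.max(np.abs(context - mean)), 1e-12)
    out = np.empty(n_ahead)
    for i in range(n_ahead):
        # clamp keeps a near-unstable model from running away over the gap
        nxt = float(np.clip(np.dot(coef, buf[::-1]), -clamp, clamp))
        out[i] = nxt
        buf.pop(0)
        buf.append(nxt)
    return out + mean


def _gaps(missing: np.ndarray):
    """Contiguous missing runs as (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def ar_fill(sig: ContSignal, cfg: ArtifactConfig = ArtifactConfig()) -> ContSignal:
    """Fill missing runs channel-wise by AR prediction from flanking context.

    Order is about a quarter of the context length (capped).  A gap with too
    little context on both sides falls back to linear interpolation with a
    warning.  Non-gap samples are untouched.
    """
    n_ctx = int(round(cfg.ar_context_ms / 1000.0 * sig.rate))
    order = max(2, min(n_ctx // 4, cfg.ar_order_max))
    chans = sig.channels.copy()
    missing = sig.missing
    gaps = _gaps(missing)
    for name in chans.columns:
        x = chans[name].to_numpy(dtype=float, copy=True)
        for start, stop in gaps:
            width = stop - start
            left = x[max(start - n_ctx, 0):start]
            right = x[stop:stop + n_ctx]
            left = left[np.isfinite(left)]
            right = right[np.isfinite(right)]
            fwd = bwd = None
            if left.size >= 2 * order:
                fwd = _predict(left, _fit_ar(left, order), width)
            if right.size >= 2 * order:
                bwd = _predict(right[::-1], _fit_ar(right[::-1], order), width)[::-1]
            if fwd is None and bwd is None:
                warnings.warn("gap without usable AR context; linear fill")
                lo = x[start - 1] if start > 0 and np.isfinite(x[start - 1]) else 0.0
                hi = x[stop] if stop < x.size and np.isfinite(x[stop]) else lo
                x[start:stop] = np.linspace(lo, hi, width + 2)[1:-1]
            elif fwd is None:
                x[start:stop] = bwd
            elif bwd is None:
                x[start:stop] = fwd
            else:
                w = np.linspace(1.0, 0.0, width + 2)[1:-1]
                x[start:stop] = w * fwd + (1.0 - w) * bwd
        chans[name] = x
    return ContSignal(sig.time, chans, sig.rate, sig.markers,
                      missing=np.zeros_like(missing))


def filter_chain(sig: ContSignal, cfg: ArtifactConfig = ArtifactConfig()) -> ContSignal:
    """Zero-phase Butterworth high-pass, low-pass, band-stop (in that order)."""
    if sig.rate < 2 * cfg.lp_hz:
        raise ValueError("sampling rate below Nyquist for the low-pass edge")
    vals = sig.channels.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("filter_chain requires a gap-free signal")
    sos_hp = sps.butter(cfg.filter_order, cfg.hp_hz, btype="highpass",
                        fs=sig.rate, output="sos")
    sos_lp = sps.butter(cfg.filter_order, cfg.lp_hz, btype="lowpass",
                        fs=sig.rate, output="sos")
    sos_bs = sps.butter(cfg.filter_order, cfg.notch_hz, btype="bandstop",
                        fs=sig.rate, output="sos")
    for sos in (sos_hp, sos_lp, sos_bs):
        vals = sps.sosfiltfilt(sos, vals, axis=0)
    chans = pd.DataFrame(vals, columns=sig.channels.columns)
    return ContSignal(sig.time, chans, sig.rate, sig.markers)


def epoch_and_baseline(sig: ContSignal, events: pd.DataFrame,
                       cfg: ArtifactConfig = ArtifactConfig()) -> EpochSet:
    """Epoch, decimate to ``out_rate_hz``, and baseline-correct.

    Output data is (n_channels, n_trials, n_times).  Per-channel per-trial
    baseline means over [-baseline_ms, 0) ms are retained in
    ``EpochSet.baselines`` for the baseline-comparison analysis.
    """
    rate = sig.rate
    step = int(round(rate / cfg.out_rate_hz))
    w0, w1 = cfg.epoch_s
    n_samp = int(round((w1 - w0) * rate)) + 1
    rel_full = w0 + np.arange(n_samp) / rate
    vals = sig.values()
    n_ch = vals.shape[0]
    n_ev = len(events)
    data = np.full((n_ch, n_ev, n_samp), np.nan)
    rejected = np.zeros(n_ev, dtype=bool)
    reasons = [""] * n_ev
    for k, onset in enumerate(events["onset_s"].to_numpy()):
        i_on = int(round((onset - sig.time[0]) * rate))
        start = i_on + int(round(w0 * rate))
        stop = start + n_samp
        if start < 0 or stop > sig.time.size:
            rejected[k] = True
            reasons[k] = "edge"
            continue
        data[:, k, :] = vals[:, start:stop]
    bl_mask = (rel_full >= -cfg.baseline_ms / 1000.0) & (rel_full < 0)
    baselines = np.nanmean(data[:, :, bl_mask], axis=2)     # (n_ch, n_trials)
    data = data - baselines[:, :, None]
    data = data[:, :, ::step]
    times = rel_full[::step]
    return EpochSet(data=data, times=times, labels=events.reset_index(drop=True),
                    rejected=rejected, reasons=reasons, baselines=baselines,
                    channels=sig.channel_names)


def clean_session(sig: ContSignal, events: pd.DataFrame,
                  cfg: ArtifactConfig = ArtifactConfig()) -> EpochSet:
    """Full chain: blank pulses, AR-fill, filter, epoch + baseline."""
    blanked = blank_pulses(sig, cfg)
    filled = ar_fill(blanked, cfg)
    filtered = filter_chain(filled, cfg)
    return epoch_and_baseline(filtered, events, cfg)
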