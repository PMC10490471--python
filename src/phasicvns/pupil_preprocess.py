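"""Pupil-trace cleaning and epoch normalization.

The cleaning follows the two-pass dilation-speed procedure standard in
pupillometry: (1) flag samples whose normalized dilation speed exceeds a
robust threshold, median + c * MAD, with c = 2.5; (2) rebuild a trend line
by linearly interpolating the resulting gaps and smoothing with a 100 ms
centered moving average, then flag samples whose absolute deviation from
the trend exceeds a MAD threshold computed on the deviation series.
Flagged samples become missing and interior gaps are filled by linear
interpolation.  Epochs are then z-scored (per subject-session pooled
scope), baseline-corrected to the mean of the 200 ms before stimulus
onset, and decimated to 100 Hz.

Trial rejection: trials with more than 50% missing samples are dropped;
subjects with more than 50% rejected trials in any one condition are
excluded wholly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import PupilTrace, EpochSet

__all__ = [
    "CleanConfig", "dilation_speed", "mad_threshold", "moving_average",
    "two_pass_clean", "epoch_trials", "reject_missing", "normalize_epochs",
    "preprocess_session",
]


@dataclass(frozen=True)
class CleanConfig:
    mad_constant: float = 2.5
    smooth_ms: float = 100.0
    baseline_ms: float = 200.0
    out_rate_hz: float = 100.0
    trial_missing_max: float = 0.5
    subject_excluded_max: float = 0.5
    epoch_est_s: Tuple[float, float] = (-2.0, 5.0)
    epoch_plrt_s: Tuple[float, float] = (-2.0, 7.0)
    zscore_scope: str = "session"     # pooled mean/SD per subject-session

    def __post_init__(self) -> None:
        if self.mad_constant <= 0:
            raise ValueError("mad_constant must be positive")
        for name in ("trial_missing_max", "subject_excluded_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


def dilation_speed(trace: PupilTrace) -> np.ndarray:
    """Normalized dilation speed: max of backward/forward |difference quotient|.

    Endpoints use their single available neighbor; samples without any
    valid neighbor, and missing samples themselves, are NaN.
    """
    valid = ~trace.missing
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid samples")
    p = np.where(valid, trace.pupil, np.nan)
    t = trace.time
    d = np.abs(np.diff(p)) / np.diff(t)
    back = np.concatenate(([np.nan], d))
    fwd = np.concatenate((d, [np.nan]))
    with np.errstate(invalid="ignore"):
        speed = np.fmax(back, fwd)   # fmax ignores a NaN on one side
    speed[~valid] = np.nan
    return speed


def mad_threshold(series: np.ndarray, c: float) -> float:
    """median(x) + c * median(|x - median(x)|), NaNs ignored."""
    x = np.asarray(series, dtype=float)
    if not np.any(np.isfinite(x)):
        raise ValueError("series has no finite values")
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    return float(med + c * mad)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges.

    NaNs are ignored inside the window; an all-NaN window yields NaN.
    """
    width = max(int(width), 1)
    half = width // 2
    n = x.size
    vals = np.where(np.isfinite(x), x, 0.0)
    cnt = np.isfinite(x).astype(float)
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    cc = np.concatenate(([0.0], np.cumsum(cnt)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    s = cs[hi] - cs[lo]
    m = cc[hi] - cc[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m > 0, s / m, np.nan)
    return out


def _interp_interior(time: np.ndarray, pupil: np.ndarray, missing: np.ndarray):
    """Linear interpolation of interior gaps; leading/trailing stay missing."""
    valid = ~missing & np.isfinite(pupil)
    out = pupil.copy()
    still = missing.copy()
    if valid.sum() < 2:
        return out, still
    iv = np.flatnonzero(valid)
    first, last = iv[0], iv[-1]
    interior = ~valid & (np.arange(time.size) > first) & (np.arange(time.size) < last)
    out[interior] = np.interp(time[interior], time[iv], pupil[iv])
    still[interior] = False
    still[:first] = True
    still[last + 1:] = True
    out[still] = np.nan
    return out, still


def two_pass_clean(trace: PupilTrace, cfg: CleanConfig = CleanConfig()):
    """Two-pass outlier removal followed by interior linear interpolation.

    Returns ``(cleaned, removed)``: a :class:`PupilTrace` whose flagged
    samples were replaced by interpolation (remaining-missing samples are
    the non-interpolatable leading/trailing gaps) and the boolean mask of
    samples removed by either pass.  Raises if cleaning empties the trace.
    """
    speed = dilation_speed(trace)
    thr1 = mad_threshold(speed, cfg.mad_constant)
    with np.errstate(invalid="ignore"):
        removed1 = speed > thr1
    miss1 = trace.missing | removed1

    # trend line: interpolate the gaps, smooth with the moving average
    interp, _ = _interp_interior(trace.time, np.where(miss1, np.nan, trace.pupil), miss1)
    width = int(round(cfg.smooth_ms / 1000.0 * trace.rate))
    trend = moving_average(interp, width)

    dev = np.abs(trace.pupil - trend)
    dev[miss1] = np.nan
    # the shrinking-window trend is biased inside half a window of the trace
    # edges; pass 2 does not evaluate there (pass 1 still covers spikes)
    half = width // 2
    if half > 0:
        dev[:half] = np.nan
        dev[-half:] = np.nan
    if not np.any(np.isfinite(dev)):
        raise ValueError("cleaning removed the entire trace (pass 1)")
    thr2 = mad_threshold(dev, cfg.mad_constant)
    with np.errstate(invalid="ignore"):
        removed2 = dev > thr2
    removed = (removed1 | removed2) & ~trace.missing
    miss = trace.missing | removed
    if np.all(miss):
        raise ValueError("cleaning removed the entire trace")
    filled, still_missing = _interp_interior(
        trace.time, np.where(miss, np.nan, trace.pupil), miss
    )
    return PupilTrace(trace.time, filled, still_missing), removed


def epoch_trials(trace: PupilTrace, events: pd.DataFrame,
                 window: Tuple[float, float]) -> EpochSet:
    """Cut one epoch per event onset; edge-clipped epochs are flagged.

    The stimulus-onset sample is the sample nearest the event onset and
    belongs to post-stimulus time.  Epoch length is
    ``round((w1 - w0) * rate) + 1`` samples.
    """
    rate = trace.rate
    n_samp = int(round((window[1] - window[0]) * rate)) + 1
    rel = window[0] + np.arange(n_samp) / rate
    n_ev = len(events)
    data = np.full((n_ev, n_samp), np.nan)
    missing = np.ones((n_ev, n_samp), dtype=bool)
    rejected = np.zeros(n_ev, dtype=bool)
    reasons = [""] * n_ev
    for k, onset in enumerate(events["onset_s"].to_numpy()):
        i_on = int(round((onset - trace.time[0]) * rate))
        start = i_on + int(round(window[0] * rate))
        stop = start + n_samp
        if start < 0 or stop > trace.time.size:
            rejected[k] = True
            reasons[k] = "edge"
            continue
        data[k] = trace.pupil[start:stop]
        missing[k] = trace.missing[start:stop]
    labels = events.reset_index(drop=True).copy()
    return EpochSet(data=data, times=rel, labels=labels, missing=missing,
                    rejected=rejected, reasons=reasons)


def reject_missing(epochs: EpochSet, cfg: CleanConfig = CleanConfig(),
                   condition_cols: Sequence[str] = ("stimulation",)) -> dict:
    """Apply the missing-data trial and subject exclusion rules in place.

    Trials strictly above ``trial_missing_max`` missing are rejected;
    subjects strictly above ``subject_excluded_max`` rejected trials in any
    single condition cell are wholly excluded.  Returns a count report.
    """
    if epochs.missing is None:
        raise ValueError("epochs carry no missing mask")
    frac = epochs.missing.mean(axis=1)
    newly = (frac > cfg.trial_missing_max) & ~epochs.rejected
    epochs.rejected |= newly
    for k in np.flatnonzero(newly):
        epochs.reasons[k] = "missing"

    excluded_subjects = []
    lab = epochs.labels
    cols = [c for c in condition_cols if c in lab.columns]
    if "subject" in lab.columns and cols:
        for subj, sub in lab.groupby("subject"):
            for _, cell in sub.groupby(cols):
                idx = cell.index.to_numpy()
                if epochs.rejected[idx].mean() > cfg.subject_excluded_max:
                    excluded_subjects.append(subj)
                    break
        for subj in excluded_subjects:
            idx = lab.index[lab["subject"] == subj].to_numpy()
            for k in idx:
                if not epochs.rejected[k]:
                    epochs.rejected[k] = True
                    epochs.reasons[k] = "subject"
    report = {
        "n_trials": int(epochs.n_trials),
        "n_rejected_missing": int(sum(r == "missing" for r in epochs.reasons)),
        "n_rejected_edge": int(sum(r == "edge" for r in epochs.reasons)),
        "excluded_subjects": sorted(set(excluded_subjects)),
    }
    return report


def normalize_epochs(epochs: EpochSet, cfg: CleanConfig = CleanConfig(),
                     mean: Optional[float] = None,
                     sd: Optional[float] = None) -> EpochSet:
    """z-score, baseline-correct, and decimate retained epochs.

    The z-score uses the pooled mean/SD of all retained-epoch samples
    (per subject-session scope when called per session); pass ``mean``/
    ``sd`` to impose an external scope.  The baseline is the epoch mean
    over [-baseline_ms, 0) ms; the onset sample is post-stimulus.
    """
    keep = epochs.retained()
    data = epochs.data[keep]
    if data.size == 0:
        raise ValueError("no retained epochs")
    vals = data[np.isfinite(data)]
    if mean is None:
        mean = float(vals.mean())
    if sd is None:
        sd = float(vals.std(ddof=0))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("zero variance in z-scoring scope")
    z = (data - mean) / sd
    # decimate before the baseline subtraction so the baseline-window mean
    # of the output is exactly zero (equivalent for band-limited traces)
    step = int(round(epochs.rate / cfg.out_rate_hz))
    z = z[:, ::step]
    times = epochs.times[::step]
    bl_mask = (times >= -cfg.baseline_ms / 1000.0) & (times < 0)
    if not bl_mask.any():
        raise ValueError("baseline window outside epoch")
    baselines = np.nanmean(z[:, bl_mask], axis=1)
    z = z - baselines[:, None]
    missing = epochs.missing[keep][:, ::step] if epochs.missing is not None else None
    return EpochSet(data=z, times=times,
                    labels=epochs.labels.loc[keep].reset_index(drop=True),
                    missing=missing, baselines=baselines)


def preprocess_session(trace: PupilTrace, events: pd.DataFrame,
                       window: Tuple[float, float],
                       cfg: CleanConfig = CleanConfig()):
    """Full single-session chain: epoch, reject, clean per epoch, normalize.

    Returns ``(EpochSet, report)`` with the cleaned, z-scored, baselined,
    decimated epochs of one subject-session.
    """
    epochs = epoch_trials(trace, events, window)
    report = reject_missing(epochs, cfg)
    removed_frac = []
    for k in np.flatnonzero(epochs.retained()):
        sub = PupilTrace(epochs.times, epochs.data[k], epochs.missing[k])
        cleaned, removed = two_pass_clean(sub, cfg)
        epochs.data[k] = cleaned.pupil
        epochs.missing[k] = cleaned.missing
        removed_frac.append(float(removed.mean()))
    report["mean_removed_fraction"] = float(np.mean(removed_frac)) if removed_frac else 0.0
    out = normalize_epochs(epochs, cfg)
    return out, report
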