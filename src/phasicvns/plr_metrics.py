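"""Pupillary-light-reflex kinematics.

Extracts onset latency, peak constriction amplitude, and constriction/
redilation velocities from a cleaned, averaged PLR trace.  The peak
constriction is the most negative value after stimulus onset; the reflex
onset is the most negative acceleration between stimulus onset and the
constriction peak (the acceleration minimum of a constriction necessarily
precedes its amplitude minimum); constriction velocities are computed
between onset and peak, dilation velocities after the peak.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .containers import PLRMetrics

__all__ = ["derivatives", "extract_plr", "NoPLRError"]


class NoPLRError(ValueError):
    """Raised when the trace contains no post-stimulus constriction."""


def derivatives(times: np.ndarray, trace: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """First (velocity) and second (acceleration) derivatives.

    Central finite differences with one-sided differences at the edges;
    lengths are preserved.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vel = np.gradient(trace, times, edge_order=2)
    acc = np.gradient(vel, times, edge_order=2)
    return vel, acc


def extract_plr(times: np.ndarray, trace: np.ndarray,
                stimulus_onset: float = 0.0,
                smooth_ms: Optional[float] = None) -> PLRMetrics:
    """Extract kinematic parameters from one averaged PLR trace.

    ``times`` in seconds relative to stimulus onset, ``trace`` in z-units
    (baseline-corrected, so the pre-flash level is ~0).  Optional light
    smoothing (``smooth_ms``) before differentiation suppresses noise
    amplification; off by default so analytic inputs are exact.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    finite = np.isfinite(trace)
    if not finite.all():
        # trim non-interpolatable leading/trailing missing stretches
        iv = np.flatnonzero(finite)
        if iv.size < 3:
            raise ValueError("too few finite samples")
        times = times[iv[0]: iv[-1] + 1]
        trace = trace[iv[0]: iv[-1] + 1]
        if not np.all(np.isfinite(trace)):
            raise ValueError("trace has interior missing samples; clean first")
    if smooth_ms:
        rate = 1.0 / float(np.median(np.diff(times)))
        w = max(int(round(smooth_ms / 1000.0 * rate)), 1)
        trace = uniform_filter1d(trace, w, mode="nearest")
    post = times >= stimulus_onset
    if post.sum() < 3:
        raise ValueError("too few post-stimulus samples")
    i_post = np.flatnonzero(post)
    i_peak = i_post[np.argmin(trace[post])]
    if trace[i_peak] >= 0:
        raise NoPLRError("no PLR detected: no post-stimulus minimum below baseline")
    vel, acc = derivatives(times, trace)
    # onset: most negative acceleration in [stimulus onset, peak constriction]
    seg = i_post[i_post <= i_peak]
    if seg.size < 2 or i_peak == i_post[0]:
        raise NoPLRError("no PLR detected: constriction peak at stimulus onset")
    i_on = seg[np.argmin(acc[seg])]
    con = slice(i_on, i_peak + 1)
    dil = slice(i_peak + 1, times.size)
    if times.size - i_peak - 1 < 1:
        raise NoPLRError("no samples after peak constriction")
    return PLRMetrics(
        onset_latency_ms=1000.0 * (times[i_on] - stimulus_onset),
        peak_constriction_amplitude=float(trace[i_peak]),
        t_peak_constriction_ms=1000.0 * (times[i_peak] - stimulus_onset),
        peak_constriction_velocity=float(np.min(vel[con])),
        avg_constriction_velocity=float(np.mean(vel[con])),
        peak_dilation_velocity=float(np.max(vel[dil])),
        avg_dilation_velocity=float(np.mean(vel[dil])),
    )
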