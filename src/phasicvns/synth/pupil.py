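"""Synthetic pupil recordings for both tasks.

Each subject/stimulation condition yields one continuous 500 Hz trace in
raw recorder units.  EST trials superimpose a luminance-driven constriction
to the face picture and a slower, gamma-shaped task-evoked dilation whose
amplitude carries the congruency and stimulation effects.  PLRT trials are
parametric light reflexes: a gamma-CDF constriction with onset latency L
to depth -A followed by exponential redilation; taVNS trials use
L + latency shift and A x amplitude scale.  Blink artifacts are missing
runs flanked by sharp spike samples, which is what the two-pass
dilation-speed cleaning is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ..containers import PupilTrace
from ..design import StudyDesign, EffectSpec

__all__ = ["PupilSim", "gen_pupil_est", "gen_plrt", "plr_template", "plr_truth"]

RAW_BASE = 4000.0     # arbitrary recorder units at rest
RAW_PER_Z = 400.0     # raw units per generated z-unit
HIPPUS_AMP = 0.5
HIPPUS_FREQ = 1.3
LIGHT_RISE = 0.2


@dataclass
class PupilSim:
    """Generator output: traces plus everything needed for recovery tests."""

    traces: Dict[Tuple[int, int], PupilTrace]   # (subject, stimulation) -> trace
    events: pd.DataFrame
    truth: pd.DataFrame
    artifact: Dict[Tuple[int, int], np.ndarray]  # injected spike-sample masks


def plr_template(t: np.ndarray, latency_s: float, amplitude: float,
                 rise_tau_s: float, redil_tau_s: float) -> np.ndarray:
    """Parametric light-reflex trace (z-units, negative-going).

    Gamma-CDF (shape 3) constriction to depth ``-amplitude`` followed by
    exponential redilation with time constant ``redil_tau_s``.  The shape
    is exactly zero before constriction start with C2 continuity (the CDF
    rises like t^3), so the trace has no onset kink; its second derivative
    has a smooth interior minimum at ``x = 2 - sqrt(2)`` rise times after
    constriction start, and the start is positioned so this acceleration
    minimum — the onset convention the kinematics extraction uses — falls
    exactly at ``latency_s``.  The constriction peak sits 6 rise times
    after start, where the CDF is treated as saturated.
    """
    from scipy.special import gammainc

    t = np.asarray(t, dtype=float)
    x_on = 2.0 - np.sqrt(2.0)   # acceleration minimum of the gamma(3) CDF
    x_sat = 6.0
    t0 = latency_s - x_on * rise_tau_s
    if t0 < 0:
        raise ValueError("rise_tau too long for this latency (onset before flash)")
    x = np.maximum(t - t0, 0.0) / rise_tau_s
    g = gammainc(3.0, np.minimum(x, x_sat)) / gammainc(3.0, x_sat)
    t_peak = t0 + x_sat * rise_tau_s
    redil = -amplitude * np.exp(-np.maximum(t - t_peak, 0.0) / redil_tau_s)
    return np.where(t <= t_peak, -amplitude * g, redil)


def plr_truth(latency_s: float, amplitude: float, rise_tau_s: float,
              redil_tau_s: float, rate_hz: float = 2000.0,
              horizon_s: float = 7.0) -> dict:
    """Kinematic ground truth of the noiseless template.

    Evaluated numerically on a fine grid with the same derivative
    definitions the extraction stage uses (acceleration minimum before the
    constriction peak marks onset).
    """
    t = np.arange(0.0, horizon_s, 1.0 / rate_hz)
    y = plr_template(t, latency_s, amplitude, rise_tau_s, redil_tau_s)
    vel = np.gradient(y, t)
    acc = np.gradient(vel, t)
    i_peak = int(np.argmin(y))
    i_on = int(np.argmin(acc[: i_peak + 1]))
    return {
        "onset_latency_ms": 1000.0 * t[i_on],
        "peak_constriction_amplitude": float(y[i_peak]),
        "t_peak_constriction_ms": 1000.0 * t[i_peak],
        "peak_constriction_velocity": float(np.min(vel[i_on : i_peak + 1])),
        "avg_constriction_velocity": float(np.mean(vel[i_on : i_peak + 1])),
        "peak_dilation_velocity": float(np.max(vel[i_peak + 1 :])),
        "avg_dilation_velocity": float(np.mean(vel[i_peak + 1 :])),
    }


def dilation_kernel(t: np.ndarray, peak_s: float, shape: float = 3.0) -> np.ndarray:
    """Gamma-shaped task-evoked dilation kernel, unit peak at ``peak_s``."""
    t = np.asarray(t, dtype=float)
    x = np.maximum(t, 0.0) / peak_s
    return np.where(t > 0, x**shape * np.exp(shape * (1.0 - x)), 0.0)


def _inject_blinks(rng, pupil, missing, onsets_idx, rate, blink_rate,
                   window_s=(0.0, 5.0)):
    """Missing runs of 100-400 ms flanked by spike samples; returns spike mask."""
    spikes = np.zeros(pupil.size, dtype=bool)
    n = pupil.size
    for idx in onsets_idx:
        if rng.random() >= blink_rate:
            continue
        dur = int(rng.uniform(0.1, 0.4) * rate)
        lo = idx + int(window_s[0] * rate)
        hi = idx + int(window_s[1] * rate) - dur
        if hi <= lo:
            continue
        start = rng.integers(lo, hi)
        stop = min(start + dur, n)
        missing[start:stop] = True
        pupil[start:stop] = np.nan
        n_edge = int(rng.integers(2, 5))
        for edge in (range(max(start - n_edge, 0), start),
                     range(stop, min(stop + n_edge, n))):
            for j in edge:
                if not missing[j]:
                    pupil[j] -= rng.uniform(1.0, 3.0) * RAW_PER_Z
                    spikes[j] = True
    return spikes


def _background(rng, n, rate, hippus_envelope=None):
    """Smooth physiological background: hippus plus slow arousal drift.

    A dominant ~1.3 Hz hippus oscillation plus very slow (<0.1 Hz) arousal
    drift.  All components are band-limited sinusoids, matching the
    smoothness of recorder-filtered pupil traces: sample-to-sample changes
    are set by bounded physiological slopes, so only blink spikes produce
    dilation-speed outliers.  ``hippus_envelope`` optionally modulates the
    hippus amplitude over time (the light reflex transiently suppresses
    hippus).
    """
    t = np.arange(n) / rate
    hip = HIPPUS_AMP * rng.uniform(0.95, 1.15) * np.sin(
        2 * np.pi * HIPPUS_FREQ * t + rng.uniform(0, 2 * np.pi))
    if hippus_envelope is not None:
        hip = hip * hippus_envelope
    z = hip
    for a, f in ((0.20, 0.02), (0.25, 0.05), (0.15, 0.08)):
        z += a * rng.normal() * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return z


def _suppression_envelope(n, rate, onsets_s, depth=0.1, hold_s=3.0,
                          ramp_s=0.4, pre_s=0.35):
    """Hippus attenuation around each stimulus: cosine ramp down to ``depth``.

    The down-ramp starts ``pre_s`` before stimulus onset (hippus quiets as
    the subject orients to the imminent stimulus during the fixation
    period), so suppression is complete just after onset and the envelope
    contributes negligible curvature during the light-reflex onset.
    """
    env = np.ones(n)
    n_hold = int(hold_s * rate)
    n_ramp = int(ramp_s * rate)
    down = depth + (1 - depth) * 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_ramp)))
    up = down[::-1]
    for onset in onsets_s:
        i0 = int(round((onset - pre_s) * rate))
        sl = slice(max(i0, 0), min(i0 + n_ramp, n))
        env[sl] = np.minimum(env[sl], down[max(0, -i0): max(0, -i0) + sl.stop - sl.start])
        sl = slice(max(min(i0 + n_ramp, n), 0), min(i0 + n_ramp + n_hold, n))
        env[sl] = np.minimum(env[sl], depth)
        i1 = i0 + n_ramp + n_hold
        sl = slice(max(i1, 0), min(i1 + n_ramp, n))
        if sl.stop > sl.start:
            env[sl] = np.minimum(env[sl], up[: sl.stop - sl.start])
    return env


def gen_pupil_est(design: StudyDesign, effects: EffectSpec, seed: int) -> PupilSim:
    """Continuous EST pupil recordings with per-trial dilation ground truth."""
    rng = np.random.default_rng(seed)
    rate = design.pupil_rate_hz
    traces, artifact = {}, {}
    ev_rows, truth_rows = [], []
    n_trials = design.trials_est_per_condition
    for subj in range(design.n_subjects):
        for stim in (0, 1):
            isis = rng.uniform(*design.isi_range_est_s, size=n_trials)
            onsets = np.empty(n_trials)
            t0 = 3.0
            for k in range(n_trials):
                onsets[k] = t0
                t0 += design.stim_duration_s + design.est_fix_post_s + 2.0 + isis[k]
            dur = onsets[-1] + design.epoch_est_s[1] + 1.0
            n = int(dur * rate)
            t = np.arange(n) / rate
            env = _suppression_envelope(n, rate, onsets, depth=0.4, hold_s=1.5)
            z = effects.background_scale * _background(rng, n, rate, hippus_envelope=env)
            congr = np.concatenate([
                rng.permutation(np.repeat([0, 1], design.trials_per_block // 2))
                for _ in range(design.n_blocks_est)
            ])
            rel = np.arange(int(6.0 * rate)) / rate  # kernel support 0..6 s
            light = plr_template(rel, 0.2, 0.8, LIGHT_RISE, 1.0)
            dil_kernel = dilation_kernel(rel, effects.pupil_dilation_peak_s)
            for k, onset in enumerate(onsets):
                amp = (
                    effects.pupil_dilation_base
                    + effects.pupil_effect_congruency * (1 - congr[k])
                    + effects.pupil_effect_stimulation * stim
                )
                i0 = int(round(onset * rate))
                sl = slice(i0, min(i0 + rel.size, n))
                z[sl] += light[: sl.stop - sl.start]
                z[sl] += amp * dil_kernel[: sl.stop - sl.start]
                ev_rows.append((subj, stim, k + 1, "EST", onset, int(congr[k])))
                truth_rows.append((subj, stim, k + 1, amp))
            if effects.noise_sd > 0:
                z += rng.normal(0, effects.noise_sd, n)
            pupil = RAW_BASE + RAW_PER_Z * z
            missing = np.zeros(n, dtype=bool)
            spikes = _inject_blinks(rng, pupil, missing,
                                    (onsets * rate).astype(int), rate,
                                    effects.blink_rate,
                                    window_s=(design.epoch_est_s[0] + 0.5,
                                              design.epoch_est_s[1] - 0.5))
            traces[(subj, stim)] = PupilTrace(t, pupil, missing)
            artifact[(subj, stim)] = spikes
    events = pd.DataFrame(
        ev_rows, columns=["subject", "stimulation", "trial", "task", "onset_s", "congruency"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["subject", "stimulation", "trial", "dilation_amp"]
    )
    return PupilSim(traces, events, truth, artifact)


def gen_plrt(design: StudyDesign, effects: EffectSpec, seed: int) -> PupilSim:
    """Continuous PLRT recordings with per-trial template ground truth."""
    if effects.plr_amplitude_scale <= 0:
        raise ValueError("plr_amplitude_scale must be positive")
    rng = np.random.default_rng(seed)
    rate = design.pupil_rate_hz
    traces, artifact = {}, {}
    ev_rows, truth_rows = [], []
    rise = effects.plr_rise_tau_ms / 1000.0
    for subj in range(design.n_subjects):
        for stim in (0, 1):
            lat = (effects.plr_latency_ms + stim * effects.plr_latency_shift_ms) / 1000.0
            amp = effects.plr_amplitude * (effects.plr_amplitude_scale if stim else 1.0)
            isis = rng.uniform(*design.isi_range_plrt_s, size=design.n_trials_plrt)
            onsets = np.empty(design.n_trials_plrt)
            t0 = 3.0
            for k in range(design.n_trials_plrt):
                onsets[k] = t0
                t0 += design.flash_duration_s + design.plrt_fix_post_s + 2.0 + isis[k]
            dur = onsets[-1] + design.epoch_plrt_s[1] + 1.0
            n = int(dur * rate)
            t = np.arange(n) / rate
            env = _suppression_envelope(n, rate, onsets)
            z = effects.background_scale * _background(rng, n, rate, hippus_envelope=env)
            rel = np.arange(int(design.epoch_plrt_s[1] * rate)) / rate
            template = plr_template(rel, lat, amp, rise, effects.plr_redilation_tau_s)
            tr = plr_truth(lat, amp, rise, effects.plr_redilation_tau_s)
            for k, onset in enumerate(onsets):
                i0 = int(round(onset * rate))
                sl = slice(i0, min(i0 + rel.size, n))
                z[sl] += template[: sl.stop - sl.start]
                ev_rows.append((subj, stim, k + 1, "PLRT", onset, -1))
                truth_rows.append((subj, stim, k + 1, lat * 1000.0, -amp,
                                   tr["onset_latency_ms"],
                                   tr["peak_constriction_amplitude"],
                                   tr["peak_constriction_velocity"],
                                   tr["avg_constriction_velocity"],
                                   tr["peak_dilation_velocity"],
                                   tr["avg_dilation_velocity"]))
            if effects.noise_sd > 0:
                z += rng.normal(0, effects.noise_sd, n)
            pupil = RAW_BASE + RAW_PER_Z * z
            missing = np.zeros(n, dtype=bool)
            spikes = _inject_blinks(rng, pupil, missing,
                                    (onsets * rate).astype(int), rate,
                                    effects.blink_rate,
                                    window_s=(design.epoch_plrt_s[0] + 0.5,
                                              design.epoch_plrt_s[1] - 0.5))
            traces[(subj, stim)] = PupilTrace(t, pupil, missing)
            artifact[(subj, stim)] = spikes
    events = pd.DataFrame(
        ev_rows, columns=["subject", "stimulation", "trial", "task", "onset_s", "congruency"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject", "stimulation", "trial", "latency_param_ms", "amplitude_param",
                 "onset_latency_ms", "peak_constriction_amplitude",
                 "peak_constriction_velocity", "avg_constriction_velocity",
                 "peak_dilation_velocity", "avg_dilation_velocity"],
    )
    return PupilSim(traces, events, truth, artifact)


def plr_session_average(seed: int, n_trials: int = 20, noise_sd: float = 0.1,
                        rate_hz: float = 100.0,
                        window_s: Tuple[float, float] = (-2.0, 7.0),
                        latency_s: float = 0.17083, amplitude: float = 2.2,
                        rise_tau_s: float = 0.2, redil_tau_s: float = 2.8):
    """One subject-session averaged PLR trace with physiological noise.

    Emulates the pipeline's unit of analysis: the template plus the mean of
    ``n_trials`` independent background realizations (hippus suppressed
    around the flash, slow arousal drift), each scaled to ``noise_sd``
    z-units.  Returns ``(times, trace)`` with times relative to flash
    onset.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(window_s[0], window_s[1], 1.0 / rate_hz)
    n = t.size
    tpl = plr_template(t, latency_s, amplitude, rise_tau_s, redil_tau_s)
    env = _suppression_envelope(n, rate_hz, [-window_s[0]])
    acc = np.zeros(n)
    for _ in range(n_trials):
        bg = _background(rng, n, rate_hz, hippus_envelope=env)
        if noise_sd > 0:
            acc += bg * (noise_sd / bg.std())
    return t, tpl + acc / max(n_trials, 1)
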