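"""Synthetic MEG-like recordings with stimulation-artifact pulse trains.

Per subject/stimulation condition, a continuous 1000 Hz multichannel
recording: 1/f background noise, a frontal-midline (FM) theta/low-alpha
oscillation and an occipital-midline (OM) alpha oscillation whose
post-stimulus amplitudes carry the condition effects, plus large biphasic
transients at every stimulation pulse (both active and sham sites are
electrically stimulated, so both conditions carry artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from ..containers import ContSignal
from ..design import StudyDesign, EffectSpec

__all__ = ["MegSim", "gen_meg", "FM_CHANNELS", "OM_CHANNELS"]

FM_CHANNELS = ["fm1", "fm2", "fm3"]
OM_CHANNELS = ["om1", "om2", "om3"]


@dataclass
class MegSim:
    signals: Dict[Tuple[int, int], ContSignal]   # (subject, stimulation)
    events: pd.DataFrame                         # trial onsets with conditions
    markers: pd.DataFrame                        # pulse onsets
    truth: pd.DataFrame                          # per-trial oscillation gains
    clean: Dict[Tuple[int, int], np.ndarray]     # artifact-free channel arrays


def _pink_noise(rng, n, rate, sd):
    """Background with ~1/f amplitude spectrum."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return sd * out / out.std()


def _narrowband(rng, n, rate, band, sd):
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.normal(0, 1, max(n, 64)))[:n]
    s = x.std()
    return sd * x / s if s > 0 else x


def _artifact_shape(rate: float, width_ms: float = 4.0) -> np.ndarray:
    """One-cycle biphasic transient of ``width_ms`` duration."""
    n = max(int(round(width_ms / 1000.0 * rate)), 2)
    return np.sin(2 * np.pi * np.arange(n) / n)


def gen_meg(design: StudyDesign, effects: EffectSpec, seed: int,
            channel_groups: Dict[str, list] | None = None,
            effect_window_s: Tuple[float, float] = (0.0, 3.0)) -> MegSim:
    """Generate EST-style MEG recordings.

    ``theta_effect`` / ``alpha_effect`` are taVNS/sham power ratios applied
    inside ``effect_window_s`` post-stimulus at FM (4-8 Hz) and OM
    (8.5-13 Hz) channels; ``congruency_power_effect`` scales FM power on
    incongruent trials.
    """
    groups = channel_groups or {"fm": FM_CHANNELS, "om": OM_CHANNELS}
    for g in groups:
        if g not in ("fm", "om"):
            raise ValueError(f"unknown channel group {g!r}")
    rng = np.random.default_rng(seed)
    rate = design.meg_rate_hz
    n_trials = design.trials_est_per_condition
    pulse_rel = np.asarray(design.stim_train.pulse_onsets_s())
    art = _artifact_shape(rate)
    signals, clean = {}, {}
    ev_rows, mk_rows, truth_rows = [], [], []
    base_amp = 1.0  # oscillation SD in signal units
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
            congr = np.concatenate([
                rng.permutation(np.repeat([0, 1], design.trials_per_block // 2))
                for _ in range(design.n_blocks_est)
            ])
            chan = {}
            for name in groups.get("fm", []) + groups.get("om", []):
                is_fm = name in groups.get("fm", [])
                band = (4.0, 8.0) if is_fm else (8.5, 13.0)
                osc = _narrowband(rng, n, rate, band, base_amp)
                gain = np.ones(n)
                for k, onset in enumerate(onsets):
                    ratio = 1.0
                    if is_fm:
                        if stim:
                            ratio *= effects.theta_effect
                        if not congr[k]:
                            ratio *= effects.congruency_power_effect
                    else:
                        if stim:
                            ratio *= effects.alpha_effect
                    i0 = int(round((onset + effect_window_s[0]) * rate))
                    i1 = min(int(round((onset + effect_window_s[1]) * rate)), n)
                    gain[i0:i1] = np.sqrt(ratio)
                x = osc * gain + _pink_noise(rng, n, rate, effects.meg_noise_sd)
                chan[name] = x
            vals = np.column_stack(list(chan.values()))
            clean_vals = vals.copy()
            sd = vals.std()
            for k, onset in enumerate(onsets):
                for p in pulse_rel:
                    i0 = int(round((onset + p) * rate))
                    sl = slice(i0, min(i0 + art.size, n))
                    vals[sl, :] += (effects.artifact_amplitude_sd * sd
                                    * art[: sl.stop - sl.start])[:, None]
                    mk_rows.append((subj, stim, k + 1, onset + p))
                ev_rows.append((subj, stim, k + 1, onset, int(congr[k])))
                truth_rows.append((subj, stim, k + 1, int(congr[k])))
            df = pd.DataFrame(vals, columns=list(chan.keys()))
            markers = np.asarray([m[3] for m in mk_rows
                                  if m[0] == subj and m[1] == stim])
            signals[(subj, stim)] = ContSignal(t, df, rate, markers)
            clean[(subj, stim)] = clean_vals.T
    events = pd.DataFrame(ev_rows, columns=["subject", "stimulation", "trial",
                                            "onset_s", "congruency"])
    markers_df = pd.DataFrame(mk_rows, columns=["subject", "stimulation", "trial",
                                                "onset_s"])
    truth = pd.DataFrame(truth_rows, columns=["subject", "stimulation", "trial",
                                              "congruency"])
    return MegSim(signals, events, markers_df, truth, clean)
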