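"""Study design and effect-size containers.

The defaults describe a within-subject crossover experiment: subjects
perform an emotional Stroop task (EST; six blocks of 20 face/word trials,
half congruent) and a passive pupillary-light-reflex task (PLRT; one block
of 20 bright flashes) twice each, once under active transcutaneous
auricular vagus nerve stimulation (taVNS) and once under sham stimulation,
with the stimulation order counterbalanced across subjects.  Stimulation is
phasic: a 500 ms train of 30 Hz monophasic pulses locked to stimulus onset.
Pupil diameter is sampled monocularly at 500 Hz and MEG-like signals at
1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

__all__ = ["StimTrain", "StudyDesign", "EffectSpec"]


@dataclass(frozen=True)
class StimTrain:
    """Phasic stimulation train locked to stimulus onset."""

    frequency_hz: float = 30.0
    duration_ms: float = 500.0
    pulse_width_us: float = 200.0
    amplitude_ma: float = 2.0

    def __post_init__(self) -> None:
        for name in ("frequency_hz", "duration_ms", "pulse_width_us", "amplitude_ma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_pulses(self) -> int:
        """Pulse count per train: floor(duration * frequency)."""
        return int(self.frequency_hz * self.duration_ms / 1000.0)

    def pulse_onsets_s(self) -> list[float]:
        """Pulse onset times in seconds relative to train start."""
        return [k / self.frequency_hz for k in range(self.n_pulses)]


@dataclass(frozen=True)
class StudyDesign:
    n_subjects: int = 29
    n_blocks_est: int = 6
    trials_per_block: int = 20        # split 50/50 congruent/incongruent
    n_trials_plrt: int = 20
    pupil_rate_hz: float = 500.0
    meg_rate_hz: float = 1000.0
    stim_duration_s: float = 1.0      # EST face picture on screen
    flash_duration_s: float = 0.5     # PLRT white screen
    est_fix_post_s: float = 5.0       # fixation after picture offset
    plrt_fix_post_s: float = 20.0     # fixation after flash offset
    isi_range_est_s: Tuple[float, float] = (1.0, 4.0)
    isi_range_plrt_s: Tuple[float, float] = (8.0, 12.0)
    epoch_est_s: Tuple[float, float] = (-2.0, 5.0)
    epoch_plrt_s: Tuple[float, float] = (-2.0, 7.0)
    stim_train: StimTrain = field(default_factory=StimTrain)
    counterbalance: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_blocks_est <= 0 or self.trials_per_block <= 0:
            raise ValueError("block/trial counts must be positive")
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must split evenly into congruent/incongruent")
        if self.n_trials_plrt <= 0:
            raise ValueError("n_trials_plrt must be positive")
        if self.pupil_rate_hz <= 0 or self.meg_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        for lo, hi in (self.isi_range_est_s, self.isi_range_plrt_s):
            if lo > hi:
                raise ValueError("ISI ranges must be ordered (lo <= hi)")

    @property
    def trials_est_per_condition(self) -> int:
        return self.n_blocks_est * self.trials_per_block

    @property
    def trials_est_total(self) -> int:
        """EST trials per subject across both stimulation conditions."""
        return 2 * self.trials_est_per_condition


@dataclass(frozen=True)
class EffectSpec:
    """Generative effect sizes.

    Behavioral log-odds coefficients parameterize a logistic mixed model of
    single-trial accuracy, ``hits ~ trialnumber + face + intensity +
    stimulation*congruency`` with subject random intercepts and slopes for
    stimulation and congruency.  Coding: congruent = 1, taVNS = 1, happy
    face = 1; intensity (mA) is centered before entering the predictor.
    Pupil effects are expressed in z-units of the normalized pupil trace;
    oscillatory effects as taVNS/sham power ratios.
    """

    # logistic accuracy model (log-odds)
    beta_intercept: float = 2.2
    beta_trial: float = 0.005
    beta_face: float = 0.06
    beta_intensity: float = -0.24
    beta_stimulation: float = 0.44
    beta_congruency: float = 0.92
    beta_interaction: float = 0.02
    re_sd_intercept: float = 0.8
    re_sd_stimulation: float = 0.3
    re_sd_congruency: float = 0.3

    # reaction times (ms)
    rt_mean_ms: float = 754.0
    rt_effect_congruency_ms: float = -54.0   # congruent faster
    rt_trial_slope_ms: float = -0.49
    rt_subject_sd_ms: float = 120.0
    rt_noise_sd_ms: float = 200.0

    # pupil (z-units of the normalized trace)
    pupil_effect_congruency: float = 0.07    # incongruent minus congruent dilation
    pupil_effect_stimulation: float = 0.135  # taVNS minus sham dilation
    pupil_dilation_base: float = 0.35
    pupil_dilation_peak_s: float = 1.3
    pupil_subject_sd: float = 0.15

    # pupillary light reflex
    plr_latency_ms: float = 170.83           # sham constriction onset
    plr_latency_shift_ms: float = 27.09      # taVNS delay
    plr_amplitude: float = 2.2               # peak constriction depth (positive scalar)
    plr_amplitude_scale: float = 0.925       # taVNS amplitude multiplier
    plr_rise_tau_ms: float = 200.0   # constriction peaks ~6 tau after start
    plr_redilation_tau_s: float = 2.8

    # oscillatory power ratios (taVNS / sham)
    theta_effect: float = 1.25               # frontal-midline theta/alpha up
    alpha_effect: float = 0.80               # occipital-midline alpha down
    congruency_power_effect: float = 1.15    # incongruent / congruent at FM
    artifact_amplitude_sd: float = 50.0      # stimulation transient, units of signal SD

    # noise
    noise_sd: float = 0.0                    # white pupil sample noise, z-units
                                             # (recorder filtering leaves white
                                             # noise below quantization; smooth
                                             # hippus/drift carry the variability)
    background_scale: float = 1.0            # hippus + drift amplitude multiplier
    meg_noise_sd: float = 1.0
    blink_rate: float = 0.15                 # per-trial blink probability
    intensity_mean_ma: float = 1.91
    intensity_sd_ma: float = 0.24

    def __post_init__(self) -> None:
        if not 0.0 <= self.blink_rate <= 1.0:
            raise ValueError("blink_rate must lie in [0, 1]")
        for name in ("plr_amplitude_scale", "theta_effect", "alpha_effect",
                     "pupil_subject_sd", "plr_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.meg_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)
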