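"""Synthetic single-trial behavior for the emotional Stroop task.

The generator inverts the analysis model: single-trial accuracy is drawn
from a logistic mixed model with subject random intercepts and random
slopes for stimulation and congruency, and reaction times from a linear
mixed model with a congruency shift.  All effect sizes live in
:class:`~phasicvns.design.EffectSpec`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..design import StudyDesign, EffectSpec

__all__ = ["gen_behavior"]


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_behavior(design: StudyDesign, effects: EffectSpec, seed: int) -> pd.DataFrame:
    """Generate one trial table for the full EST (both stimulation halves).

    Returns a DataFrame with columns ``subject, trial, block, stimulation,
    congruency, face, intensity_ma, correct, rt_ms`` plus the ground-truth
    per-trial success probability ``p_true``.  Congruent/taVNS/happy are
    coded 1.  Trial numbers run continuously across the session.
    """
    if design.n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)

    n_per_block = design.trials_per_block
    n_blocks = design.n_blocks_est
    rows = []
    for subj in range(design.n_subjects):
        # counterbalanced stimulation order: even subjects taVNS first
        if design.counterbalance and subj % 2 == 0:
            halves = (1, 0)
        else:
            halves = (0, 1)
        u = rng.normal(
            0.0,
            [effects.re_sd_intercept, effects.re_sd_stimulation, effects.re_sd_congruency],
        )
        rt_u = rng.normal(0.0, effects.rt_subject_sd_ms)
        intensity = {
            stim: float(np.clip(rng.normal(effects.intensity_mean_ma, effects.intensity_sd_ma), 0.5, 2.0))
            for stim in (0, 1)
        }
        trial = 0
        for half, stim in enumerate(halves):
            for block in range(n_blocks):
                congr = rng.permutation(
                    np.repeat([0, 1], n_per_block // 2)
                )
                face = rng.permutation(np.repeat([0, 1], n_per_block // 2))
                for c, f in zip(congr, face):
                    trial += 1
                    rows.append(
                        (subj, trial, half * n_blocks + block + 1, stim, int(c), int(f),
                         intensity[stim], u[0], u[1], u[2], rt_u)
                    )
    df = pd.DataFrame(
        rows,
        columns=["subject", "trial", "block", "stimulation", "congruency", "face",
                 "intensity_ma", "_u0", "_us", "_uc", "_rt_u"],
    )
    intensity_c = df["intensity_ma"] - df["intensity_ma"].mean()
    eta = (
        effects.beta_intercept
        + effects.beta_trial * df["trial"]
        + effects.beta_face * df["face"]
        + effects.beta_intensity * intensity_c
        + effects.beta_stimulation * df["stimulation"]
        + effects.beta_congruency * df["congruency"]
        + effects.beta_interaction * df["stimulation"] * df["congruency"]
        + df["_u0"] + df["_us"] * df["stimulation"] + df["_uc"] * df["congruency"]
    )
    p = _expit(eta.to_numpy())
    df["p_true"] = p
    df["correct"] = (rng.random(len(df)) < p).astype(int)
    rt = (
        effects.rt_mean_ms
        + effects.rt_effect_congruency_ms * df["congruency"]
        + effects.rt_trial_slope_ms * df["trial"]
        + df["_rt_u"]
        + rng.normal(0.0, effects.rt_noise_sd_ms, len(df))
    )
    df["rt_ms"] = np.maximum(rt, 150.0)
    return df.drop(columns=["_u0", "_us", "_uc", "_rt_u"])
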