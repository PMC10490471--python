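"""Generator-level checks: determinism, design conservation, effect truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from phasicvns.design import StudyDesign, StimTrain, EffectSpec
from phasicvns.synth import (gen_behavior, gen_pupil_est, gen_plrt, gen_meg,
                             plr_template, plr_truth)


class TestStimTrain:
    def test_pulse_count_is_floor_of_duration_times_rate(self):
        assert StimTrain(30.0, 500.0).n_pulses == 15
        assert StimTrain(30.0, 490.0).n_pulses == 14

    def test_invalid_train_rejected(self):
        with pytest.raises(ValueError):
            StimTrain(frequency_hz=-1.0)


class TestBehavior:
    def test_null_model_gives_chance_accuracy(self):
        d = StudyDesign(n_subjects=20, n_blocks_est=2)
        e = EffectSpec(beta_intercept=0, beta_trial=0, beta_face=0,
                       beta_intensity=0, beta_stimulation=0, beta_congruency=0,
                       beta_interaction=0, re_sd_intercept=1e-9,
                       re_sd_stimulation=1e-9, re_sd_congruency=1e-9)
        df = gen_behavior(d, e, 3)
        acc = df["correct"].mean()
        n = len(df)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_same_seed_reproduces_table(self, tiny_design, default_effects):
        a = gen_behavior(tiny_design, default_effects, 7)
        b = gen_behavior(tiny_design, default_effects, 7)
        pd.testing.assert_frame_equal(a, b)

    def test_row_count_matches_design(self, tiny_design, default_effects):
        df = gen_behavior(tiny_design, default_effects, 1)
        assert len(df) == tiny_design.n_subjects * tiny_design.trials_est_total

    def test_congruency_balanced_within_block(self, tiny_design, default_effects):
        df = gen_behavior(tiny_design, default_effects, 1)
        per_block = df.groupby(["subject", "stimulation", "block"])["congruency"].sum()
        assert (per_block == tiny_design.trials_per_block // 2).all()

    def test_invalid_design_rejected(self, default_effects):
        with pytest.raises(ValueError):
            StudyDesign(n_subjects=0)


class TestPupilEst:
    def test_epoch_conservation_and_determinism(self, tiny_design, default_effects):
        a = gen_pupil_est(tiny_design, default_effects, 11)
        b = gen_pupil_est(tiny_design, default_effects, 11)
        assert len(a.events) == tiny_design.n_subjects * 2 * tiny_design.trials_est_per_condition
        for key in a.traces:
            np.testing.assert_array_equal(a.traces[key].pupil, b.traces[key].pupil)

    def test_stimulation_effect_visible_in_condition_means(self):
        d = StudyDesign(n_subjects=4, n_blocks_est=2)
        e = EffectSpec(blink_rate=0.0, background_scale=0.2)
        sim = gen_pupil_est(d, e, 5)
        rate = d.pupil_rate_hz
        means = {0: [], 1: []}
        for (subj, stim), trace in sim.traces.items():
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            for onset in ev["onset_s"]:
                i0 = int(onset * rate)
                means[stim].append(trace.pupil[i0 + int(0.8 * rate):
                                               i0 + int(2.0 * rate)].mean()
                                   - trace.pupil[i0 - int(0.2 * rate):i0].mean())
        assert np.mean(means[1]) > np.mean(means[0])

    def test_blink_rate_one_gives_missing_run_every_trial(self, default_effects):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        e = EffectSpec(blink_rate=1.0)
        sim = gen_pupil_est(d, e, 9)
        rate = d.pupil_rate_hz
        for (subj, stim), trace in sim.traces.items():
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            for onset in ev["onset_s"]:
                i0 = int(onset * rate)
                window = trace.missing[i0 - int(1.5 * rate): i0 + int(4.5 * rate)]
                assert window.any()

    def test_zero_noise_zero_background_trials_identical_within_condition(self):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        e = EffectSpec(noise_sd=0.0, blink_rate=0.0, background_scale=0.0,
                       pupil_effect_congruency=0.0, pupil_effect_stimulation=0.0)
        sim = gen_pupil_est(d, e, 2)
        trace = sim.traces[(0, 0)]
        rate = d.pupil_rate_hz
        ev = sim.events.query("subject == 0 and stimulation == 0")
        segs = [trace.pupil[int(round(o * rate)): int(round(o * rate)) + int(4 * rate)]
                for o in ev["onset_s"]]
        for s in segs[1:]:
            np.testing.assert_allclose(s, segs[0], atol=1e-9)


class TestPLRT:
    def test_default_latencies_match_condition_means(self, default_effects):
        # sham 170.83 ms onset; taVNS delayed by 27.09 ms
        sham = plr_truth(0.17083, 2.2, 0.2, 2.8)
        tavns = plr_truth(0.19792, 2.2 * 0.925, 0.2, 2.8)
        assert sham["onset_latency_ms"] == pytest.approx(170.83, abs=2)
        assert tavns["onset_latency_ms"] - sham["onset_latency_ms"] == pytest.approx(27.09, abs=2)

    def test_zero_noise_trace_equals_template(self):
        d = StudyDesign(n_subjects=1, n_trials_plrt=2)
        e = EffectSpec(noise_sd=0.0, blink_rate=0.0, background_scale=0.0)
        sim = gen_plrt(d, e, 4)
        trace = sim.traces[(0, 0)]
        rate = d.pupil_rate_hz
        onset = sim.events.query("subject == 0 and stimulation == 0")["onset_s"].iloc[0]
        i0 = int(round(onset * rate))
        rel = np.arange(int(d.epoch_plrt_s[1] * rate)) / rate
        lat = e.plr_latency_ms / 1000.0
        tpl = plr_template(rel, lat, e.plr_amplitude,
                           e.plr_rise_tau_ms / 1000.0, e.plr_redilation_tau_s)
        from phasicvns.synth.pupil import RAW_BASE, RAW_PER_Z
        np.testing.assert_allclose(trace.pupil[i0:i0 + rel.size],
                                   RAW_BASE + RAW_PER_Z * tpl, atol=1e-6)

    def test_amplitude_scale_makes_constriction_shallower(self):
        t = np.arange(0, 7, 0.002)
        full = plr_template(t, 0.17, 2.0, 0.2, 2.8)
        scaled = plr_template(t, 0.17, 2.0 * 0.9, 0.2, 2.8)
        assert scaled.min() == pytest.approx(0.9 * full.min(), rel=1e-9)

    def test_amplitude_scale_must_be_positive(self, tiny_design):
        with pytest.raises(ValueError):
            EffectSpec(plr_amplitude_scale=0.0)

    def test_truth_table_carries_per_trial_kinematics(self, tiny_design, default_effects):
        sim = gen_plrt(tiny_design, default_effects, 6)
        assert {"onset_latency_ms", "peak_constriction_amplitude",
                "peak_constriction_velocity"} <= set(sim.truth.columns)
        lat = sim.truth.groupby("stimulation")["onset_latency_ms"].mean()
        assert lat[1] > lat[0]


class TestMeg:
    def test_fifteen_markers_per_trial(self, default_effects):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        sim = gen_meg(d, default_effects, 8)
        per_trial = sim.markers.groupby(["subject", "stimulation", "trial"]).size()
        assert (per_trial == d.stim_train.n_pulses).all()
        assert d.stim_train.n_pulses == 15

    def test_zero_artifact_amplitude_leaves_signal_clean(self):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        e = EffectSpec(artifact_amplitude_sd=1e-12)
        sim = gen_meg(d, e, 8)
        key = (0, 1)
        np.testing.assert_allclose(sim.signals[key].values(), sim.clean[key],
                                   atol=1e-6)

    def test_alpha_suppression_in_generated_occipital_power(self):
        d = StudyDesign(n_subjects=2, n_blocks_est=2)
        e = EffectSpec(alpha_effect=0.5, artifact_amplitude_sd=1e-12,
                       meg_noise_sd=0.1)
        sim = gen_meg(d, e, 3, effect_window_s=(0.0, 5.0))
        powers = {0: [], 1: []}
        for (subj, stim), sig in sim.signals.items():
            rate = sig.rate
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            x = sig.channels["om1"].to_numpy()
            for onset in ev["onset_s"]:
                seg = x[int(onset * rate): int((onset + 5) * rate)]
                f, p = sps.welch(seg, fs=rate, nperseg=1024)
                band = (f >= 8.5) & (f <= 13)
                powers[stim].append(p[band].mean())
        assert np.mean(powers[1]) < np.mean(powers[0])

    def test_unknown_channel_group_rejected(self, tiny_design, default_effects):
        with pytest.raises(ValueError):
            gen_meg(tiny_design, default_effects, 1,
                    channel_groups={"temporal": ["t1"]})
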