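"""Two-pass MAD cleaning, epoching, rejection rules, normalization."""

import numpy as np
import pandas as pd
import pytest

from phasicvns.containers import PupilTrace
from phasicvns.design import StudyDesign, EffectSpec
from phasicvns.pupil_preprocess import (CleanConfig, dilation_speed,
                                        mad_threshold, moving_average,
                                        two_pass_clean, epoch_trials,
                                        reject_missing, normalize_epochs,
                                        preprocess_session)
from phasicvns.synth import gen_pupil_est


def make_trace(pupil, rate=500.0, missing=None):
    pupil = np.asarray(pupil, dtype=float)
    t = np.arange(pupil.size) / rate
    if missing is None:
        missing = np.zeros(pupil.size, dtype=bool)
    return PupilTrace(t, pupil, missing)


class TestDilationSpeed:
    def test_constant_trace_zero_speed(self):
        s = dilation_speed(make_trace(np.full(100, 5.0)))
        np.testing.assert_allclose(s, 0.0)

    def test_linear_ramp_speed_equals_slope(self):
        k = 3.7
        tr = make_trace(k * np.arange(200) / 500.0)
        s = dilation_speed(tr)
        np.testing.assert_allclose(s, abs(k), rtol=1e-9)

    def test_unit_spike_speed_at_spike_and_neighbors(self):
        # unit spike, 2 ms sampling -> 500 units/s at spike and both neighbors
        p = np.zeros(50)
        p[25] = 1.0
        s = dilation_speed(make_trace(p, rate=500.0))
        assert s[25] == pytest.approx(500.0)
        assert s[24] == pytest.approx(500.0)
        assert s[26] == pytest.approx(500.0)

    def test_missing_samples_propagate(self):
        missing = np.zeros(50, dtype=bool)
        missing[10] = True
        p = np.arange(50.0)
        p[10] = np.nan
        s = dilation_speed(make_trace(p, missing=missing))
        assert np.isnan(s[10])
        assert np.isfinite(s[9]) and np.isfinite(s[11])

    def test_too_few_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            dilation_speed(make_trace([1.0, 2.0], rate=500.0))


class TestMadThreshold:
    def test_worked_example(self):
        assert mad_threshold(np.array([1, 2, 3, 4, 5.0]), 2.5) == pytest.approx(5.5)

    def test_constant_series(self):
        assert mad_threshold(np.full(10, 4.2), 2.5) == pytest.approx(4.2)

    def test_outlier_above_threshold(self):
        series = np.array([1, 1, 1, 1, 10.0])
        thr = mad_threshold(series, 2.5)
        assert thr == pytest.approx(1.0)
        assert (series > thr).sum() == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mad_threshold(np.full(5, np.nan), 2.5)


class TestMovingAverage:
    def test_preserves_linear_trend_in_interior(self):
        x = np.arange(100.0)
        out = moving_average(x, 9)
        np.testing.assert_allclose(out[10:-10], x[10:-10])

    def test_shrinking_edges_stay_finite(self):
        out = moving_average(np.arange(20.0), 11)
        assert np.all(np.isfinite(out))


class TestTwoPassClean:
    def test_clean_smooth_trace_untouched(self):
        t = np.arange(3000) / 500.0
        p = 4000 + 100 * np.sin(2 * np.pi * 1.0 * t)
        cleaned, removed = two_pass_clean(make_trace(p))
        assert removed.sum() == 0
        np.testing.assert_array_equal(cleaned.pupil, p)

    def test_spikes_flagged_clean_samples_kept(self):
        d = StudyDesign(n_subjects=2, n_blocks_est=1)
        e = EffectSpec(noise_sd=0.0, blink_rate=0.6)
        sim = gen_pupil_est(d, e, 21)
        hits = n_art = false = n_clean = 0
        for key, trace in sim.traces.items():
            art = sim.artifact[key]
            _, removed = two_pass_clean(trace)
            hits += (removed & art).sum()
            n_art += art.sum()
            clean_mask = ~art & ~trace.missing
            false += (removed & clean_mask).sum()
            n_clean += clean_mask.sum()
        assert hits / n_art >= 0.95
        assert false / n_clean <= 0.01

    def test_leading_gap_not_extrapolated(self):
        p = np.sin(np.arange(1000) / 100.0) + 5
        missing = np.zeros(1000, dtype=bool)
        missing[:50] = True
        p = p.copy()
        p[:50] = np.nan
        cleaned, _ = two_pass_clean(make_trace(p, missing=missing))
        assert cleaned.missing[:50].all()
        assert np.isnan(cleaned.pupil[:50]).all()

    def test_idempotence(self):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        e = EffectSpec(noise_sd=0.0, blink_rate=0.5)
        sim = gen_pupil_est(d, e, 33)
        trace = sim.traces[(0, 0)]
        cleaned, removed1 = two_pass_clean(trace)
        _, removed2 = two_pass_clean(cleaned)
        # rerunning flags only the slope kinks the straight-line gap fills
        # leave at blink-gap edges, a small fraction of the trace
        assert removed2.sum() <= 5e-3 * cleaned.pupil.size

    def test_flagging_never_alters_unflagged_samples(self):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        sim = gen_pupil_est(d, EffectSpec(blink_rate=0.5), 3)
        trace = sim.traces[(0, 1)]
        cleaned, removed = two_pass_clean(trace)
        keep = ~removed & ~trace.missing & ~cleaned.missing
        np.testing.assert_array_equal(cleaned.pupil[keep], trace.pupil[keep])


class TestEpoching:
    def test_epoch_count_and_length(self):
        rate = 500.0
        n = int(300 * rate)
        trace = make_trace(np.random.default_rng(0).normal(4000, 10, n))
        onsets = 5 + 14 * np.arange(20)
        events = pd.DataFrame({"onset_s": onsets})
        eps = epoch_trials(trace, events, (-2.0, 5.0))
        assert eps.n_trials == 20
        assert eps.n_times == 3501

    def test_empty_events_give_empty_set(self):
        trace = make_trace(np.zeros(5000) + 1)
        eps = epoch_trials(trace, pd.DataFrame({"onset_s": []}), (-2.0, 5.0))
        assert eps.n_trials == 0

    def test_event_near_edge_flagged_not_dropped(self):
        trace = make_trace(np.ones(int(5 * 500)))
        eps = epoch_trials(trace, pd.DataFrame({"onset_s": [1.0]}), (-2.0, 5.0))
        assert eps.n_trials == 1
        assert eps.rejected[0]
        assert eps.reasons[0] == "edge"


class TestRejection:
    def _epochs(self, missing_fracs, subjects=None, stims=None):
        n_t = len(missing_fracs)
        data = np.ones((n_t, 100))
        missing = np.zeros((n_t, 100), dtype=bool)
        for k, f in enumerate(missing_fracs):
            missing[k, : int(f * 100)] = True
        labels = pd.DataFrame({
            "subject": subjects if subjects is not None else [0] * n_t,
            "stimulation": stims if stims is not None else [0] * n_t,
        })
        from phasicvns.containers import EpochSet
        return EpochSet(data=data, times=np.linspace(-2, 5, 100), labels=labels,
                        missing=missing)

    def test_trial_above_half_missing_rejected(self):
        eps = self._epochs([0.51, 0.0, 0.50])
        reject_missing(eps)
        assert list(eps.rejected) == [True, False, False]  # strictly > 50%

    def test_subject_with_majority_rejected_trials_excluded(self):
        fracs = [0.9] * 11 + [0.0] * 9      # 11 of 20 rejected -> 55% > 50%
        eps = self._epochs(fracs)
        report = reject_missing(eps)
        assert report["excluded_subjects"] == [0]
        assert eps.rejected.all()

    def test_subject_at_exactly_half_not_excluded(self):
        fracs = [0.9] * 10 + [0.0] * 10
        eps = self._epochs(fracs)
        report = reject_missing(eps)
        assert report["excluded_subjects"] == []


class TestNormalize:
    def _clean_epochs(self, n_trials=6, rate=500.0, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        times = -2.0 + np.arange(3501) / rate
        data = rng.normal(4000, 100, (n_trials, 3501))
        from phasicvns.containers import EpochSet
        labels = pd.DataFrame({"subject": [0] * n_trials,
                               "stimulation": [0] * n_trials})
        return EpochSet(data=data, times=times, labels=labels,
                        missing=np.zeros((n_trials, 3501), dtype=bool))

    def test_baseline_window_mean_zero(self):
        out = normalize_epochs(self._clean_epochs())
        bl = (out.times >= -0.2) & (out.times < 0)
        np.testing.assert_allclose(np.nanmean(out.data[:, bl], axis=1), 0.0,
                                   atol=1e-6)

    def test_decimation_to_100hz_gives_701_samples(self):
        out = normalize_epochs(self._clean_epochs())
        assert out.n_times == 701
        assert out.rate == pytest.approx(100.0)

    def test_constant_epochs_raise_zero_variance(self):
        eps = self._clean_epochs()
        eps.data[:] = 7.0
        with pytest.raises(ValueError, match="variance"):
            normalize_epochs(eps)

    def test_condition_difference_preserved_up_to_scale(self):
        # z-scoring + baselining is affine within session: the between-
        # condition post-stimulus difference keeps its sign and ordering
        eps = self._clean_epochs(n_trials=8)
        post = eps.times >= 0
        eps.data[4:, post] += 50.0
        eps.labels.loc[4:, "stimulation"] = 1
        out = normalize_epochs(eps)
        post_out = out.times >= 0.5
        d = (out.data[4:][:, post_out].mean()
             - out.data[:4][:, post_out].mean())
        assert d > 0


class TestSessionChain:
    def test_full_chain_produces_normalized_epochs(self):
        d = StudyDesign(n_subjects=1, n_blocks_est=1)
        sim = gen_pupil_est(d, EffectSpec(), 17)
        trace = sim.traces[(0, 0)]
        ev = sim.events.query("subject == 0 and stimulation == 0")
        eps, report = preprocess_session(trace, ev, d.epoch_est_s, CleanConfig())
        assert eps.n_times == 701
        assert report["n_trials"] == len(ev)
        bl = (eps.times >= -0.2) & (eps.times < 0)
        np.testing.assert_allclose(np.nanmean(eps.data[:, bl], axis=1), 0.0,
                                   atol=1e-6)
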