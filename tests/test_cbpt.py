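"""Cluster formation, permutation null, p values, effect sizes, TFR clusters."""

import numpy as np
import pytest
from scipy import stats

from phasicvns.cbpt import (PermScheme, Cluster, paired_t, form_clusters,
                            max_cluster_mass, sign_flip_null, cluster_p,
                            cluster_effect_sizes, cbpt_paired,
                            pointwise_lmm_chisq, tfr_cbpt)


class TestFormClusters:
    def test_worked_example_masses(self):
        stat = np.array([0.1, 3.2, 4.1, 0.3, 5.0])
        clusters = form_clusters(stat, threshold=2.0, signed=False)
        assert len(clusters) == 2
        assert clusters[0].indices.tolist() == [1, 2]
        assert clusters[0].mass == pytest.approx(7.3)
        assert clusters[1].indices.tolist() == [4]
        assert clusters[1].mass == pytest.approx(5.0)

    def test_all_subthreshold_empty(self):
        assert form_clusters(np.zeros(10), 1.0) == []

    def test_all_suprathreshold_single_cluster(self):
        clusters = form_clusters(np.full(8, 3.0), 1.0, signed=False)
        assert len(clusters) == 1
        assert clusters[0].indices.size == 8

    def test_signed_stats_split_by_direction(self):
        stat = np.array([3.0, 3.0, -3.0, -3.0])
        clusters = form_clusters(stat, 2.0, signed=True)
        assert sorted(c.direction for c in clusters) == [-1, 1]

    def test_nan_points_are_subthreshold(self):
        stat = np.array([3.0, np.nan, 3.0])
        clusters = form_clusters(stat, 2.0, signed=False)
        assert len(clusters) == 2


class TestClusterP:
    def test_floor_at_one_over_nperm(self):
        c = Cluster(indices=np.array([0]), mass=100.0, direction=1)
        null = np.zeros(10000)
        out = cluster_p([c], null)
        assert out[0].p == pytest.approx(1.0 / 10000)

    def test_median_mass_p_half(self):
        c = Cluster(indices=np.array([0]), mass=5.0, direction=1)
        null = np.concatenate([np.full(500, 1.0), np.full(500, 9.0)])
        assert cluster_p([c], null)[0].p == pytest.approx(0.5)

    def test_below_all_null_p_one(self):
        c = Cluster(indices=np.array([0]), mass=0.5, direction=1)
        assert cluster_p([c], np.ones(1000))[0].p == 1.0

    def test_ties_count_toward_null(self):
        c = Cluster(indices=np.array([0]), mass=2.0, direction=1)
        null = np.full(100, 2.0)
        assert cluster_p([c], null)[0].p == 1.0


class TestEffectSizes:
    def test_identical_conditions_zero(self):
        a = np.random.default_rng(0).normal(0, 1, (10, 20))
        c = Cluster(indices=np.arange(5, 10), mass=1.0, direction=1)
        cluster_effect_sizes(c, a, a.copy())
        assert c.d_avg == 0.0 and c.d_max == 0.0

    def test_constant_shift_closed_form(self):
        rng = np.random.default_rng(1)
        subj_shift = 1.0 + 0.5 * rng.normal(0, 1, 12)   # delta SD 0.5
        a = np.tile(subj_shift[:, None], (1, 30))
        b = np.zeros_like(a)
        c = Cluster(indices=np.arange(10, 20), mass=1.0, direction=1)
        cluster_effect_sizes(c, a, b)
        expected = subj_shift.mean() / subj_shift.std(ddof=1)
        assert c.d_avg == pytest.approx(expected)
        assert c.d_max == pytest.approx(expected)

    def test_d_max_location_at_effect_peak(self):
        rng = np.random.default_rng(2)
        n_sub, n_pts = 30, 60
        profile = np.exp(-0.5 * ((np.arange(n_pts) - 30) / 4.0) ** 2)
        a = profile[None, :] + rng.normal(0, 1, (n_sub, n_pts))
        b = rng.normal(0, 1, (n_sub, n_pts))
        c = Cluster(indices=np.arange(20, 41), mass=1.0, direction=1)
        cluster_effect_sizes(c, a, b)
        assert abs(c.d_max_loc - 30) <= 2

    def test_single_subject_rejected(self):
        c = Cluster(indices=np.array([0]), mass=1.0, direction=1)
        with pytest.raises(ValueError):
            cluster_effect_sizes(c, np.zeros((1, 5)), np.zeros((1, 5)))


class TestPermutationNull:
    def test_exhaustive_enumeration_for_three_subjects(self):
        delta = np.random.default_rng(3).normal(0, 1, (3, 12))
        with pytest.warns(UserWarning, match="exhaustively"):
            null = sign_flip_null(delta, PermScheme(n_perm=100, seed=0))
        assert null.size == 8

    def test_sampled_p_equals_exhaustive_for_tiny_designs(self):
        # with 2^n <= n_perm the engine enumerates, so the permutation p of
        # every observed cluster is an exact, seed-independent quantity
        rng = np.random.default_rng(4)
        delta = rng.normal(0.8, 1, (4, 15))
        thr = float(stats.t.ppf(0.975, 3))
        tobs = paired_t(delta)
        clusters = form_clusters(tobs, thr)
        with pytest.warns(UserWarning):
            null_a = sign_flip_null(delta, PermScheme(n_perm=100, seed=0))
            null_b = sign_flip_null(delta, PermScheme(n_perm=5000, seed=99))
        np.testing.assert_array_equal(np.sort(null_a), np.sort(null_b))
        pa = [c.p for c in cluster_p(clusters, null_a)]
        pb = [c.p for c in cluster_p(clusters, null_b)]
        assert pa == pb

    def test_same_seed_same_null(self):
        delta = np.random.default_rng(5).normal(0, 1, (25, 30))
        a = sign_flip_null(delta, PermScheme(n_perm=300, seed=7))
        b = sign_flip_null(delta, PermScheme(n_perm=300, seed=7))
        np.testing.assert_array_equal(a, b)


class TestCbptPaired:
    def test_detects_injected_effect(self):
        rng = np.random.default_rng(6)
        n_sub, n_pts = 24, 80
        a = rng.normal(0, 1, (n_sub, n_pts))
        b = rng.normal(0, 1, (n_sub, n_pts))
        a[:, 30:50] += 1.0
        clusters = cbpt_paired(a, b, PermScheme(n_perm=500, seed=1))
        sig = [c for c in clusters if c.p <= 0.05]
        assert sig
        best = max(sig, key=lambda c: abs(c.mass))
        lo, hi = best.extent
        assert lo < 50 and hi >= 30        # overlaps the injected window

    def test_monotone_detection_in_effect_size(self):
        rates = []
        for eff in (0.0, 0.6, 1.2):
            det = 0
            for rep in range(20):
                rng = np.random.default_rng(100 * rep + int(eff * 10))
                a = rng.normal(0, 1, (16, 50))
                b = rng.normal(0, 1, (16, 50))
                a[:, 20:35] += eff
                cl = cbpt_paired(a, b, PermScheme(n_perm=200, seed=rep))
                det += any(c.p <= 0.05 for c in cl)
            rates.append(det / 20)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9

    def test_agrees_with_mne_cluster_test(self):
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(8)
        delta = rng.normal(0, 1, (18, 60))
        delta[:, 10:25] += 0.9
        thr = float(stats.t.ppf(0.975, 17))
        ours = cbpt_paired(delta, np.zeros_like(delta),
                           PermScheme(n_perm=1000, seed=3))
        t_obs, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            delta, threshold=thr, n_permutations=1000, tail=0, seed=4,
            out_type="indices", verbose=False)
        mne_sig = {tuple(int(i) for i in np.atleast_1d(m[0]))
                   for m, p in zip(clusters, pvals) if p <= 0.05}
        our_sig = {tuple(int(i) for i in c.indices) for c in ours if c.p <= 0.05}
        assert our_sig == mne_sig


class TestPointwiseLMM:
    def _long(self, effect_pts, n_subj=14, n_pts=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            u = rng.normal(0, 0.3)
            for trial in range(8):
                x = trial % 2
                for pt in range(n_pts):
                    mu = u + (0.8 * x if pt in effect_pts else 0.0)
                    rows.append((s, trial, x, pt, mu + rng.normal(0, 0.4)))
        import pandas as pd
        return pd.DataFrame(rows, columns=["subject", "trial", "x", "point", "y"])

    def test_statistic_elevated_at_effect_points(self):
        df = self._long(effect_pts={2, 3})
        chisq = pointwise_lmm_chisq(df, "y", "x", "x", groups="subject")
        inside = chisq[[2, 3]].mean()
        outside = np.delete(chisq, [2, 3]).mean()
        assert inside > 2 * outside

    def test_identical_outcome_identical_statistic(self):
        df = self._long(effect_pts=set())
        df["y"] = df.groupby(["subject", "trial"])["y"].transform("first")
        chisq = pointwise_lmm_chisq(df, "y", "x", "x", groups="subject")
        np.testing.assert_allclose(chisq, chisq[0], atol=1e-6)


class TestTfrCbpt:
    def _adj(self, n):
        a = np.zeros((n, n), dtype=int)
        for i in range(n - 1):
            a[i, i + 1] = a[i + 1, i] = 1
        return a

    def test_degenerate_single_sensor_single_freq_matches_1d(self):
        rng = np.random.default_rng(9)
        delta = rng.normal(0, 1, (12, 40))
        delta[:, 10:20] += 1.2
        tfr_a = delta[:, None, None, :]
        tfr_b = np.zeros_like(tfr_a)
        times = np.linspace(0.6, 5.0, 40)
        res3d = tfr_cbpt(tfr_a, tfr_b, np.zeros((1, 1), int),
                         PermScheme(n_perm=300, seed=2), times=times)
        res1d = cbpt_paired(delta, np.zeros_like(delta),
                            PermScheme(n_perm=300, seed=2))
        m3 = {(tuple(c.indices % 40), round(c.mass, 6)) for c in res3d}
        m1 = {(tuple(c.indices), round(c.mass, 6)) for c in res1d}
        assert m3 == m1

    def test_detects_injected_tf_effect(self):
        rng = np.random.default_rng(10)
        n_sub, n_sens, n_f, n_t = 16, 3, 10, 30
        a = rng.normal(0, 1, (n_sub, n_sens, n_f, n_t))
        b = rng.normal(0, 1, (n_sub, n_sens, n_f, n_t))
        a[:, 1:, 4:8, 10:20] -= 1.0        # occipital-like alpha suppression
        clusters = tfr_cbpt(a, b, self._adj(n_sens),
                            PermScheme(n_perm=300, seed=5))
        sig = [c for c in clusters if c.p <= 0.05 and c.direction == -1]
        assert sig

    def test_window_outside_support_rejected(self):
        a = np.zeros((5, 1, 2, 10))
        with pytest.raises(ValueError):
            tfr_cbpt(a, a, np.zeros((1, 1), int), PermScheme(n_perm=100),
                     times=np.linspace(-1, 0, 10))
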