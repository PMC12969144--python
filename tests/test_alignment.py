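"""plvs, surrogate-null, cluster-permutation, slope and paired-t tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import special, stats

from respalign.alignment import (
    cluster_permutation,
    paired_t,
    plvs,
    plvs_slope,
    surrogate_threshold,
)
from respalign.types import EpochedPhase, InsufficientDataError


def make_epochs(phase_matrix, fs=20.0, valid=None):
    phase_matrix = np.atleast_2d(np.asarray(phase_matrix, dtype=float))
    n_times = phase_matrix.shape[1]
    rel = (np.arange(n_times) - n_times // 2) / fs
    if valid is None:
        valid = np.ones_like(phase_matrix, dtype=bool)
    return EpochedPhase(phase=phase_matrix, valid=valid, rel_times=rel, fs=fs)


class TestPlvs:
    def test_identical_phases_give_one(self):
        ep = make_epochs(np.full((8, 5), 1.3))
        np.testing.assert_allclose(plvs(ep, min_trials=1).plvs, 1.0)

    def test_symmetric_quartet_cancels(self):
        ep = make_epochs(np.array([[0.0], [np.pi / 2], [np.pi], [3 * np.pi / 2]]))
        np.testing.assert_allclose(plvs(ep, min_trials=1).plvs, 0.0, atol=1e-12)

    def test_two_phase_pair(self):
        ep = make_epochs(np.array([[0.0], [np.pi / 2]]))
        np.testing.assert_allclose(plvs(ep, min_trials=1).plvs, np.sqrt(2) / 2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 2 * np.pi, size=(30, 11))
        a = plvs(make_epochs(ph), min_trials=1).plvs
        b = plvs(make_epochs(np.mod(ph + 1.234, 2 * np.pi)), min_trials=1).plvs
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_min_trials_masks_result(self):
        ph = np.zeros((4, 3))
        valid = np.ones_like(ph, dtype=bool)
        valid[:, 1] = [True, False, False, False]
        res = plvs(make_epochs(ph, valid=valid), min_trials=2)
        assert np.isnan(res.plvs[1])
        assert res.plvs[0] == 1.0

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0])
    def test_bessel_ratio_at_epoch_center(self, kappa):
        """plvs of von Mises phases matches I1(k)/I0(k) within 3 MC SEs."""
        n = 400
        rng = np.random.default_rng(42 + int(kappa))
        ph = np.mod(rng.vonmises(np.pi, max(kappa, 1e-12), size=(n, 1)), 2 * np.pi)
        observed = plvs(make_epochs(ph), min_trials=1).plvs[0]
        expected = special.i1(kappa) / special.i0(kappa) if kappa > 0 else 0.0
        reps = np.abs(np.exp(1j * rng.vonmises(np.pi, max(kappa, 1e-12),
                                               size=(200, n))).mean(axis=1))
        assert abs(observed - expected - (reps.mean() - expected)) <= 3 * reps.std(ddof=1)


class TestSurrogate:
    @staticmethod
    def _ramp_epochs(rng, n_trials, n_times, locked=True, fs=20.0):
        """Breathing-like phase ramps; trial-locked at the epoch center if asked."""
        period = 4.0
        t = (np.arange(n_times) - n_times // 2) / fs
        if locked:
            offsets = np.zeros(n_trials)
        else:
            offsets = rng.uniform(0, period, size=n_trials)
        ph = 2 * np.pi * (t[None, :] + offsets[:, None]) / period
        return make_epochs(np.mod(ph, 2 * np.pi), fs=fs)

    def test_null_rejection_rate_controlled(self):
        """Uniform (unlocked) epochs exceed the corrected threshold at <= 2%."""
        rng = np.random.default_rng(5)
        n_sig = 0
        n_tot = 0
        for rep in range(5):
            eps = [self._ramp_epochs(rng, 80, 161, locked=False) for _ in range(8)]
            null = surrogate_threshold(eps, n_iter=400, conf=0.99,
                                       seed=1000 + rep, min_trials=10)
            n_sig += int(null.significant().sum())
            n_tot += null.observed.size
        rate = n_sig / n_tot
        assert rate <= 0.02 + 3 * np.sqrt(0.01 * 0.99 / n_tot)

    def test_locked_epochs_exceed_threshold(self):
        """Perfectly trial-locked ramps give plvs = 1, above any surrogate."""
        rng = np.random.default_rng(6)
        eps = [self._ramp_epochs(rng, 40, 81, locked=True) for _ in range(4)]
        null = surrogate_threshold(eps, n_iter=200, conf=0.99, seed=3)
        np.testing.assert_allclose(null.observed, 1.0)
        assert null.threshold < 1.0
        assert null.significant().all()

    def test_threshold_monotone_in_confidence(self):
        rng = np.random.default_rng(7)
        eps = [self._ramp_epochs(rng, 40, 81, locked=False) for _ in range(4)]
        hi = surrogate_threshold(eps, n_iter=300, conf=0.99, seed=9)
        lo = surrogate_threshold(eps, n_iter=300, conf=0.95, seed=9)
        assert hi.threshold >= lo.threshold

    def test_low_iteration_warning(self):
        rng = np.random.default_rng(8)
        eps = [self._ramp_epochs(rng, 20, 41, locked=False)]
        with pytest.warns(UserWarning):
            surrogate_threshold(eps, n_iter=50, conf=0.99, seed=1)


def brute_force_cluster_p(diff, rel_times, t_crit, min_len, target_sum):
    """Exhaustive sign-flip oracle: naive loop over all 2^P patterns."""
    P, T = diff.shape
    count = 0
    for pattern in range(2**P):
        signs = np.array([1.0 if pattern >> j & 1 else -1.0 for j in range(P)])
        d = signs[:, None] * diff
        m = d.mean(axis=0)
        s = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (s / np.sqrt(P))
        best = 0.0
        i = 0
        above = np.where(np.isfinite(t) & (np.abs(t) > t_crit), np.sign(t), 0.0)
        while i < T:
            if above[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < T and above[j + 1] == above[i]:
                j += 1
            if j - i + 1 >= min_len:
                best = max(best, abs(t[i : j + 1].sum()))
            i = j + 1
        if best >= target_sum:
            count += 1
    return count / 2**P


class TestClusterPermutation:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 60))
        res = cluster_permutation(a, a.copy(), np.arange(60) / 20.0, n_rand=200, seed=1)
        assert res.clusters == []

    def test_exhaustive_matches_brute_force_oracle(self):
        """Sign-flip null over all 2^10 patterns equals an independent oracle."""
        rng = np.random.default_rng(11)
        P, T = 10, 60
        rel = np.arange(T) / 20.0 - 1.5
        base = rng.normal(0, 0.05, size=(P, T))
        a = base.copy()
        a[:, 20:40] += 0.12  # 1 s planted offset
        b = np.zeros((P, T))
        res = cluster_permutation(a, b, rel, seed=0, exhaustive=True)
        assert len(res.clusters) >= 1
        top = max(res.clusters, key=lambda c: abs(c.max_sum_stat))
        p_oracle = brute_force_cluster_p(a - b, rel, res.t_crit, 5,
                                         abs(top.max_sum_stat))
        assert top.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(12)
        P, T = 10, 60
        rel = np.arange(T) / 20.0
        a = rng.normal(0, 0.05, size=(P, T))
        a[:, 10:30] += 0.1
        b = np.zeros((P, T))
        exact = cluster_permutation(a, b, rel, seed=0, exhaustive=True)
        mc = cluster_permutation(a, b, rel, n_rand=4000, seed=5)
        pe = max(exact.clusters, key=lambda c: abs(c.max_sum_stat)).p_value
        pm = max(mc.clusters, key=lambda c: abs(c.max_sum_stat)).p_value
        se = np.sqrt(pe * (1 - pe) / 4000)
        assert abs(pm - pe) <= 3 * se + 2.0 / 4000

    def test_min_cluster_duration_five_samples_at_20hz(self):
        """Runs shorter than 250 ms (5 samples at 20 Hz) are never reported."""
        rng = np.random.default_rng(13)
        P, T = 12, 80
        rel = np.arange(T) / 20.0
        short = rng.normal(0, 0.02, size=(P, T))
        short[:, 30:34] += 0.5  # 4-sample run only
        res4 = cluster_permutation(short, np.zeros((P, T)), rel, n_rand=100, seed=2)
        assert all(not (c.t_start_s >= rel[29] and c.t_end_s <= rel[34])
                   for c in res4.clusters)
        longer = rng.normal(0, 0.02, size=(P, T))
        longer[:, 30:35] += 0.5  # 5-sample run qualifies
        res5 = cluster_permutation(longer, np.zeros((P, T)), rel, n_rand=100, seed=2)
        assert any(c.t_start_s <= rel[30] and c.t_end_s >= rel[34]
                   for c in res5.clusters)

    def test_type_one_error_rate(self):
        """Exchangeable smooth null: rejection rate at alpha=0.05 in [0.03, 0.07].

        The null traces are temporally smoothed (as respiratory plvs traces
        are); without smoothness almost no 250 ms run forms and the test is
        merely conservative.
        """
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(99)
        n_rej = 0
        n_rep = 500
        for rep in range(n_rep):
            diff = gaussian_filter1d(rng.normal(0, 1, size=(8, 40)), 4.0, axis=1)
            res = cluster_permutation(diff, np.zeros_like(diff),
                                      np.arange(40) / 20.0, n_rand=199,
                                      seed=rep)
            if any(c.p_value < 0.05 for c in res.clusters):
                n_rej += 1
        assert 0.03 <= n_rej / n_rep <= 0.07

    def test_too_few_participants(self):
        with pytest.raises(InsufficientDataError):
            cluster_permutation(np.zeros((1, 10)), np.zeros((1, 10)),
                                np.arange(10) / 20.0)


class TestSlope:
    rel = np.linspace(-8, 4, 241)

    def test_constant_trace_zero_slope(self):
        assert plvs_slope(np.full(241, 0.4), self.rel) == 0.0

    def test_min_max_arithmetic(self):
        vals = np.full(241, 0.35)
        vals[(self.rel >= -2) & (self.rel <= -1)] = 0.20
        vals[(self.rel >= 1) & (self.rel <= 2)] = 0.50
        assert plvs_slope(vals, self.rel) == pytest.approx(0.30)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            plvs_slope(np.zeros(41), np.linspace(-1, 1, 41))

    def test_robust_to_half_second_window_shift(self):
        """On a smooth ramp, shifting both windows by 0.5 s moves slope < 15%."""
        vals = 0.2 + 0.3 / (1.0 + np.exp(-self.rel / 1.2))
        base = plvs_slope(vals, self.rel)
        shifted = plvs_slope(vals, self.rel, pre_window=(-1.5, -0.5),
                             post_window=(1.5, 2.5))
        assert abs(shifted - base) / base < 0.15


class TestPairedT:
    def test_equal_samples(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_hand_computed_fixture(self):
        """Differences (0.2,0.1,0.3,0.15,0.25): t = 5.657, D = 2.530."""
        b = np.zeros(5)
        a = np.array([0.2, 0.1, 0.3, 0.15, 0.25])
        res = paired_t(a, b)
        assert res.t == pytest.approx(5.6569, abs=1e-3)
        assert res.cohens_d == pytest.approx(2.5298, abs=1e-3)
        # independent check against scipy
        t_sp, p_sp = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t_sp)
        assert res.p == pytest.approx(p_sp)

    def test_consistent_sign_for_small_jitter(self):
        rng = np.random.default_rng(3)
        d = 1.0 + rng.normal(0, 1e-6, size=4)
        res = paired_t(d, np.zeros(4))
        assert res.t > 1e4 and res.cohens_d > 1e4

    def test_zero_variance_nonzero_mean(self):
        res = paired_t(np.full(4, 0.3), np.zeros(4))
        assert np.isinf(res.cohens_d) and res.cohens_d > 0
        assert np.isnan(res.t)
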